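import numpy as np
import pandas as pd
import pytest

from rrgwas import (
    GenotypeMatrix,
    IntervalSet,
    KinshipMatrix,
    allele_frequencies,
    bonferroni_threshold,
    enrichment_coefficient,
    filter_snps,
    hwe_test,
    ld_prune,
    ld_r2,
    vanraden_kinship,
)
from rrgwas.genotype_qc import MISSING


def make_geno(codes, positions=None, chrom="1"):
    codes = np.asarray(codes)
    n_ind, n_snps = codes.shape
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(n_snps)],
            "chromosome": chrom,
            "position": positions if positions is not None else np.arange(1, n_snps + 1) * 100,
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeMatrix(codes, meta, [f"i{i}" for i in range(n_ind)])


# ---------------------------------------------------------------- frequencies

def test_allele_frequencies_with_and_without_missing():
    # columns: balanced [0,1,2], fixed [2,2,2], and [0,1,2,2,NA] (hand count 5/8)
    codes = np.array(
        [[0, 2, 0], [1, 2, 1], [2, 2, 2], [1, 2, 2], [2, 2, MISSING]]
    )
    p = allele_frequencies(make_geno(codes[:3, :]))
    assert p[0] == pytest.approx(0.5)
    assert p[1] == pytest.approx(1.0)
    g2 = make_geno(np.array([[0], [1], [2], [2], [MISSING]]))
    assert allele_frequencies(g2)[0] == pytest.approx(5 / 8)


def test_allele_frequencies_all_missing_names_snp():
    g = make_geno(np.array([[MISSING], [MISSING]]))
    with pytest.raises(ValueError, match="s0"):
        allele_frequencies(g)


def test_invalid_codes_rejected():
    with pytest.raises(ValueError, match="invalid genotype codes"):
        make_geno(np.array([[3]]))


# ------------------------------------------------------------------------ HWE

@pytest.mark.parametrize(
    "counts,p_expected",
    [((25, 50, 25), 1.0), ((100, 0, 0), 1.0)],
)
def test_hwe_exact_proportions_and_monomorphic(counts, p_expected):
    assert hwe_test(*counts) == pytest.approx(p_expected)


def test_hwe_chi2_hand_value():
    # p=0.5, expected (25,50,25), chi2 = 1+2+1 = 4
    assert hwe_test(30, 40, 30) == pytest.approx(0.0455, abs=2e-4)


def test_hwe_negative_counts():
    with pytest.raises(ValueError):
        hwe_test(-1, 2, 3)


# --------------------------------------------------------------------- filter

def test_filter_removes_low_maf_and_hwe_failures():
    rng = np.random.default_rng(0)
    low_maf = rng.binomial(2, 0.02, 200)
    hwe_bad = np.array([0] * 60 + [1] * 80 + [2] * 60)  # (60,80,60): chi2 = 4
    good = rng.binomial(2, 0.5, 200)
    g = make_geno(np.column_stack([low_maf, hwe_bad, good]))
    filtered, report = filter_snps(g, maf_min=0.03, hwe_p_min=0.05)
    assert filtered.snp_meta["snp_id"].tolist() == ["s2"]
    reasons = dict(zip(report["snp_id"], report["reason"]))
    assert reasons == {"s0": "MAF", "s1": "HWE"}


def test_filter_is_idempotent():
    rng = np.random.default_rng(1)
    g = make_geno(rng.binomial(2, rng.uniform(0.01, 0.5, 40), size=(100, 40)))
    once, _ = filter_snps(g)
    twice, rep = filter_snps(once)
    assert np.array_equal(once.codes, twice.codes)
    assert rep.empty


# -------------------------------------------------------------------- kinship

def test_vanraden_single_snp_hand_value():
    g = make_geno(np.array([[2], [0]]))
    K = vanraden_kinship(g, np.array([0.5]))
    # centered code 1, denominator 2*0.25 -> self-relationship 2.0
    assert K.values[0, 0] == pytest.approx(2.0)


def test_vanraden_duplicate_rows():
    rng = np.random.default_rng(2)
    row = rng.binomial(2, 0.4, 50)
    g = make_geno(np.vstack([row, row]))
    K = vanraden_kinship(g)
    assert K.values[0, 1] == pytest.approx(K.values[0, 0])
    assert K.values[0, 1] == pytest.approx(K.values[1, 1])


def test_vanraden_diagonal_scaling():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.1, 0.5, 500)
    codes = rng.binomial(2, p, size=(200, 500))
    K = vanraden_kinship(make_geno(codes), p)
    assert np.mean(np.diag(K.values)) == pytest.approx(1.0, abs=0.05)


def test_vanraden_column_order_invariance():
    rng = np.random.default_rng(4)
    codes = rng.binomial(2, 0.3, size=(30, 20))
    g = make_geno(codes)
    perm = rng.permutation(20)
    gp = g.subset_snps(perm)
    K1 = vanraden_kinship(g)
    K2 = vanraden_kinship(gp)
    assert np.allclose(K1.values, K2.values)


def test_vanraden_monomorphic_panel_errors():
    g = make_geno(np.array([[2, 2], [2, 2]]))
    with pytest.raises(ValueError, match="monomorphic"):
        vanraden_kinship(g)


# ------------------------------------------------------------------------- LD

def test_ld_r2_hand_values():
    assert ld_r2([0, 1, 2, 2], [0, 1, 2, 2]) == pytest.approx(1.0)
    assert ld_r2([0, 1, 2, 2], [0, 1, 2, 0]) == pytest.approx((1.25 / 2.75) ** 2)
    with pytest.warns(UserWarning):
        assert ld_r2([1, 1, 1, 1], [0, 1, 2, 0]) == 0.0


def test_ld_prune_independent_panel_keeps_nearly_all():
    rng = np.random.default_rng(5)
    codes = rng.binomial(2, rng.uniform(0.2, 0.5, 120), size=(200, 120))
    g = make_geno(codes)
    kept = ld_prune(g)
    assert len(kept) >= 0.95 * 120


def test_ld_prune_duplicate_pair_and_triplet():
    rng = np.random.default_rng(6)
    base = rng.binomial(2, 0.5, size=(100, 10))
    base[:, 4] = base[:, 3]  # duplicated pair
    g = make_geno(base)
    kept = ld_prune(g)
    assert len(kept) == 9 and ("s3" in kept) != ("s4" in kept)

    # a perfectly correlated triplet loses two members
    tri = rng.binomial(2, 0.5, size=(100, 10))
    tri[:, 5] = tri[:, 2]
    tri[:, 8] = tri[:, 2]
    g2 = make_geno(tri)
    kept2 = ld_prune(g2)
    assert len(kept2) == 8
    assert sum(s in kept2 for s in ("s2", "s5", "s8")) == 1


def test_ld_prune_requires_sorted_positions():
    g = make_geno(np.array([[0, 1], [1, 2], [2, 0]]), positions=[200, 100])
    with pytest.raises(ValueError, match="sort"):
        ld_prune(g)


# ---------------------------------------------------------------- thresholds

def test_bonferroni_values():
    assert bonferroni_threshold(0.05, 45573) == pytest.approx(1.097e-6, rel=1e-3)
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


# ----------------------------------------------------------------- enrichment

def test_enrichment_toy_coefficient():
    regions = IntervalSet([("1", 1, 100)], genome_size=1000)
    positions = [("1", 10 * i + 1) for i in range(10)]  # 5 in, 5 out
    flags = [True] * 10
    coef, expected = enrichment_coefficient(positions, flags, regions)
    # hand check: first five positions (1..41) inside [1,100]? 1,11,21,31,41 in; 51..91 in too
    # use explicit placement instead
    positions = [("1", p) for p in [10, 20, 30, 40, 50, 150, 250, 350, 450, 550]]
    coef, expected = enrichment_coefficient(positions, flags, regions)
    assert coef == pytest.approx((5 / 100) / (5 / 900))
    assert expected == pytest.approx(10 * 100 / 1000)


def test_enrichment_expected_by_chance_paper_style():
    # 84 significant SNPs, regions covering 6.25% of the genome
    genome = 100_000
    regions = IntervalSet([("1", 1, 6250)], genome_size=genome)
    pos = [("2", 10 * (i + 1)) for i in range(84)]
    _, expected = enrichment_coefficient(pos, [True] * 84, regions)
    assert expected == pytest.approx(84 * 0.0625)
    assert round(expected) == 5


def test_enrichment_uniform_null_is_near_one():
    rng = np.random.default_rng(7)
    regions = IntervalSet([("1", 1, 50_000)], genome_size=1_000_000).merged()
    coefs = []
    for _ in range(200):
        pos = [("1", int(p)) for p in rng.integers(1, 1_000_001, size=40)]
        c, _ = enrichment_coefficient(pos, [True] * 40, regions)
        coefs.append(c)
    assert np.mean(coefs) == pytest.approx(1.0, abs=0.25)


def test_enrichment_all_inside_is_infinite():
    regions = IntervalSet([("1", 1, 100)], genome_size=1000)
    coef, _ = enrichment_coefficient([("1", 50)], [True], regions)
    assert np.isinf(coef)


def test_intervalset_merge_and_bed3(tmp_path):
    ivs = IntervalSet([("1", 10, 20), ("1", 15, 30), ("2", 5, 8)], 1000).merged()
    assert ivs.intervals == [("1", 10, 30), ("2", 5, 8)]
    bed = tmp_path / "r.bed"
    bed.write_text("1\t9\t30\n2\t4\t8\n")
    got = IntervalSet.from_bed3(bed, 1000)
    assert got.intervals == [("1", 10, 30), ("2", 5, 8)]
    assert got.contains("1", 10) and not got.contains("1", 9)
    assert got.contains("1", 30) and not got.contains("1", 31)


def test_kinship_align_subset_and_missing():
    K = KinshipMatrix(np.array([[1.0, 0.2], [0.2, 1.0]]), ["a", "b"])
    sub = K.align(["b", "a"])
    assert sub[0, 1] == pytest.approx(0.2) and sub[0, 0] == 1.0
    with pytest.raises(KeyError):
        K.align(["a", "z"])
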