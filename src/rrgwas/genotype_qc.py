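"""Genotype containers, quality control, kinship and multiple-testing helpers.

Genotypes are allele-count codes 0/1/2 (copies of the second/effect allele,
so aa -> 0, Aa -> 1, AA -> 2) with ``-1`` as the missing sentinel.  The module
provides the MAF and Hardy-Weinberg filters, the VanRaden genomic
relationship matrix K = MM'/(2 Σ p_i(1-p_i)), PLINK-style windowed LD
pruning used to count effective tests for the Bonferroni threshold, and the
per-bp enrichment coefficient of significant SNPs inside annotated QTL
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "KinshipMatrix",
    "IntervalSet",
    "allele_frequencies",
    "hwe_test",
    "filter_snps",
    "vanraden_kinship",
    "ld_r2",
    "ld_prune",
    "bonferroni_threshold",
    "enrichment_coefficient",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs allele-count matrix with SNP metadata.

    ``codes`` is an integer array with entries in {0, 1, 2, MISSING};
    ``snp_meta`` is a DataFrame with columns snp_id, chromosome, position,
    allele1, allele2 (one row per SNP column, in order).
    """

    codes: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x snps)")
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        if self.codes.shape != (len(self.individual_ids), len(self.snp_meta)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_meta)} SNPs"
            )
        ids = self.snp_meta["snp_id"]
        if ids.duplicated().any():
            raise ValueError(f"duplicate SNP ids: {ids[ids.duplicated()].tolist()}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def subset_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            codes=self.codes[:, idx],
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
            individual_ids=list(self.individual_ids),
        )


@dataclass
class KinshipMatrix:
    """Symmetric marker-derived relationship matrix with individual labels."""

    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match individual ids")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("kinship matrix is not symmetric")

    def align(self, ids: list[str]) -> np.ndarray:
        """Kinship submatrix in the order of ``ids``."""
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"individuals absent from kinship: {missing[:10]}")
        idx = np.array([pos[g] for g in ids])
        return self.values[np.ix_(idx, idx)]


@dataclass
class IntervalSet:
    """Genomic intervals (1-based, inclusive) plus the total genome size."""

    intervals: list[tuple[str, int, int]]
    genome_size: int

    def merged(self) -> "IntervalSet":
        """Non-overlapping union of the intervals."""
        out: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in self.intervals:
            if s >= e:
                raise ValueError(f"invalid interval {c}:{s}-{e}")
            by_chrom.setdefault(str(c), []).append((s, e))
        for c in sorted(by_chrom):
            ivs = sorted(by_chrom[c])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((c, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((c, cur_s, cur_e))
        return IntervalSet(out, self.genome_size)

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == str(chrom) and s <= pos <= e for c, s, e in self.intervals)

    @classmethod
    def from_bed3(cls, path, genome_size: int) -> "IntervalSet":
        """Read BED3 (0-based half-open) and convert to 1-based inclusive."""
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split()[:3]
                ivs.append((chrom, int(start) + 1, int(end)))
        return cls(ivs, genome_size)


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Second-allele frequency p_i per SNP from non-missing calls."""
    codes = geno.codes
    obs = codes != MISSING
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        bad = geno.snp_meta["snp_id"][n_obs == 0].tolist()
        raise ValueError(f"SNP(s) with no non-missing calls: {bad}")
    total = np.where(obs, codes, 0).sum(axis=0)
    return total / (2.0 * n_obs)


def hwe_test(n_aa: int, n_Aa: int, n_AA: int) -> float:
    """1-df chi-squared goodness-of-fit p-value against HWE proportions.

    A monomorphic SNP is in trivial equilibrium (p = 1).
    """
    counts = np.array([n_aa, n_Aa, n_AA], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotype calls")
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    stat = np.sum((counts - expected) ** 2 / expected)
    return float(stats.chi2.sf(stat, df=1))


def filter_snps(
    geno: GenotypeMatrix,
    maf_min: float = 0.03,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """MAF / HWE filter.

    Keeps SNPs with minor-allele frequency >= ``maf_min`` and HWE
    goodness-of-fit p-value >= ``hwe_p_min``.  Returns the filtered matrix
    and a report DataFrame (snp_id, reason, value) of removals.
    """
    p = allele_frequencies(geno)
    maf = np.minimum(p, 1 - p)
    keep = np.ones(geno.n_snps, dtype=bool)
    report_rows = []
    for j in range(geno.n_snps):
        if maf[j] < maf_min:
            keep[j] = False
            report_rows.append((geno.snp_meta["snp_id"].iat[j], "MAF", maf[j]))
            continue
        col = geno.codes[:, j]
        col = col[col != MISSING]
        hwe_p = hwe_test(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
        if hwe_p < hwe_p_min:
            keep[j] = False
            report_rows.append((geno.snp_meta["snp_id"].iat[j], "HWE", hwe_p))
    if not keep.any():
        warnings.warn("all SNPs removed by QC filters")
    report = pd.DataFrame(report_rows, columns=["snp_id", "reason", "value"])
    return geno.subset_snps(keep), report


def vanraden_kinship(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> KinshipMatrix:
    """VanRaden genomic relationship matrix K = MM' / (2 Σ p_i(1-p_i)).

    Column i of M is the genotype code centered by twice the allele
    frequency; missing codes contribute 0 after centering (mean
    imputation).
    """
    if freqs is None:
        freqs = allele_frequencies(geno)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (geno.n_snps,):
        raise ValueError("freqs not aligned with SNP columns")
    denom = 2.0 * np.sum(freqs * (1 - freqs))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    M = np.where(geno.codes == MISSING, 0.0, geno.codes - 2.0 * freqs)
    K = (M @ M.T) / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(geno.individual_ids))


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype-code vectors.

    Computed over pairwise-complete individuals; a zero-variance vector
    gives r² = 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete genotype calls")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        warnings.warn("zero-variance genotype column in LD computation; r2 set to 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    geno: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> list[str]:
    """Windowed greedy LD pruning (PLINK ``--indep-pairwise`` style).

    Within each ``window``-SNP window on a chromosome, any pair with
    r² > ``r2_max`` loses one member (the lower-MAF SNP; ties remove the
    later position); the window then advances by ``step`` SNPs.  SNPs must
    be sorted by (chromosome, position).  Returns retained SNP ids in
    input order.
    """
    meta = geno.snp_meta
    for _, grp in meta.groupby("chromosome", sort=False):
        if not grp["position"].is_monotonic_increasing:
            raise ValueError("SNPs must be sorted by (chromosome, position) before pruning")
    p = allele_frequencies(geno)
    maf = np.minimum(p, 1 - p)
    removed = np.zeros(geno.n_snps, dtype=bool)
    for _, grp in meta.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        start = 0
        while True:
            win = [j for j in idx[start : start + window] if not removed[j]]
            changed = True
            while changed:
                changed = False
                for a_i in range(len(win)):
                    for b_i in range(a_i + 1, len(win)):
                        ja, jb = win[a_i], win[b_i]
                        if ld_r2(geno.codes[:, ja], geno.codes[:, jb]) > r2_max:
                            if maf[ja] < maf[jb]:
                                drop = ja
                            elif maf[jb] < maf[ja]:
                                drop = jb
                            else:  # tie: drop the later position
                                drop = jb
                            removed[drop] = True
                            win.remove(drop)
                            changed = True
                            break
                    if changed:
                        break
            if start + window >= len(idx):
                break
            start += step
    return meta["snp_id"][~removed].tolist()


def bonferroni_threshold(alpha: float = 0.05, m_eff: int = 1) -> float:
    """Genome-wide significance threshold alpha / (effective test count)."""
    if m_eff < 1:
        raise ValueError("m_eff must be at least 1")
    return alpha / m_eff


def enrichment_coefficient(
    snp_positions: list[tuple[str, int]],
    significant_flags,
    regions: IntervalSet,
) -> tuple[float, float]:
    """Per-bp enrichment of significant SNPs inside annotated regions.

    Returns ``(coefficient, expected_in_regions_by_chance)`` where the
    coefficient is (significant per bp inside) / (significant per bp
    outside) and the expectation is n_significant × (region fraction of
    the genome).  The coefficient is 1 when significant SNPs fall
    uniformly, and +inf when all of them are inside the regions.
    """
    if regions.genome_size <= 0:
        raise ValueError("genome_size must be positive")
    merged = regions.merged()
    L_in = merged.total_length
    L_out = regions.genome_size - L_in
    if L_out <= 0:
        raise ValueError("regions cover the whole genome")
    flags = np.asarray(significant_flags, dtype=bool)
    sig_positions = [pos for pos, f in zip(snp_positions, flags) if f]
    n_sig = len(sig_positions)
    n_in = sum(merged.contains(c, p) for c, p in sig_positions)
    n_out = n_sig - n_in
    expected = n_sig * L_in / regions.genome_size
    if n_out == 0:
        coef = float("inf") if n_in > 0 else float("nan")
    else:
        coef = (n_in / L_in) / (n_out / L_out)
    return coef, expected
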