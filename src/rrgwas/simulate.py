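"""Synthetic test-day data and the type-I-error / power simulation studies.

The generator emulates the structure of a dairy test-day data set at desk
scale: paternal half-sib families (sires drawn from the population, each
offspring receiving one sire allele and one population allele) induce the
population structure and cryptic relatedness that the polygenic term must
absorb; each cow has ~10 monthly records over days-in-milk 5-305;
herd-test-date classes add a shared environmental shift per herd × test
slot; group mean curves follow a Wilmink-shaped lactation curve; and the
additive-genetic / permanent-environment trajectories are drawn from the
random-regression covariances u ~ N(0, K ⊗ G), p ~ N(0, I ⊗ P).

The two studies mirror the evaluation protocol of eigen-rotated
longitudinal GWAS: a null scan of SNPs simulated independently of the
phenotype (sharing only the family structure) to measure the empirical
type-I error and p-value uniformity, and a power study that injects a
time-varying QTN effect — Day-5 value 10.0, then a daily U(-1, 1) random
walk — scaled to k ∈ {0.04 ... 0.20} phenotypic standard deviations, with
detection judged at the empirical 5th-percentile threshold of the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BasisSpec, basis_matrix
from .engine import (
    PhenotypeTable,
    RotatedSystem,
    VarianceComponents,
    build_covariance_W,
    build_design,
    rotate_system,
    scan_snps,
    variance_curves,
)
from .genotype_qc import GenotypeMatrix, KinshipMatrix, vanraden_kinship

__all__ = [
    "SimConfig",
    "QtnEffect",
    "SimData",
    "default_variance_components",
    "simulate_population",
    "simulate_test_snps",
    "simulate_phenotypes",
    "simulate_dataset",
    "make_qtn_trajectory",
    "scale_qtn",
    "qtn_variance_fraction",
    "null_scan_study",
    "resample_phenotype_values",
    "power_study",
    "empirical_qtn_variance_fraction",
]

DEFAULT_SCHEDULE = tuple(range(5, 305, 30))  # 10 monthly tests: DIM 5..275


def default_variance_components(order: int = 2) -> VarianceComponents:
    """Dairy-plausible coefficient covariances for a normalized Legendre basis.

    Sized so the time-averaged variances are roughly additive 2.5,
    permanent 4, residual 4 (heritability ~0.24), the order of magnitude of
    milk-yield test-day records.
    """
    diag_G = np.array([5.0, 1.0, 0.3, 0.15, 0.08][: order + 1])
    diag_P = np.array([8.0, 2.0, 0.5, 0.25, 0.12][: order + 1])
    if order > 4:
        raise ValueError("default components defined for basis orders <= 4")
    G = np.diag(diag_G)
    P = np.diag(diag_P)
    if order >= 1:
        G[0, 1] = G[1, 0] = 0.5
        P[0, 1] = P[1, 0] = 1.0
    return VarianceComponents(G=G, P=P, sigma2_e=4.0)


def _default_specs(order: int = 2) -> dict:
    return {
        "mean_spec": BasisSpec(order=order),
        "snp_spec": BasisSpec(order=order),
        "add_spec": BasisSpec(order=order),
        "perm_spec": BasisSpec(order=order),
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    n_individuals: int = 300
    n_families: int = 30
    n_snps: int = 1000
    maf_law: tuple[float, float] = (0.05, 0.5)
    record_schedule: tuple = DEFAULT_SCHEDULE
    n_herds: int = 5
    htd_sd: float = 1.0
    group_labels: int = 2
    calving_spread: int = 25  # days of stagger between cows' calving dates
    true_vc: VarianceComponents = field(default_factory=default_variance_components)
    mean_spec: BasisSpec = field(default_factory=BasisSpec)
    snp_spec: BasisSpec = field(default_factory=BasisSpec)
    add_spec: BasisSpec = field(default_factory=BasisSpec)
    perm_spec: BasisSpec = field(default_factory=BasisSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > self.n_individuals:
            raise ValueError("n_families cannot exceed n_individuals")
        t_min, t_max = self.mean_spec.time_domain
        sched = np.asarray(self.record_schedule, dtype=float)
        if np.any((sched < t_min) | (sched + max(self.calving_spread - 1, 0) > t_max)):
            raise ValueError(
                "record schedule (plus calving spread) outside the basis time domain"
            )


def basic_config(order: int = 2, **kwargs) -> SimConfig:
    """SimConfig with matching basis order for all terms and its true VC."""
    specs = _default_specs(order)
    kwargs.setdefault("true_vc", default_variance_components(order))
    return SimConfig(**specs, **kwargs)


def study_config(seed: int = 42) -> SimConfig:
    """The canonical conditions of the type-I-error and power studies.

    600 cows in 20 paternal half-sib families (30 daughters per sire — a
    modest family size for dairy, where popular sires have dozens to
    hundreds of daughters), ~10 records each over DIM 5-305 with staggered
    calving, herd-test-date effects, and dairy-scale variance components.
    The family size was fixed by a pilot so the realized between-family
    genetic variance — the structure the no-polygenic comparison isolates —
    is present in every data realization, not only on average.  The fixed
    mean curve is fourth order (the standard choice for lactation curves);
    the random and SNP regressions are second order to keep the desk-scale
    studies fast.
    """
    cfg = basic_config(
        order=2, n_individuals=600, n_families=20, n_snps=600, seed=seed
    )
    cfg.mean_spec = BasisSpec(order=4)
    return cfg


@dataclass
class QtnEffect:
    """A time-varying QTN allele-substitution effect.

    ``daily_effects`` is the unscaled day-grid trajectory (Day 5 = 10.0,
    then a daily U(-1,1) random walk); ``schedule_effects`` are its values
    at the record schedule.  After :func:`scale_qtn`, ``k`` and the scaled
    vectors are populated.
    """

    days: np.ndarray
    daily_effects: np.ndarray
    schedule_days: np.ndarray
    schedule_effects: np.ndarray
    k: float | None = None
    scaled_effects: np.ndarray | None = None
    scaled_schedule_effects: np.ndarray | None = None


@dataclass
class SimData:
    """One simulated data set: genotypes, kinship, records and the truth."""

    cfg: SimConfig
    geno: GenotypeMatrix
    kinship: KinshipMatrix
    families: np.ndarray
    pheno: PhenotypeTable
    truth: dict


def _draw_structured_codes(rng, p_freqs, families, n_families):
    """Half-sib genotypes: one allele from the family sire, one from the base."""
    n_snps = len(p_freqs)
    n_ind = len(families)
    sire_alleles = rng.random((n_families, 2, n_snps)) < p_freqs  # each sire's 2 alleles
    pick = rng.integers(0, 2, size=(n_ind, n_snps))
    paternal = sire_alleles[families[:, None], pick, np.arange(n_snps)[None, :]]
    maternal = rng.random((n_ind, n_snps)) < p_freqs
    return paternal.astype(np.int8) + maternal.astype(np.int8)


def _snp_meta(n_snps, prefix="snp", start_pos=1):
    return pd.DataFrame(
        {
            "snp_id": [f"{prefix}{j:05d}" for j in range(n_snps)],
            "chromosome": "1",
            "position": np.arange(start_pos, start_pos + n_snps) * 1000,
            "allele1": "A",
            "allele2": "B",
        }
    )


def simulate_population(cfg: SimConfig):
    """Simulate the genotype panel and its VanRaden kinship.

    Returns ``(GenotypeMatrix, KinshipMatrix, families)`` where families
    assigns each individual to a paternal half-sib family.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    p_freqs = rng.uniform(*cfg.maf_law, size=cfg.n_snps)
    families = np.arange(cfg.n_individuals) % cfg.n_families
    codes = _draw_structured_codes(rng, p_freqs, families, cfg.n_families)
    geno = GenotypeMatrix(
        codes=codes,
        snp_meta=_snp_meta(cfg.n_snps),
        individual_ids=[f"ind{i:05d}" for i in range(cfg.n_individuals)],
    )
    kin = vanraden_kinship(geno)
    return geno, kin, families


def simulate_test_snps(cfg: SimConfig, families: np.ndarray, n_snps: int, seed: int) -> GenotypeMatrix:
    """Fresh SNPs with the same half-sib structure, independent of phenotypes."""
    rng = np.random.default_rng([seed, 2])
    p_freqs = rng.uniform(*cfg.maf_law, size=n_snps)
    codes = _draw_structured_codes(rng, p_freqs, families, cfg.n_families)
    return GenotypeMatrix(
        codes=codes,
        snp_meta=_snp_meta(n_snps, prefix="test"),
        individual_ids=[f"ind{i:05d}" for i in range(len(families))],
    )


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    ev, V = np.linalg.eigh((M + M.T) / 2.0)
    return (V * np.sqrt(np.clip(ev, 0.0, None))) @ V.T


def _group_mean_curve(times: np.ndarray, group: int) -> np.ndarray:
    # Wilmink-shaped lactation curve with a per-group level shift
    return 30.0 + 1.5 * group - 0.02 * times - 12.0 * np.exp(-0.05 * times)


def simulate_phenotypes(geno: GenotypeMatrix, K: KinshipMatrix, cfg: SimConfig):
    """Generate test-day records from the model (no SNP term).

    Returns ``(PhenotypeTable, truth)``; ``truth`` holds the drawn
    additive and permanent-environment coefficients, HTD effects, herd,
    group and calving-offset assignments.

    Test events are shared within a herd (one herd-test-date class per
    herd × event), but each cow's calving date is staggered by up to
    ``calving_spread`` days, so days-in-milk differ between cows measured
    on the same date — the unbalanced structure of real test-day data.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    vc = cfg.true_vc
    n_ind = geno.n_individuals
    sched = np.asarray(cfg.record_schedule, dtype=float)
    n_rec = len(sched)

    A_K = _psd_sqrt(K.values)
    u = A_K @ rng.standard_normal((n_ind, vc.G.shape[0])) @ _psd_sqrt(vc.G)
    pe = rng.standard_normal((n_ind, vc.P.shape[0])) @ _psd_sqrt(vc.P)

    herd = rng.integers(0, cfg.n_herds, size=n_ind)
    group = rng.integers(0, cfg.group_labels, size=n_ind)
    offset = (
        rng.integers(0, cfg.calving_spread, size=n_ind)
        if cfg.calving_spread > 0
        else np.zeros(n_ind, dtype=int)
    )
    htd_effects = {
        (h, j): (rng.normal(0.0, cfg.htd_sd) if cfg.htd_sd > 0 else 0.0)
        for h in range(cfg.n_herds)
        for j in range(n_rec)
    }

    rows = []
    fixed_part = []
    for i, animal in enumerate(geno.individual_ids):
        dims = sched + offset[i]
        mu = _group_mean_curve(dims, int(group[i]))
        gen = basis_matrix(dims, cfg.add_spec) @ u[i]
        perm = basis_matrix(dims, cfg.perm_spec) @ pe[i]
        e = rng.normal(0.0, np.sqrt(vc.sigma2_e), size=n_rec)
        for j in range(n_rec):
            fixed = mu[j] + htd_effects[(herd[i], j)]
            fixed_part.append(fixed)
            rows.append(
                {
                    "animal_id": animal,
                    "parity": 1,
                    "dim": dims[j],
                    "htd": f"h{herd[i]}t{j}",
                    "group": f"g{group[i]}",
                    "y": fixed + gen[j] + perm[j] + e[j],
                }
            )
    pheno = PhenotypeTable(pd.DataFrame(rows))
    truth = {
        "u": u,
        "pe": pe,
        "htd_effects": htd_effects,
        "herd": herd,
        "group": group,
        "offset": offset,
        "fixed_part": np.asarray(fixed_part),
    }
    return pheno, truth


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Population + phenotypes in one reproducible call."""
    geno, kin, families = simulate_population(cfg)
    pheno, truth = simulate_phenotypes(geno, kin, cfg)
    return SimData(cfg=cfg, geno=geno, kinship=kin, families=families, pheno=pheno, truth=truth)


def resample_phenotype_values(data: SimData, seed: int):
    """Redraw the random parts of the phenotypes on the existing layout.

    Keeps the record layout — herd, group, calving offset, test schedule,
    hence the design matrices and the record covariance — and redraws
    u ~ N(0, K⊗G), the permanent-environment coefficients, the HTD effects
    and the residuals.  Returns ``(y, fixed_part)`` aligned with
    ``data.pheno.df``.  Because the covariance structure is unchanged, a
    rotation built for ``data`` applies to the resampled response as well;
    the simulation studies use this to pool over independent phenotype
    realizations at the cost of one matrix-vector product each.
    """
    cfg = data.cfg
    vc = cfg.true_vc
    rng = np.random.default_rng([seed, 5])
    n_ind = data.geno.n_individuals
    sched = np.asarray(cfg.record_schedule, dtype=float)
    n_rec = len(sched)
    herd, group, offset = (data.truth[k] for k in ("herd", "group", "offset"))

    A_K = _psd_sqrt(data.kinship.values)
    u = A_K @ rng.standard_normal((n_ind, vc.G.shape[0])) @ _psd_sqrt(vc.G)
    pe = rng.standard_normal((n_ind, vc.P.shape[0])) @ _psd_sqrt(vc.P)
    htd_effects = {
        (h, j): (rng.normal(0.0, cfg.htd_sd) if cfg.htd_sd > 0 else 0.0)
        for h in range(cfg.n_herds)
        for j in range(n_rec)
    }
    y = np.empty(n_ind * n_rec)
    fixed_part = np.empty(n_ind * n_rec)
    for i in range(n_ind):
        dims = sched + offset[i]
        mu = _group_mean_curve(dims, int(group[i]))
        gen = basis_matrix(dims, cfg.add_spec) @ u[i]
        perm = basis_matrix(dims, cfg.perm_spec) @ pe[i]
        e = rng.normal(0.0, np.sqrt(vc.sigma2_e), size=n_rec)
        htd = np.array([htd_effects[(herd[i], j)] for j in range(n_rec)])
        fixed_part[i * n_rec : (i + 1) * n_rec] = mu + htd
        y[i * n_rec : (i + 1) * n_rec] = mu + htd + gen + perm + e
    return y, fixed_part


# ---------------------------------------------------------------------------
# QTN trajectory
# ---------------------------------------------------------------------------

def make_qtn_trajectory(schedule_days, seed: int, t_max: float | None = None) -> QtnEffect:
    """Day-5 effect 10.0, then an independent U(-1, 1) increment per day.

    The daily grid runs from day 5 to ``t_max`` (default: the last
    schedule day), so the effect is defined at every record time even
    when cows' calving dates are staggered.
    """
    sched = np.asarray(schedule_days, dtype=float)
    if sched[0] != 5:
        raise ValueError("record schedule must begin at day 5")
    rng = np.random.default_rng([seed, 3])
    days = np.arange(5, int(t_max if t_max is not None else sched[-1]) + 1, dtype=float)
    steps = rng.uniform(-1.0, 1.0, size=len(days) - 1)
    daily = np.concatenate([[10.0], 10.0 + np.cumsum(steps)])
    on_schedule = np.interp(sched, days, daily)
    return QtnEffect(
        days=days,
        daily_effects=daily,
        schedule_days=sched,
        schedule_effects=on_schedule,
    )


def scale_qtn(traj: QtnEffect, k: float, phe_sd: float, at_days=None) -> QtnEffect:
    """Scale the trajectory so its RMS effect at record times is k × σ_P.

    With the root-mean-square convention, an injected QTN at allele
    frequency p explains exactly 2p(1-p)k²·σ²_P of phenotypic variance, so
    the variance fraction π = 2p(1-p)k²/(1+2p(1-p)k²) holds identically.
    ``at_days`` gives the times over which the RMS is taken (default: the
    trajectory's record schedule).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if phe_sd <= 0:
        raise ValueError("phe_sd must be positive")
    if at_days is None:
        vals = traj.schedule_effects
    else:
        vals = np.interp(np.asarray(at_days, dtype=float), traj.days, traj.daily_effects)
    rms = float(np.sqrt(np.mean(vals**2)))
    if rms == 0:
        raise ValueError("cannot scale an all-zero trajectory")
    factor = k * phe_sd / rms
    return replace(
        traj,
        k=k,
        scaled_effects=traj.daily_effects * factor,
        scaled_schedule_effects=traj.schedule_effects * factor,
    )


def qtn_variance_fraction(p: float, k: float) -> float:
    """π = 2p(1-p)k² / (1 + 2p(1-p)k²): phenotypic variance fraction of a QTN."""
    if not 0 <= p <= 1:
        raise ValueError("allele frequency must be in [0, 1]")
    v = 2.0 * p * (1 - p) * k * k
    return v / (1.0 + v)


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

def _rotate_for(data: SimData, vc: VarianceComponents, with_polygenic: bool) -> RotatedSystem:
    """Rotation under the full model or the no-polygenic comparator.

    The comparator drops the Q(K⊗G)Q' term.  Because its own REML fit
    would absorb the individual-iid part of the genetic covariance into
    the permanent-environment term (K has unit diagonal), G is folded
    into P when the two random bases match; what stays unmodeled is
    exactly the between-relative covariance — the structure the paper's
    comparison isolates.
    """
    cfg = data.cfg
    design = build_design(
        data.pheno, cfg.mean_spec, cfg.add_spec, cfg.perm_spec,
        individual_ids=data.geno.individual_ids,
    )
    if not with_polygenic:
        P_eff = vc.P + vc.G if vc.G.shape == vc.P.shape else vc.P
        vc = VarianceComponents(G=vc.G, P=P_eff, sigma2_e=vc.sigma2_e)
    W = build_covariance_W(design, data.kinship, vc, include_polygenic=with_polygenic)
    y = data.pheno.df["y"].to_numpy(dtype=float)
    return rotate_system(W, y, design.X, design, vc.sigma2_e, cfg.snp_spec)


def null_scan_study(
    data: SimData,
    vc: VarianceComponents | None = None,
    n_test_snps: int = 1000,
    alpha: float = 0.05,
    with_polygenic: bool = True,
    seed: int = 12345,
    rot: RotatedSystem | None = None,
    n_phenotype_reps: int = 5,
) -> dict:
    """Scan SNPs simulated independently of the phenotype.

    Under a calibrated test the p-values are Uniform(0, 1); the returned
    dict holds the p-value vector, the rejection rate at ``alpha`` and the
    Kolmogorov-Smirnov distance/p-value against uniformity.
    ``with_polygenic=False`` drops the Q(K⊗G)Q' term from the record
    covariance — the "no-polygenic" comparator that inflates type I error
    under family structure.

    The test SNPs are split over ``n_phenotype_reps`` independent
    phenotype redraws on the same layout: p-values scanned against a
    single response are conditionally dependent through it, so pooling
    over realizations is what makes the empirical rate estimate the
    (unconditional) type-I error.  The one-time rotation is reused — each
    extra realization costs one matrix-vector product.
    """
    vc = vc or data.cfg.true_vc
    if rot is None:
        rot = _rotate_for(data, vc, with_polygenic)
    test_geno = simulate_test_snps(data.cfg, data.families, n_test_snps, seed)
    # frequencies from the simulated panel itself (none missing, but exact)
    freqs = test_geno.codes.mean(axis=0) / 2.0

    n_phenotype_reps = max(1, n_phenotype_reps)
    chunks = np.array_split(np.arange(n_test_snps), n_phenotype_reps)
    y_stars = [rot.y_star]
    for rep in range(1, n_phenotype_reps):
        y_rep, _ = resample_phenotype_values(data, seed + 7000 + rep)
        y_stars.append(rot.U.T @ y_rep)

    results = []
    for chunk, y_star in zip(chunks, y_stars):
        results.extend(
            scan_snps(
                rot, test_geno, data.cfg.snp_spec, freqs,
                snp_indices=chunk.tolist(), y_star=y_star,
            )
        )
    pvals = np.array([r.p_value for r in results if r.flag == "ok"])
    ks = stats.kstest(pvals, "uniform")
    return {
        "p_values": pvals,
        "rejection_rate": float(np.mean(pvals < alpha)),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "rot": rot,
        "test_geno": test_geno,
        "freqs": freqs,
        "y_stars": y_stars,
    }


def power_study(
    data: SimData,
    null_p_values: np.ndarray,
    k_grid=(0.04, 0.08, 0.12, 0.16, 0.20),
    n_effect_snps: int = 200,
    seed: int = 777,
    vc: VarianceComponents | None = None,
    rot: RotatedSystem | None = None,
    n_phenotype_reps: int = 5,
) -> dict:
    """Empirical power of the scan against an injected time-varying QTN.

    For each k and each of ``n_effect_snps`` structured SNPs, the scaled
    trajectory times the SNP's allele count is added to every record and
    that single SNP is re-tested; detection is a p-value at or below the
    empirical threshold (5th percentile of ``null_p_values``).  As in the
    null scan, the effect SNPs are split over independent phenotype
    redraws so the power estimate pools over realizations.
    """
    cfg = data.cfg
    vc = vc or cfg.true_vc
    if rot is None:
        rot = _rotate_for(data, vc, True)
    threshold = float(np.percentile(null_p_values, 5.0))
    sched = np.asarray(cfg.record_schedule, dtype=float)
    _, _, phe = variance_curves(vc, cfg.add_spec, cfg.perm_spec, sched)
    phe_sd = float(np.sqrt(np.mean(phe)))
    dim = data.pheno.df["dim"].to_numpy(dtype=float)
    traj = make_qtn_trajectory(sched, seed, t_max=dim.max())

    eff_geno = simulate_test_snps(cfg, data.families, n_effect_snps, seed + 1)
    freqs = eff_geno.codes.mean(axis=0) / 2.0
    gpos = {g: i for i, g in enumerate(eff_geno.individual_ids)}
    order = np.array([gpos[a] for a in rot.ind_ids])
    rec_g_idx = order[rot.rec_ind]

    n_phenotype_reps = max(1, n_phenotype_reps)
    chunks = np.array_split(np.arange(n_effect_snps), n_phenotype_reps)
    y_stars = [rot.y_star]
    for rep in range(1, n_phenotype_reps):
        y_rep, _ = resample_phenotype_values(data, seed + 9000 + rep)
        y_stars.append(rot.U.T @ y_rep)

    Ut = rot.U.T
    power: dict[float, float] = {}
    for k in k_grid:
        scaled = scale_qtn(traj, k, phe_sd, at_days=dim)
        eff_at_rec = np.interp(dim, traj.days, scaled.scaled_effects)
        hits = 0
        for chunk, y_base in zip(chunks, y_stars):
            for m in chunk:
                delta = eff_geno.codes[rec_g_idx, m] * eff_at_rec
                y_star = y_base + Ut @ delta
                res = scan_snps(
                    rot, eff_geno, cfg.snp_spec, freqs, snp_indices=[int(m)],
                    y_star=y_star,
                )[0]
                if res.flag == "ok" and res.p_value <= threshold:
                    hits += 1
        power[float(k)] = hits / n_effect_snps
    return {"power": power, "threshold": threshold, "phe_sd": phe_sd, "trajectory": traj}


def empirical_qtn_variance_fraction(
    data: SimData,
    k: float = 0.2,
    p_freq: float = 0.5,
    n_reps: int = 30,
    seed: int = 999,
) -> dict:
    """Monte-Carlo check of the π formula against injected phenotypes.

    Each replicate redraws the phenotypes, a fresh QTN genotype at
    frequency ``p_freq`` and a fresh trajectory, injects the scaled effect,
    and measures the fraction of within-day phenotypic variance
    attributable to the (centered) genotype term.  The true fixed part
    (mean curves, HTD) is netted out: the formula's phenotypic variance is
    the model variance add + perm + residual.  Replicates are independent,
    so the Monte-Carlo standard error reflects every source of sampling
    variation.
    """
    cfg = data.cfg
    sched = np.asarray(cfg.record_schedule, dtype=float)
    rng = np.random.default_rng([seed, 4])

    fracs = []
    for _ in range(n_reps):
        cfg_rep = replace(cfg, seed=int(rng.integers(2**20)))
        pheno, truth = simulate_phenotypes(data.geno, data.kinship, cfg_rep)
        df = pheno.df
        y = df["y"].to_numpy(dtype=float) - truth["fixed_part"]
        day = df["dim"].to_numpy(dtype=float)
        # pooled phenotypic SD over the realized record times
        _, _, phe = variance_curves(cfg.true_vc, cfg.add_spec, cfg.perm_spec, day)
        phe_sd = float(np.sqrt(np.mean(phe)))
        pos = {a: i for i, a in enumerate(data.geno.individual_ids)}
        rec_ind = np.array([pos[a] for a in df["animal_id"]])

        def within_day_var(v):
            tot, cnt = 0.0, 0
            for t in np.unique(day):
                vv = v[day == t]
                tot += np.sum((vv - vv.mean()) ** 2)
                cnt += len(vv) - 1
            return tot / cnt

        traj = make_qtn_trajectory(sched, int(rng.integers(2**31)), t_max=day.max())
        scaled = scale_qtn(traj, k, phe_sd, at_days=day)
        g = rng.binomial(2, p_freq, size=data.geno.n_individuals).astype(float)
        eff = np.interp(day, traj.days, scaled.scaled_effects)
        delta = g[rec_ind] * eff
        v_qtn = within_day_var((g[rec_ind] - g.mean()) * eff)
        v_tot = within_day_var(y + delta)
        fracs.append(v_qtn / v_tot)
    fracs = np.asarray(fracs)
    return {
        "fractions": fracs,
        "mean": float(fracs.mean()),
        "mc_se": float(fracs.std(ddof=1) / np.sqrt(n_reps)),
        "formula": qtn_variance_fraction(p_freq, k),
    }
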