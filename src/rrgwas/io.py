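"""File formats and the end-to-end GWAS run.

Genotypes are read from PLINK bed/bim/fam (SNP-major 2-bit .bed, decoded so
codes count copies of the bim allele1, PLINK's minor allele) or from a
plain-text individuals × SNPs matrix with a header row of SNP ids and NA
for missing.  Phenotypes are long-format TSV/CSV.  ``run_gwas`` chains
QC → frequencies → kinship → variance components (read or REML) →
covariance → one eigen rotation → genome scan → LD pruning → Bonferroni
threshold, writing plain TSV results with a provenance header (tool
version, config hash, seed) so runs are auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .basis import BasisSpec
from .engine import (
    PhenotypeTable,
    build_covariance_W,
    build_design,
    rotate_system,
    scan_snps,
    scan_table,
    variance_curves,
)
from .genotype_qc import (
    MISSING,
    GenotypeMatrix,
    allele_frequencies,
    bonferroni_threshold,
    filter_snps,
    ld_prune,
    vanraden_kinship,
)
from .varcomp import DENSE_RECORD_GUARD, read_varcomp, reml_estimate, write_varcomp

logger = logging.getLogger("rrgwas")

__all__ = [
    "read_phenotypes",
    "read_genotypes",
    "read_plink",
    "write_plink",
    "read_text_genotypes",
    "write_text_genotypes",
    "run_gwas",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> allele1 copy counts (01 = missing)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(
    path,
    column_map: dict | None = None,
    min_records: int = 5,
    time_domain: tuple[float, float] | None = None,
) -> PhenotypeTable:
    """Read long-format test-day records.

    ``column_map`` maps canonical names (animal_id, parity, dim, htd,
    group, y) to the file's column names.  Rows with missing trait values
    are dropped (count logged); animals must have strictly more than
    ``min_records`` records to be retained; times are validated against
    ``time_domain`` when given.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.empty:
        raise ValueError(f"phenotype file {path} has no data rows")
    column_map = column_map or {}
    rename = {}
    for canonical in ("animal_id", "parity", "dim", "htd", "group", "y"):
        src = column_map.get(canonical, canonical)
        if src not in df.columns:
            raise ValueError(f"required phenotype column {src!r} ({canonical}) not found")
        rename[src] = canonical
    df = df.rename(columns=rename)[list(rename.values())]

    n_missing = int(df["y"].isna().sum())
    if n_missing:
        logger.info("dropping %d records with missing trait values", n_missing)
        df = df.dropna(subset=["y"])

    counts = df.groupby("animal_id")["animal_id"].transform("size")
    removed = df.loc[counts <= min_records, "animal_id"].nunique()
    if removed:
        logger.info(
            "removing %d animal(s) with <= %d test-day records", removed, min_records
        )
    df = df[counts > min_records].reset_index(drop=True)
    if df.empty:
        raise ValueError("no animals satisfy the minimum-records filter")

    if time_domain is not None:
        t = df["dim"].to_numpy(dtype=float)
        bad = (t < time_domain[0]) | (t > time_domain[1])
        if bad.any():
            raise ValueError(
                f"{bad.sum()} record(s) outside the time domain {time_domain}"
            )
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def read_plink(prefix) -> GenotypeMatrix:
    """Read a bed/bim/fam triple given the shared path prefix."""
    prefix = str(prefix)
    bed, bim, fam = (Path(prefix + s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"PLINK file {f} not found")
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    individual_ids = fam_df[1].tolist()
    bim_df = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    n_ind, n_snps = len(individual_ids), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{bed} is not a SNP-major PLINK .bed file (bad magic)")
    bytes_per_snp = (n_ind + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * n_snps:
        raise ValueError(
            f"{bed} holds {len(body)} data bytes; fam/bim imply "
            f"{bytes_per_snp * n_snps}"
        )
    body = body.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit fields, LSB pair first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = _BED_DECODE[two_bit.reshape(n_snps, -1)[:, :n_ind]].T
    meta = bim_df[["snp_id", "chromosome", "position", "allele1", "allele2"]].copy()
    return GenotypeMatrix(codes=codes, snp_meta=meta, individual_ids=individual_ids)


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a SNP-major bed/bim/fam triple."""
    prefix = str(prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    with open(prefix + ".fam", "w") as fh:
        for iid in geno.individual_ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for _, m in geno.snp_meta.iterrows():
            fh.write(
                f"{m['chromosome']}\t{m['snp_id']}\t0\t{m['position']}"
                f"\t{m['allele1']}\t{m['allele2']}\n"
            )
    n_ind = geno.n_individuals
    bytes_per_snp = (n_ind + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(geno.n_snps):
            col = geno.codes[:, j]
            bits = np.empty(n_ind, dtype=np.uint8)
            for code, b in _BED_ENCODE.items():
                bits[col == code] = b
            padded = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
            padded[:n_ind] = bits
            packed = (
                padded[0::4]
                | (padded[1::4] << 2)
                | (padded[2::4] << 4)
                | (padded[3::4] << 6)
            )
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# plain-text genotypes
# ---------------------------------------------------------------------------

def read_text_genotypes(path) -> GenotypeMatrix:
    """Individuals × SNPs whitespace table: header of SNP ids, NA missing."""
    df = pd.read_csv(path, sep=r"\s+", index_col=0, comment="#")
    codes = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    snp_ids = [str(c) for c in df.columns]
    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": "0",
            "position": np.arange(1, len(snp_ids) + 1),
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeMatrix(
        codes=codes, snp_meta=meta, individual_ids=[str(i) for i in df.index]
    )


def write_text_genotypes(geno: GenotypeMatrix, path) -> None:
    codes = geno.codes.astype(object)
    codes[geno.codes == MISSING] = "NA"
    df = pd.DataFrame(
        codes, index=geno.individual_ids, columns=geno.snp_meta["snp_id"]
    )
    df.to_csv(path, sep="\t", index_label="id")


def read_genotypes(path_prefix_or_file) -> GenotypeMatrix:
    """Dispatch on format: PLINK prefix / .bed path, else text matrix."""
    p = str(path_prefix_or_file)
    if p.endswith(".bed"):
        return read_plink(p[:-4])
    if Path(p + ".bed").exists():
        return read_plink(p)
    return read_text_genotypes(p)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _header_lines(config: dict, seed) -> str:
    digest = hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:12]
    return (
        f"# rrgwas {__version__} config_hash={digest} seed={seed} "
        f"date={time.strftime('%Y-%m-%d')}\n"
    )


def _write_tsv(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_gwas(config: dict, out_dir) -> dict:
    """Execute the full pipeline described by a run-config mapping.

    Recognized keys: ``pheno`` (path), ``geno`` (PLINK prefix or text
    matrix), ``vc_file`` (read variance components) or ``estimate_vc``
    (REML), basis settings (``basis_family``, ``nf1``, ``nf2``, ``nr1``,
    ``nr2``, ``t_min``, ``t_max``, ``normalized``, ``wilmink_rate``),
    filters (``maf_min``, ``hwe_p_min``, ``min_records``), the pruning
    parameters (``prune_window``, ``prune_step``, ``prune_r2``), ``alpha``
    and ``seed``.  Writes scan.tsv, threshold.txt, significant.tsv,
    curves.tsv, filter_report.tsv and varcomp.txt under ``out_dir`` and
    returns the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    header = _header_lines(config, seed)

    def spec(order_key, default_order):
        return BasisSpec(
            family=config.get("basis_family", "legendre"),
            order=int(config.get(order_key, default_order)),
            time_domain=(
                float(config.get("t_min", 5.0)),
                float(config.get("t_max", 305.0)),
            ),
            normalized=bool(config.get("normalized", True)),
            wilmink_rate=float(config.get("wilmink_rate", 0.05)),
        )

    mean_spec = spec("nf1", 4)
    snp_spec = spec("nf2", 4)
    add_spec = spec("nr1", 4)
    perm_spec = spec("nr2", 4)

    stage = "read phenotypes"
    try:
        pheno = read_phenotypes(
            config["pheno"],
            column_map=config.get("column_map"),
            min_records=int(config.get("min_records", 5)),
            time_domain=mean_spec.time_domain,
        )
        logger.info("%d records, %d animals", pheno.n_records, len(pheno.animals))
        if pheno.n_records > int(config.get("record_guard", DENSE_RECORD_GUARD)):
            raise ValueError(
                f"{pheno.n_records} records exceed the dense eigendecomposition "
                "guard; raise record_guard knowingly or reduce the data"
            )

        stage = "read genotypes"
        geno = read_genotypes(config["geno"])
        logger.info("%d individuals x %d SNPs", geno.n_individuals, geno.n_snps)

        stage = "genotype QC"
        geno, report = filter_snps(
            geno,
            maf_min=float(config.get("maf_min", 0.03)),
            hwe_p_min=float(config.get("hwe_p_min", 1e-6)),
        )
        logger.info("%d SNPs pass QC (%d removed)", geno.n_snps, len(report))
        _write_tsv(report, out / "filter_report.tsv", header)

        stage = "allele frequencies / kinship"
        freqs = allele_frequencies(geno)
        kin = vanraden_kinship(geno, freqs)

        stage = "variance components"
        if config.get("vc_file"):
            vc = read_varcomp(
                config["vc_file"], expected_orders=(add_spec.order, perm_spec.order)
            )
            logger.info("variance components read from %s", config["vc_file"])
        else:
            vc, rep = reml_estimate(pheno, kin, mean_spec, add_spec, perm_spec)
            logger.info(
                "REML: %d iterations, logL=%.4f, converged=%s",
                rep.iterations, rep.loglik, rep.converged,
            )
        write_varcomp(vc, out / "varcomp.txt")

        stage = "design / covariance / rotation"
        design = build_design(
            pheno, mean_spec, add_spec, perm_spec, individual_ids=geno.individual_ids
        )
        W = build_covariance_W(design, kin, vc)
        y = pheno.df["y"].to_numpy(dtype=float)
        rot = rotate_system(W, y, design.X, design, vc.sigma2_e, snp_spec)

        stage = "SNP scan"
        results = scan_snps(rot, geno, snp_spec, freqs)
        table = scan_table(results, geno, freqs)
        _write_tsv(table, out / "scan.tsv", header)

        stage = "LD pruning / threshold"
        retained = ld_prune(
            geno,
            window=int(config.get("prune_window", 50)),
            step=int(config.get("prune_step", 5)),
            r2_max=float(config.get("prune_r2", 0.5)),
        )
        m_eff = int(config.get("m_eff", len(retained)))
        threshold = bonferroni_threshold(float(config.get("alpha", 0.05)), m_eff)
        with open(out / "threshold.txt", "w") as fh:
            fh.write(header)
            fh.write(f"m_eff\t{m_eff}\nthreshold\t{threshold:.4g}\n")
        logger.info("m_eff=%d, Bonferroni threshold %.4g", m_eff, threshold)

        sig = table[(table["flag"] == "ok") & (table["p_value"] < threshold)]
        _write_tsv(sig, out / "significant.tsv", header)
        logger.info("%d genome-wide significant SNPs", len(sig))

        stage = "variance curves"
        times = np.arange(mean_spec.time_domain[0], mean_spec.time_domain[1] + 1, 5.0)
        add, perm, phe = variance_curves(vc, add_spec, perm_spec, times)
        _write_tsv(
            pd.DataFrame({"t": times, "add": add, "perm": perm, "phe": phe}),
            out / "curves.tsv",
            header,
        )
    except Exception as exc:
        raise RuntimeError(f"GWAS run failed at stage '{stage}': {exc}") from exc

    return {
        "scan": table,
        "significant": sig,
        "threshold": threshold,
        "m_eff": m_eff,
        "vc": vc,
        "retained": retained,
    }
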