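"""The whole pipeline through one config: files in, result tables out.

Writes simulated PLINK + phenotype files, then runs QC -> kinship -> REML ->
rotation -> scan -> pruning -> threshold exactly as the `rrgwas gwas` CLI
subcommand does.
"""

import tempfile
from pathlib import Path

import rrgwas as r
from rrgwas.io import run_gwas, write_plink
from rrgwas.varcomp import write_varcomp

tmp = Path(tempfile.mkdtemp())
cfg = r.basic_config(order=2, n_individuals=120, n_families=12, n_snps=200, seed=5)
data = r.simulate_dataset(cfg)
write_plink(data.geno, tmp / "panel")
data.pheno.df.to_csv(tmp / "pheno.tsv", sep="\t", index=False)
write_varcomp(cfg.true_vc, tmp / "vc.txt")  # known variances: REML is skipped

config = {
    "pheno": str(tmp / "pheno.tsv"),
    "geno": str(tmp / "panel"),
    "vc_file": str(tmp / "vc.txt"),
    "nf1": 2, "nf2": 2, "nr1": 2, "nr2": 2,
    "alpha": 0.05,
    "seed": 7,
}
res = run_gwas(config, tmp / "out")

print(f"scanned {len(res['scan'])} SNPs after QC")
print(f"m_eff = {res['m_eff']} pruned SNPs -> Bonferroni threshold {res['threshold']:.3g}")
print(f"significant SNPs: {len(res['significant'])} (none expected under the null)")
print(f"results written to {tmp/'out'}: scan.tsv, threshold.txt, curves.tsv, ...")
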