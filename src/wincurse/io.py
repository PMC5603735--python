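"""Real-data ingestion and the end-to-end pipeline.

Genotypes arrive either as VCF 4.2 (GT fields, biallelic sites) or as a
plain dosage TSV (subjects x variants).  Dosages are always oriented to
the *minor* allele as determined by the pooled sample frequency —
within-dataset orientation, so the sign of a case/control frequency
difference is dataset-relative.  A two-column phenotype table
(subject_id, status in {0, 1}) fixes the subject order and the
case/control labels, and a gene-set table (gene_id, variant_id) groups
variants into the units the gene-based test runs on.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correct, gbt, posthoc
from .data import CaseControlGenotypes

__all__ = [
    "GeneSetDefinition",
    "read_phenotypes",
    "read_gene_sets",
    "read_genotypes",
    "run_pipeline",
]

logger = logging.getLogger("wincurse")


@dataclass(frozen=True)
class GeneSetDefinition:
    """Ordered list of variant identifiers forming one testing unit."""

    gene_id: str
    variant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.variant_ids) == 0:
            raise ValueError(f"gene {self.gene_id!r} has no variants")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"gene {self.gene_id!r} lists duplicate variants")


def read_phenotypes(path) -> pd.DataFrame:
    """Two-column phenotype TSV: subject_id, status in {0, 1}."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns or "status" not in df.columns:
        raise ValueError("phenotype table needs 'subject_id' and 'status' columns")
    if not df["status"].isin([0, 1]).all():
        raise ValueError("phenotype status must be binary (0 = control, 1 = case)")
    return df[["subject_id", "status"]]


def read_gene_sets(path) -> list[GeneSetDefinition]:
    """Gene-set TSV with columns gene_id, variant_id (ordered per gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "variant_id" not in df.columns:
        raise ValueError("gene-set table needs 'gene_id' and 'variant_id' columns")
    out = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        out.append(GeneSetDefinition(gene_id, tuple(sub["variant_id"])))
    return out


def _orient_to_minor(dosages: np.ndarray, prefer_alt_on_tie: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Flip dosage columns whose pooled allele frequency exceeds 1/2 so
    that dosage counts the minor allele; ties keep the ALT orientation."""
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5 if prefer_alt_on_tie else freq >= 0.5
    out = dosages.copy()
    out[:, flip] = 2 - out[:, flip]
    return out, flip


def _read_vcf_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """ALT-dosage matrix from a biallelic VCF: (dosages, subject_ids,
    variant_ids).  Multi-allelic sites are skipped with a warning;
    missing genotypes are imputed to 0 and counted in the log."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    variant_ids = []
    n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic site {var.ID or var.POS}")
            continue
        gt = np.asarray(var.gt_types, dtype=np.int64)  # 0/1/2 = ALT count, 3 = missing
        missing = gt == 3
        n_missing += int(missing.sum())
        gt[missing] = 0
        rows.append(gt)
        variant_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if n_missing:
        logger.info("imputed %d missing genotypes to dosage 0", n_missing)
    dosages = np.array(rows, dtype=np.int64).T if rows else np.empty((len(samples), 0), dtype=np.int64)
    return dosages, samples, variant_ids


def read_genotypes(path, phenotypes, fmt: str | None = None) -> CaseControlGenotypes:
    """Load a case-control dosage matrix from VCF or dosage TSV.

    ``phenotypes`` is a path or DataFrame with subject_id/status; its
    row order fixes the subject order of the result.  Every genotyped
    subject must appear in the phenotype table and vice versa.
    """
    if not isinstance(phenotypes, pd.DataFrame):
        phenotypes = read_phenotypes(phenotypes)
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        dosages, subjects, variant_ids = _read_vcf_matrix(path)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
        variant_ids = [c for c in df.columns if c not in ("subject_id", "status")]
        subjects = list(df["subject_id"])
        dosages = df[variant_ids].to_numpy(dtype=np.int64)
    else:
        raise ValueError(f"unknown genotype format: {fmt!r}")

    pheno_subjects = list(phenotypes["subject_id"])
    missing_from_pheno = set(subjects) - set(pheno_subjects)
    if missing_from_pheno:
        raise ValueError(
            f"subjects present in genotypes but absent from phenotype table: "
            f"{sorted(missing_from_pheno)[:5]}"
        )
    missing_from_geno = set(pheno_subjects) - set(subjects)
    if missing_from_geno:
        raise ValueError(
            f"subjects present in phenotype table but absent from genotypes: "
            f"{sorted(missing_from_geno)[:5]}"
        )
    order = [subjects.index(s) for s in pheno_subjects]
    dosages = dosages[order]
    dosages, flipped = _orient_to_minor(dosages)
    if flipped.any():
        logger.info(
            "flipped %d variants to minor-allele orientation", int(flipped.sum())
        )
    return CaseControlGenotypes(
        dosages=dosages,
        status=phenotypes["status"].to_numpy(),
        variant_ids=variant_ids,
        subject_ids=pheno_subjects,
    )


REQUIRED_CONFIG = (
    "genotypes",
    "phenotypes",
    "gene_sets",
    "test",
    "statistic",
    "alpha",
    "n_bootstrap",
    "seed",
    "output_dir",
)


def run_pipeline(config) -> dict:
    """Run the two-step analysis for every gene set in a configuration.

    ``config`` is a YAML path or a dict with keys: genotypes,
    phenotypes, gene_sets, test (burden|skat), statistic (D|D2), alpha,
    n_bootstrap, seed, output_dir (and optional genotype_format).
    Genes failing Step 1 never reach the adjusted-output file — the
    gate is structural.  All randomness flows from the single seed.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    for key in REQUIRED_CONFIG:
        if key not in config:
            raise ValueError(f"missing required config field: {key!r}")

    pheno = read_phenotypes(config["phenotypes"])
    geno = read_genotypes(config["genotypes"], pheno, config.get("genotype_format"))
    gene_sets = read_gene_sets(config["gene_sets"])
    test_family = config["test"]
    statistic_family = config["statistic"]
    alpha = float(config["alpha"])
    n_bootstrap = int(config["n_bootstrap"])
    seed = int(config["seed"])
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    vid_index = {v: i for i, v in enumerate(geno.variant_ids)}
    gbt_rows = []
    adjusted_frames = []
    for gi, gs in enumerate(gene_sets):
        missing = [v for v in gs.variant_ids if v not in vid_index]
        if missing:
            raise ValueError(f"gene {gs.gene_id!r} references unknown variants: {missing}")
        sub = CaseControlGenotypes(
            dosages=geno.dosages[:, [vid_index[v] for v in gs.variant_ids]],
            status=geno.status,
            variant_ids=list(gs.variant_ids),
            subject_ids=geno.subject_ids,
        )
        res = gbt.run_test(sub, test_family, alpha=alpha)
        gbt_rows.append(
            {
                "gene": gs.gene_id,
                "test_family": res.test_family,
                "q_value": res.q_value,
                "p_value": res.p_value,
                "alpha": alpha,
                "significant": res.significant,
                "m": sub.n_variants,
                "n_cases": sub.n_cases,
                "n_controls": sub.n_controls,
            }
        )
        if not res.significant:
            logger.info("gene %s not significant at Step 1 (p=%.3g); stopping", gs.gene_id, res.p_value)
            continue
        stats = posthoc.naive_stats(sub, statistic_family)
        rng = np.random.default_rng(np.random.SeedSequence([seed, gi]))
        run = correct.estimate_bias(
            sub,
            test_family=test_family,
            statistic_family=statistic_family,
            alpha=alpha,
            n_bootstrap=n_bootstrap,
            seed=rng,
        )
        if run.n_significant > 0:
            stats = correct.adjust(stats, run)
        adjusted_frames.append(stats.to_frame(gene=gs.gene_id))

    gbt_table = pd.DataFrame(gbt_rows)
    gbt_table.to_csv(outdir / "gbt_results.tsv", sep="\t", index=False)
    if adjusted_frames:
        adj_table = pd.concat(adjusted_frames, ignore_index=True)
    else:
        adj_table = pd.DataFrame()
    adj_table.to_csv(outdir / "adjusted_stats.tsv", sep="\t", index=False)
    meta = {
        "test": test_family,
        "statistic": statistic_family,
        "alpha": alpha,
        "n_bootstrap": n_bootstrap,
        "seed": seed,
        "n_genes": len(gene_sets),
        "n_significant_genes": int(gbt_table["significant"].sum()) if len(gbt_table) else 0,
    }
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return {"gbt": gbt_table, "adjusted": adj_table, "meta": meta}
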