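"""File interchange: VCF / CSV dosage genotypes, cohort CSV, model YAML."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .synthdata import (
    BiomarkerSpec,
    CohortModel,
    CohortTable,
    ConfounderSpec,
    GenotypeMatrix,
    REGION_LEVELS,
    SnpSpec,
)

__all__ = [
    "write_vcf", "read_vcf",
    "write_dosage_csv", "read_dosage_csv",
    "write_cohort_csv", "read_cohort_csv",
    "model_to_yaml", "model_from_yaml",
]

PathLike = Union[str, Path]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: PathLike) -> None:
    """Write a minimal VCFv4.2 with GT calls; ALT is the minor allele, so the
    ALT dosage equals the stored minor-allele count. SNP metadata is carried
    in INFO (GENE, MAF, BETA_LNX)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Design minor allele frequency">',
        '##INFO=<ID=BETA_LNX,Number=1,Type=Float,Description="Per-minor-allele effect on ln 25(OH)D">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.sample_ids),
    ]
    for j, s in enumerate(genotypes.snps):
        calls = []
        for d in genotypes.dosages[:, j]:
            calls.append("./." if np.isnan(d) else _GT[int(d)])
        info = f"GENE={s.gene};MAF={s.maf:g};BETA_LNX={s.beta_lnx:g}"
        lines.append(
            f"1\t{j + 1}\t{s.snp_id}\tA\tG\t.\t.\t{info}\tGT\t" + "\t".join(calls))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: PathLike) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field; ALT-allele dosage)."""
    from cyvcf2 import VCF

    v = VCF(str(path))
    samples = list(v.samples)
    snps, rows = [], []
    for rec in v:
        gene = rec.INFO.get("GENE") or "NA"
        maf = rec.INFO.get("MAF")
        beta = rec.INFO.get("BETA_LNX")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        g = np.asarray(rec.gt_types, dtype=float)
        dos = np.where(g == 2, np.nan, np.where(g == 3, 2.0, g))
        if maf is None:
            called = dos[~np.isnan(dos)]
            f = float(np.mean(called) / 2.0) if len(called) else 0.25
            maf = min(max(f, 1e-6), 0.5)
        snps.append(SnpSpec(rec.ID or f"{rec.CHROM}:{rec.POS}", gene,
                            float(maf), float(beta) if beta is not None else 0.0))
        rows.append(dos)
    return GenotypeMatrix(np.column_stack(rows), snps, samples)


def write_dosage_csv(genotypes: GenotypeMatrix, path: PathLike) -> None:
    genotypes.to_dataframe().to_csv(path, index_label="sample_id")


def read_dosage_csv(path: PathLike, snps=None) -> GenotypeMatrix:
    """Read an individuals x SNPs 0/1/2 dosage CSV (empty cells = missing).
    When SNP metadata is not supplied, MAF is estimated from the data and
    effects default to 0."""
    df = pd.read_csv(path, index_col=0)
    if snps is None:
        snps = []
        for c in df.columns:
            g = df[c].to_numpy(dtype=float)
            called = g[~np.isnan(g)]
            f = float(np.mean(called) / 2.0) if len(called) else 0.25
            snps.append(SnpSpec(c, "NA", min(max(f, 1e-6), 0.5), 0.0))
    return GenotypeMatrix(df.to_numpy(dtype=float), list(snps),
                          [str(i) for i in df.index])


def write_cohort_csv(cohort: CohortTable, path: PathLike) -> None:
    """Columns: x_25ohd (nmol/L), ln_25ohd, sex (1 = male), region, y_outcome,
    then one column per lifestyle factor and biomarker."""
    cohort.to_frame().to_csv(path, index_label="sample_id")


def read_cohort_csv(path: PathLike,
                    lifestyle_cols=(), biomarker_cols=()) -> CohortTable:
    df = pd.read_csv(path, index_col=0)
    known = {"x_25ohd", "ln_25ohd", "sex", "region", "y_outcome"}
    if not lifestyle_cols and not biomarker_cols:
        extra = [c for c in df.columns if c not in known]
        lifestyle_cols = [c for c in extra if set(df[c].dropna().unique()) <= {0, 1}]
        biomarker_cols = [c for c in extra if c not in lifestyle_cols]
    x = df["x_25ohd"].to_numpy(dtype=float)
    return CohortTable(
        x=x, lnx=np.log(x),
        sex=df["sex"].to_numpy(),
        region=pd.Categorical(df["region"], categories=list(REGION_LEVELS)),
        y=df["y_outcome"].to_numpy(dtype=float),
        lifestyle=df[list(lifestyle_cols)],
        biomarkers=df[list(biomarker_cols)],
        sample_ids=[str(i) for i in df.index],
    )


def model_to_yaml(model: CohortModel, path: PathLike) -> None:
    doc = {
        "snps": [{"snp_id": s.snp_id, "gene": s.gene, "maf": s.maf,
                  "beta_lnx": s.beta_lnx, "lowering": s.lowering}
                 for s in model.snps],
        "sd_lnx": model.sd_lnx, "gm_x": model.gm_x,
        "sex_effect": model.sex_effect,
        "causal_effect_per10": model.causal_effect_per10,
        "causal_scale": model.causal_scale,
        "outcome_mean": model.outcome_mean, "outcome_sd": model.outcome_sd,
        "confounders": [{"name": c.name, "prevalence": c.prevalence,
                         "effect_lnx": c.effect_lnx, "effect_y": c.effect_y,
                         "snp_assoc": c.snp_assoc,
                         "snp_log_odds": c.snp_log_odds}
                        for c in model.confounders],
        "biomarkers": [{"name": b.name, "mean": b.mean, "sd": b.sd,
                        "loading_lnx": b.loading_lnx,
                        "snp_effects": dict(b.snp_effects)}
                       for b in model.biomarkers],
        "region_assoc_snp": model.region_assoc_snp,
        "region_maf_shift": model.region_maf_shift,
        "region_probs": list(model.region_probs),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def model_from_yaml(path: PathLike) -> CohortModel:
    doc = yaml.safe_load(Path(path).read_text())
    return CohortModel(
        snps=tuple(SnpSpec(**d) for d in doc["snps"]),
        sd_lnx=doc.get("sd_lnx", 0.48),
        gm_x=doc.get("gm_x", 53.0),
        sex_effect=doc.get("sex_effect", -0.05),
        causal_effect_per10=doc.get("causal_effect_per10", -0.05),
        causal_scale=doc.get("causal_scale", "sd_outcome"),
        outcome_mean=doc.get("outcome_mean", 125.0),
        outcome_sd=doc.get("outcome_sd", 15.0),
        confounders=tuple(ConfounderSpec(**d) for d in doc.get("confounders", [])),
        biomarkers=tuple(BiomarkerSpec(**d) for d in doc.get("biomarkers", [])),
        region_assoc_snp=doc.get("region_assoc_snp"),
        region_maf_shift=doc.get("region_maf_shift", 0.05),
        region_probs=tuple(doc.get("region_probs", (0.30, 0.25, 0.30, 0.15))),
    )
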