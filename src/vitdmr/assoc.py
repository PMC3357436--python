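"""Per-SNP association with ln 25(OH)D, genotype QC, and instrument-strength
diagnostics.

Association fits are ordinary least squares with additive genotype coding and
two-sided Wald p-values. Betas are always reported per minor allele; when the
supplied dosage counts the major allele it is flipped to 2−g. Instrument
strength follows the standard first-stage conventions: the F-statistic of the
simple (covariate-free) regression, F = (n−2)·R²/(1−R²); relative bias of IV
versus OLS approximated as 1/F; F < 10 flags a weak instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthdata import GenotypeMatrix, CohortTable

__all__ = [
    "AssociationResult",
    "QcThresholds",
    "SnpQcStats",
    "fit_linear_assoc",
    "f_statistic",
    "relative_bias",
    "hwe_test",
    "compute_snp_qc",
    "qc_filter",
    "select_instruments",
    "interaction_test",
    "association_table",
]

WEAK_F = 10.0
#: Below this first-stage F the 1/F bias approximation is unreliable and the
#: relative bias is reported as undefined.
MIN_F_FOR_BIAS = 1.9


@dataclass(frozen=True)
class AssociationResult:
    """Summary of one SNP's association with a continuous trait.

    beta/se/p come from the covariate-adjusted model; r2 and f_stat from the
    simple (unadjusted) regression, as conventional for first-stage
    instrument-strength reporting.
    """

    snp_id: str
    n: int
    maf: float
    beta: float
    se: float
    p: float
    r2: float
    f_stat: float
    relative_bias: Optional[float]
    weak: bool
    gene: Optional[str] = None


@dataclass(frozen=True)
class QcThresholds:
    """Genotype QC inclusion thresholds; a SNP passes only with HWE p, MAF and
    call rate strictly above each bound."""

    hwe_p_min: float = 0.01
    maf_min: float = 0.01
    call_rate_min: float = 0.80

    def __post_init__(self):
        for v in (self.hwe_p_min, self.maf_min, self.call_rate_min):
            if not (0.0 < v < 1.0):
                raise ValueError("QC thresholds must be in (0, 1)")


@dataclass(frozen=True)
class SnpQcStats:
    snp_id: str
    maf: float
    call_rate: float
    hwe_p: float


def _design(cols: Sequence[np.ndarray]) -> np.ndarray:
    X = np.column_stack(cols)
    return sm.add_constant(X, has_constant="add")


def _complete_rows(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= ~np.isnan(a)
    return mask


def fit_linear_assoc(
    response,
    dosage,
    covariates: Optional[Mapping[str, np.ndarray]] = None,
    snp_id: str = "snp",
    gene: Optional[str] = None,
) -> AssociationResult:
    """OLS association of a continuous response with an additively coded SNP.

    Rows with any missing value are dropped (complete-case n reported). The
    dosage is re-oriented to count the minor allele if needed, so the
    reported beta is per minor allele.
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(dosage, dtype=float)
    cov_arrays = []
    if covariates:
        cov_arrays = [np.asarray(v, dtype=float) for v in covariates.values()]
    mask = _complete_rows(y, g, *cov_arrays)
    y, g = y[mask], g[mask]
    cov_arrays = [c[mask] for c in cov_arrays]
    n = len(y)
    n_params = 2 + len(cov_arrays)
    if n <= n_params:
        raise ValueError(f"{snp_id}: n={n} too small for {n_params} parameters")

    freq = float(np.mean(g) / 2.0)
    if freq > 0.5:
        g = 2.0 - g
        freq = 1.0 - freq
    if np.var(g) == 0:
        raise ValueError(f"{snp_id}: monomorphic SNP")

    if np.var(y) == 0.0:
        # Degenerate constant response: slope and residuals are both zero, so
        # the Wald statistic is undefined; report a null, weak result.
        return AssociationResult(snp_id, n, freq, 0.0, np.inf, 1.0,
                                 0.0, 0.0, None, True, gene)

    adj = sm.OLS(y, _design([g] + cov_arrays)).fit()
    beta, se, p = float(adj.params[1]), float(adj.bse[1]), float(adj.pvalues[1])

    simple = sm.OLS(y, _design([g])).fit()
    r2 = float(simple.rsquared)
    f = np.inf if r2 >= 1.0 - 1e-12 else f_statistic(r2, n)
    return AssociationResult(
        snp_id=snp_id, n=n, maf=freq, beta=beta, se=se, p=p, r2=r2,
        f_stat=f, relative_bias=relative_bias(f) if f >= MIN_F_FOR_BIAS else None,
        weak=bool(f < WEAK_F), gene=gene,
    )


def f_statistic(r2: float, n: int) -> float:
    """First-stage F from the variance fraction: F = (n−2)·r2/(1−r2).

    Identical to the regression F of the simple linear model with one
    predictor on n observations.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return (n - 2) * r2 / (1.0 - r2)


def relative_bias(f_stat: float) -> Optional[float]:
    """Approximate relative bias of IV vs OLS, 100/F percent (1 decimal).

    Undefined (None) below F = 1.9, where the approximation breaks down.
    """
    if f_stat < MIN_F_FOR_BIAS:
        return None
    return round(100.0 / f_stat, 1)


def hwe_test(genotype_counts: Sequence[int]) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    ``genotype_counts`` is (n_AA, n_Aa, n_aa). The allele frequency is
    estimated from the counts; one df is lost to it.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_bb + n_ab) / (2.0 * n)
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: trivially consistent with HWE
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def compute_snp_qc(genotypes: GenotypeMatrix) -> list[SnpQcStats]:
    """Per-SNP MAF, call rate and HWE p from a dosage matrix."""
    out = []
    for sid in genotypes.snp_ids:
        g = genotypes.dosage(sid)
        called = g[~np.isnan(g)]
        call_rate = len(called) / len(g)
        if len(called) == 0:
            out.append(SnpQcStats(sid, 0.0, 0.0, 1.0))
            continue
        f = float(np.mean(called) / 2.0)
        maf = min(f, 1.0 - f)
        counts = [int(np.sum(called == k)) for k in (0, 1, 2)]
        out.append(SnpQcStats(sid, maf, call_rate, hwe_test(counts)))
    return out


def qc_filter(snp_stats: Iterable[SnpQcStats],
              thresholds: QcThresholds = QcThresholds()) -> pd.DataFrame:
    """Apply inclusion criteria; returns one row per SNP with pass flag and
    failure reasons. Boundaries are strict: a SNP exactly at a threshold
    fails."""
    rows = []
    for s in snp_stats:
        reasons = []
        if s.hwe_p <= thresholds.hwe_p_min:
            reasons.append("HWE")
        if s.maf <= thresholds.maf_min:
            reasons.append("MAF")
        if s.call_rate <= thresholds.call_rate_min:
            reasons.append("call_rate")
        rows.append({"snp_id": s.snp_id, "maf": s.maf, "call_rate": s.call_rate,
                     "hwe_p": s.hwe_p, "passed": not reasons,
                     "reasons": ",".join(reasons)})
    return pd.DataFrame(rows)


def select_instruments(
    results: Sequence[AssociationResult],
    gene_map: Mapping[str, str],
    gwa_default_snps: Iterable[str],
    n_candidate_genes: int,
    replication_flags: Iterable[str] = (),
    borderline_factor: float = 2.0,
) -> pd.DataFrame:
    """Bonferroni instrument selection.

    SNPs in ``gwa_default_snps`` are carried forward by default. Other SNPs
    are selected iff p < 0.05 / n_candidate_genes (genes, not SNPs, in the
    denominator to allow for within-gene LD). A non-selected SNP with prior
    replication evidence and p below ``borderline_factor`` times the
    threshold is marked "borderline" for further evaluation.
    """
    if n_candidate_genes <= 0:
        raise ValueError("n_candidate_genes must be positive")
    thr = 0.05 / n_candidate_genes
    gwa = set(gwa_default_snps)
    rep = set(replication_flags)
    rows = []
    for r in results:
        if r.snp_id in gwa:
            status = "selected_default"
        elif r.p < thr:
            status = "selected"
        elif r.snp_id in rep and r.p < borderline_factor * thr:
            status = "borderline"
        else:
            status = "excluded"
        rows.append({"snp_id": r.snp_id, "gene": gene_map.get(r.snp_id, r.gene),
                     "p": r.p, "threshold": thr, "status": status})
    return pd.DataFrame(rows)


def interaction_test(
    response,
    term_a,
    term_b,
    covariates: Optional[Mapping[str, np.ndarray]] = None,
    bonferroni_m: int = 5,
) -> tuple[float, bool]:
    """Wald test of the a x b product term in a linear model, flagged at the
    Bonferroni level 0.05 / bonferroni_m."""
    y = np.asarray(response, float)
    a = np.asarray(term_a, float)
    b = np.asarray(term_b, float)
    cov = [np.asarray(v, float) for v in (covariates or {}).values()]
    mask = _complete_rows(y, a, b, *cov)
    y, a, b = y[mask], a[mask], b[mask]
    cov = [c[mask] for c in cov]
    X = _design([a, b, a * b] + cov)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("interaction term collinear with main effects")
    fit = sm.OLS(y, X).fit()
    p = float(fit.pvalues[3])
    return p, bool(p < 0.05 / bonferroni_m)


def association_table(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    adjust_sex: bool = True,
) -> pd.DataFrame:
    """Per-SNP association summary in the conventional table layout
    (gene, SNP, n, MAF, beta, SE, p, % variance, F, relative bias %)."""
    cov = {"sex": np.asarray(cohort.sex, float)} if adjust_sex else None
    rows = []
    for s in genotypes.snps:
        try:
            r = fit_linear_assoc(cohort.lnx, genotypes.dosage(s.snp_id),
                                 covariates=cov, snp_id=s.snp_id, gene=s.gene)
        except ValueError as e:
            warnings.warn(str(e), stacklevel=2)
            continue
        rows.append({
            "gene": s.gene, "snp": r.snp_id, "n": r.n, "maf": round(r.maf, 2),
            "beta": r.beta, "se": r.se, "p": r.p,
            "pct_variance": 100.0 * r.r2, "f_stat": r.f_stat,
            "relative_bias_pct": r.relative_bias,
        })
    return pd.DataFrame(rows)
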