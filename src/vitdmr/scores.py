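"""Un-weighted vitamin-D-lowering allele scores.

A score counts, across a set of pathway SNPs, the number of alleles that
lower 25(OH)D; a SNP whose minor allele raises 25(OH)D contributes 2−g. The
canonical pathway groupings are:

* synthesis — DHCR7, CYP2R1 (upstream of 25(OH)D production)
* metabolism — GC, CYP24A1, CYP27B1 (downstream)
* metabolism_gwa — GC, CYP24A1 (the GWA-confirmed subset)

Sparse top score categories are merged downward before categorical analysis,
and category-level 25(OH)D is summarized by geometric means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import assoc
from .synthdata import GenotypeMatrix, SnpSpec

__all__ = [
    "PATHWAY_GENES",
    "AlleleScoreDefinition",
    "ScoreSummary",
    "pathway_definition",
    "build_score",
    "collapse_categories",
    "geometric_mean_ci",
    "score_association",
]

PATHWAY_GENES: dict[str, frozenset[str]] = {
    "synthesis": frozenset({"DHCR7", "CYP2R1"}),
    "metabolism": frozenset({"GC", "CYP24A1", "CYP27B1"}),
    "metabolism_gwa": frozenset({"GC", "CYP24A1"}),
}


@dataclass(frozen=True)
class AlleleScoreDefinition:
    """Membership and allele orientation of an un-weighted allele score.

    ``flip`` maps snp_id -> True when the stored dosage counts a
    25(OH)D-raising minor allele and must be replaced by 2−g so that the
    counted allele is always the lowering one. Orientation is fixed from the
    designated lowering alleles, not re-estimated from the data at hand.
    """

    name: str
    snp_ids: tuple[str, ...]
    flip: Mapping[str, bool]
    collapse_min: int = 100

    def __post_init__(self):
        if not self.snp_ids:
            raise ValueError("score must contain at least one SNP")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP in score definition")

    @classmethod
    def from_snps(cls, name: str, snps: Sequence[SnpSpec],
                  collapse_min: int = 100) -> "AlleleScoreDefinition":
        return cls(
            name=name,
            snp_ids=tuple(s.snp_id for s in snps),
            flip={s.snp_id: not s.lowering for s in snps},
            collapse_min=collapse_min,
        )


def pathway_definition(name: str, snps: Sequence[SnpSpec],
                       collapse_min: int = 100) -> AlleleScoreDefinition:
    """Build the named pathway score from whichever of its member genes are
    present in ``snps``."""
    genes = PATHWAY_GENES[name]
    members = [s for s in snps if s.gene in genes]
    if not members:
        raise ValueError(f"no SNPs from genes {sorted(genes)} available")
    return AlleleScoreDefinition.from_snps(name, members, collapse_min)


def build_score(genotypes: GenotypeMatrix,
                definition: AlleleScoreDefinition) -> np.ndarray:
    """Count lowering alleles per individual; NaN when any member genotype is
    missing (score-complete cases only). Range [0, 2·k] for k member SNPs."""
    cols = []
    for sid in definition.snp_ids:
        g = genotypes.dosage(sid)  # raises KeyError naming an absent SNP
        cols.append(2.0 - g if definition.flip.get(sid, False) else g)
    return np.sum(np.column_stack(cols), axis=1)


def collapse_categories(scores, collapse_min: int = 100) -> pd.Categorical:
    """Merge sparse top score categories into their lower neighbour.

    While the topmost category holds fewer than ``collapse_min`` individuals
    it is merged downward; labels list the merged values, e.g. "4, 5, 6".
    Total count is preserved. NaN scores yield NaN categories.
    """
    if collapse_min < 1:
        raise ValueError("collapse_min must be >= 1")
    s = np.asarray(scores, dtype=float)
    valid = s[~np.isnan(s)]
    if valid.size == 0:
        raise ValueError("no non-missing scores to categorize")
    levels = [[int(v)] for v in np.sort(np.unique(valid))]
    counts = {int(v): int(np.sum(valid == v)) for v in np.unique(valid)}

    def level_count(level):
        return sum(counts[v] for v in level)

    while len(levels) > 1 and level_count(levels[-1]) < collapse_min:
        top = levels.pop()
        levels[-1] = levels[-1] + top

    labels = [", ".join(str(v) for v in lev) for lev in levels]
    value_to_label = {v: lab for lev, lab in zip(levels, labels) for v in lev}
    assigned = pd.Series(s).map(lambda v: value_to_label.get(int(v)) if not np.isnan(v) else np.nan)
    return pd.Categorical(assigned, categories=labels, ordered=True)


def geometric_mean_ci(x, z: float = 1.96) -> tuple[float, float, float]:
    """Geometric mean with normal-theory CI on the log scale:
    exp(mean(ln x) ± z·sd(ln x)/√n)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(np.isnan(x)):
        raise ValueError("all values must be positive and non-missing")
    lx = np.log(x)
    m = float(np.mean(lx))
    if len(x) == 1:
        return float(np.exp(m)), float(np.exp(m)), float(np.exp(m))
    sem = float(np.std(lx, ddof=1) / np.sqrt(len(x)))
    return float(np.exp(m)), float(np.exp(m - z * sem)), float(np.exp(m + z * sem))


@dataclass
class ScoreSummary:
    """Category-level and per-allele association of an allele score with
    ln 25(OH)D. ``categories`` holds one row per (collapsed) score category:
    n, geometric mean of 25(OH)D with CI, and the ln-scale contrast against
    the zero-lowering-allele reference."""

    name: str
    categories: pd.DataFrame
    per_allele: assoc.AssociationResult
    n_total: int


def score_association(
    lnx,
    scores,
    covariates: Optional[Mapping[str, np.ndarray]] = None,
    collapse_min: int = 100,
    name: str = "score",
) -> ScoreSummary:
    """Fit the categorical (vs reference category) and per-allele models of
    ln 25(OH)D on an allele score, with instrument-strength metrics for the
    per-allele model."""
    lnx = np.asarray(lnx, dtype=float)
    s = np.asarray(scores, dtype=float)
    cov_items = list((covariates or {}).items())
    cov_arrays = [np.asarray(v, float) for _, v in cov_items]
    mask = ~np.isnan(lnx) & ~np.isnan(s)
    for c in cov_arrays:
        mask &= ~np.isnan(c)
    lnx, s = lnx[mask], s[mask]
    cov_arrays = [c[mask] for c in cov_arrays]

    cats = collapse_categories(s, collapse_min)
    labels = list(cats.categories)
    if len(labels) < 2:
        raise ValueError("score has a single category; no contrast possible")

    codes = np.asarray(cats.codes)
    dummies = [(codes == k).astype(float) for k in range(1, len(labels))]
    fit = sm.OLS(lnx, sm.add_constant(np.column_stack(dummies + cov_arrays),
                                      has_constant="add")).fit()

    x = np.exp(lnx)
    rows = [{"category": labels[0], "n": int(np.sum(codes == 0)),
             **dict(zip(("gm", "gm_lo", "gm_hi"), geometric_mean_ci(x[codes == 0]))),
             "beta": 0.0, "se": np.nan}]
    for k in range(1, len(labels)):
        sel = codes == k
        gm, lo, hi = geometric_mean_ci(x[sel])
        rows.append({"category": labels[k], "n": int(np.sum(sel)),
                     "gm": gm, "gm_lo": lo, "gm_hi": hi,
                     "beta": float(fit.params[k]), "se": float(fit.bse[k])})
    categories = pd.DataFrame(rows)

    # Per-allele model fit directly (scores exceed the 0-2 dosage range, so the
    # minor-allele reflection in fit_linear_assoc does not apply).
    fitp = sm.OLS(lnx, sm.add_constant(np.column_stack([s] + cov_arrays),
                                       has_constant="add")).fit()
    simple = sm.OLS(lnx, sm.add_constant(s, has_constant="add")).fit()
    r2 = float(simple.rsquared)
    f = assoc.f_statistic(r2, len(lnx))
    per_allele = assoc.AssociationResult(
        snp_id=f"{name}_per_allele", n=len(lnx), maf=np.nan,
        beta=float(fitp.params[1]), se=float(fitp.bse[1]),
        p=float(fitp.pvalues[1]), r2=r2, f_stat=f,
        relative_bias=assoc.relative_bias(f) if f >= assoc.MIN_F_FOR_BIAS else None,
        weak=bool(f < assoc.WEAK_F),
    )
    return ScoreSummary(name=name, categories=categories,
                        per_allele=per_allele, n_total=len(lnx))
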