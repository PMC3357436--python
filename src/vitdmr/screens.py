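"""Confounding, pleiotropy and sensitivity screens for candidate instruments.

Three checks on the core instrumental-variable assumptions:

* ``confounder_screen`` — direct instrument-lifestyle associations by
  logistic regression, Bonferroni-corrected over the factor list (0.05/14
  for the default 14 factors).
* ``pleiotropy_screen`` — direct instrument-biomarker associations adjusted
  for ln 25(OH)D (0.05/15 for the default 15 biomarkers): a path that acts
  only through 25(OH)D attenuates under the adjustment, a pleiotropic one
  does not.
* ``adjustment_sensitivity`` — the instrument-25(OH)D association with and
  without covariate adjustment; loss of significance flags an association
  driven by confounding rather than a direct genetic effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ScreenResult",
    "SensitivityResult",
    "confounder_screen",
    "pleiotropy_screen",
    "adjustment_sensitivity",
    "dichotomize_region",
    "screens_table",
]


@dataclass(frozen=True)
class ScreenResult:
    instrument_id: str
    target_name: str
    target_kind: str  # lifestyle | region | biomarker
    model: str  # logistic | linear
    estimate: float  # log-odds (logistic) or beta (linear)
    se: float
    p: float
    bonferroni_threshold: float
    flagged: bool


@dataclass(frozen=True)
class SensitivityResult:
    instrument_id: str
    beta_unadjusted: float
    p_unadjusted: float
    beta_adjusted: float
    p_adjusted: float
    adjustment_set: tuple[str, ...]
    attenuated: bool


def dichotomize_region(region) -> np.ndarray:
    """South/Middle (0) vs North/Scotland (1), the screening dichotomy for
    the four-level region variable."""
    r = np.asarray(region, dtype=object)
    return np.where(pd.isna(r), np.nan,
                    np.isin(r, ("North", "Scotland")).astype(float))


def _complete(*arrays):
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= ~np.isnan(np.asarray(a, dtype=float))
    return mask


def confounder_screen(
    instrument,
    factors: pd.DataFrame,
    covariates: Optional[Mapping[str, np.ndarray]] = None,
    instrument_id: str = "instrument",
    region_factors: Sequence[str] = ("region",),
) -> list[ScreenResult]:
    """Logistic screen of an instrument against binary lifestyle/social
    factors. The Bonferroni denominator is the number of factors supplied.
    A factor with a single observed level is skipped with a warning."""
    z = np.asarray(instrument, dtype=float)
    cov = {k: np.asarray(v, float) for k, v in (covariates or {}).items()}
    thr = 0.05 / factors.shape[1]
    out: list[ScreenResult] = []
    for name in factors.columns:
        f = np.asarray(factors[name], dtype=float)
        mask = _complete(z, f, *cov.values())
        fm, zm = f[mask], z[mask]
        if len(np.unique(fm)) < 2:
            warnings.warn(f"factor {name!r} has one level; skipped", stacklevel=2)
            continue
        X = sm.add_constant(
            np.column_stack([zm] + [c[mask] for c in cov.values()]),
            has_constant="add")
        try:
            fit = sm.Logit(fm, X).fit(disp=0)
            est, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            warnings.warn(f"logistic fit failed for {name!r}; skipped", stacklevel=2)
            continue
        kind = "region" if name in region_factors else "lifestyle"
        out.append(ScreenResult(instrument_id, name, kind, "logistic",
                                est, se, p, thr, bool(p < thr)))
    return out


def pleiotropy_screen(
    instrument,
    biomarkers: pd.DataFrame,
    lnx,
    covariates: Optional[Mapping[str, np.ndarray]] = None,
    instrument_id: str = "instrument",
) -> list[ScreenResult]:
    """Linear screen biomarker ~ instrument + ln 25(OH)D (+ covariates).
    The Bonferroni denominator is the number of biomarkers supplied."""
    z = np.asarray(instrument, dtype=float)
    lx = np.asarray(lnx, dtype=float)
    cov = {k: np.asarray(v, float) for k, v in (covariates or {}).items()}
    thr = 0.05 / biomarkers.shape[1]
    out: list[ScreenResult] = []
    for name in biomarkers.columns:
        b = np.asarray(biomarkers[name], dtype=float)
        mask = _complete(z, b, lx, *cov.values())
        bm = b[mask]
        if np.var(bm) == 0:
            warnings.warn(f"biomarker {name!r} is constant; skipped", stacklevel=2)
            continue
        X = sm.add_constant(
            np.column_stack([z[mask], lx[mask]] + [c[mask] for c in cov.values()]),
            has_constant="add")
        fit = sm.OLS(bm, X).fit()
        est, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
        out.append(ScreenResult(instrument_id, name, "biomarker", "linear",
                                est, se, p, thr, bool(p < thr)))
    return out


def adjustment_sensitivity(
    instrument,
    lnx,
    adjustment_sets: Mapping[str, pd.DataFrame],
    instrument_id: str = "instrument",
) -> list[SensitivityResult]:
    """Instrument-ln 25(OH)D association with and without each adjustment
    set (a single joint model per set). ``attenuated`` marks associations
    significant unadjusted (p < 0.05) but not after adjustment."""
    z = np.asarray(instrument, dtype=float)
    lx = np.asarray(lnx, dtype=float)
    out: list[SensitivityResult] = []
    for set_name, adj in adjustment_sets.items():
        cols = list(adj.columns)
        for c in cols:
            if np.array_equal(np.asarray(adj[c], float), z, equal_nan=True):
                raise ValueError(
                    f"adjustment set {set_name!r}: column {c!r} duplicates the instrument")
        arrays = [np.asarray(adj[c], float) for c in cols]
        mask = _complete(z, lx, *arrays)
        zu, lu = z[mask], lx[mask]
        unadj = sm.OLS(lu, sm.add_constant(zu, has_constant="add")).fit()
        if cols:
            Xa = sm.add_constant(np.column_stack([zu] + [a[mask] for a in arrays]),
                                 has_constant="add")
            adj_fit = sm.OLS(lu, Xa).fit()
        else:
            adj_fit = unadj
        bu, pu = float(unadj.params[1]), float(unadj.pvalues[1])
        ba, pa = float(adj_fit.params[1]), float(adj_fit.pvalues[1])
        out.append(SensitivityResult(
            instrument_id=instrument_id, beta_unadjusted=bu, p_unadjusted=pu,
            beta_adjusted=ba, p_adjusted=pa, adjustment_set=tuple(cols),
            attenuated=bool(pu < 0.05 and pa >= 0.05),
        ))
    return out


def screens_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Long-format screen summary (one row per instrument-target pair)."""
    return pd.DataFrame(
        [{"instrument": r.instrument_id, "target": r.target_name,
          "kind": r.target_kind, "model": r.model, "estimate": r.estimate,
          "se": r.se, "p": r.p, "threshold": r.bonferroni_threshold,
          "flagged": r.flagged} for r in results]
    )
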