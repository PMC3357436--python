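"""Two-stage least squares IV estimation and Monte-Carlo power / sample-size
calculation for Mendelian-randomization designs.

The causal effect of 25(OH)D (nmol/L) on the outcome is estimated by 2SLS:
stage 1 regresses the exposure on the instrument(s) (+ covariates), stage 2
regresses the outcome on the fitted exposure, with the residual variance of
the second stage computed against the *observed* exposure (the standard 2SLS
variance, not naive OLS-on-fitted). With a single instrument and no
covariates the estimate reduces to the Wald ratio cov(z,y)/cov(z,x).

Power for a given sample size is the fraction of simulated cohorts in which
the 2SLS test rejects at level alpha; the sample size for a target power is
found by bisection around an analytic normal-approximation warm start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from . import scores as scores_mod
from .synthdata import CohortModel, simulate_cohort

__all__ = [
    "TslsFit",
    "PowerResult",
    "PowerCurve",
    "tsls_fit",
    "instrument_columns",
    "power_simulation",
    "power_curve",
    "analytic_sample_size",
    "sample_size_for_power",
]

WEAK_F = 10.0


@dataclass(frozen=True)
class TslsFit:
    """2SLS estimate of the causal effect (outcome units per exposure unit)."""

    estimate: float
    se: float
    p: float
    first_stage_f: float
    n: int
    instrument_ids: tuple[str, ...]

    @property
    def weak(self) -> bool:
        return self.first_stage_f < WEAK_F


@dataclass(frozen=True)
class PowerResult:
    n: int
    reps: int
    alpha: float
    power: float
    seed: int

    @property
    def mc_se(self) -> float:
        """Binomial Monte-Carlo standard error of the power estimate."""
        return float(np.sqrt(self.power * (1.0 - self.power) / self.reps))


@dataclass
class PowerCurve:
    instrument: str
    grid: list[PowerResult]
    n_at_target: Optional[int] = None
    target_power: Optional[float] = None


def tsls_fit(
    y,
    x,
    instruments,
    covariates=None,
    instrument_ids: Optional[Sequence[str]] = None,
    robust: bool = False,
) -> TslsFit:
    """Two-stage least squares fit of y on x using ``instruments``.

    instruments: 1-D vector or (n, k) matrix of excluded instruments.
    covariates: optional (n, c) matrix of exogenous covariates included in
    both stages. Inference uses the asymptotic normal distribution; pass
    robust=True for an HC0 sandwich variance.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Z_excl = np.atleast_2d(np.asarray(instruments, dtype=float))
    if Z_excl.shape[0] == 1 and len(y) != 1:
        Z_excl = Z_excl.T
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] == 1 and len(y) != 1:
            C = C.T
    n = len(y)
    ones = np.ones((n, 1))
    Z = np.hstack([ones, Z_excl] + ([C] if C is not None else []))
    X = np.hstack([ones, x[:, None]] + ([C] if C is not None else []))
    k = X.shape[1]
    if n <= max(k, Z.shape[1]):
        raise ValueError("sample size too small for the number of parameters")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient instrument matrix")

    # Projection of X on the instrument space via least squares.
    coef, *_ = np.linalg.lstsq(Z, X, rcond=None)
    Xhat = Z @ coef
    XtX = Xhat.T @ X  # equals Xhat'Xhat
    beta = np.linalg.solve(XtX, Xhat.T @ y)
    u = y - X @ beta  # residuals against observed X
    bread = np.linalg.inv(Xhat.T @ Xhat)
    if robust:
        meat = (Xhat * (u ** 2)[:, None]).T @ Xhat
        cov_b = bread @ meat @ bread
    else:
        sigma2 = float(u @ u) / (n - k)
        cov_b = sigma2 * bread
    est = float(beta[1])
    se = float(np.sqrt(cov_b[1, 1]))
    p = float(2.0 * stats.norm.sf(abs(est) / se))

    f = _first_stage_f(x, Z_excl, C)
    fit = TslsFit(estimate=est, se=se, p=p, first_stage_f=f, n=n,
                  instrument_ids=tuple(instrument_ids or
                                       (f"z{j}" for j in range(Z_excl.shape[1]))))
    if f < WEAK_F:
        warnings.warn(
            f"weak instrument: first-stage F = {f:.2f} < {WEAK_F:g}", stacklevel=2)
    return fit


def _first_stage_f(x, Z_excl, C) -> float:
    """Partial F of the excluded instruments in the first stage."""
    n = len(x)
    ones = np.ones((n, 1))
    X1 = np.hstack([ones, Z_excl] + ([C] if C is not None else []))
    X0 = ones if C is None else np.hstack([ones, C])
    rss1 = _rss(x, X1)
    rss0 = _rss(x, X0)
    q = Z_excl.shape[1]
    df2 = n - X1.shape[1]
    if rss1 <= 0:
        return float("inf")
    return float(((rss0 - rss1) / q) / (rss1 / df2))


def _rss(y, X) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


# ---------------------------------------------------------------------------
# Instrument specification for power runs

InstrumentSpec = Union[str, scores_mod.AlleleScoreDefinition,
                       Sequence[scores_mod.AlleleScoreDefinition]]


def instrument_columns(model: CohortModel, genotypes,
                       spec: InstrumentSpec) -> tuple[np.ndarray, tuple[str, ...]]:
    """Resolve an instrument specification to a column matrix.

    Accepted forms: a SNP id present in the model; a pathway score name
    ("synthesis", "metabolism", "metabolism_gwa"); "both" (synthesis +
    metabolism scores as two columns, entered per-allele as in the
    categorical-free per-allele models); an AlleleScoreDefinition; or a
    sequence of definitions.
    """
    if isinstance(spec, str):
        if spec == "both":
            defs = [scores_mod.pathway_definition(p, model.snps)
                    for p in ("synthesis", "metabolism")]
        elif spec in scores_mod.PATHWAY_GENES:
            defs = [scores_mod.pathway_definition(spec, model.snps)]
        else:
            return genotypes.dosage(spec)[:, None], (spec,)
    elif isinstance(spec, scores_mod.AlleleScoreDefinition):
        defs = [spec]
    else:
        defs = list(spec)
    cols = np.column_stack([scores_mod.build_score(genotypes, d) for d in defs])
    return cols, tuple(d.name for d in defs)


def power_simulation(
    model: CohortModel,
    instrument: InstrumentSpec,
    n: int,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of the 2SLS causal-effect test.

    Each replicate simulates a fresh cohort of size n from ``model``, builds
    the instrument column(s), runs 2SLS of the outcome on 25(OH)D, and
    records whether p < alpha. Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    model = _reduced_model(model, instrument)
    r2 = _instrument_r2_lnx(model, instrument)
    if r2 <= 0:
        warnings.warn("instrument explains no exposure variance; power ~= alpha",
                      stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # weak-instrument warnings per rep
        for _ in range(reps):
            gm, cohort = simulate_cohort(model, n, rng)
            cols, ids = instrument_columns(model, gm, instrument)
            fit = tsls_fit(cohort.y, cohort.x, cols, instrument_ids=ids)
            hits += fit.p < alpha
    return PowerResult(n=n, reps=reps, alpha=alpha, power=hits / reps, seed=seed)


def power_curve(
    model: CohortModel,
    instrument: InstrumentSpec,
    grid: Sequence[int],
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerCurve:
    """Power at each sample size in ``grid`` (independent streams per point)."""
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(len(grid)) % (2 ** 31)
    results = [power_simulation(model, instrument, int(n), reps, alpha, int(s))
               for n, s in zip(grid, children)]
    name = instrument if isinstance(instrument, str) else "custom"
    return PowerCurve(instrument=name, grid=results)


def _reduced_model(model: CohortModel, spec: InstrumentSpec) -> CohortModel:
    """Drop SNPs the instrument does not use (their ln-scale contribution is
    absorbed into the residual, leaving the joint law of the instrument,
    exposure and outcome unchanged); referenced SNPs are always kept."""
    from dataclasses import replace

    if isinstance(spec, str) and spec not in scores_mod.PATHWAY_GENES and spec != "both":
        needed = {spec}
    elif isinstance(spec, str):
        names = ("synthesis", "metabolism") if spec == "both" else (spec,)
        needed = set()
        for p in names:
            needed |= set(scores_mod.pathway_definition(p, model.snps).snp_ids)
    elif isinstance(spec, scores_mod.AlleleScoreDefinition):
        needed = set(spec.snp_ids)
    else:
        needed = {sid for d in spec for sid in d.snp_ids}
    needed |= {c.snp_assoc for c in model.confounders if c.snp_assoc}
    for b in model.biomarkers:
        needed |= set(b.snp_effects)
    if model.region_assoc_snp:
        needed.add(model.region_assoc_snp)
    kept = tuple(s for s in model.snps if s.snp_id in needed)
    if len(kept) == len(model.snps):
        return model
    return replace(model, snps=kept)


def _instrument_r2_lnx(model: CohortModel, spec: InstrumentSpec) -> float:
    """Population R² of the instrument on ln 25(OH)D (independent SNPs).

    For a single score column: R² = (Σ|β|·2pq)² / (Σ2pq · sd_lnx²); for
    multiple columns (independent members) the per-column R² values add.
    """
    if isinstance(spec, str) and spec not in scores_mod.PATHWAY_GENES and spec != "both":
        return model.snp(spec).r2(model.sd_lnx)
    if isinstance(spec, str):
        names = ("synthesis", "metabolism") if spec == "both" else (spec,)
        defs = [scores_mod.pathway_definition(p, model.snps) for p in names]
    elif isinstance(spec, scores_mod.AlleleScoreDefinition):
        defs = [spec]
    else:
        defs = list(spec)
    total = 0.0
    for d in defs:
        num = sum(abs(model.snp(sid).beta_lnx) * model.snp(sid).var_dosage
                  for sid in d.snp_ids)
        den = sum(model.snp(sid).var_dosage for sid in d.snp_ids)
        total += num ** 2 / (den * model.sd_lnx ** 2)
    return total


def analytic_sample_size(
    model: CohortModel,
    instrument: InstrumentSpec,
    target_power: float = 0.80,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation sample size for the 2SLS test:
    n ≈ (z_{1−α/2} + z_{power})² / (R²_zx · ρ²_xy / (1 − ρ²_xy)),
    with the instrument-exposure R² mapped from the ln to the natural
    25(OH)D scale and ρ_xy the standardized causal exposure-outcome
    correlation."""
    r2_lnx = _instrument_r2_lnx(model, instrument)
    if r2_lnx <= 0:
        raise ValueError("instrument explains no exposure variance")
    s2 = model.sd_lnx ** 2
    damp = s2 / np.expm1(s2)  # corr(z, exp(W))² / corr(z, W)² for normal W
    r2_zx = r2_lnx * damp
    rho = model.causal_slope_sd * model.sd_x
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(target_power)
    return float(z ** 2 * (1 - rho ** 2) / (r2_zx * rho ** 2))


def sample_size_for_power(
    model: CohortModel,
    instrument: InstrumentSpec,
    target_power: float = 0.80,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    n_bounds: tuple[int, int] = (1000, 1_000_000),
    bracket_tol: int = 2000,
) -> PowerCurve:
    """Smallest sample size whose Monte-Carlo 2SLS power reaches
    ``target_power``, by bisection warm-started at the analytic
    approximation.

    Bisection stops when the bracket is narrower than ``bracket_tol``
    individuals or the current power estimate's 95% CI contains the target.
    Returns the curve of evaluated points with ``n_at_target`` set.
    """
    if not (alpha < target_power < 1):
        raise ValueError("target_power must be in (alpha, 1)")
    lo_n, hi_n = n_bounds
    n0 = int(np.clip(analytic_sample_size(model, instrument, target_power, alpha),
                     lo_n, hi_n))

    ss = np.random.SeedSequence(seed)
    evaluated: dict[int, PowerResult] = {}

    def power_at(n: int) -> PowerResult:
        if n not in evaluated:
            child = int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31)) ^ (n % (2 ** 31))
            evaluated[n] = power_simulation(model, instrument, n, reps, alpha,
                                            seed=child)
        return evaluated[n]

    # Bracket the target starting from the warm start: hi tracks the smallest
    # n seen with power >= target, lo the largest with power < target.
    lo, hi = n0, n0
    if power_at(n0).power >= target_power:
        while lo > lo_n:
            cand = max(lo_n, int(lo / 1.5))
            if power_at(cand).power < target_power:
                lo = cand
                break
            hi = lo = cand
    else:
        while hi < hi_n:
            cand = min(hi_n, int(hi * 1.5))
            if power_at(cand).power >= target_power:
                hi = cand
                break
            lo = hi = cand
        if power_at(hi).power < target_power:
            raise RuntimeError(
                f"target power {target_power} not reached by n = {hi_n} "
                f"(last bracket [{lo}, {hi}])")

    while hi - lo > bracket_tol:
        mid = (lo + hi) // 2
        r = power_at(mid)
        # Accept mid when its power CI contains the target, but only once the
        # bracket is narrow enough that the CI rule pins the crossing rather
        # than firing on a distant midpoint.
        if (abs(r.power - target_power) < 1.96 * r.mc_se
                and hi - lo <= max(bracket_tol, int(0.15 * mid))):
            hi = mid
            break
        if r.power >= target_power:
            hi = mid
        else:
            lo = mid

    grid = [evaluated[k] for k in sorted(evaluated)]
    name = instrument if isinstance(instrument, str) else "custom"
    return PowerCurve(instrument=name, grid=grid, n_at_target=int(hi),
                      target_power=target_power)
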