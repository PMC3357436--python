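"""Synthetic cohort generation for vitamin D Mendelian-randomization studies.

Generates cohorts with the statistical structure of a mid-life British birth
cohort: independent SNPs in Hardy-Weinberg equilibrium, log-normally
distributed serum 25-hydroxyvitamin D (25(OH)D, nmol/L) with additive
per-allele effects on the natural-log scale, binary lifestyle/dietary
factors, a four-level geographical region with an optional allele-frequency
gradient for one SNP, continuous biomarkers, and a blood-pressure-like
outcome causally downstream of 25(OH)D.

All stochastic functions take an explicit integer seed (or a
``numpy.random.Generator``) and are deterministic given it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpSpec",
    "ConfounderSpec",
    "BiomarkerSpec",
    "CohortModel",
    "GenotypeMatrix",
    "CohortTable",
    "REGION_LEVELS",
    "simulate_genotypes",
    "calibrate_sd_lnx",
    "simulate_cohort",
    "cohort_model_1958bc",
    "power_model",
    "LIFESTYLE_FACTOR_NAMES",
    "BIOMARKER_NAMES",
]

REGION_LEVELS = ("South", "Middle", "North", "Scotland")

#: The 14 lifestyle/social screen targets (13 Bernoulli factors; region is
#: carried separately on the cohort and dichotomized when screened).
LIFESTYLE_FACTOR_NAMES = (
    "time_outside",
    "sun_cover",
    "oily_fish",
    "vitd_supplement",
    "season_winter",
    "smoking",
    "alcohol",
    "pc_tv_time",
    "met_hours_low",
    "manual_social_class",
    "bmi_high",
    "abdominal_obesity",
    "sex_male",
)

#: The 15 biomarkers screened for pleiotropy.
BIOMARKER_NAMES = (
    "vwf", "tpa", "d_dimer", "fibrinogen", "crp", "ige",
    "triglycerides", "ldl", "hdl", "total_cholesterol", "fev",
    "dbp", "sbp", "igf1", "hba1c",
)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_ids(n: int) -> np.ndarray:
    return np.char.add("id", np.arange(n).astype("U"))


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic SNP: identity, minor allele frequency and its per-minor-allele
    effect on ln 25(OH)D.

    ``lowering`` marks whether the minor allele lowers 25(OH)D (beta < 0);
    allele scores count lowering alleles, so raising minor alleles are flipped
    at score construction.
    """

    snp_id: str
    gene: str
    maf: float
    beta_lnx: float
    lowering: Optional[bool] = None

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF must be in (0, 0.5], got {self.maf}")
        if not np.isfinite(self.beta_lnx):
            raise ValueError(f"{self.snp_id}: beta_lnx must be finite")
        if self.lowering is None:
            object.__setattr__(self, "lowering", bool(self.beta_lnx < 0))
        elif self.beta_lnx != 0 and self.lowering != (self.beta_lnx < 0):
            raise ValueError(
                f"{self.snp_id}: lowering flag inconsistent with sign of beta_lnx"
            )

    @property
    def var_dosage(self) -> float:
        """Variance of the dosage under HWE, 2·maf·(1−maf)."""
        return 2.0 * self.maf * (1.0 - self.maf)

    def r2(self, sd_lnx: float) -> float:
        """Fraction of ln-25(OH)D variance this SNP explains."""
        return self.beta_lnx ** 2 * self.var_dosage / sd_lnx ** 2


@dataclass(frozen=True)
class ConfounderSpec:
    """A binary lifestyle/social factor.

    effect_lnx is in ln-nmol/L; effect_y in outcome-SD units. A non-zero
    ``snp_log_odds`` makes the factor's prevalence depend (per-allele, on the
    log-odds scale) on the dosage of ``snp_assoc``, creating genotype-factor
    confounding for screen tests.
    """

    name: str
    prevalence: float
    effect_lnx: float = 0.0
    effect_y: float = 0.0
    snp_assoc: Optional[str] = None
    snp_log_odds: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"{self.name}: prevalence must be in (0,1)")


@dataclass(frozen=True)
class BiomarkerSpec:
    """A continuous biomarker, optionally loaded on ln 25(OH)D (mediation) or
    directly on SNP dosages (pleiotropy).

    ``loading_lnx`` is the standardized loading on standardized ln 25(OH)D;
    ``snp_effects`` maps SNP id to a standardized per-allele direct effect.
    Residual noise is scaled so the marginal variance is ``sd``².
    """

    name: str
    mean: float = 0.0
    sd: float = 1.0
    loading_lnx: float = 0.0
    snp_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")


@dataclass(frozen=True)
class CohortModel:
    """Generative model for a synthetic cohort.

    Parameters
    ----------
    snps
        SNPs simulated independently under HWE.
    sd_lnx
        Total SD of ln 25(OH)D (ln nmol/L). Residual noise is scaled so the
        marginal variance of ln 25(OH)D equals ``sd_lnx``².
    gm_x
        Geometric mean of 25(OH)D in nmol/L (genetic/covariate contributions
        are mean-centered so the population geometric mean is ``gm_x``).
    sex_effect
        Additive effect of male sex on ln 25(OH)D.
    causal_effect_per10
        Causal effect of 25(OH)D on the outcome per 10 nmol/L increase.
        Interpreted per ``causal_scale``: "sd_outcome" (default; in outcome-SD
        units) or "percent_mean" (fraction of ``outcome_mean``).
    outcome_mean, outcome_sd
        Location/scale of the blood-pressure-like outcome (mmHg semantics).
    region_assoc_snp
        SNP id whose allele frequency follows a South-to-Scotland gradient of
        total width ``region_maf_shift``.
    """

    snps: Sequence[SnpSpec]
    sd_lnx: float = 0.48
    gm_x: float = 53.0
    sex_effect: float = -0.05
    causal_effect_per10: float = -0.05
    causal_scale: str = "sd_outcome"
    outcome_mean: float = 125.0
    outcome_sd: float = 15.0
    confounders: Sequence[ConfounderSpec] = ()
    biomarkers: Sequence[BiomarkerSpec] = ()
    region_assoc_snp: Optional[str] = None
    region_maf_shift: float = 0.05
    region_probs: Sequence[float] = (0.30, 0.25, 0.30, 0.15)

    def __post_init__(self):
        if self.sd_lnx <= 0:
            raise ValueError("sd_lnx must be positive")
        if self.gm_x <= 0:
            raise ValueError("gm_x must be positive")
        if self.outcome_sd <= 0:
            raise ValueError("outcome_sd must be positive")
        if self.causal_scale not in ("sd_outcome", "percent_mean"):
            raise ValueError("causal_scale must be 'sd_outcome' or 'percent_mean'")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in model")
        if self.region_assoc_snp is not None and self.region_assoc_snp not in ids:
            raise ValueError(f"region_assoc_snp {self.region_assoc_snp!r} not in snps")
        if abs(sum(self.region_probs) - 1.0) > 1e-9 or len(self.region_probs) != 4:
            raise ValueError("region_probs must be 4 probabilities summing to 1")
        r2s = [s.r2(self.sd_lnx) for s in self.snps]
        if any(r >= 1 for r in r2s) or sum(r2s) >= 1:
            raise ValueError("SNP R^2 values exceed total ln-25(OH)D variance")

    def snp(self, snp_id: str) -> SnpSpec:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    @property
    def lnx_residual_var(self) -> float:
        """Residual ln-scale variance after genetic, sex and confounder terms."""
        explained = sum(s.beta_lnx ** 2 * s.var_dosage for s in self.snps)
        explained += self.sex_effect ** 2 * 0.25
        explained += sum(
            c.effect_lnx ** 2 * c.prevalence * (1 - c.prevalence)
            for c in self.confounders
        )
        return self.sd_lnx ** 2 - explained

    # Log-normal moments of x = exp(lnx) used by the outcome stage and by
    # analytic power approximations.
    @property
    def mean_x(self) -> float:
        return self.gm_x * np.exp(self.sd_lnx ** 2 / 2.0)

    @property
    def sd_x(self) -> float:
        s2 = self.sd_lnx ** 2
        return float(self.gm_x * np.exp(s2 / 2.0) * np.sqrt(np.expm1(s2)))

    @property
    def causal_slope_sd(self) -> float:
        """Causal slope in outcome-SD units per nmol/L of 25(OH)D."""
        c = self.causal_effect_per10 / 10.0
        if self.causal_scale == "percent_mean":
            c = c * self.outcome_mean / self.outcome_sd
        return c


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix (counts of the minor allele, 0/1/2;
    NaN marks a missing call) plus SNP metadata."""

    dosages: np.ndarray
    snps: Sequence[SnpSpec]
    sample_ids: Sequence[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if m != len(self.snps) or n != len(self.sample_ids):
            raise ValueError("dosage dimensions inconsistent with metadata")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def dosage(self, snp_id: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None
        return self.dosages[:, j]

    def spec(self, snp_id: str) -> SnpSpec:
        return self.snps[self.snp_ids.index(snp_id)]

    def empirical_maf(self, snp_id: str) -> float:
        g = self.dosage(snp_id)
        g = g[~np.isnan(g)]
        f = float(np.mean(g) / 2.0)
        return min(f, 1.0 - f)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.snp_ids,
                            index=list(self.sample_ids))


@dataclass
class CohortTable:
    """Per-individual phenotypes: 25(OH)D (x, nmol/L; lnx = ln(x) exactly),
    sex, lifestyle factors, region, biomarkers, and the continuous outcome y."""

    x: np.ndarray
    lnx: np.ndarray
    sex: np.ndarray
    region: pd.Categorical
    y: np.ndarray
    lifestyle: pd.DataFrame
    biomarkers: pd.DataFrame
    sample_ids: Sequence[str]

    def __post_init__(self):
        if np.any(self.x <= 0):
            raise ValueError("25(OH)D must be positive")
        if not np.array_equal(self.lnx, np.log(self.x)):
            raise ValueError("lnx must equal ln(x) exactly")

    @property
    def n(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"x_25ohd": self.x, "ln_25ohd": self.lnx, "sex": self.sex,
             "region": self.region, "y_outcome": self.y},
            index=list(self.sample_ids),
        )
        for c in self.lifestyle.columns:
            df[c] = np.asarray(self.lifestyle[c])
        for c in self.biomarkers.columns:
            df[c] = np.asarray(self.biomarkers[c])
        return df


def simulate_genotypes(snps: Sequence[SnpSpec], n: int, seed) -> GenotypeMatrix:
    """Draw independent HWE genotypes: dosage ~ Binomial(2, maf) per SNP.

    Deterministic given ``seed``; identical seeds give identical matrices.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    mafs = np.array([s.maf for s in snps])
    dos = rng.binomial(2, mafs, size=(n, len(snps))).astype(float)
    return GenotypeMatrix(dos, list(snps), _sample_ids(n))


def calibrate_sd_lnx(snps: Sequence[SnpSpec], r2_targets: Sequence[float],
                     tol: float = 0.01) -> float:
    """Find the total SD of ln 25(OH)D consistent with per-SNP variance
    fractions.

    Solves beta_j²·2·maf_j·(1−maf_j) / sd² = r2_j for sd. With several SNPs
    the system is over-determined and the least-squares compromise in
    u = 1/sd² is returned; if any relative residual exceeds ``tol`` a warning
    reports the residuals.
    """
    r2 = np.asarray(r2_targets, dtype=float)
    if len(r2) != len(snps):
        raise ValueError("one r2 target per SNP required")
    if np.any((r2 <= 0) | (r2 >= 1)):
        raise ValueError("r2 targets must be in (0, 1)")
    k = np.array([s.beta_lnx ** 2 * s.var_dosage for s in snps])
    if np.any(k == 0):
        raise ValueError("SNP with zero effect cannot have a positive r2 target")
    u = float(np.dot(k, r2) / np.dot(k, k))  # lstsq in u = 1/sd^2
    resid = k * u - r2
    rel = np.abs(resid) / r2
    if np.any(rel > tol):
        warnings.warn(
            "inconsistent r2 targets; relative residuals: "
            + ", ".join(f"{s.snp_id}={r:.3g}" for s, r in zip(snps, rel)),
            stacklevel=2,
        )
    return 1.0 / np.sqrt(u)


def _region_mafs(spec: SnpSpec, shift: float) -> np.ndarray:
    # Linear South -> Scotland gradient of total width `shift`, centered on maf.
    grad = shift * (np.arange(4) - 1.5) / 1.5
    return np.clip(spec.maf + grad, 0.005, 0.995)


def simulate_cohort(model: CohortModel, n: int, seed) -> tuple[GenotypeMatrix, CohortTable]:
    """Simulate a full cohort (genotypes + phenotypes) under ``model``.

    ln 25(OH)D is ln(gm_x) plus mean-centered genetic, sex and confounder
    contributions plus Gaussian noise scaled so its marginal variance is
    sd_lnx²; x = exp(lnx). The outcome is outcome_mean + outcome_sd times a
    standardized variable combining the causal term
    causal_slope_sd·(x − E[x]), centered confounder effects, and noise scaled
    to unit total variance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)

    resid_var = model.lnx_residual_var
    if resid_var <= 0:
        raise ValueError(
            "genetic + covariate ln-scale variance exceeds sd_lnx^2 "
            f"(residual variance {resid_var:.4g})"
        )

    region_idx = rng.choice(4, size=n, p=np.asarray(model.region_probs, float))

    mafs = {}
    dos = np.empty((n, len(model.snps)))
    for j, s in enumerate(model.snps):
        if s.snp_id == model.region_assoc_snp:
            pr = _region_mafs(s, model.region_maf_shift)
            dos[:, j] = rng.binomial(2, pr[region_idx])
            mafs[s.snp_id] = float(np.dot(model.region_probs, pr))
        else:
            dos[:, j] = rng.binomial(2, s.maf, size=n)
            mafs[s.snp_id] = s.maf
    ids = _sample_ids(n)
    gm = GenotypeMatrix(dos, list(model.snps), ids)

    sex = rng.binomial(1, 0.5, size=n)

    # Lifestyle factors; prevalence may shift with an associated SNP's dosage.
    life = {}
    for c in model.confounders:
        if c.snp_assoc is not None and c.snp_log_odds != 0.0:
            g = gm.dosage(c.snp_assoc)
            logit0 = np.log(c.prevalence / (1 - c.prevalence))
            p = 1.0 / (1.0 + np.exp(-(logit0 + c.snp_log_odds * (g - 2 * mafs[c.snp_assoc]))))
            life[c.name] = rng.binomial(1, p)
        else:
            life[c.name] = rng.binomial(1, c.prevalence, size=n)
    lifestyle = pd.DataFrame(life) if life else pd.DataFrame(index=range(n))

    lnx = np.full(n, np.log(model.gm_x))
    for j, s in enumerate(model.snps):
        lnx += s.beta_lnx * (dos[:, j] - 2 * mafs[s.snp_id])
    lnx += model.sex_effect * (sex - 0.5)
    for c in model.confounders:
        lnx += c.effect_lnx * (np.asarray(lifestyle[c.name]) - c.prevalence)
    lnx += rng.normal(0.0, np.sqrt(resid_var), size=n)
    x = np.exp(lnx)
    lnx = np.log(x)  # re-derive so the lnx == ln(x) invariant holds bit-exactly

    # Outcome: standardized, then rescaled to outcome_mean/outcome_sd.
    slope = model.causal_slope_sd
    causal_var = slope ** 2 * model.sd_x ** 2
    conf_var = sum(c.effect_y ** 2 * c.prevalence * (1 - c.prevalence)
                   for c in model.confounders)
    y_resid_var = 1.0 - causal_var - conf_var
    if y_resid_var <= 0:
        raise ValueError("causal + confounder variance exceeds outcome variance")
    y_std = slope * (x - model.mean_x)
    for c in model.confounders:
        y_std = y_std + c.effect_y * (np.asarray(lifestyle[c.name]) - c.prevalence)
    y_std = y_std + rng.normal(0.0, np.sqrt(y_resid_var), size=n)
    y = model.outcome_mean + model.outcome_sd * y_std

    z_lnx = (lnx - np.log(model.gm_x)) / model.sd_lnx
    bios = {}
    for b in model.biomarkers:
        expl = b.loading_lnx ** 2
        bm = b.loading_lnx * z_lnx
        for sid, eff in b.snp_effects.items():
            s = gm.spec(sid)
            bm = bm + eff * (gm.dosage(sid) - 2 * mafs[sid])
            expl += eff ** 2 * s.var_dosage
        if expl >= 1:
            raise ValueError(f"biomarker {b.name}: loadings exceed unit variance")
        bm = bm + rng.normal(0.0, np.sqrt(1 - expl), size=n)
        bios[b.name] = b.mean + b.sd * bm
    biomarkers = pd.DataFrame(bios) if bios else pd.DataFrame(index=range(n))

    region = pd.Categorical.from_codes(region_idx, categories=list(REGION_LEVELS))
    cohort = CohortTable(x=x, lnx=lnx, sex=sex, region=region, y=y,
                         lifestyle=lifestyle, biomarkers=biomarkers, sample_ids=ids)
    return gm, cohort


# ---------------------------------------------------------------------------
# Reference models

#: Instrument SNPs with the observed MAFs and per-minor-allele effects on
#: ln 25(OH)D (sex-adjusted) in the 1958 British birth cohort.
SNPS_1958BC = (
    SnpSpec("rs4588", "GC", 0.30, -0.08),
    SnpSpec("rs12785878", "DHCR7", 0.22, -0.05),
    SnpSpec("rs10741657", "CYP2R1", 0.40, +0.03),
    SnpSpec("rs6013897", "CYP24A1", 0.20, -0.03),
    SnpSpec("rs10877012", "CYP27B1", 0.33, -0.02),
)


def cohort_model_1958bc(**overrides) -> CohortModel:
    """Default cohort model: the five instrument SNPs at their observed MAFs
    and effects, geometric-mean 25(OH)D 53 nmol/L, total ln-scale SD 0.48,
    a DHCR7 allele-frequency gradient across region, null lifestyle factors
    at realistic prevalences, and a 5%-of-SD per 10 nmol/L causal effect on
    a 125/15 mmHg blood-pressure-like outcome."""
    confs = tuple(
        ConfounderSpec(name, prev)
        for name, prev in zip(
            LIFESTYLE_FACTOR_NAMES[:-1],  # sex carried separately on the cohort
            (0.45, 0.35, 0.30, 0.10, 0.25, 0.25, 0.70, 0.50, 0.40, 0.45, 0.30, 0.35),
        )
    )
    bios = tuple(BiomarkerSpec(name) for name in BIOMARKER_NAMES)
    base = CohortModel(
        snps=SNPS_1958BC,
        confounders=confs,
        biomarkers=bios,
        region_assoc_snp="rs12785878",
    )
    return replace(base, **overrides) if overrides else base


def power_model(**overrides) -> CohortModel:
    """Lean model for Monte-Carlo power runs: the five instrument SNPs and the
    causal outcome only (no lifestyle factors, biomarkers, or region shift)."""
    base = CohortModel(snps=SNPS_1958BC)
    return replace(base, **overrides) if overrides else base
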