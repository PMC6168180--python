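"""Synthetic SNAP adult population generator.

Generates a weighted synthetic population of US adults aged 35-80 on SNAP with
the joint structure the microsimulation assumes: sociodemographics matching
published survey marginals, cardiometabolic risk factors drawn through a
Gaussian copula with configurable rank correlations, and right-skewed baseline
dietary intakes for nine food categories.

The population is returned as a :class:`pandas.DataFrame`, one row per person
(the canonical in-memory container for the package); column dictionary in
:data:`COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats


class ConfigurationError(ValueError):
    """Raised when a population configuration violates its invariants."""


# Marginal targets for the categorical variables (proportions).
# Insurance: medicare/medicaid are reported including dual-eligibles (22.4 and
# 29.5) so the exclusive categories are 12.2 / 19.3 / 10.2 / 58.3.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "age_band": {"35-44": 0.294, "45-54": 0.309, "55-64": 0.247,
                 "65-74": 0.106, "75-80": 0.044},
    "sex": {"male": 0.457, "female": 0.543},
    "race_ethnicity": {"nh_white": 0.508, "nh_black": 0.243,
                       "hispanic": 0.189, "other": 0.060},
    "education": {"lt_high_school": 0.361, "high_school": 0.289,
                  "some_college": 0.280, "college_grad": 0.070},
    "income_poverty_ratio": {"<1.30": 0.674, "1.30-1.84": 0.139,
                             "1.85-2.99": 0.112, ">=3.00": 0.075},
    "insurance": {"medicare": 0.122, "medicaid": 0.193,
                  "dual": 0.102, "other": 0.583},
}

AGE_BANDS = {"35-44": (35.0, 45.0), "45-54": (45.0, 55.0), "55-64": (55.0, 65.0),
             "65-74": (65.0, 75.0), "75-80": (75.0, 80.0)}

DEFAULT_AGE_MEAN = 52.1
DEFAULT_AGE_SD = 12.3

# Continuous risk-factor marginals: calibration inputs (not printed for the
# SNAP subsample); chosen to reflect a low-income US adult population.
DEFAULT_RISK_FACTORS: dict[str, dict] = {
    "sbp": {"family": "normal", "mean": 127.0, "sd": 17.0, "lo": 80.0, "hi": 230.0},
    "total_chol": {"family": "normal", "mean": 199.0, "sd": 40.0, "lo": 90.0, "hi": 400.0},
    "hdl": {"family": "normal", "mean": 51.0, "sd": 15.0, "lo": 20.0, "hi": 120.0},
    "bmi": {"family": "normal", "mean": 30.0, "sd": 6.5, "lo": 15.0, "hi": 60.0},
}

DEFAULT_SMOKING_PREVALENCE = 0.30
# Baseline diabetic prevalence is a calibration input (configurable).
DEFAULT_DIABETES_PREVALENCE = 0.25
# BMI-diabetes association: log-odds slope per kg/m^2 around the BMI mean.
DEFAULT_DIABETES_BMI_SLOPE = 0.08

FOOD_CATEGORIES = ["fruits", "vegetables", "nuts", "whole_grains", "fish",
                   "plant_oils", "ssb", "processed_meat", "junk_food"]

# Baseline mean intakes, g/day. SSB: 414 g/d = 14.0 fl oz/d at 29.57 g/fl oz.
DEFAULT_DIET_MEANS: dict[str, float] = {
    "fruits": 81.3, "vegetables": 134.8, "nuts": 5.4, "whole_grains": 13.9,
    "fish": 20.6, "plant_oils": 18.7, "ssb": 414.0, "processed_meat": 31.8,
    "junk_food": 66.5,
}

GRAMS_PER_FL_OZ = 29.57

# Rank-correlation structure among (age, sbp, total_chol, hdl, bmi):
# modest positive SBP-age and cholesterol-age associations, negative HDL-BMI.
COPULA_VARS = ["age", "sbp", "total_chol", "hdl", "bmi"]
DEFAULT_CORRELATION = np.array([
    # age   sbp    tc     hdl    bmi
    [1.00, 0.35, 0.15, 0.05, -0.05],   # age
    [0.35, 1.00, 0.10, 0.00, 0.20],    # sbp
    [0.15, 0.10, 1.00, 0.10, 0.05],    # total_chol
    [0.05, 0.00, 0.10, 1.00, -0.20],   # hdl
    [-0.05, 0.20, 0.05, -0.20, 1.00],  # bmi
])

COLUMNS = {
    "id": "integer person identifier",
    "age": "years at baseline (35-80)",
    "sex": "male / female",
    "race_ethnicity": "nh_white / nh_black / hispanic / other",
    "education": "lt_high_school / high_school / some_college / college_grad",
    "income_poverty_ratio": "<1.30 / 1.30-1.84 / 1.85-2.99 / >=3.00",
    "insurance": "medicare / medicaid / dual / other",
    "weight": "survey weight (positive; 1.0 for synthetic persons)",
    "sbp": "systolic blood pressure, mmHg",
    "total_chol": "total cholesterol, mg/dL",
    "hdl": "HDL cholesterol, mg/dL",
    "bmi": "body mass index, kg/m^2",
    "smoker": "current smoker (bool)",
    "diabetic": "prevalent type 2 diabetes (bool)",
    **{f"diet_{f}": f"baseline intake of {f}, g/day" for f in FOOD_CATEGORIES},
}


@dataclass
class PopulationConfig:
    """Configuration of the synthetic population generator."""

    size: int = 100_000
    seed: int = 0
    marginal_targets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    risk_factor_distributions: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RISK_FACTORS.items()})
    diet_baseline_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIET_MEANS))
    diet_cv: float = 1.0
    correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATION.copy())
    smoking_prevalence: float = DEFAULT_SMOKING_PREVALENCE
    diabetes_prevalence: float = DEFAULT_DIABETES_PREVALENCE
    diabetes_bmi_slope: float = DEFAULT_DIABETES_BMI_SLOPE

    def validate(self) -> None:
        if self.size < 1:
            raise ConfigurationError("population size must be >= 1")
        for var, targets in self.marginal_targets.items():
            total = sum(targets.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"marginal targets for {var!r} sum to {total}, not 1")
            if any(p < 0 for p in targets.values()):
                raise ConfigurationError(f"negative proportion in {var!r}")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (len(COPULA_VARS),) * 2 or not np.allclose(corr, corr.T):
            raise ConfigurationError("correlation matrix must be symmetric 5x5")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ConfigurationError("correlation matrix is not positive semidefinite")
        if not (0 < self.diet_cv):
            raise ConfigurationError("diet_cv must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "correlation" in raw:
            raw["correlation"] = np.asarray(raw["correlation"], dtype=float)
        return cls(**raw)


# ---------------------------------------------------------------------------
# Age distribution: piecewise tilted-uniform within bands.
#
# Within band [l, h] the density in u = 2(x - mid)/w in [-1, 1] is
# f(u) = (1 + s*u)/2 with tilt s in [-1, 1]; band mean = mid + w*s/6 and band
# variance = (w/2)^2 (1/3 - s^2/9). The tilt vector is solved so the mixture
# matches the configured overall mean and SD exactly while band probabilities
# stay at their target values.
# ---------------------------------------------------------------------------

def _solve_age_tilts(bands: dict[str, tuple[float, float]],
                     probs: np.ndarray, mean_t: float, sd_t: float) -> np.ndarray:
    lo = np.array([bands[b][0] for b in bands])
    hi = np.array([bands[b][1] for b in bands])
    w = hi - lo
    mid = (lo + hi) / 2.0

    def moments(s):
        mb = mid + w * s / 6.0
        vb = (w / 2.0) ** 2 * (1.0 / 3.0 - s ** 2 / 9.0)
        mean = float(probs @ mb)
        var = float(probs @ (vb + (mb - mean_t) ** 2))
        return mean, var

    res = optimize.minimize(
        lambda s: float(s @ s), np.zeros(len(w)),
        bounds=[(-1.0, 1.0)] * len(w), method="SLSQP",
        constraints=[
            {"type": "eq", "fun": lambda s: moments(s)[0] - mean_t},
            {"type": "eq", "fun": lambda s: moments(s)[1] - sd_t ** 2},
        ],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    mean, var = moments(res.x)
    if not res.success or abs(mean - mean_t) > 1e-6 or abs(var - sd_t ** 2) > 1e-4:
        raise ConfigurationError(
            "age band marginals are incompatible with the requested mean/SD")
    return res.x


def _tilted_uniform_ppf(r: np.ndarray, s: float) -> np.ndarray:
    """Inverse CDF of f(u) = (1 + s u)/2 on [-1, 1]."""
    if abs(s) < 1e-12:
        return 2.0 * r - 1.0
    # CDF: F(u) = (u+1)/2 + s(u^2-1)/4  ->  s/4 u^2 + u/2 + (1/4 - s/4 - r)... solve
    a = s / 4.0
    b = 0.5
    c = 0.5 - s / 4.0 - r
    disc = np.maximum(b ** 2 - 4 * a * c, 0.0)
    u = (-b + np.sqrt(disc)) / (2 * a)
    return np.clip(u, -1.0, 1.0)


class _AgeDistribution:
    """Mixture of tilted uniforms over the configured age bands."""

    def __init__(self, marginals: dict[str, float], mean: float, sd: float):
        self.bands = {b: AGE_BANDS[b] for b in marginals}
        self.probs = np.array([marginals[b] for b in self.bands])
        self.tilts = _solve_age_tilts(self.bands, self.probs, mean, sd)
        self.cum = np.concatenate([[0.0], np.cumsum(self.probs)])
        self.cum[-1] = 1.0

    def ppf(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        idx = np.clip(np.searchsorted(self.cum, q, side="right") - 1,
                      0, len(self.probs) - 1)
        out = np.empty_like(q)
        keys = list(self.bands)
        for k in range(len(keys)):
            m = idx == k
            if not m.any():
                continue
            lo, hi = self.bands[keys[k]]
            w = hi - lo
            r = (q[m] - self.cum[k]) / self.probs[k]
            u = _tilted_uniform_ppf(np.clip(r, 0.0, 1.0), self.tilts[k])
            out[m] = (lo + hi) / 2.0 + u * w / 2.0
        return out

    def band_of(self, age: np.ndarray) -> np.ndarray:
        keys = list(self.bands)
        edges = [self.bands[k][0] for k in keys] + [self.bands[keys[-1]][1]]
        idx = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, len(keys) - 1)
        return np.array(keys, dtype=object)[idx]


def _truncnorm(mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _marginal_dist(spec: dict):
    fam = spec.get("family", "normal")
    if fam == "normal":
        return _truncnorm(spec["mean"], spec["sd"], spec["lo"], spec["hi"])
    if fam == "lognormal":
        sigma = np.sqrt(np.log1p((spec["sd"] / spec["mean"]) ** 2))
        mu = np.log(spec["mean"]) - sigma ** 2 / 2
        return stats.lognorm(sigma, scale=np.exp(mu))
    raise ConfigurationError(f"unknown risk-factor family {fam!r}")


def _draw_categorical(rng: np.random.Generator, targets: dict[str, float],
                      n: int) -> np.ndarray:
    cats = np.array(list(targets), dtype=object)
    p = np.array([targets[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=n, p=p)


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate a synthetic SNAP adult population.

    Continuous risk factors (and age) are drawn through a Gaussian copula with
    the configured rank-correlation matrix; categorical variables are
    independent draws matching their marginal targets; dietary intakes are
    independent gamma draws with the configured means and coefficient of
    variation. Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.size

    # Gaussian copula over (age, sbp, total_chol, hdl, bmi).
    corr = np.asarray(config.correlation, dtype=float)
    # nudge to strictly PD for Cholesky if needed
    eig = np.linalg.eigvalsh(corr).min()
    if eig < 1e-10:
        corr = corr + (1e-10 - eig) * np.eye(len(corr))
    z = rng.multivariate_normal(np.zeros(len(COPULA_VARS)), corr, size=n,
                                method="cholesky")
    u = stats.norm.cdf(z)

    age_dist = _AgeDistribution(config.marginal_targets["age_band"],
                                config.age_mean, config.age_sd)
    age = age_dist.ppf(u[:, 0])

    cont = {"age": age}
    for j, var in enumerate(COPULA_VARS[1:], start=1):
        dist = _marginal_dist(config.risk_factor_distributions[var])
        cont[var] = dist.ppf(u[:, j])

    df = pd.DataFrame({"id": np.arange(n, dtype=np.int64)})
    df["age"] = cont["age"]
    for var, targets in config.marginal_targets.items():
        if var == "age_band":
            continue
        df[var] = _draw_categorical(rng, targets, n)
    df["weight"] = 1.0
    for var in ("sbp", "total_chol", "hdl", "bmi"):
        df[var] = cont[var]
    df["smoker"] = rng.random(n) < config.smoking_prevalence

    # prevalent diabetes: logistic in BMI around the configured prevalence
    bmi_mean = config.risk_factor_distributions["bmi"]["mean"]
    base_logit = np.log(config.diabetes_prevalence / (1 - config.diabetes_prevalence))
    logit = base_logit + config.diabetes_bmi_slope * (df["bmi"].to_numpy() - bmi_mean)
    df["diabetic"] = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    cv = config.diet_cv
    shape = 1.0 / cv ** 2
    for food in FOOD_CATEGORIES:
        mean = config.diet_baseline_means[food]
        df[f"diet_{food}"] = rng.gamma(shape, mean / shape, size=n)

    return df


def scale_to_national(population: pd.DataFrame, national_count: float) -> np.ndarray:
    """Per-person expansion factors so weighted persons sum to ``national_count``."""
    if len(population) == 0:
        raise ValueError("population is empty")
    if national_count <= 0:
        raise ValueError("national_count must be positive")
    w = population["weight"].to_numpy(dtype=float)
    return w * (national_count / w.sum())


# Number of US SNAP participants in 2017 and the adult (35+) share.
SNAP_PARTICIPANTS_2017 = 42_138_000
ADULT_SHARE = 0.345
NATIONAL_ADULTS = SNAP_PARTICIPANTS_2017 * ADULT_SHARE  # 14,537,610


def summarize_population(population: pd.DataFrame) -> dict:
    """Weighted means for continuous fields and proportions for categoricals."""
    if len(population) == 0:
        raise ValueError("population is empty")
    w = population["weight"].to_numpy(dtype=float)
    wsum = w.sum()
    out: dict = {}
    for col in ("age", "sbp", "total_chol", "hdl", "bmi"):
        x = population[col].to_numpy(dtype=float)
        m = float((w * x).sum() / wsum)
        out[f"{col}_mean"] = m
        out[f"{col}_sd"] = float(np.sqrt((w * (x - m) ** 2).sum() / wsum))
    for col in ("sex", "race_ethnicity", "education", "income_poverty_ratio",
                "insurance"):
        props = {}
        for cat in population[col].unique():
            props[str(cat)] = float(w[population[col].to_numpy() == cat].sum() / wsum)
        out[col] = props
    for col in ("smoker", "diabetic"):
        out[f"{col}_prevalence"] = float(
            (w * population[col].to_numpy(dtype=float)).sum() / wsum)
    ins = out["insurance"]
    out["medicare_or_medicaid"] = sum(
        ins.get(k, 0.0) for k in ("medicare", "medicaid", "dual"))
    for food in FOOD_CATEGORIES:
        col = f"diet_{food}"
        if col in population:
            out[f"{col}_mean"] = float(
                (w * population[col].to_numpy(dtype=float)).sum() / wsum)
    return out


def write_population(population: pd.DataFrame, path) -> None:
    population.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("smoker", "diabetic"):
        df[col] = df[col].astype(bool)
    return df
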