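"""Synthetic cohort emulator for the applied study schema.

Generates tabular cohorts that match the published sample description of a
military primary-care suicide-risk cohort: 18 predictor scales with given
means/SDs clipped to instrument ranges, six two-level environment variables
(prior suicidal ideation, prior suicide attempt, prior non-suicidal
self-injury, race, age group, gender) with given prevalences, and a rare
binary outcome (default marginal event rate 2.1%).

Marginals are truncated normals on the instrument bounds, moment-matched so
the *truncated* mean hits the published mean exactly; for strongly skewed
scales no truncated normal attains the published SD (its SD/mean ratio is
bounded), so the SD is matched as closely as feasible.  Cross-scale
dependence is a single exchangeable correlation among the clinical scales.
The outcome is drawn from a logistic model whose coefficients are synthetic
placeholders (small positive weights on shame, suicidogenic beliefs and
negative affect); they are NOT estimates of any real cohort.  The intercept
is found by bisection so the marginal event rate converges to the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .dataset import Dataset
from .exceptions import ConfigError, InvalidEnvironmentError
from .study import dichotomize_environment


def _dichotomize_lenient(column: pd.Series, rule: Mapping) -> np.ndarray:
    """Pipeline dichotomization, tolerating single-level results.

    Tiny cohorts can legitimately miss one level of a derived environment;
    the resulting column is still stored (downstream analyses will flag it
    as untestable) rather than failing generation.
    """
    try:
        return dichotomize_environment(column, rule).to_numpy()
    except InvalidEnvironmentError:
        if "threshold" in rule:
            values = pd.to_numeric(column, errors="coerce")
            return (values <= float(rule["threshold"])).astype(float).to_numpy()
        return column.map({k: float(v) for k, v in rule["mapping"].items()}).to_numpy(
            dtype=float
        )


class PredictorSpec(NamedTuple):
    name: str
    mean: float
    sd: float
    minimum: float
    maximum: float


class EnvironmentSpec(NamedTuple):
    name: str
    prevalence: float  # probability of level 1


@dataclass
class StudySchema:
    predictor_specs: list[PredictorSpec]
    environment_specs: list[EnvironmentSpec]
    outcome_rate: float = 0.021
    n_default: int = 2744
    exchangeable_corr: float = 0.3

    def __post_init__(self) -> None:
        self.predictor_specs = [PredictorSpec(*s) for s in self.predictor_specs]
        self.environment_specs = [EnvironmentSpec(*s) for s in self.environment_specs]
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.outcome_rate < 1.0:
            raise ConfigError("outcome_rate must lie strictly inside (0, 1)")
        if self.n_default < 1:
            raise ConfigError("n_default must be >= 1")
        if not 0.0 <= self.exchangeable_corr < 1.0:
            raise ConfigError("exchangeable_corr must be in [0, 1)")
        for spec in self.predictor_specs:
            if spec.sd <= 0:
                raise ConfigError(f"{spec.name}: sd must be positive")
            if not spec.minimum < spec.maximum:
                raise ConfigError(f"{spec.name}: min must be below max")
            if not spec.minimum < spec.mean < spec.maximum:
                raise ConfigError(f"{spec.name}: mean must lie inside the range")
        for env in self.environment_specs:
            if not 0.0 < env.prevalence < 1.0:
                raise ConfigError(f"{env.name}: prevalence must be in (0, 1)")

    @property
    def predictor_names(self) -> list[str]:
        return [s.name for s in self.predictor_specs]

    def predictor(self, name: str) -> PredictorSpec:
        for s in self.predictor_specs:
            if s.name == name:
                return s
        raise ConfigError(f"unknown predictor {name!r}")

    # ------------------------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = {
            "predictor_specs": [list(s) for s in self.predictor_specs],
            "environment_specs": [[e.name, float(e.prevalence)]
                                  for e in self.environment_specs],
            "outcome_rate": float(self.outcome_rate),
            "n_default": int(self.n_default),
            "exchangeable_corr": float(self.exchangeable_corr),
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "StudySchema":
        from .scm import _read_yaml_source

        return cls(**yaml.safe_load(_read_yaml_source(source)))


# ----------------------------------------------------------------------
# Published sample description: 2,744 primary care patients; 58 (2.1%)
# reported suicidal behavior during one-year follow-up.  Scale moments and
# environment counts as printed in the cohort's descriptor table.
_TABLE_PREDICTORS = [
    ("Age", 40.4, 19.6, 18, 85),
    ("DES-IV guilt", 6.8, 3.4, 3, 15),
    ("DES-IV shame", 6.4, 3.4, 3, 15),
    ("DES-IV inward hostility", 5.2, 3.1, 3, 15),
    ("ES internal", 5.8, 8.8, 0, 40),
    ("ES external", 3.3, 5.7, 0, 24),
    ("ISEL appraisal", 12.8, 2.9, 4, 16),
    ("ISEL belonging", 12.3, 3.0, 4, 16),
    ("ISEL tangible", 12.4, 2.7, 4, 16),
    ("I-PANAS-SF positive affect", 13.1, 5.0, 5, 25),
    ("I-PANAS-SF negative affect", 7.9, 3.9, 5, 25),
    ("PC-PTSD", 1.1, 1.5, 0, 4),
    ("PHQ-9", 6.0, 6.0, 0, 27),
    ("PHQ-9 suicide ideation item", 0.1, 0.5, 0, 3),
    ("SCS-R", 6.6, 11.0, 0, 64),
    ("ACSS-FAD", 14.2, 4.0, 0, 32),
    ("BRFLI", 53.0, 16.6, 14, 84),
    ("ISI", 16.4, 7.2, 7, 35),
]

_N_COHORT = 2744
_ENV_COUNTS = {
    "prior_si": 774,
    "prior_sa": 238,
    "prior_nssi": 312,
    "race": 1811,  # level 1 = White
}
# gender response categories (male, female, other, prefer-not, missing)
_GENDER_COUNTS = {"male": 1380, "female": 1279, "other": 9,
                  "prefer_not": 17, "missing": 59}
AGE_THRESHOLD = 23  # environment level 1: aged <= 23

# Centered latent shifts (in latent-normal SD units) tying the history
# environments to the risk scales, so environments are associated with the
# outcome through the predictors; demographics are left neutral.
_ENV_SHIFTS: dict[str, dict[str, float]] = {
    "prior_si": {
        "DES-IV shame": 0.25,
        "SCS-R": 0.30,
        "I-PANAS-SF negative affect": 0.25,
        "PHQ-9": 0.25,
        "PHQ-9 suicide ideation item": 0.30,
    },
    "prior_sa": {"SCS-R": 0.25, "DES-IV shame": 0.20, "ACSS-FAD": 0.20},
    "prior_nssi": {"DES-IV shame": 0.25, "DES-IV inward hostility": 0.25},
}

#: synthetic placeholder outcome weights (standardized scale); not estimates
DEFAULT_OUTCOME_WEIGHTS: dict[str, float] = {
    "DES-IV shame": 0.40,
    "SCS-R": 0.35,
    "I-PANAS-SF negative affect": 0.30,
}


@lru_cache(maxsize=128)
def _truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Location/scale of a truncated normal on [lo, hi] matching ``mean``
    exactly and ``sd`` as closely as the family allows."""

    def moments(mu: float, sigma: float) -> tuple[float, float]:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def mu_for_mean(sigma: float) -> float:
        # truncated mean is monotone in mu and pinned to (lo, hi); a bracket
        # of +/-30 sigma beyond the bounds keeps the standardized bounds in
        # scipy's numerically stable range
        lo_mu, hi_mu = lo - 30.0 * sigma, hi + 30.0 * sigma
        f_lo = moments(lo_mu, sigma)[0] - mean
        f_hi = moments(hi_mu, sigma)[0] - mean
        if f_lo >= 0.0:
            return lo_mu
        if f_hi <= 0.0:
            return hi_mu
        return optimize.brentq(
            lambda mu: moments(mu, sigma)[0] - mean, lo_mu, hi_mu, xtol=1e-10
        )

    def sd_gap(sigma: float) -> float:
        return abs(moments(mu_for_mean(sigma), sigma)[1] - sd)

    res = optimize.minimize_scalar(
        sd_gap, bounds=(0.15 * sd, 6.0 * sd), method="bounded",
        options={"xatol": 1e-6},
    )
    sigma = float(res.x)
    return mu_for_mean(sigma), sigma


def _age_prevalence() -> float:
    """P(age <= threshold) under the moment-matched age marginal."""
    spec = PredictorSpec(*_TABLE_PREDICTORS[0])
    mu, sigma = _truncnorm_params(spec.mean, spec.sd, spec.minimum, spec.maximum)
    a, b = (spec.minimum - mu) / sigma, (spec.maximum - mu) / sigma
    return float(stats.truncnorm.cdf(AGE_THRESHOLD, a, b, loc=mu, scale=sigma))


def default_schema() -> StudySchema:
    """The published cohort schema: 18 predictor specs (printed M, SD and
    range), 6 environment prevalences from the printed counts, event rate
    2.1%, default cohort size 2,744."""
    envs = [
        EnvironmentSpec("prior_si", _ENV_COUNTS["prior_si"] / _N_COHORT),
        EnvironmentSpec("prior_sa", _ENV_COUNTS["prior_sa"] / _N_COHORT),
        EnvironmentSpec("prior_nssi", _ENV_COUNTS["prior_nssi"] / _N_COHORT),
        EnvironmentSpec("race", _ENV_COUNTS["race"] / _N_COHORT),
        EnvironmentSpec("age", _age_prevalence()),
        # prevalence of level 1 (male) among rows mapped to either level;
        # other/prefer-not/missing responses carry no environment label
        EnvironmentSpec(
            "gender",
            _GENDER_COUNTS["male"] / (_GENDER_COUNTS["male"] + _GENDER_COUNTS["female"]),
        ),
    ]
    return StudySchema(
        predictor_specs=[PredictorSpec(*row) for row in _TABLE_PREDICTORS],
        environment_specs=envs,
        outcome_rate=0.021,
        n_default=_N_COHORT,
    )


# ----------------------------------------------------------------------
def _calibrated_intercept(eta0: np.ndarray, target: float) -> float:
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(1.0 / (1.0 + np.exp(-(mid + eta0))))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_study_like(
    schema: StudySchema,
    n: int | None = None,
    seed: int = 0,
    outcome_weights: Mapping[str, float] | None = None,
) -> Dataset:
    """Draw a synthetic cohort from a study schema.  Deterministic given
    ``seed``.

    The age environment is the continuous age column dichotomized at the
    published cut (<= 23 vs 24+); gender is drawn with its full response
    categories, and responses outside the male/female dichotomy yield
    missing environment labels (excluded from that environment only).
    """
    if n is None:
        n = schema.n_default
    if n < 1:
        raise ConfigError("n must be >= 1")
    schema.validate()
    if outcome_weights is None:
        outcome_weights = DEFAULT_OUTCOME_WEIGHTS
    unknown = [k for k in outcome_weights if k not in schema.predictor_names]
    if unknown:
        raise ConfigError(f"outcome weights reference unknown predictors {unknown!r}")

    rng = np.random.default_rng(seed)
    env_names = [e.name for e in schema.environment_specs]

    # --- environment indicators ------------------------------------------------
    env: dict[str, np.ndarray] = {}
    for espec in schema.environment_specs:
        if espec.name in ("age", "gender"):
            continue  # derived below
        env[espec.name] = (rng.random(n) < espec.prevalence).astype(float)
    gender_labels = None
    if "gender" in env_names:
        cats = list(_GENDER_COUNTS)
        probs = np.array([_GENDER_COUNTS[c] for c in cats], dtype=float)
        probs /= probs.sum()
        gender_labels = rng.choice(cats, size=n, p=probs)
        env["gender"] = _dichotomize_lenient(
            pd.Series(gender_labels), {"mapping": {"male": 1, "female": 0}}
        )

    # --- latent normals with exchangeable correlation among clinical scales ----
    rho = schema.exchangeable_corr
    common = rng.standard_normal(n)
    columns = {}
    for spec in schema.predictor_specs:
        eps = rng.standard_normal(n)
        if spec.name == "Age":
            z = eps
        else:
            z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * eps
        for env_name, shifts in _ENV_SHIFTS.items():
            if env_name in env and spec.name in shifts:
                prevalence = float(np.mean(env[env_name]))
                z = z + shifts[spec.name] * (env[env_name] - prevalence)
        mu, sigma = _truncnorm_params(spec.mean, spec.sd, spec.minimum, spec.maximum)
        a, b = (spec.minimum - mu) / sigma, (spec.maximum - mu) / sigma
        u = np.clip(stats.norm.cdf(z), 1e-12, 1.0 - 1e-12)
        columns[spec.name] = stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
    X = pd.DataFrame(columns)

    if "age" in env_names:
        env["age"] = _dichotomize_lenient(
            X["Age"], {"threshold": AGE_THRESHOLD, "direction": "le"}
        )

    # --- outcome: calibrated logistic on standardized synthetic weights --------
    eta0 = np.zeros(n)
    for name, weight in outcome_weights.items():
        spec = schema.predictor(name)
        eta0 += weight * (X[name].to_numpy() - spec.mean) / spec.sd
    intercept = _calibrated_intercept(eta0, schema.outcome_rate)
    prob = 1.0 / (1.0 + np.exp(-(intercept + eta0)))
    y = (rng.random(n) < prob).astype(float)

    extras = None
    if gender_labels is not None:
        extras = pd.DataFrame({"gender_response": gender_labels})
    return Dataset(
        X=X,
        y=pd.Series(y, name="y"),
        env=pd.DataFrame({name: env[name] for name in env_names}),
        provenance={
            "source": "study-schema",
            "seed": int(seed),
            "n": int(n),
            "outcome_intercept": float(intercept),
            "outcome_weights": dict(outcome_weights),
        },
        extras=extras,
    )
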