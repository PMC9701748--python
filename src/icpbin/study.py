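"""Applied study workflow: environment handling, the method x environment x
alpha grid, and report rendering.

Environments here are pre-existing two-level traits (history of suicidal
ideation, age group, ...).  A valid environment must show both levels and
should be associated with the outcome; association is *screened* and
reported but never used to silently drop an environment, since a null
association may itself be informative.

The grid mirrors the study layout: for each method (exhaustive search or
lasso-screened), each environment, and each significance level, one
invariant-causal-prediction run.  A cell's estimate renders as the set of
predictor names, as ``None`` when subsets were accepted but share no
predictor, or as ``-`` when no subset at all was accepted (model rejected).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _version
from .dataset import Dataset
from .exceptions import ConfigError, ICPError, InvalidEnvironmentError
from .model import (
    ICPResults,
    InvariantCausalPrediction,
    STATUS_MODEL_REJECTED,
)

DEFAULT_ALPHAS = (0.1, 0.05, 0.01)
DEFAULT_METHODS = ("full", "lasso")


# ----------------------------------------------------------------------
def dichotomize_environment(
    column: pd.Series | np.ndarray | Sequence,
    rule: Mapping,
) -> pd.Series:
    """Map a raw column to {0, 1} environment labels.

    ``rule`` is either ``{"threshold": v}`` (optionally ``"direction"``:
    ``"le"`` (default, 1 when value <= v) or ``"ge"``) or
    ``{"mapping": {value: 0/1, ...}}``.  Values not covered by a mapping
    become NaN — excluded from that environment's analysis only — and their
    count is recorded on the returned series' ``attrs["n_unmapped"]``.
    """
    series = pd.Series(column).reset_index(drop=True)
    if "threshold" in rule:
        direction = rule.get("direction", "le")
        values = pd.to_numeric(series, errors="coerce")
        if direction == "le":
            labels = (values <= float(rule["threshold"])).astype(float)
        elif direction == "ge":
            labels = (values >= float(rule["threshold"])).astype(float)
        else:
            raise ConfigError(f"unknown threshold direction {direction!r}")
        labels[values.isna()] = np.nan
    elif "mapping" in rule:
        mapping = {k: float(v) for k, v in rule["mapping"].items()}
        bad = [v for v in mapping.values() if v not in (0.0, 1.0)]
        if bad:
            raise ConfigError("mapping values must be 0 or 1")
        labels = series.map(mapping).astype(float)
    else:
        raise ConfigError("rule must provide 'threshold' or 'mapping'")
    observed = set(labels.dropna().unique())
    if not observed:
        raise InvalidEnvironmentError("no rows could be mapped to either level")
    if observed != {0.0, 1.0}:
        raise InvalidEnvironmentError(
            "dichotomized column shows a single level; not a usable environment"
        )
    labels.attrs["n_unmapped"] = int(labels.isna().sum())
    return labels


@dataclass
class EnvScreenResult:
    """Association screen between one environment and the outcome."""

    env_name: str
    outcome_association_p: float
    both_levels_present: bool
    valid: bool
    note: str = ""
    test_used: str = "chi2"

    def to_dict(self) -> dict:
        return {
            "env": self.env_name,
            "p": self.outcome_association_p,
            "both_levels_present": self.both_levels_present,
            "valid": self.valid,
            "test": self.test_used,
            "note": self.note,
        }


def screen_environment(dataset: Dataset, env_name: str) -> EnvScreenResult:
    """2x2 independence test of environment vs outcome.

    Chi-square with Fisher's exact fallback when any expected cell count is
    below 5.  A weak association yields ``valid=True`` with a warning note:
    screening informs, it does not drop environments.  A (near-)perfect
    association is flagged as suspicious — the environment may be a
    descendant of the outcome, which would invalidate it.
    """
    env = np.asarray(dataset.env[env_name], dtype=float)
    keep = ~np.isnan(env)
    env = env[keep]
    y = np.asarray(dataset.y, dtype=float)[keep]
    levels = set(np.unique(env))
    both = levels == {0.0, 1.0}
    if not both:
        return EnvScreenResult(env_name, float("nan"), False, False,
                               note="missing an environment level")
    table = np.array(
        [
            [np.sum((env == a) & (y == b)) for b in (0.0, 1.0)]
            for a in (0.0, 1.0)
        ]
    )
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        test_used = "fisher"
    else:
        p = float(stats.chi2_contingency(table, correction=False).pvalue)
        test_used = "chi2"
    note = ""
    # rows where env determines the outcome (or vice versa) almost exactly
    if min(table[0, 1] + table[1, 0], table[0, 0] + table[1, 1]) == 0:
        note = "environment coincides with the outcome; possible causal descendant"
    elif p > 0.05:
        note = "warning: weak association with the outcome; environments may not be distinct"
    return EnvScreenResult(env_name, float(p), True, True, note=note,
                           test_used=test_used)


# ----------------------------------------------------------------------
@dataclass
class StudyConfig:
    """Column roles and grid settings for one study analysis."""

    outcome: str = "y"
    predictors: Sequence[str] | None = None
    environments: Sequence[str] | None = None  # names of existing env columns
    env_rules: Mapping[str, Mapping] = field(default_factory=dict)
    alphas: Sequence[float] = DEFAULT_ALPHAS
    methods: Sequence[str] = DEFAULT_METHODS
    k_max: int = 8
    max_size: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, source: str | Path) -> "StudyConfig":
        from .scm import _read_yaml_source

        payload = yaml.safe_load(_read_yaml_source(source))
        if not isinstance(payload, dict):
            raise ConfigError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)!r}")
        return cls(**payload)

    def to_yaml(self) -> str:
        payload = {
            "outcome": self.outcome,
            "predictors": list(self.predictors) if self.predictors else None,
            "environments": list(self.environments) if self.environments else None,
            "env_rules": {k: dict(v) for k, v in self.env_rules.items()},
            "alphas": [float(a) for a in self.alphas],
            "methods": list(self.methods),
            "k_max": self.k_max,
            "max_size": self.max_size,
            "seed": self.seed,
        }
        return yaml.safe_dump(payload, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Full grid of ICP runs with screening diagnostics."""

    grid: dict[tuple[str, str, float], ICPResults | str]
    screening: list[EnvScreenResult]
    config_yaml: str
    config_hash: str
    seed: int
    version: str = _version

    # ------------------------------------------------------------------
    def cell_text(self, method: str, env: str, alpha: float) -> str:
        cell = self.grid[(method, env, alpha)]
        if isinstance(cell, str):  # recorded per-cell failure
            return f"!{cell}"
        if cell.status == STATUS_MODEL_REJECTED:
            return "-"
        if not cell.estimated_set:
            return "None"
        return ", ".join(cell.estimated_set)

    @property
    def methods(self) -> list[str]:
        return sorted({m for m, _, _ in self.grid}, reverse=True)  # full before lasso

    @property
    def environments(self) -> list[str]:
        seen: list[str] = []
        for _, env, _ in self.grid:
            if env not in seen:
                seen.append(env)
        return seen

    @property
    def alphas(self) -> list[float]:
        return sorted({a for _, _, a in self.grid}, reverse=True)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "config": self.config_yaml,
            "screening": [s.to_dict() for s in self.screening],
            "grid": [
                {
                    "method": m,
                    "env": e,
                    "alpha": a,
                    "cell": (
                        self.grid[(m, e, a)].to_dict()
                        if isinstance(self.grid[(m, e, a)], ICPResults)
                        else {"error": self.grid[(m, e, a)]}
                    ),
                }
                for (m, e, a) in sorted(self.grid, key=lambda k: (k[0], k[1], -k[2]))
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def empty_fraction(self) -> float:
        """Fraction of grid cells with an empty estimated set."""
        cells = [c for c in self.grid.values() if isinstance(c, ICPResults)]
        if not cells:
            return float("nan")
        return float(np.mean([len(c.estimated_set) == 0 for c in cells]))


def run_study_analysis(dataset: Dataset, config: StudyConfig) -> StudyReport:
    """Run the method x environment x alpha grid on one cohort.

    Environment columns named in ``config.env_rules`` are derived from raw
    columns (found in ``dataset.extras`` or ``dataset.X``) via
    :func:`dichotomize_environment`; names in ``config.environments`` must
    already exist as binary columns.  Per-cell failures are recorded in the
    grid rather than aborting the whole analysis.  Deterministic given
    ``config.seed``.
    """
    env_frame = dataset.env.copy()
    for name, rule in config.env_rules.items():
        source = None
        if dataset.extras is not None and name in dataset.extras.columns:
            source = dataset.extras[name]
        elif name in dataset.X.columns:
            source = dataset.X[name]
        elif name in env_frame.columns:
            source = env_frame[name]
        if source is None:
            raise ConfigError(f"no source column for environment rule {name!r}")
        env_frame[name] = dichotomize_environment(source, rule).to_numpy()
    env_names = list(config.environments) if config.environments else list(
        env_frame.columns
    )
    missing = [e for e in env_names if e not in env_frame.columns]
    if missing:
        raise ConfigError(f"unknown environments {missing!r}")
    predictors = list(config.predictors) if config.predictors else list(
        dataset.X.columns
    )
    working = Dataset(
        X=dataset.X,
        y=dataset.y,
        env=env_frame[env_names],
        provenance=dataset.provenance,
        extras=dataset.extras,
    )
    screening = [screen_environment(working, e) for e in env_names]
    grid: dict[tuple[str, str, float], ICPResults | str] = {}
    alphas = [float(a) for a in config.alphas]
    for method in config.methods:
        for env in env_names:
            try:
                model = InvariantCausalPrediction(working, env, predictors=predictors)
                per_alpha = model.fit_alphas(
                    alphas,
                    method=method,
                    k_max=config.k_max,
                    max_size=config.max_size,
                    seed=config.seed,
                )
                for alpha in alphas:
                    grid[(method, env, alpha)] = per_alpha[alpha]
            except ICPError as exc:
                for alpha in alphas:
                    grid[(method, env, alpha)] = f"{type(exc).__name__}: {exc}"
    return StudyReport(
        grid=grid,
        screening=screening,
        config_yaml=config.to_yaml(),
        config_hash=config.digest(),
        seed=config.seed,
    )


# ----------------------------------------------------------------------
def render_report(report: StudyReport, format: str = "markdown") -> str:
    """Serialize a study report (``tsv``, ``json`` or ``markdown``).

    Output is byte-reproducible for identical reports.  Cell conventions:
    a comma-separated predictor set; ``None`` when subsets were accepted but
    intersect to the empty set; ``-`` when no subset was accepted.
    """
    if format == "json":
        return report.to_json()
    alphas = report.alphas
    if format == "tsv":
        lines = ["\t".join(["method", "environment"] + [f"alpha_{a:g}" for a in alphas])]
        for method in report.methods:
            for env in report.environments:
                cells = [report.cell_text(method, env, a) for a in alphas]
                lines.append("\t".join([method, env] + cells))
        return "\n".join(lines) + "\n"
    if format == "markdown":
        header = "| Method | Environment | " + " | ".join(
            f"α < {a:g}" for a in alphas
        ) + " |"
        sep = "|" + "---|" * (2 + len(alphas))
        lines = [header, sep]
        for method in report.methods:
            for i, env in enumerate(report.environments):
                label = method.capitalize() if i == 0 else ""
                cells = [report.cell_text(method, env, a) for a in alphas]
                lines.append(
                    "| " + " | ".join([label, env] + cells) + " |"
                )
        lines.append("")
        lines.append(f"Config hash: {report.config_hash}; seed {report.seed}.")
        return "\n".join(lines) + "\n"
    raise ConfigError(f"unknown report format {format!r}")
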