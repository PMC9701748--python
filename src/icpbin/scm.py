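"""Linear-Gaussian structural causal models with a logistic binary outcome.

The generator draws the predictors in topological order as linear functions of
their parents plus Gaussian noise, applies per-environment interventions
(mean shift, noise scale, or hard ``do``), and finally draws the outcome

    Y ~ Bernoulli( sigmoid( c + sum_{j in S*} w_j X_j ) )

where ``S*`` is the set of direct causal parents of the outcome.  The outcome
mechanism is never intervened on: the conditional law of Y given its parents
is therefore identical across environments by construction, which is the
invariance the testing machinery is built to detect.

The outcome has no children in this generator (predictors are drawn first);
specifications with outgoing edges from the outcome are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .dataset import Dataset
from .exceptions import ConfigError, ContractViolationError, StructuralError

OUTCOME_NODE = "Y"
VALID_KINDS = ("shift", "scale", "do")


def _read_yaml_source(source) -> str:
    """Accept either a filesystem path or literal YAML text."""
    text = str(source)
    if "\n" not in text:
        path = Path(text)
        try:
            if path.exists():
                return path.read_text()
        except OSError:
            pass
    return text


class Intervention(NamedTuple):
    """One per-environment mechanism change on a predictor."""

    variable: str
    kind: str  # shift | scale | do
    magnitude: float


@dataclass
class SCMSpec:
    """Ground-truth causal structure for simulation and validation.

    Parameters
    ----------
    names
        Predictor names, in generation order of the node indexing.
    adjacency
        ``(p+1) x (p+1)`` weight matrix; node ``p`` is the outcome.
        ``adjacency[i, j]`` is the coefficient of node ``i`` in node ``j``'s
        structural equation.  The outcome row must be zero.
    outcome_intercept
        Intercept ``c`` of the logistic outcome mechanism.
    noise_scales
        Per-predictor Gaussian noise standard deviations (positive).
    interventions
        Map environment level -> interventions applied in that environment.
    """

    names: list[str]
    adjacency: np.ndarray
    outcome_intercept: float = 0.0
    noise_scales: np.ndarray | None = None
    interventions: dict[int, list[Intervention]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        p = len(self.names)
        if self.adjacency.shape != (p + 1, p + 1):
            raise StructuralError(
                f"adjacency must be ({p + 1}, {p + 1}) including the outcome node"
            )
        if self.noise_scales is None:
            self.noise_scales = np.ones(p)
        self.noise_scales = np.asarray(self.noise_scales, dtype=float)
        if self.noise_scales.shape != (p,) or (self.noise_scales <= 0).any():
            raise StructuralError("noise_scales must be positive, one per predictor")
        self.interventions = {
            int(level): [Intervention(*iv) for iv in ivs]
            for level, ivs in self.interventions.items()
        }
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.names)

    @property
    def outcome_parents(self) -> list[str]:
        """Names of the direct causal parents S* of the outcome."""
        p = self.n_vars
        return [self.names[i] for i in range(p) if self.adjacency[i, p] != 0.0]

    @property
    def outcome_weights(self) -> np.ndarray:
        return self.adjacency[: self.n_vars, self.n_vars]

    def validate(self) -> None:
        p = self.n_vars
        if len(set(self.names)) != p:
            raise StructuralError("predictor names must be unique")
        if OUTCOME_NODE in self.names:
            raise StructuralError(f"{OUTCOME_NODE!r} is reserved for the outcome node")
        if np.any(self.adjacency[p, :] != 0.0):
            raise StructuralError("the outcome cannot have children in this generator")
        graph = nx.from_numpy_array(self.adjacency, create_using=nx.DiGraph)
        if not nx.is_directed_acyclic_graph(graph):
            raise StructuralError("adjacency is cyclic; no topological order exists")
        for level, ivs in self.interventions.items():
            for iv in ivs:
                if iv.kind not in VALID_KINDS:
                    raise ConfigError(f"unknown intervention kind {iv.kind!r}")
                if iv.variable == OUTCOME_NODE:
                    raise ContractViolationError(
                        "interventions must never target the outcome"
                    )
                if iv.variable not in self.names:
                    raise ConfigError(f"unknown intervention target {iv.variable!r}")

    def topological_order(self) -> list[int]:
        p = self.n_vars
        sub = nx.from_numpy_array(
            self.adjacency[:p, :p], create_using=nx.DiGraph
        )
        return list(nx.topological_sort(sub))

    # ------------------------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        p = self.n_vars
        edges = []
        labels = self.names + [OUTCOME_NODE]
        for i in range(p + 1):
            for j in range(p + 1):
                if self.adjacency[i, j] != 0.0:
                    edges.append([labels[i], labels[j], float(self.adjacency[i, j])])
        payload = {
            "names": list(self.names),
            "edges": edges,
            "outcome_intercept": float(self.outcome_intercept),
            "noise_scales": [float(s) for s in self.noise_scales],
            "interventions": {
                int(level): [[iv.variable, iv.kind, float(iv.magnitude)] for iv in ivs]
                for level, ivs in self.interventions.items()
            },
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SCMSpec":
        return cls.from_dict(yaml.safe_load(_read_yaml_source(source)))

    @classmethod
    def from_dict(cls, payload: dict) -> "SCMSpec":
        names = list(payload["names"])
        labels = names + [OUTCOME_NODE]
        index = {name: i for i, name in enumerate(labels)}
        adjacency = np.zeros((len(names) + 1, len(names) + 1))
        for src, dst, weight in payload.get("edges", []):
            adjacency[index[src], index[dst]] = float(weight)
        return cls(
            names=names,
            adjacency=adjacency,
            outcome_intercept=float(payload.get("outcome_intercept", 0.0)),
            noise_scales=np.asarray(
                payload.get("noise_scales", np.ones(len(names))), dtype=float
            ),
            interventions={
                int(level): [Intervention(v, k, float(m)) for v, k, m in ivs]
                for level, ivs in payload.get("interventions", {}).items()
            },
        )


# ----------------------------------------------------------------------
def default_interventions(spec: SCMSpec, magnitude_scale: float = 1.0) -> SCMSpec:
    """Return a copy with the default intervention regime installed.

    Environment 0 is observational; in environment 1 every predictor that is
    *not* a direct parent of the outcome receives a mean shift of
    ``magnitude_scale`` times its noise scale — the simplest setting under
    which invariance-based identification is exercised.
    """
    parents = set(spec.outcome_parents)
    shifts = [
        Intervention(name, "shift", magnitude_scale * float(scale))
        for name, scale in zip(spec.names, spec.noise_scales)
        if name not in parents
    ]
    return SCMSpec(
        names=list(spec.names),
        adjacency=spec.adjacency.copy(),
        outcome_intercept=spec.outcome_intercept,
        noise_scales=spec.noise_scales.copy(),
        interventions={1: shifts},
    )


def simulate_scm(
    spec: SCMSpec,
    n_per_env: int,
    env_levels: int = 2,
    seed: int = 0,
    env_name: str = "env",
) -> Dataset:
    """Draw a multi-environment dataset from a structural causal model.

    Rows are grouped by generating environment (``n_per_env`` rows each);
    the environment label is recorded in ``dataset.env[env_name]``.
    Deterministic given ``seed``.
    """
    if n_per_env < 1:
        raise ConfigError("n_per_env must be >= 1")
    if env_levels < 1:
        raise ConfigError("env_levels must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    p = spec.n_vars
    order = spec.topological_order()
    blocks: list[np.ndarray] = []
    y_blocks: list[np.ndarray] = []
    for level in range(env_levels):
        ivs = {iv.variable: iv for iv in spec.interventions.get(level, [])}
        X = np.zeros((n_per_env, p))
        for j in order:
            name = spec.names[j]
            iv = ivs.get(name)
            if iv is not None and iv.kind == "do":
                X[:, j] = iv.magnitude
                continue
            noise_scale = spec.noise_scales[j]
            if iv is not None and iv.kind == "scale":
                noise_scale = noise_scale * iv.magnitude
            value = X @ spec.adjacency[:p, j] + noise_scale * rng.standard_normal(
                n_per_env
            )
            if iv is not None and iv.kind == "shift":
                value = value + iv.magnitude
            X[:, j] = value
        eta = spec.outcome_intercept + X @ spec.outcome_weights
        prob = 1.0 / (1.0 + np.exp(-eta))
        y_blocks.append((rng.random(n_per_env) < prob).astype(float))
        blocks.append(X)
    X_all = np.vstack(blocks)
    env_labels = np.repeat(np.arange(env_levels, dtype=float), n_per_env)
    return Dataset(
        X=pd.DataFrame(X_all, columns=spec.names),
        y=pd.Series(np.concatenate(y_blocks), name="y"),
        env=pd.DataFrame({env_name: env_labels}),
        provenance={"source": "scm", "seed": int(seed), "n_per_env": int(n_per_env)},
    )


def calibrate_intercept(
    spec: SCMSpec,
    event_rate: float,
    n_ref: int = 200_000,
    env_levels: int = 2,
    seed: int = 0,
) -> float:
    """Intercept for which the pooled marginal event rate hits ``event_rate``.

    Bisects on the analytic mean of the sigmoid evaluated over a large
    reference draw of the predictors (pooled across environments), which is a
    smooth, monotone function of the intercept.
    """
    if not 0.0 < event_rate < 1.0:
        raise ConfigError("event_rate must lie strictly inside (0, 1)")
    probe = SCMSpec(
        names=list(spec.names),
        adjacency=spec.adjacency.copy(),
        outcome_intercept=0.0,
        noise_scales=spec.noise_scales.copy(),
        interventions=spec.interventions,
    )
    ds = simulate_scm(probe, n_per_env=max(1, n_ref // env_levels),
                      env_levels=env_levels, seed=seed)
    eta0 = ds.X.to_numpy() @ spec.outcome_weights

    def mean_rate(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + eta0)))))

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < event_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------
def load_preset(name: str) -> SCMSpec:
    """Load one of the named SCM families shipped with the package.

    Available presets: ``strong`` (two well-separated parents, unit shifts on
    the non-parents), ``weak`` (attenuated coefficients and shifts) and
    ``rare`` (weak family re-used at a rare outcome prevalence; callers
    typically recalibrate the intercept to a target event rate).
    """
    try:
        text = (
            resources.files("icpbin").joinpath("presets", f"{name}.yaml").read_text()
        )
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown SCM preset {name!r}") from exc
    return SCMSpec.from_dict(yaml.safe_load(text))


def planted_signal_spec(
    n_predictors: int = 18,
    parent_weights: Iterable[float] = (1.2, -1.0),
    intercept: float = 0.0,
) -> SCMSpec:
    """Independent-noise design with a small planted parent set.

    The first ``len(parent_weights)`` predictors carry the signal; the rest
    are pure noise.  Used to probe screening selection-consistency.
    """
    weights = list(parent_weights)
    if n_predictors < len(weights):
        raise ConfigError("n_predictors smaller than the planted parent set")
    names = [f"X{i + 1}" for i in range(n_predictors)]
    adjacency = np.zeros((n_predictors + 1, n_predictors + 1))
    for i, w in enumerate(weights):
        adjacency[i, n_predictors] = w
    return SCMSpec(names=names, adjacency=adjacency, outcome_intercept=intercept)
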