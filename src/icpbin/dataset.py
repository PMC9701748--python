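"""Aligned cohort container: predictors, binary outcome, environment labels.

A :class:`Dataset` holds an ``n x p`` predictor frame ``X``, a {0,1} outcome
vector ``y`` and one or more binary environment columns.  Environment entries
may be NaN for rows that could not be mapped to either level (e.g. a gender
response outside the male/female dichotomy); such rows are excluded from that
environment's analysis only, never listwise.

Serialization is a single CSV (outcome column ``y``, environment columns
prefixed ``env_``) plus a JSON sidecar carrying provenance and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, UntestableEnvironmentError

ENV_PREFIX = "env_"
OUTCOME_COLUMN = "y"


@dataclass
class Dataset:
    X: pd.DataFrame
    y: pd.Series
    env: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    extras: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = len(self.X)
        if len(self.y) != n or len(self.env) != n:
            raise DataError("X, y and env must share the same number of rows")
        yv = np.asarray(self.y, dtype=float)
        if not np.isin(yv, (0.0, 1.0)).all():
            raise DataError("outcome must contain only 0/1 values")
        for name in self.env.columns:
            col = np.asarray(self.env[name], dtype=float)
            observed = set(np.unique(col[~np.isnan(col)]))
            if not observed <= {0.0, 1.0}:
                raise DataError(f"environment {name!r} must be coded 0/1 (NaN allowed)")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def predictors(self) -> list[str]:
        return list(self.X.columns)

    @property
    def environments(self) -> list[str]:
        return list(self.env.columns)

    def require_two_levels(self, env_name: str) -> None:
        """Raise unless ``env_name`` exists and shows both levels."""
        if env_name not in self.env.columns:
            raise DataError(f"unknown environment column {env_name!r}")
        col = np.asarray(self.env[env_name], dtype=float)
        levels = set(np.unique(col[~np.isnan(col)]))
        if levels != {0.0, 1.0}:
            raise UntestableEnvironmentError(
                f"environment {env_name!r} does not contain both levels"
            )

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        env = self.env.rename(columns=lambda c: f"{ENV_PREFIX}{c}")
        parts = [self.X, pd.DataFrame({OUTCOME_COLUMN: self.y}), env]
        if self.extras is not None:
            parts.append(self.extras)
        return pd.concat(parts, axis=1)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls.from_frame(df, provenance=provenance)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        outcome: str = OUTCOME_COLUMN,
        env_columns: list[str] | None = None,
        predictors: list[str] | None = None,
        provenance: dict | None = None,
    ) -> "Dataset":
        """Build a Dataset from a flat frame.

        Environment columns default to those prefixed ``env_`` (the prefix is
        stripped); predictors default to every remaining numeric column.
        """
        if outcome not in df.columns:
            raise DataError(f"outcome column {outcome!r} not found")
        if env_columns is None:
            env_columns = [c for c in df.columns if c.startswith(ENV_PREFIX)]
        env = df[env_columns].rename(
            columns=lambda c: c[len(ENV_PREFIX):] if c.startswith(ENV_PREFIX) else c
        )
        if predictors is None:
            predictors = [
                c
                for c in df.columns
                if c not in env_columns and c != outcome
                and pd.api.types.is_numeric_dtype(df[c])
            ]
        return cls(
            X=df[predictors].astype(float).reset_index(drop=True),
            y=df[outcome].astype(float).reset_index(drop=True),
            env=env.astype(float).reset_index(drop=True),
            provenance=provenance or {"source": "file"},
        )
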