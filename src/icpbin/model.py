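"""Subset search and the invariant-causal-prediction estimator.

The estimator tests every candidate subset of predictors for invariance of
the outcome's conditional distribution across a two-level environment and
returns the intersection of all accepted subsets.  With probability at least
``1 - alpha`` that intersection is contained in the set of direct causal
parents of the outcome, provided the environments arise from interventions
that spare the outcome mechanism.

Exhaustive enumeration grows as ``2^p``; the ``lasso`` method first screens
predictors with L1-penalized logistic regression (cross-validated penalty)
so the search stays tractable.

The public surface follows the model/results idiom::

    model = InvariantCausalPrediction(dataset, env_name="env")
    res = model.fit(alpha=0.05, method="full")
    print(res.summary())
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .dataset import Dataset
from .exceptions import ConfigError, DataError
from .invariance import SubsetTestResult, test_subset

STATUS_OK = "ok"
STATUS_MODEL_REJECTED = "model_rejected"
STATUS_EMPTY_INTERSECTION = "empty_by_intersection"


# ----------------------------------------------------------------------
def enumerate_subsets(
    predictors: Sequence[str], max_size: int | None = None
) -> Iterator[tuple[str, ...]]:
    """Yield all predictor subsets, empty set first, in size-then-lex order.

    "Lexicographic" refers to the order in which the predictors are given,
    so the sequence is deterministic for a fixed predictor list.
    """
    predictors = list(predictors)
    if not predictors:
        raise ConfigError("predictor list must be non-empty")
    if len(set(predictors)) != len(predictors):
        raise ConfigError("predictor list contains duplicates")
    top = len(predictors) if max_size is None else min(max_size, len(predictors))
    for size in range(top + 1):
        yield from itertools.combinations(predictors, size)


def n_subsets(n_predictors: int, max_size: int | None = None) -> int:
    if max_size is None or max_size >= n_predictors:
        return 2 ** n_predictors
    from math import comb

    return sum(comb(n_predictors, k) for k in range(max_size + 1))


def intersect_accepted(
    accepted_sets: Iterable[Iterable[str]],
) -> tuple[tuple[str, ...], str]:
    """Intersection of accepted subsets and its interpretation.

    Returns ``(estimated_set, status)`` where status distinguishes an empty
    estimate caused by *no* subset being accepted (``model_rejected`` — the
    invariance assumption failed everywhere) from an empty intersection of
    non-empty acceptances (``empty_by_intersection`` — no single predictor is
    common to every invariant subset).
    """
    sets = [frozenset(s) for s in accepted_sets]
    if not sets:
        return (), STATUS_MODEL_REJECTED
    common = frozenset.intersection(*sets)
    if not common:
        return (), STATUS_EMPTY_INTERSECTION
    return tuple(sorted(common)), STATUS_OK


# ----------------------------------------------------------------------
def lasso_screen(dataset: Dataset, k_max: int = 8, seed: int = 0) -> list[str]:
    """Screen predictors with cross-validated L1 logistic regression.

    Predictors are standardized; the penalty is chosen by 10-fold
    cross-validated deviance (folds seeded), taking the deviance-minimizing
    penalty so the screen over-selects rather than drops weak parents.
    Returns the predictors with nonzero coefficients, truncated to the
    ``k_max`` largest absolute coefficients, in original column order.
    """
    if k_max < 1:
        raise ConfigError("k_max must be >= 1")
    X = dataset.X.to_numpy(dtype=float)
    y = np.asarray(dataset.y, dtype=float)
    if np.unique(y).size < 2:
        raise DataError("outcome has a single class; screening undefined")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    n_splits = min(10, int(np.sum(y == 1)), int(np.sum(y == 0)))
    if n_splits < 2:
        warnings.warn("too few events for cross-validation; screening returns nothing")
        return []
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = LogisticRegressionCV(
            Cs=np.logspace(-3, 2, 12),
            cv=cv,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=2000,
            refit=True,
        ).fit(Z, y)
    coef = model.coef_.ravel()
    nonzero = np.flatnonzero(coef != 0.0)
    if nonzero.size == 0:
        warnings.warn(
            "lasso screen selected no predictors at the CV-chosen penalty; "
            "only the empty subset will be tested"
        )
        return []
    order = nonzero[np.argsort(-np.abs(coef[nonzero]), kind="stable")][:k_max]
    keep = sorted(order)  # report in original column order
    return [dataset.X.columns[i] for i in keep]


# ----------------------------------------------------------------------
@dataclass
class ICPResults:
    """Results of one invariant-causal-prediction fit.

    ``estimated_set`` is the intersection of all accepted subsets;
    ``status`` separates "no subset accepted" (invariance rejected
    everywhere, the method's model check fails) from "accepted subsets share
    no predictor" (indeterminacy).
    """

    env_name: str
    alpha: float
    method: str
    screened_predictors: tuple[str, ...]
    accepted_sets: list[tuple[str, ...]]
    estimated_set: tuple[str, ...]
    status: str
    n_subsets_tested: int
    subset_results: list[SubsetTestResult] = field(default_factory=list, repr=False)

    @property
    def any_accepted(self) -> bool:
        return len(self.accepted_sets) > 0

    def to_dict(self) -> dict:
        return {
            "env": self.env_name,
            "alpha": self.alpha,
            "method": self.method,
            "screened_predictors": list(self.screened_predictors),
            "n_subsets_tested": self.n_subsets_tested,
            "n_accepted": len(self.accepted_sets),
            "any_accepted": self.any_accepted,
            "accepted_sets": [list(s) for s in self.accepted_sets],
            "estimated_set": list(self.estimated_set),
            "status": self.status,
        }

    def subset_table(self) -> pd.DataFrame:
        """Per-subset audit table (subset, t, dof, p, accepted)."""
        return pd.DataFrame([r.to_record(self.env_name) for r in self.subset_results])

    def summary(self) -> str:
        lines = [
            "Invariant Causal Prediction Results",
            "===================================",
            f"Environment:        {self.env_name}",
            f"Method:             {self.method}",
            f"Significance level: {self.alpha:g}",
            f"Subsets tested:     {self.n_subsets_tested}"
            f" (over {len(self.screened_predictors)} candidate predictors)",
            f"Subsets accepted:   {len(self.accepted_sets)}",
            f"Status:             {self.status}",
        ]
        if self.status == STATUS_MODEL_REJECTED:
            lines.append(
                "Estimated parents:  - (no invariant subset; model rejected)"
            )
        elif not self.estimated_set:
            lines.append(
                "Estimated parents:  None (accepted subsets share no predictor)"
            )
        else:
            lines.append(f"Estimated parents:  {', '.join(self.estimated_set)}")
        return "\n".join(lines)


class InvariantCausalPrediction:
    """Invariance-based causal parent estimation for a binary outcome.

    Parameters
    ----------
    dataset
        Aligned predictors / outcome / environment container.
    env_name
        Which binary environment column to test against.
    predictors
        Candidate predictor pool; defaults to all predictor columns.
    """

    def __init__(
        self,
        dataset: Dataset,
        env_name: str,
        predictors: Sequence[str] | None = None,
    ) -> None:
        dataset.require_two_levels(env_name)
        self.dataset = dataset
        self.env_name = env_name
        self.predictors = list(predictors) if predictors is not None else list(
            dataset.X.columns
        )
        unknown = [p for p in self.predictors if p not in dataset.X.columns]
        if unknown:
            raise ConfigError(f"unknown predictors {unknown!r}")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        env: str,
        outcome: str = "y",
        predictors: Sequence[str] | None = None,
    ) -> "InvariantCausalPrediction":
        env_col = env if env in df.columns else f"env_{env}"
        if env_col not in df.columns:
            raise ConfigError(f"environment column {env!r} not found")
        if predictors is None:
            predictors = [
                c
                for c in df.columns
                if c not in (outcome, env_col)
                and not str(c).startswith("env_")
                and pd.api.types.is_numeric_dtype(df[c])
            ]
        ds = Dataset(
            X=df[list(predictors)].astype(float).reset_index(drop=True),
            y=df[outcome].astype(float).reset_index(drop=True),
            env=pd.DataFrame(
                {env.removeprefix("env_"): df[env_col].astype(float).reset_index(drop=True)}
            ),
            provenance={"source": "dataframe"},
        )
        return cls(ds, env.removeprefix("env_"))

    # ------------------------------------------------------------------
    def _screen(self, method: str, k_max: int, seed: int) -> list[str]:
        if method == "full":
            return list(self.predictors)
        if method == "lasso":
            pool = Dataset(
                X=self.dataset.X[self.predictors],
                y=self.dataset.y,
                env=self.dataset.env,
                provenance=self.dataset.provenance,
            )
            return lasso_screen(pool, k_max=k_max, seed=seed)
        raise ConfigError(f"unknown method {method!r}; choose 'full' or 'lasso'")

    def _test_all(
        self,
        screened: Sequence[str],
        max_size: int | None,
        residual_type: str,
        alpha_for_records: float,
        reject_direction: str,
    ) -> list[SubsetTestResult]:
        results = []
        if screened:
            subsets = enumerate_subsets(screened, max_size=max_size)
        else:
            subsets = iter([()])
        for subset in subsets:
            results.append(
                test_subset(
                    self.dataset,
                    subset,
                    self.env_name,
                    alpha_for_records,
                    residual_type=residual_type,
                    reject_direction=reject_direction,
                )
            )
        return results

    def fit(
        self,
        alpha: float = 0.05,
        method: str = "full",
        k_max: int = 8,
        max_size: int | None = None,
        seed: int = 0,
        residual_type: str = "response",
        reject_direction: str = "standard",
    ) -> ICPResults:
        """Run the full subset search at one significance level."""
        return self.fit_alphas(
            [alpha],
            method=method,
            k_max=k_max,
            max_size=max_size,
            seed=seed,
            residual_type=residual_type,
            reject_direction=reject_direction,
        )[alpha]

    def fit_alphas(
        self,
        alphas: Sequence[float],
        method: str = "full",
        k_max: int = 8,
        max_size: int | None = None,
        seed: int = 0,
        residual_type: str = "response",
        reject_direction: str = "standard",
    ) -> dict[float, ICPResults]:
        """Fit at several significance levels sharing the per-subset tests.

        The subset p-values do not depend on alpha, so the grid reuses one
        sweep of logistic fits; results are identical to separate
        :meth:`fit` calls.
        """
        if not alphas:
            raise ConfigError("need at least one significance level")
        screened = self._screen(method, k_max, seed)
        tests = self._test_all(
            screened, max_size, residual_type, float(alphas[0]), reject_direction
        )
        out: dict[float, ICPResults] = {}
        for alpha in alphas:
            if reject_direction == "standard":
                flags = [t.p_value >= alpha for t in tests]
            else:
                flags = [t.p_value < alpha for t in tests]
            accepted_sets = [t.subset for t, ok in zip(tests, flags) if ok]
            estimated, status = intersect_accepted(accepted_sets)
            per_alpha = [
                SubsetTestResult(
                    subset=t.subset,
                    t_statistic=t.t_statistic,
                    dof=t.dof,
                    p_value=t.p_value,
                    accepted=bool(ok),
                    alpha=float(alpha),
                    n_per_env=t.n_per_env,
                    fit=t.fit,
                )
                for t, ok in zip(tests, flags)
            ]
            out[alpha] = ICPResults(
                env_name=self.env_name,
                alpha=float(alpha),
                method=method,
                screened_predictors=tuple(screened),
                accepted_sets=accepted_sets,
                estimated_set=estimated,
                status=status,
                n_subsets_tested=len(tests),
                subset_results=per_alpha,
            )
        return out


def estimate_chain_monotone(results_by_alpha: dict[float, ICPResults]) -> bool:
    """Check that the estimate shrinks as alpha grows, where defined.

    Stricter levels accept more subsets, so intersecting over more sets can
    only shrink the estimate.  A level where *no* subset was accepted has no
    estimate at all (the intersection over an empty family is vacuously the
    full predictor set, reported as model rejection, not as an empty
    estimate); such levels are skipped.  Rejection can only occur at the
    widest levels of a chain, since the accepted collections are nested.
    """
    wider_estimate: set[str] | None = None
    for alpha in sorted(results_by_alpha, reverse=True):
        res = results_by_alpha[alpha]
        if res.status == STATUS_MODEL_REJECTED:
            continue
        current = set(res.estimated_set)
        if wider_estimate is not None and not current <= wider_estimate:
            return False
        wider_estimate = current
    return True


def run_icp(
    dataset: Dataset,
    env_name: str,
    alpha: float,
    method: str = "full",
    k_max: int = 8,
    max_size: int | None = None,
    seed: int = 0,
    predictors: Sequence[str] | None = None,
    residual_type: str = "response",
) -> ICPResults:
    """One-call interface: screen, enumerate, test, intersect."""
    model = InvariantCausalPrediction(dataset, env_name, predictors=predictors)
    return model.fit(
        alpha=alpha, method=method, k_max=k_max, max_size=max_size, seed=seed,
        residual_type=residual_type,
    )
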