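"""Per-subset invariance test for a binary outcome.

The procedure for one candidate predictor subset S:

1. fit a pooled (all environments together) logistic regression of the
   outcome on S by Newton/IRLS maximum likelihood;
2. form residuals from the model predictions (response residuals
   ``y - p_hat`` by default; Pearson and deviance available);
3. split the residuals by the two-level environment;
4. compare the residual means with a Welch (unequal-variance) two-sample
   t-test;
5. the subset is *accepted* — invariance not rejected — when p >= alpha.

If the conditional distribution of the outcome given its direct causal
parents is invariant to the interventions that distinguish the environments,
any subset containing exactly those parents passes this test at its nominal
level; subsets whose conditional changes across environments are rejected
with power growing in the sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import Dataset
from .exceptions import (
    DataError,
    DegenerateOutcomeError,
    UntestableEnvironmentError,
)

#: ridge applied to slopes (never the intercept) when the MLE does not exist
TINY_RIDGE = 1e-6
#: |linear predictor| beyond which fitted probabilities are numerically 0/1,
#: taken as evidence of separation
SEPARATION_ETA = 30.0

RESIDUAL_TYPES = ("response", "pearson", "deviance")


@dataclass
class LogisticFit:
    """Summary of one pooled logistic fit on a predictor subset."""

    subset: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, then one slope per predictor
    fitted_probs: np.ndarray
    converged: bool
    regularization_used: str = "none"  # "none" | "tiny-ridge"
    n_iter: int = 0

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]


@dataclass
class SubsetTestResult:
    """Invariance evidence for one subset against one environment split."""

    subset: tuple[str, ...]
    t_statistic: float
    dof: float
    p_value: float
    accepted: bool
    alpha: float
    n_per_env: tuple[int, int]
    fit: LogisticFit | None = field(default=None, repr=False)

    def to_record(self, env_name: str = "") -> dict:
        return {
            "subset": "+".join(self.subset) if self.subset else "(empty)",
            "t": self.t_statistic,
            "dof": self.dof,
            "p": self.p_value,
            "accepted": self.accepted,
            "alpha": self.alpha,
            "env": env_name,
            "n_env0": self.n_per_env[0],
            "n_env1": self.n_per_env[1],
        }


# ----------------------------------------------------------------------
def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ez = np.exp(eta[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _irls(
    design: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> tuple[np.ndarray, bool, int]:
    """Newton/IRLS for the logistic log-likelihood.

    ``ridge`` penalizes slopes only, never the intercept.  A rank-deficient
    Newton system falls back to the pseudo-inverse with a warning.  Step
    halving guards against overshoot in near-separated designs.
    """
    n, k = design.shape
    beta = np.zeros(k)
    penalty = np.zeros(k)
    penalty[1:] = ridge

    def negloglik(b: np.ndarray) -> float:
        eta = design @ b
        # log(1+exp(eta)) - y*eta, numerically stable
        return float(
            np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(penalty * b * b)
        )

    nll = negloglik(beta)
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = _sigmoid(eta)
        grad = design.T @ (y - mu) - penalty * beta
        w = mu * (1.0 - mu)
        hess = (design * w[:, None]).T @ design + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            warnings.warn(
                "rank-deficient design; using pseudo-inverse Newton step",
                stacklevel=2,
            )
            step = np.linalg.pinv(hess) @ grad
        # step halving on the penalized negative log-likelihood
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            cand_nll = negloglik(candidate)
            if cand_nll <= nll + 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        nll = negloglik(beta)
        if np.max(np.abs(scale * step)) < tol:
            return beta, True, it
    return beta, False, max_iter


def fit_logistic(
    dataset: Dataset,
    subset: list[str] | tuple[str, ...],
    rows: np.ndarray | None = None,
) -> LogisticFit:
    """Pooled maximum-likelihood logistic fit of the outcome on ``subset``.

    The empty subset yields the closed-form intercept-only fit.  On detected
    separation or non-convergence the model is refit with a tiny ridge
    penalty on the slopes (``TINY_RIDGE``) and flagged, so fitted
    probabilities stay strictly inside (0, 1) and every subset remains
    testable.  ``rows`` optionally restricts the fit to a boolean row mask
    (used for per-environment complete-case analysis).
    """
    subset = tuple(subset)
    missing = [name for name in subset if name not in dataset.X.columns]
    if missing:
        raise DataError(f"unknown predictors {missing!r}")
    y = np.asarray(dataset.y, dtype=float)
    if rows is not None:
        y = y[rows]
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateOutcomeError(
            "outcome has a single observed class; logistic MLE is undefined"
        )
    n = y.size
    if not subset:
        p_bar = float(np.mean(y))
        intercept = float(np.log(p_bar / (1.0 - p_bar)))
        return LogisticFit(
            subset=subset,
            coefficients=np.array([intercept]),
            fitted_probs=np.full(n, p_bar),
            converged=True,
        )
    X = dataset.X[list(subset)].to_numpy(dtype=float)
    if rows is not None:
        X = X[rows]
    design = np.column_stack([np.ones(n), X])
    beta, converged, n_iter = _irls(design, y)
    eta = design @ beta
    separated = bool(np.max(np.abs(eta)) > SEPARATION_ETA)
    regularization = "none"
    if not converged or separated:
        beta, converged, n_iter = _irls(design, y, ridge=TINY_RIDGE)
        regularization = "tiny-ridge"
        eta = design @ beta
    probs = np.clip(_sigmoid(eta), 1e-12, 1.0 - 1e-12)
    return LogisticFit(
        subset=subset,
        coefficients=beta,
        fitted_probs=probs,
        converged=converged,
        regularization_used=regularization,
        n_iter=n_iter,
    )


def residuals(
    fit: LogisticFit, y: np.ndarray, kind: str = "response"
) -> np.ndarray:
    """Residuals from model predictions.

    ``response`` (default): ``y - p_hat``; ``pearson``: response scaled by
    ``sqrt(p_hat (1 - p_hat))``; ``deviance``: signed square-root deviance
    contributions.
    """
    y = np.asarray(y, dtype=float)
    p = fit.fitted_probs
    if y.shape != p.shape:
        raise DataError("y and fitted probabilities have mismatched lengths")
    if kind == "response":
        return y - p
    if kind == "pearson":
        return (y - p) / np.sqrt(p * (1.0 - p))
    if kind == "deviance":
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = -2.0 * (y * np.log(p) + (1.0 - y) * np.log1p(-p))
        return np.sign(y - p) * np.sqrt(np.maximum(dev, 0.0))
    raise DataError(f"unknown residual type {kind!r}; choose from {RESIDUAL_TYPES}")


# ----------------------------------------------------------------------
def welch_test(sample0: np.ndarray, sample1: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-test returning ``(t, dof, two-sided p)``.

    ``t`` is signed as (mean of group 0) minus (mean of group 1).  Two
    identical samples give ``t = 0, p = 1``; zero pooled variance with
    unequal means gives ``t = +/-inf, p = 0``.
    """
    a = np.asarray(sample0, dtype=float)
    b = np.asarray(sample1, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UntestableEnvironmentError(
            "each environment level needs at least 2 observations"
        )
    v0 = float(np.var(a, ddof=1))
    v1 = float(np.var(b, ddof=1))
    diff = float(np.mean(a) - np.mean(b))
    se2 = v0 / a.size + v1 / b.size
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(a.size + b.size - 2), 1.0
        return float(np.sign(diff)) * np.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    dof = float(res.df)
    p = float(res.pvalue)
    if not np.isfinite(t):  # defensive; degenerate cases handled above
        t, p = 0.0, 1.0
    return t, dof, p


def invariance_test(
    resid: np.ndarray,
    env_labels: np.ndarray,
    alpha: float,
    reject_direction: str = "standard",
) -> SubsetTestResult:
    """Welch t-test of residual means between the two environment levels.

    ``reject_direction='standard'`` accepts a subset when the invariance null
    is *not* rejected (p >= alpha).  ``'reversed'`` flips the decision, for
    sensitivity analysis only.
    """
    resid = np.asarray(resid, dtype=float)
    env = np.asarray(env_labels, dtype=float)
    if resid.shape != env.shape:
        raise DataError("residuals and environment labels have mismatched lengths")
    keep = ~np.isnan(env)
    resid, env = resid[keep], env[keep]
    levels = set(np.unique(env))
    if levels != {0.0, 1.0}:
        raise UntestableEnvironmentError("environment must show both levels 0 and 1")
    r0, r1 = resid[env == 0.0], resid[env == 1.0]
    t, dof, p = welch_test(r0, r1)
    accepted = p >= alpha if reject_direction == "standard" else p < alpha
    return SubsetTestResult(
        subset=(),
        t_statistic=t,
        dof=dof,
        p_value=p,
        accepted=bool(accepted),
        alpha=float(alpha),
        n_per_env=(int(r0.size), int(r1.size)),
    )


def test_subset(
    dataset: Dataset,
    subset: list[str] | tuple[str, ...],
    env_name: str,
    alpha: float,
    residual_type: str = "response",
    reject_direction: str = "standard",
) -> SubsetTestResult:
    """Fit pooled, residualize, and test invariance across one environment.

    Rows whose environment label is missing (unmapped level) are excluded
    from this environment's analysis only.
    """
    dataset.require_two_levels(env_name)
    env = np.asarray(dataset.env[env_name], dtype=float)
    rows = ~np.isnan(env)
    fit = fit_logistic(dataset, subset, rows=rows if not rows.all() else None)
    y = np.asarray(dataset.y, dtype=float)[rows]
    resid = residuals(fit, y, kind=residual_type)
    result = invariance_test(resid, env[rows], alpha, reject_direction)
    result.subset = tuple(subset)
    result.fit = fit
    return result
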