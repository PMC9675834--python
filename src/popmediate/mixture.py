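"""Joint multivariate mediation: unpenalized / ridge outcome models + bootstrap.

The mediator model is a multivariate regression M_i = alpha_0 + A_i alpha_a +
alpha_z Z_i + eps (fit equation-by-equation, which is the MLE with identical
predictors); the outcome model regresses Y on A, all 15 mediators and Z,
either unpenalized or with a ridge penalty on the mediator coefficients only
(the exposure group and covariates are never penalized: the penalty targets
variance inflation from the collinear chemicals, and shrinking A would bias
the direct effect). The global indirect effect is alpha_a' beta_m; inference
comes from a nonparametric participant bootstrap with percentile intervals.
Survey weights enter point estimation, but strata/PSUs do not enter the
variance of these two estimators (the summary-score methods cover the fully
design-aware route).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mediation import covariate_matrix

__all__ = [
    "RidgeSpec",
    "BootstrapDistribution",
    "fit_multivariate_mediator_model",
    "fit_joint_outcome_model",
    "select_ridge_lambda",
    "global_indirect",
    "global_mediation",
    "bootstrap_mediation",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3.0, 5.0, 25)


@dataclass
class RidgeSpec:
    """Ridge penalty configuration: lambda >= 0 on the mediator columns only."""

    lam: float = 0.0
    cv_folds: int = 5
    cv_seed: int = 0
    lambda_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_LAMBDA_GRID.copy()
    )

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"ridge penalty must be >= 0, got {self.lam}")


@dataclass
class MediatorModelFit:
    alpha_a: pd.Series  # group coefficient per mediator
    coef: pd.DataFrame  # full coefficient matrix (predictors x mediators)


def fit_multivariate_mediator_model(
    cohort: pd.DataFrame, mediators: Sequence[str], weighted: bool = True
) -> MediatorModelFit:
    """Weighted LS of every mediator on [const, A, Z] in one solve."""
    X = covariate_matrix(cohort)
    M = cohort[list(mediators)].to_numpy(float)
    w = cohort["weight"].to_numpy(float) if weighted else np.ones(len(cohort))
    sw = np.sqrt(w)[:, None]
    beta, *_ = np.linalg.lstsq(X.to_numpy(float) * sw, M * sw, rcond=None)
    coef = pd.DataFrame(beta, index=X.columns, columns=list(mediators))
    return MediatorModelFit(alpha_a=coef.loc["group"], coef=coef)


@dataclass
class JointOutcomeFit:
    beta_a: float
    beta_m: pd.Series
    params: pd.Series
    lam: float


def fit_joint_outcome_model(
    cohort: pd.DataFrame,
    mediators: Sequence[str],
    spec: RidgeSpec | None = None,
    weighted: bool = True,
    z_columns: Sequence[str] | None = None,
) -> JointOutcomeFit:
    """Y on [const, A, M..., Z], optionally ridge-penalizing the mediators.

    Penalized columns are standardized internally (weighted mean/sd) and the
    coefficients mapped back to the original scale; lambda = 0 reduces to the
    unpenalized weighted LS fit exactly.
    """
    spec = spec or RidgeSpec(lam=0.0)
    X = covariate_matrix(cohort, extra=list(mediators), z_columns=z_columns)
    names = list(X.columns)
    y = cohort["y"].to_numpy(float)
    w = cohort["weight"].to_numpy(float) if weighted else np.ones(len(cohort))
    w = w / w.mean()  # lambda acts on a scale-free weighted problem
    Xa = X.to_numpy(float).copy()
    med_idx = [names.index(m) for m in mediators]
    centers = np.zeros(Xa.shape[1])
    scales = np.ones(Xa.shape[1])
    for j in med_idx:
        centers[j] = np.average(Xa[:, j], weights=w)
        scales[j] = np.sqrt(np.average((Xa[:, j] - centers[j]) ** 2, weights=w))
        Xa[:, j] = (Xa[:, j] - centers[j]) / scales[j]
    pen = np.zeros(Xa.shape[1])
    pen[med_idx] = spec.lam
    xtwx = Xa.T @ (w[:, None] * Xa) + np.diag(pen)
    beta_std = np.linalg.solve(xtwx, Xa.T @ (w * y))
    beta = beta_std / scales
    beta[names.index("const")] -= float(np.sum(beta_std[med_idx] * centers[med_idx]
                                               / scales[med_idx]))
    params = pd.Series(beta, index=names)
    return JointOutcomeFit(
        beta_a=float(params["group"]),
        beta_m=params[list(mediators)],
        params=params,
        lam=spec.lam,
    )


def _make_folds(n: int, k: int, groups: np.ndarray, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        perm = rng.permutation(n)
        folds = [perm[i::k] for i in range(k)]
        ok = all(
            len(np.unique(groups[np.setdiff1d(perm, f)])) == 2 and len(f) > 0
            for f in folds
        )
        if ok:
            if attempt > 0:
                warnings.warn("refolded cross-validation splits to keep both "
                              "exposure groups in every training fold")
            return folds
    raise ValueError("could not build CV folds containing both exposure groups")


def select_ridge_lambda(
    cohort: pd.DataFrame,
    mediators: Sequence[str],
    spec: RidgeSpec | None = None,
    weighted: bool = True,
) -> float:
    """Grid-search k-fold CV of the ridge penalty on weighted prediction error.

    Deterministic under ``spec.cv_seed``; ties broken toward the smaller
    lambda.
    """
    spec = spec or RidgeSpec()
    if spec.cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    n = len(cohort)
    folds = _make_folds(n, spec.cv_folds, cohort["group"].to_numpy(), spec.cv_seed)
    w = cohort["weight"].to_numpy(float) if weighted else np.ones(n)
    y = cohort["y"].to_numpy(float)
    errors = np.zeros(len(spec.lambda_grid))
    for fold in folds:
        train = cohort.drop(cohort.index[fold])
        X_val = covariate_matrix(cohort, extra=list(mediators)).iloc[fold]
        for i, lam in enumerate(spec.lambda_grid):
            fit = fit_joint_outcome_model(
                train, mediators,
                RidgeSpec(lam=lam, cv_folds=spec.cv_folds, cv_seed=spec.cv_seed),
                weighted=weighted,
            )
            pred = X_val.to_numpy(float) @ fit.params.to_numpy()
            errors[i] += float(np.sum(w[fold] * (y[fold] - pred) ** 2))
    return float(spec.lambda_grid[int(np.argmin(errors))])


def global_indirect(alpha_a: pd.Series, beta_m: pd.Series) -> float:
    """Global indirect effect alpha_a' beta_m."""
    if len(alpha_a) != len(beta_m):
        raise ValueError("alpha_a and beta_m must have equal length")
    a = np.asarray(alpha_a, dtype=float)
    b = (
        beta_m.reindex(alpha_a.index).to_numpy(dtype=float)
        if isinstance(alpha_a, pd.Series) and isinstance(beta_m, pd.Series)
        else np.asarray(beta_m, dtype=float)
    )
    if np.any(np.isnan(b)):
        raise ValueError("alpha_a and beta_m indexes do not match")
    return float(a @ b)


def global_mediation(
    cohort: pd.DataFrame,
    mediators: Sequence[str],
    spec: RidgeSpec | None = None,
    weighted: bool = True,
) -> dict[str, float]:
    """Point decomposition of the joint model: IE, DE, total, percent."""
    alpha = fit_multivariate_mediator_model(cohort, mediators, weighted=weighted)
    outcome = fit_joint_outcome_model(cohort, mediators, spec, weighted=weighted)
    ie = global_indirect(alpha.alpha_a, outcome.beta_m)
    total = outcome.beta_a + ie
    return {
        "indirect": ie,
        "direct": outcome.beta_a,
        "total": total,
        "percent": 100.0 * ie / total if total != 0 else np.nan,
    }


@dataclass
class BootstrapDistribution:
    """Replicates of a global-IE estimator with percentile CI and p-value."""

    replicates: np.ndarray
    seed: int
    n_failed: int

    @property
    def B(self) -> int:
        return len(self.replicates)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo = float(np.quantile(self.replicates, a, method="closest_observation"))
        hi = float(np.quantile(self.replicates, 1 - a, method="closest_observation"))
        return lo, hi

    @property
    def p(self) -> float:
        b = self.replicates
        n = len(b)
        p_lo = (1.0 + np.sum(b <= 0.0)) / (n + 1.0)
        p_hi = (1.0 + np.sum(b >= 0.0)) / (n + 1.0)
        return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def bootstrap_mediation(
    cohort: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], float],
    B: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.05,
    cluster: bool = False,
) -> BootstrapDistribution:
    """Nonparametric participant bootstrap of a global-IE estimator.

    Participants are resampled with replacement and the estimator recomputed
    per replicate. With ``cluster=True`` (an extension, off by default)
    whole PSUs are resampled with replacement within each stratum instead,
    which respects the sampling dependence the default i.i.d. resampling
    ignores; the cohort must then carry ``stratum``/``psu`` columns. Failed
    refits are excluded; more than ``max_failure_rate`` of them is an error.
    """
    if B < 50:
        raise ValueError("B must be >= 50 for percentile intervals")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    if cluster:
        missing = [c for c in ("stratum", "psu") if c not in cohort.columns]
        if missing:
            raise ValueError(f"cluster bootstrap needs design column(s): {missing}")
        groups: dict = {}
        for (h, _), sub in cohort.groupby(["stratum", "psu"]):
            groups.setdefault(h, []).append(cohort.index.get_indexer(sub.index))
    reps, failed = [], 0
    for _ in range(B):
        if cluster:
            parts = []
            for block in groups.values():
                n_h = len(block)
                for k in rng.integers(0, n_h, n_h):
                    parts.append(block[k])
            idx = np.concatenate(parts)
        else:
            idx = rng.integers(0, n, n)
        sample = cohort.iloc[idx].reset_index(drop=True)
        try:
            reps.append(float(estimator(sample)))
        except Exception:
            failed += 1
    if failed > max_failure_rate * B:
        raise RuntimeError(
            f"{failed}/{B} bootstrap replicates failed (> {max_failure_rate:.0%})"
        )
    return BootstrapDistribution(
        replicates=np.asarray(reps, dtype=float), seed=seed, n_failed=failed
    )


def make_global_ie_estimator(
    mediators: Sequence[str],
    spec: RidgeSpec | None = None,
    reselect_lambda: bool = True,
    weighted: bool = True,
) -> Callable[[pd.DataFrame], float]:
    """Estimator closure for :func:`bootstrap_mediation`.

    With a ridge spec, lambda is re-selected by CV inside every replicate by
    default (honest inference); ``reselect_lambda=False`` freezes the given
    lambda (fast mode).
    """

    def estimate(sample: pd.DataFrame) -> float:
        s = spec
        if s is not None and reselect_lambda:
            lam = select_ridge_lambda(sample, mediators, s, weighted=weighted)
            s = RidgeSpec(lam=lam, cv_folds=s.cv_folds, cv_seed=s.cv_seed,
                          lambda_grid=s.lambda_grid)
        return global_mediation(sample, mediators, s, weighted=weighted)["indirect"]

    return estimate
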