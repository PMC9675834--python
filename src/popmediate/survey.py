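"""Weighted least squares with design-based (Taylor-linearized) variance.

Point estimation is plain weighted least squares. For a stratified cluster
sample the linearization variance uses the between-PSU variation of the
weighted score totals within strata with the usual n_h/(n_h - 1) factor —
the with-replacement first-stage approximation used by standard survey
software. Every model fit in the package goes through this module.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "FitResult",
    "DesignError",
    "fit_wls",
    "taylor_variance",
    "fit_survey",
    "wald_test",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SurveyDesign:
    """Stratum ids, PSU ids nested within strata, and sampling weights."""

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "stratum", np.asarray(self.stratum))
        object.__setattr__(self, "psu", np.asarray(self.psu))
        object.__setattr__(self, "weight", np.asarray(self.weight, dtype=float))

    def validate(self) -> None:
        if np.any(self.weight <= 0):
            raise DesignError("all survey weights must be strictly positive")
        for h in np.unique(self.stratum):
            n_psu = len(np.unique(self.psu[self.stratum == h]))
            if n_psu < 2:
                raise DesignError(
                    f"stratum {h!r} contains {n_psu} PSU: design-based variance "
                    "needs >= 2 PSUs per stratum (collapse strata or designate "
                    "certainty units before fitting)"
                )

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "SurveyDesign":
        missing = [c for c in ("stratum", "psu", "weight") if c not in cohort.columns]
        if missing:
            raise DesignError(f"cohort table lacks design column(s): {missing}")
        return cls(
            stratum=cohort["stratum"].to_numpy(),
            psu=cohort["psu"].to_numpy(),
            weight=cohort["weight"].to_numpy(dtype=float),
        )


@dataclass
class FitResult:
    """Coefficients and covariance of a (possibly survey-weighted) WLS fit."""

    params: pd.Series
    cov: pd.DataFrame
    n: int
    residuals: np.ndarray
    label: str
    design_based: bool = False
    _X: np.ndarray = field(default=None, repr=False)
    _weights: np.ndarray = field(default=None, repr=False)

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))

    def var(self, name: str) -> float:
        return float(self.cov.loc[name, name])


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return sorted(
        [names[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
        + [names[p] for p in piv[len(diag):]]
    )


def fit_wls(
    y: np.ndarray,
    X: pd.DataFrame,
    weights: np.ndarray | None = None,
    label: str = "",
) -> FitResult:
    """Weighted least squares with model-based covariance.

    With unit weights this is ordinary least squares. The model-based
    covariance is sigma^2 (X'WX)^{-1}; call :func:`taylor_variance` to
    replace it with the design-based one.
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != n or Xa.shape[0] != n:
        raise ValueError("y, X and weights must have equal length")
    sw = np.sqrt(w)
    Xs, ys = Xa * sw[:, None], y * sw
    if np.linalg.matrix_rank(Xs) < Xa.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; aliased columns: "
            f"{_aliased_columns(Xs, names)}"
        )
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = y - Xa @ beta
    dof = max(n - Xa.shape[1], 1)
    sigma2 = float(np.sum(w * resid**2) / dof)
    xtwx_inv = np.linalg.inv(Xa.T @ (w[:, None] * Xa))
    cov = sigma2 * xtwx_inv
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n=n,
        residuals=resid,
        label=label,
        _X=Xa,
        _weights=w,
    )


def taylor_variance(fit: FitResult, design: SurveyDesign) -> FitResult:
    """Replace the model-based covariance by the linearization estimate.

    V = (X'WX)^{-1} B (X'WX)^{-1}, with B the stratum-summed between-PSU
    covariance of the weighted score totals w_i x_i e_i, each stratum scaled
    by n_h/(n_h - 1). Invariant to rescaling all weights by a constant.
    """
    design.validate()
    X, w, e = fit._X, fit._weights, fit.residuals
    if X is None:
        raise ValueError("fit does not carry its design matrix")
    if len(design.weight) != fit.n:
        raise ValueError("design and fit sizes differ")
    score = X * (w * e)[:, None]
    p = X.shape[1]
    B = np.zeros((p, p))
    for h in np.unique(design.stratum):
        in_h = design.stratum == h
        psus = np.unique(design.psu[in_h])
        n_h = len(psus)
        totals = np.vstack(
            [score[in_h & (design.psu == j)].sum(axis=0) for j in psus]
        )
        centered = totals - totals.mean(axis=0)
        B += n_h / (n_h - 1) * centered.T @ centered
    a_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    V = a_inv @ B @ a_inv
    V = (V + V.T) / 2.0
    names = list(fit.params.index)
    return replace(
        fit,
        cov=pd.DataFrame(V, index=names, columns=names),
        design_based=True,
    )


def fit_survey(
    y: np.ndarray, X: pd.DataFrame, design: SurveyDesign, label: str = ""
) -> FitResult:
    """Survey-weighted fit: WLS point estimates + Taylor-linearized covariance."""
    return taylor_variance(fit_wls(y, X, weights=design.weight, label=label), design)


def wald_test(
    fit: FitResult, coefficient: str, df: float | None = None
) -> tuple[float, float]:
    """Wald z (or t, when ``df`` is given) statistic and two-sided p-value."""
    est = fit.coef(coefficient)
    se = fit.se(coefficient)
    if se == 0.0:
        raise ValueError(f"zero standard error for coefficient {coefficient!r}")
    z = est / se
    if df is None:
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = 2.0 * stats.t.sf(abs(z), df)
    return float(z), float(p)


def design_df(design: SurveyDesign) -> float:
    """Conventional survey degrees of freedom: PSUs minus strata."""
    pairs = {(h, j) for h, j in zip(design.stratum, design.psu)}
    return float(len(pairs) - len(np.unique(design.stratum)))
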