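"""Summary exposure scores (PCA, PDM, TEQ) run through single-mediator mediation.

A summary score collapses the 15 correlated chemicals into one linear
combination S_i = sum_j w_j M_ij, which is then substituted as the sole
mediator in the survey-weighted single-mediator framework — the route that
fully honours the complex sampling design. Three weight constructions:

* **PCA** — first principal component of the standardized log
  concentrations (correlation-scale, computed on the stacked completed
  data), sign-oriented so the weight sum is positive;
* **PDM** — first principal direction of mediation: the unit-norm weight
  vector maximizing the magnitude of the score's mediated effect
  |alpha_w * beta_w|, found by seeded multi-start numerical optimization;
* **TEQ** — a priori toxic-equivalency-factor potency weights applied to
  natural-scale concentrations (chemicals without a TEF are excluded), with
  the resulting score log-transformed before modelling.

Score mediation is invariant to positive rescaling of the weights: alpha_w
scales by c and beta_w by 1/c, leaving the indirect effect unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .mediation import (
    MediationResult,
    covariate_matrix,
    fit_mediator_model,
    fit_outcome_model,
    indirect_effect,
    pooled_single_mediation,
)
from .survey import SurveyDesign

__all__ = [
    "ScoreWeights",
    "pca_weights",
    "pdm_weights",
    "teq_score",
    "score_mediation",
    "subclass_pca_mediation",
]


@dataclass
class ScoreWeights:
    """Linear-combination weights defining a summary exposure score.

    For pca/pdm the weights have unit Euclidean norm and apply to
    standardized log concentrations (the standardization constants are
    stored so the score is computable on new data); for teq the weights are
    non-negative TEFs applied to natural-scale concentrations and the score
    is log-transformed afterwards.
    """

    weights: pd.Series
    method: str  # "pca" | "pdm" | "teq"
    center: pd.Series | None = None
    scale: pd.Series | None = None
    objective: float | None = None

    @property
    def subset(self) -> list[str]:
        return list(self.weights.index)

    def score(self, cohort: pd.DataFrame) -> np.ndarray:
        cols = self.subset
        logs = cohort[cols].to_numpy(float)
        if self.method == "teq":
            s = np.exp(logs) @ self.weights.to_numpy(float)
            if np.any(s <= 0.0):
                positive = s[s > 0.0]
                if positive.size == 0:
                    raise ValueError("TEQ score is zero for every participant")
                offset = 0.5 * float(positive.min())
                warnings.warn(
                    f"{int((s <= 0).sum())} TEQ score(s) <= 0; offset by half "
                    "the smallest positive score before the log transform"
                )
                s = s + offset
            return np.log(s)
        std = (logs - self.center[cols].to_numpy(float)) / self.scale[cols].to_numpy(
            float
        )
        return std @ self.weights.to_numpy(float)


def _orient(w: np.ndarray) -> np.ndarray:
    s = w.sum()
    if s < 0 or (s == 0 and w[np.nonzero(w)[0][0]] < 0):
        return -w
    return w


def pca_weights(logs: pd.DataFrame, subset: Sequence[str] | None = None) -> ScoreWeights:
    """First principal component of the standardized log concentrations."""
    cols = list(subset) if subset is not None else list(logs.columns)
    if len(cols) < 1:
        raise ValueError("empty chemical subset")
    X = logs[cols].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        bad = [c for c, s in zip(cols, sd) if s == 0.0]
        raise ValueError(f"zero-variance chemical(s): {bad}")
    center = X.mean(axis=0)
    if len(cols) == 1:
        w = np.array([1.0])
    else:
        corr = np.corrcoef(X, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        w = _orient(eigvecs[:, -1])
    return ScoreWeights(
        weights=pd.Series(w, index=cols),
        method="pca",
        center=pd.Series(center, index=cols),
        scale=pd.Series(sd, index=cols),
        objective=float(eigvals[-1]) if len(cols) > 1 else 1.0,
    )


def _pdm_precompute(cohort: pd.DataFrame, mediators: Sequence[str]):
    """Reduce the PDM objective to f(w) = (w'a)(w'b) / (w'Cw).

    With S = M_std w, the M|A,Z group coefficient is alpha_w = w'a (a stacks
    the per-chemical group coefficients), and by Frisch-Waugh the Y|S,A,Z
    score coefficient is beta_w = (w' Mr' W yr) / (w' Mr' W Mr w) where Mr,
    yr are weighted residuals against [const, A, Z].
    """
    cols = list(mediators)
    M = cohort[cols].to_numpy(float)
    center, sd = M.mean(axis=0), M.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        raise ValueError("zero-variance mediator in PDM")
    Ms = (M - center) / sd
    X0 = covariate_matrix(cohort).to_numpy(float)
    w = cohort["weight"].to_numpy(float)
    sw = np.sqrt(w)[:, None]
    y = cohort["y"].to_numpy(float)
    # weighted projections onto [const, A, Z]
    q, _ = np.linalg.qr(X0 * sw)
    Msw = Ms * sw
    ysw = y * sw[:, 0]
    Mr = Msw - q @ (q.T @ Msw)
    yr = ysw - q @ (q.T @ ysw)
    coef_a, *_ = np.linalg.lstsq(X0 * sw, Msw, rcond=None)
    a = coef_a[1]  # group row of the multivariate mediator fit
    b = Mr.T @ yr
    C = Mr.T @ Mr
    return pd.Series(center, index=cols), pd.Series(sd, index=cols), a, b, C


def _pdm_objective(w: np.ndarray, a: np.ndarray, b: np.ndarray, C: np.ndarray) -> float:
    """Mediated effect of the score: alpha_w * beta_w (scale-invariant in w)."""
    q = float(w @ C @ w)
    if q <= 0.0:
        return 0.0
    return float((w @ a) * (w @ b) / q)


def pdm_weights(
    cohort: pd.DataFrame,
    mediators: Sequence[str],
    seed: int = 0,
    n_restarts: int = 20,
) -> ScoreWeights:
    """First principal direction of mediation on the unit sphere.

    Maximizes |alpha_w * beta_w| by multi-start quasi-Newton optimization of
    the (scale-invariant) squared objective; deterministic under ``seed``.
    """
    cols = list(mediators)
    if len(cols) == 1:
        center = cohort[cols].mean()
        scale = cohort[cols].std(ddof=1)
        return ScoreWeights(
            weights=pd.Series([1.0], index=cols), method="pdm",
            center=center, scale=scale, objective=None,
        )
    center, scale, a, b, C = _pdm_precompute(cohort, cols)

    def neg_sq(v):
        return -_pdm_objective(v, a, b, C) ** 2

    rng = np.random.default_rng(seed)
    best_v, best_obj = None, np.inf
    starts = [a / np.linalg.norm(a), b / np.linalg.norm(b)]
    starts += [rng.standard_normal(len(cols)) for _ in range(n_restarts - 2)]
    trace = []
    for v0 in starts:
        res = optimize.minimize(neg_sq, v0, method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 500})
        trace.append(float(res.fun))
        if res.fun < best_obj and np.linalg.norm(res.x) > 0:
            best_obj, best_v = float(res.fun), res.x
    if best_v is None or not np.isfinite(best_obj):
        raise RuntimeError(f"PDM optimization failed; objective trace: {trace}")
    w = _orient(best_v / np.linalg.norm(best_v))
    return ScoreWeights(
        weights=pd.Series(w, index=cols), method="pdm",
        center=center, scale=scale,
        objective=abs(_pdm_objective(w, a, b, C)),
    )


def teq_score(conc_natural: pd.DataFrame, tef_table: Mapping[str, float]) -> pd.Series:
    """Potency-weighted exposure: sum of TEF_j x concentration_ij.

    Chemicals without a TEF are excluded from the sum.
    """
    if any(v < 0 for v in tef_table.values()):
        bad = {k: v for k, v in tef_table.items() if v < 0}
        raise ValueError(f"negative TEF weight(s): {bad}")
    cols = [c for c in conc_natural.columns if c in tef_table]
    if not cols:
        raise ValueError("no chemical in the panel has a TEF")
    w = np.array([tef_table[c] for c in cols])
    return pd.Series(conc_natural[cols].to_numpy(float) @ w, name="teq")


def teq_weights(tef_table: Mapping[str, float], chemicals: Sequence[str]) -> ScoreWeights:
    """TEF weights restricted to the available chemicals."""
    cols = [c for c in chemicals if c in tef_table]
    return ScoreWeights(
        weights=pd.Series({c: float(tef_table[c]) for c in cols}), method="teq"
    )


def load_tef_csv(path) -> dict[str, float]:
    """Read a TEF table from a two-column CSV (chemical, tef)."""
    df = pd.read_csv(path)
    missing = [c for c in ("chemical", "tef") if c not in df.columns]
    if missing:
        raise ValueError(f"TEF CSV lacks column(s): {missing}")
    return dict(zip(df["chemical"].astype(str), df["tef"].astype(float)))


def write_tef_csv(tef_table: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"chemical": list(tef_table), "tef": list(tef_table.values())}
    ).to_csv(path, index=False, float_format="%.8g")


def score_mediation(
    cohort: "pd.DataFrame | Sequence[pd.DataFrame]",
    weights: ScoreWeights,
    design: SurveyDesign,
) -> MediationResult:
    """Substitute the summary score as the sole mediator and run the
    survey-weighted single-mediator framework (Rubin-pooled when a sequence
    of completed cohorts is given)."""
    cohorts = [cohort] if isinstance(cohort, pd.DataFrame) else list(cohort)
    missing = [c for c in weights.subset if c not in cohorts[0].columns]
    if missing:
        raise ValueError(f"weights reference unavailable chemicals: {missing}")
    scored = []
    for c in cohorts:
        cc = c.copy()
        cc["score"] = weights.score(c)
        scored.append(cc)
    if len(scored) == 1:
        alpha = fit_mediator_model(scored[0], design, "score")
        beta = fit_outcome_model(scored[0], design, "score")
        result = indirect_effect(alpha, beta, "score")
    else:
        result = pooled_single_mediation(scored, design, "score")
    result.mediator = f"{weights.method}_score"
    return result


def subclass_pca_mediation(
    cohorts: "pd.DataFrame | Sequence[pd.DataFrame]",
    design: SurveyDesign,
    class_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """PCA-score mediation restricted to each chemical subclass.

    ``class_map`` maps subclass label -> chemical subset (e.g. all PCBs,
    non-ortho PCBs, non-dioxin-like PCBs, dioxins, furans). PCA weights are
    derived on the stacked completed data per subclass.
    """
    clist = [cohorts] if isinstance(cohorts, pd.DataFrame) else list(cohorts)
    rows = []
    for label, subset in class_map.items():
        subset = list(subset)
        if not subset:
            raise ValueError(f"subclass {label!r} is empty")
        stacked = pd.concat([c[subset] for c in clist], axis=0, ignore_index=True)
        w = pca_weights(stacked, subset)
        r = score_mediation(clist if len(clist) > 1 else clist[0], w, design)
        rows.append(
            {
                "model": label,
                "ide": r.indirect,
                "de": r.direct,
                "total": r.total,
                "pct_ide": r.percent,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "p_raw": r.p,
            }
        )
    return pd.DataFrame(rows)
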