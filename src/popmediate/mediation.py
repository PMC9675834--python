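"""Single-mediator product-of-coefficients mediation with Sobel inference.

For mediator j the three survey-weighted models are

    Y|A,Z:    Y = mu_0 + mu_a A + Z' mu_z + e          (total effect mu_a)
    M|A,Z:    M_j = alpha_0j + alpha_aj A + Z' alpha_zj + e
    Y|M,A,Z:  Y = beta_0j + beta_aj A + beta_mj M_j + Z' beta_zj + e

The indirect effect is alpha_aj * beta_mj, the direct effect beta_aj, and on
any one completed dataset the decomposition mu_a = beta_aj + alpha_aj*beta_mj
holds exactly (an algebraic identity of nested weighted LS fits sharing
weights and covariates). Sobel's delta-method standard error drives the Wald
test, with a Benjamini-Hochberg correction across mediators; estimates from
multiply imputed datasets are pooled by Rubin's rules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Z_COLUMNS
from .imputation import pool_rubin
from .survey import FitResult, SurveyDesign, fit_survey, wald_test

__all__ = [
    "MediationResult",
    "covariate_matrix",
    "fit_total_effect",
    "fit_mediator_model",
    "fit_outcome_model",
    "indirect_effect",
    "percent_mediated",
    "bh_adjust",
    "interaction_sensitivity",
    "pooled_single_mediation",
    "mediation_table",
]


@dataclass
class MediationResult:
    """Indirect/direct/total decomposition for one mediator (or score)."""

    mediator: str
    indirect: float
    indirect_se: float
    ci: tuple[float, float]
    p: float
    direct: float
    total: float
    percent: float
    p_adjusted: float | None = None

    @property
    def inconsistent(self) -> bool:
        """Percent mediated outside [0, 100] (inconsistent mediation)."""
        return not (0.0 <= self.percent <= 100.0)


def covariate_matrix(
    cohort: pd.DataFrame,
    extra: Sequence[str] = (),
    z_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Design matrix [const, group, *extra, Z...] in fixed column order."""
    z_columns = Z_COLUMNS if z_columns is None else list(z_columns)
    cols = {"const": np.ones(len(cohort)), "group": cohort["group"].to_numpy(float)}
    for c in extra:
        cols[c] = cohort[c].to_numpy(float)
    for c in z_columns:
        cols[c] = cohort[c].to_numpy(float)
    return pd.DataFrame(cols)


def fit_total_effect(cohort: pd.DataFrame, design: SurveyDesign) -> FitResult:
    """Survey-weighted Y|A,Z fit; ``group`` carries the total effect mu_a."""
    return fit_survey(
        cohort["y"].to_numpy(float), covariate_matrix(cohort), design, label="Y|A,Z"
    )


def fit_mediator_model(
    cohort: pd.DataFrame, design: SurveyDesign, mediator: str
) -> FitResult:
    """Survey-weighted M|A,Z fit; ``group`` carries alpha_aj."""
    if cohort["group"].nunique() < 2:
        raise ValueError("exposure group is constant: no contrast to estimate")
    return fit_survey(
        cohort[mediator].to_numpy(float),
        covariate_matrix(cohort),
        design,
        label=f"M|A,Z[{mediator}]",
    )


def fit_outcome_model(
    cohort: pd.DataFrame, design: SurveyDesign, mediator: str
) -> FitResult:
    """Survey-weighted Y|M,A,Z fit; ``group`` is beta_aj, mediator is beta_mj."""
    return fit_survey(
        cohort["y"].to_numpy(float),
        covariate_matrix(cohort, extra=[mediator]),
        design,
        label=f"Y|M,A,Z[{mediator}]",
    )


def _sobel(
    alpha: float, var_alpha: float, beta: float, var_beta: float, second_order: bool
) -> float:
    v = alpha**2 * var_beta + beta**2 * var_alpha
    if second_order:
        v += var_alpha * var_beta
    return math.sqrt(v)


def indirect_effect(
    alpha_fit: FitResult,
    beta_fit: FitResult,
    mediator: str,
    total_fit: FitResult | None = None,
    second_order: bool = False,
) -> MediationResult:
    """Product-of-coefficients indirect effect with Sobel SE, CI and p.

    The first-order Sobel variance alpha^2 Var(beta_m) + beta_m^2 Var(alpha)
    is the default; ``second_order`` adds the Var*Var term. The total effect
    is taken from ``total_fit`` when given, otherwise reconstructed from the
    exact decomposition direct + indirect.
    """
    alpha = alpha_fit.coef("group")
    var_alpha = alpha_fit.var("group")
    beta = beta_fit.coef(mediator)
    var_beta = beta_fit.var(mediator)
    direct = beta_fit.coef("group")
    ie = alpha * beta
    se = _sobel(alpha, var_alpha, beta, var_beta, second_order)
    if se == 0.0:
        if ie != 0.0:
            raise ValueError("zero Sobel standard error for a nonzero indirect effect")
        z, p = 0.0, 1.0
    else:
        z = ie / se
        p = 2.0 * stats.norm.sf(abs(z))
    total = total_fit.coef("group") if total_fit is not None else direct + ie
    return MediationResult(
        mediator=mediator,
        indirect=ie,
        indirect_se=se,
        ci=(ie - 1.959963984540054 * se, ie + 1.959963984540054 * se),
        p=float(p),
        direct=direct,
        total=total,
        percent=percent_mediated(ie, total),
    )


def percent_mediated(ie: float, total: float) -> float:
    """100 x indirect / total; values outside [0, 100] indicate inconsistent
    mediation and are returned as-is (callers may flag them)."""
    if total == 0.0:
        raise ValueError("percent mediated undefined: total effect is zero")
    return 100.0 * ie / total


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def interaction_sensitivity(
    cohort: pd.DataFrame, design: SurveyDesign, mediator: str
) -> tuple[float, float]:
    """Refit Y|M,A,Z with an added A x M_j term; Wald test of the interaction."""
    X = covariate_matrix(cohort, extra=[mediator])
    X["group_x_mediator"] = X["group"] * X[mediator]
    fit = fit_survey(
        cohort["y"].to_numpy(float), X, design, label=f"Y|M,A,Z+AxM[{mediator}]"
    )
    _, p = wald_test(fit, "group_x_mediator")
    return fit.coef("group_x_mediator"), p


def pooled_single_mediation(
    cohorts: Sequence[pd.DataFrame],
    design: SurveyDesign,
    mediator: str,
    second_order: bool = False,
) -> MediationResult:
    """Single-mediator mediation across m completed datasets, Rubin-pooled.

    Per imputation the indirect effect and its Sobel variance are computed;
    Rubin's rules give the pooled estimate, SE and reference df. Direct and
    total effects are pooled as means of the per-imputation points, and the
    percent mediated is computed from the pooled points.
    """
    ies, ses, directs, totals = [], [], [], []
    for c in cohorts:
        a = fit_mediator_model(c, design, mediator)
        b = fit_outcome_model(c, design, mediator)
        r = indirect_effect(a, b, mediator, second_order=second_order)
        ies.append(r.indirect)
        ses.append(r.indirect_se)
        directs.append(r.direct)
        totals.append(r.total)
    pooled = pool_rubin(np.array(ies), np.array(ses) ** 2)
    ie, se = pooled.estimate, pooled.se
    if se == 0.0:
        z, p = 0.0, 1.0
    elif np.isfinite(pooled.df):
        z = ie / se
        p = 2.0 * stats.t.sf(abs(z), pooled.df)
    else:
        z = ie / se
        p = 2.0 * stats.norm.sf(abs(z))
    direct = float(np.mean(directs))
    total = float(np.mean(totals))
    return MediationResult(
        mediator=mediator,
        indirect=ie,
        indirect_se=se,
        ci=(ie - 1.959963984540054 * se, ie + 1.959963984540054 * se),
        p=float(p),
        direct=direct,
        total=total,
        percent=percent_mediated(ie, total),
    )


def mediation_table(
    cohorts: Sequence[pd.DataFrame],
    design: SurveyDesign,
    mediators: Sequence[str],
) -> pd.DataFrame:
    """One row per mediator with BH-adjusted p-values across the set."""
    results = [pooled_single_mediation(cohorts, design, m) for m in mediators]
    adj = bh_adjust([r.p for r in results])
    rows = []
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        rows.append(
            {
                "model": r.mediator,
                "ide": r.indirect,
                "de": r.direct,
                "total": r.total,
                "pct_ide": r.percent,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "p_raw": r.p,
                "p_bh": r.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
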