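"""Synthetic NHANES-like cohort generator with known mediation ground truth.

Generates one row per participant: a binary exposure-group indicator A
(analogue of self-reported Black race), a log-scale outcome Y (log T/S
telomere ratio), the adjustment-covariate set (standardized age and age^2,
sex, five-level education, log cotinine, log lipids, white-cell count, five
differential percentages, survey-cycle indicator), 15 correlated log-scale
chemical concentrations, and stratum/PSU/weight design columns. The true
(pre-censoring) concentrations are kept in the cohort table; a companion
:class:`~popmediate.imputation.LodPanel` records natural-scale values,
below-LOD flags and the per-chemical per-cycle LODs.

The data-generating process is the linear mediation model

    M_i  = alpha_0 + A_i alpha_a + eps_i,      eps_i ~ MVN(0, Sigma_m)
    Y_i  = beta_0 + beta_a A_i + M_i' beta_m + Z_i' beta_z + e_i

so that the total effect decomposes exactly as
mu_a = beta_a + alpha_a' beta_m.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig, Z_COLUMNS
from .imputation import LodPanel

__all__ = [
    "EffectTruth",
    "generate_cohort",
    "empirical_correlations",
    "correlation_summary",
]


@dataclass(frozen=True)
class EffectTruth:
    """Ground-truth effects implied by a :class:`SimulationConfig`.

    ``true_indirect_per_mediator`` holds the probability limit of the
    *single-mediator* indirect-effect estimand for each chemical,
    alpha_aj * (Sigma_m beta_m)_j / (Sigma_m)_jj: when mediators are
    correlated, the mediator coefficient of the one-mediator outcome model
    absorbs the effects transmitted by the omitted, correlated chemicals.
    ``true_path_products`` keeps the raw per-path products alpha_aj*beta_mj,
    which sum (with the direct effect) to the total effect.
    """

    true_direct: float
    true_indirect_per_mediator: pd.Series
    true_path_products: pd.Series
    true_global_indirect: float
    true_total: float
    true_percent_mediated: float

    def to_flat(self) -> dict[str, float]:
        flat = {
            "true_direct": self.true_direct,
            "true_global_indirect": self.true_global_indirect,
            "true_total": self.true_total,
            "true_percent_mediated": self.true_percent_mediated,
        }
        for name, val in self.true_indirect_per_mediator.items():
            flat[f"true_indirect_{name}"] = float(val)
        return flat


def effect_truth(config: SimulationConfig) -> EffectTruth:
    alpha = np.asarray(config.mediator_group_shifts, dtype=float)
    beta = np.asarray(config.mediator_effects, dtype=float)
    cov = np.asarray(config.chemical_log_cov, dtype=float)
    global_ie = float(alpha @ beta)
    total = config.direct_effect + global_ie
    # single-mediator estimand: marginal mediator coefficient times alpha_aj
    marginal_beta = (cov @ beta) / np.diag(cov)
    single_ie = alpha * marginal_beta
    pct = 100.0 * global_ie / total if total != 0 else np.nan
    return EffectTruth(
        true_direct=float(config.direct_effect),
        true_indirect_per_mediator=pd.Series(single_ie, index=config.chemicals),
        true_path_products=pd.Series(alpha * beta, index=config.chemicals),
        true_global_indirect=global_ie,
        true_total=float(total),
        true_percent_mediated=float(pct),
    )


def _draw_covariates(rng: np.random.Generator, n: int, batch_share: float) -> pd.DataFrame:
    age = rng.normal(50.8, 19.3, n)
    age_std = (age - age.mean()) / age.std(ddof=0)
    sex = rng.binomial(1, 0.537, n)
    educ = rng.choice(
        np.arange(1, 6), size=n, p=np.array([81, 215, 324, 338, 293]) / 1251.0
    )
    log_cotinine = rng.normal(-0.55, 3.80, n)
    log_lipids = rng.normal(6.48, 0.22, n)
    wbc = np.clip(rng.normal(7.18, 2.15, n), 2.0, None)
    lymph = np.clip(rng.normal(29.78, 9.07, n), 2.0, 70.0)
    eos = np.clip(rng.normal(2.92, 2.44, n), 0.0, 20.0)
    baso = np.clip(rng.normal(0.67, 0.46, n), 0.0, 5.0)
    mono = np.clip(rng.normal(8.25, 2.39, n), 0.5, 25.0)
    # neutrophils close the differential up to a small measurement slack,
    # keeping the five percentages from being exactly collinear
    slack = np.clip(rng.normal(0.0, 0.6, n), -1.9, 1.9)
    neut = 100.0 - (lymph + eos + baso + mono) + slack
    batch = rng.binomial(1, batch_share, n)
    return pd.DataFrame(
        {
            "age_std": age_std,
            "age_std_sq": age_std**2,
            "sex": sex,
            "educ": educ,
            "log_cotinine": log_cotinine,
            "log_lipids": log_lipids,
            "wbc": wbc,
            "pct_lymph": lymph,
            "pct_neut": neut,
            "pct_eos": eos,
            "pct_baso": baso,
            "pct_mono": mono,
            "batch": batch,
        }
    )


def _education_dummies(educ: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({f"educ_{k}": (educ == k).astype(float) for k in range(2, 6)})


def _design_columns(
    rng: np.random.Generator, n: int, config: SimulationConfig, age_std: np.ndarray
) -> pd.DataFrame:
    cells = config.n_strata * config.psus_per_stratum
    # balanced random assignment guarantees >= 2 non-empty PSUs per stratum
    cell = rng.permutation(np.arange(n) % cells)
    stratum = cell // config.psus_per_stratum
    psu = cell % config.psus_per_stratum
    weight = rng.lognormal(0.0, config.weight_log_sd, n)
    if config.informative_design != 0.0:
        weight = weight * np.exp(config.informative_design * age_std)
    weight = weight * (config.population_size / weight.sum())
    return pd.DataFrame({"stratum": stratum, "psu": psu, "weight": weight})


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, LodPanel, EffectTruth]:
    """Simulate a cohort, its censoring panel, and the implied ground truth.

    The returned cohort carries the true (pre-censoring) log concentrations;
    the :class:`LodPanel` records natural-scale concentrations, below-LOD
    flags, and LODs set as per-batch empirical quantiles at the configured
    censoring targets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    p = config.n_chemicals

    group = rng.binomial(1, config.p_group, n)
    cov_df = _draw_covariates(rng, n, config.batch_share)

    chol = np.linalg.cholesky(np.asarray(config.chemical_log_cov, dtype=float))
    eps = rng.standard_normal((n, p)) @ chol.T
    log_m = (
        np.asarray(config.chemical_log_means, dtype=float)[None, :]
        + group[:, None] * np.asarray(config.mediator_group_shifts, dtype=float)[None, :]
        + eps
    )
    if config.confounding_strength != 0.0:
        log_m = log_m + config.confounding_strength * cov_df["age_std"].to_numpy()[:, None]

    z = pd.concat(
        [cov_df.drop(columns=["educ"]), _education_dummies(cov_df["educ"].to_numpy())],
        axis=1,
    )[Z_COLUMNS]
    beta_z = np.array([config.covariate_effects.get(c, 0.0) for c in Z_COLUMNS])
    y = (
        config.direct_effect * group
        + log_m @ np.asarray(config.mediator_effects, dtype=float)
        + z.to_numpy() @ beta_z
        + rng.normal(0.0, config.outcome_sd, n)
    )
    if config.interaction_effects is not None:
        y = y + (group[:, None] * log_m) @ np.asarray(
            config.interaction_effects, dtype=float
        )

    design = _design_columns(rng, n, config, cov_df["age_std"].to_numpy())

    cohort = pd.concat(
        [
            pd.DataFrame({"participant_id": np.arange(n), "group": group, "y": y}),
            z,
            cov_df[["educ"]],
            design,
            pd.DataFrame(log_m, columns=config.chemicals),
        ],
        axis=1,
    )

    # censoring panel: LODs as per-batch empirical quantiles of the
    # natural-scale concentrations at the configured censoring targets
    conc = pd.DataFrame(np.exp(log_m), columns=config.chemicals)
    batch = cov_df["batch"].astype(int)
    lod_rows = []
    below = pd.DataFrame(False, index=conc.index, columns=config.chemicals)
    lq = np.asarray(config.lod_quantiles, dtype=float)
    for b in range(config.n_batches):
        mask = (batch == b).to_numpy()
        for j, chem in enumerate(config.chemicals):
            q = lq[j, b]
            vals = conc.loc[mask, chem]
            lod = float(np.quantile(vals, q)) if q > 0 else float(vals.min()) * 0.5
            below.loc[mask, chem] = vals < lod
            lod_rows.append(
                {
                    "chemical": chem,
                    "batch": b,
                    "lod": lod,
                    "percent_below": 100.0 * float((vals < lod).mean()),
                }
            )
    panel = LodPanel(
        conc=conc,
        below_lod=below,
        lod=pd.DataFrame(lod_rows),
        batch=batch.rename("batch"),
    )
    return cohort, panel, effect_truth(config)


class ConstantColumnError(ValueError):
    """A column has zero variance, so its correlations are undefined."""


def empirical_correlations(data: "LodPanel | pd.DataFrame") -> pd.DataFrame:
    """Correlation matrix of log concentrations.

    Accepts a complete :class:`LodPanel` (pre-censoring truth or an imputed
    panel) — in which case concentrations are log-transformed first — or a
    DataFrame already on the log scale. A constant column raises
    :class:`ConstantColumnError` rather than propagating NaNs.
    """
    if isinstance(data, LodPanel):
        logs = np.log(data.conc)
    else:
        logs = pd.DataFrame(data)
    sd = logs.std(ddof=0)
    constant = sd.index[sd.to_numpy() == 0.0].tolist()
    if constant:
        raise ConstantColumnError(
            f"correlation undefined for constant column(s): {constant}"
        )
    corr = np.corrcoef(logs.to_numpy(), rowvar=False)
    return pd.DataFrame(corr, index=logs.columns, columns=logs.columns)


def correlation_summary(
    corr: pd.DataFrame, families: dict[str, str]
) -> pd.DataFrame:
    """Min/max off-diagonal correlation within and across chemical classes."""
    rows = []
    fams = sorted(set(families.values()))
    for i, fa in enumerate(fams):
        for fb in fams[i:]:
            a = [c for c in corr.index if families.get(c) == fa]
            b = [c for c in corr.index if families.get(c) == fb]
            vals = corr.loc[a, b].to_numpy().ravel()
            if fa == fb:
                block = corr.loc[a, b].to_numpy()
                vals = block[~np.eye(len(a), dtype=bool)].ravel()
            if len(vals):
                rows.append(
                    {
                        "class_a": fa,
                        "class_b": fb,
                        "min": float(vals.min()),
                        "max": float(vals.max()),
                    }
                )
    return pd.DataFrame(rows)
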