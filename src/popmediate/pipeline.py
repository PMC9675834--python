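"""Pipeline orchestration: simulate -> filter -> impute -> mediate -> report.

Runs every requested mediation estimator over a simulated or user-supplied
cohort and writes a results bundle: a mediation summary CSV (one row per
model: indirect effect, direct effect, percent mediated, CI, p, with
Benjamini-Hochberg columns for the single-mediator rows), a score-weight CSV
(chemical x method), a subclass sensitivity CSV, and a JSON manifest with all
seeds, the estimator design-awareness roster, and the simulation ground truth
when simulating. All randomness flows from one master seed through named
substreams, so reruns with an identical config are byte-identical.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemicals import SUBCLASS_SETS, TEF_TABLE
from .config import SimulationConfig, Z_COLUMNS
from .evalue import mediation_evalue
from .imputation import (
    LodPanel,
    chemical_filter,
    impute_below_lod,
    imputation_covariates,
)
from .mediation import mediation_table
from .mixture import (
    RidgeSpec,
    bootstrap_mediation,
    global_mediation,
    make_global_ie_estimator,
    select_ridge_lambda,
)
from .scores import (
    load_tef_csv,
    pca_weights,
    pdm_weights,
    score_mediation,
    subclass_pca_mediation,
    teq_weights,
    write_tef_csv,
)
from .survey import DesignError, SurveyDesign

log = logging.getLogger("popmediate")

ALL_ESTIMATORS = ("single", "ols", "ridge", "pca", "pdm", "teq", "subclass-pca")

#: which estimators honour the stratified-cluster weighted design in inference
DESIGN_AWARE = {
    "single": True,
    "ols": False,
    "ridge": False,
    "pca": True,
    "pdm": True,
    "teq": True,
    "subclass-pca": True,
}

MODEL_LABELS = {
    "ols": "Unpenalized Linear Regression",
    "ridge": "Ridge Regression",
    "pca": "PCA: All Toxicants",
    "pdm": "PDM",
    "teq": "TEQ",
}

#: required cohort CSV schema (besides the chemical columns)
REQUIRED_COHORT_COLUMNS = ["participant_id", "group", "y", *Z_COLUMNS]


def derive_lipids(total_cholesterol: float, triglycerides: float) -> float:
    """Total serum lipids (mg/dL) by the Phillips short formula:
    2.27 x total cholesterol + triglycerides + 62.3."""
    tc = np.asarray(total_cholesterol, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    if np.any(tc <= 0) or np.any(tg <= 0):
        raise ValueError("cholesterol and triglycerides must be positive")
    out = 2.27 * tc + tg + 62.3
    return float(out) if out.ndim == 0 else out


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    ``mode`` is "simulate" (default) or "csv"; in csv mode ``cohort_csv``
    (and optionally ``lod_csv``/``lod_meta_csv`` for censored panels) point
    at user-supplied tables with the documented column schema.
    """

    mode: str = "simulate"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort_csv: str | None = None
    lod_csv: str | None = None
    lod_meta_csv: str | None = None
    tef_csv: str | None = None
    estimators: tuple[str, ...] = ALL_ESTIMATORS
    m: int = 5
    n_boot: int = 200
    cv_folds: int = 5
    reselect_lambda: bool = False
    seed: int = 0
    out_dir: str = "popmediate_results"


def _substream_seeds(master: int) -> dict[str, int]:
    names = ("simulation", "imputation", "bootstrap", "cv", "pdm")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)
    }


def _load_cohort_csv(path: str, chemicals: list[str]) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS + chemicals if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required column(s): {missing}")
    known = set(REQUIRED_COHORT_COLUMNS + chemicals + ["stratum", "psu", "weight", "educ"])
    unknown = [c for c in cohort.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {unknown}")
    return cohort


def _mix_bootstrap(completed, estimator, B, seed):
    """Bootstrap within each completed dataset, pool replicate distributions."""
    dists = [
        bootstrap_mediation(c, estimator, B=B, seed=seed + i)
        for i, c in enumerate(completed)
    ]
    reps = np.concatenate([d.replicates for d in dists])
    from .mixture import BootstrapDistribution

    return BootstrapDistribution(
        replicates=reps, seed=seed, n_failed=sum(d.n_failed for d in dists)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured estimators and write the report bundle."""
    unknown = [e for e in config.estimators if e not in ALL_ESTIMATORS]
    if unknown:
        raise ValueError(
            f"unknown estimator(s) {unknown}; choose from {ALL_ESTIMATORS}"
        )
    seeds = _substream_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    panel = None
    if config.mode == "simulate":
        sim = config.simulation
        sim.seed = seeds["simulation"]
        from .simulate import generate_cohort

        cohort, panel, truth = generate_cohort(sim)
        chemicals = list(sim.chemicals)
    elif config.mode == "csv":
        from .chemicals import CHEMICAL_NAMES

        chemicals = list(CHEMICAL_NAMES)
        cohort = _load_cohort_csv(config.cohort_csv, chemicals)
        if config.lod_csv is not None:
            panel = LodPanel.read_csv(config.lod_csv, config.lod_meta_csv)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # design: required by the survey-aware estimators, optional for ols/ridge
    try:
        design = SurveyDesign.from_cohort(cohort)
        design.validate()
    except DesignError as err:
        design = None
        needs_design = [e for e in config.estimators if DESIGN_AWARE[e]]
        if needs_design:
            raise DesignError(
                f"estimators {needs_design} require stratum/psu/weight columns: {err}"
            ) from err
        log.warning("no valid survey design (%s); ols/ridge proceed unweighted", err)
        cohort = cohort.copy()
        cohort["weight"] = 1.0

    # chemical filter (>50% below LOD in any batch excludes the chemical)
    filter_props = None
    if panel is not None:
        retained, filter_props = chemical_filter(panel, threshold=0.5)
        dropped = [c for c in chemicals if c not in retained]
        if dropped:
            log.info("excluded by the >50%%-below-LOD rule: %s", dropped)
        chemicals = retained
        panel = LodPanel(
            conc=panel.conc[retained],
            below_lod=panel.below_lod[retained],
            lod=panel.lod[panel.lod["chemical"].isin(retained)],
            batch=panel.batch,
        )

    # multiple imputation of non-detects (m copies of the completed cohort)
    if panel is not None and panel.below_lod.to_numpy().any():
        imputed = impute_below_lod(
            panel, imputation_covariates(cohort), m=config.m, seed=seeds["imputation"]
        )
        completed = imputed.completed_cohorts(cohort)
    else:
        completed = [cohort]

    rows: list[dict] = []
    weight_cols: dict[str, pd.Series] = {}
    subclass_df = None
    evalue_row = None
    stacked = pd.concat(completed, axis=0, ignore_index=True)

    if "single" in config.estimators:
        tab = mediation_table(completed, design, chemicals)
        for _, r in tab.iterrows():
            rows.append({**r.to_dict(), "estimator": "single", "design_aware": True})

    ridge_spec = None
    for name in ("ols", "ridge"):
        if name not in config.estimators:
            continue
        spec = None
        if name == "ridge":
            lam = float(
                np.mean(
                    [
                        select_ridge_lambda(
                            c, chemicals, RidgeSpec(cv_folds=config.cv_folds,
                                                    cv_seed=seeds["cv"])
                        )
                        for c in completed
                    ]
                )
            )
            spec = RidgeSpec(lam=lam, cv_folds=config.cv_folds, cv_seed=seeds["cv"])
            ridge_spec = spec
        points = [global_mediation(c, chemicals, spec) for c in completed]
        est = make_global_ie_estimator(
            chemicals, spec, reselect_lambda=config.reselect_lambda
        )
        boot = _mix_bootstrap(completed, est, config.n_boot, seeds["bootstrap"])
        ie = float(np.mean([p["indirect"] for p in points]))
        de = float(np.mean([p["direct"] for p in points]))
        total = ie + de
        lo, hi = boot.ci()
        rows.append(
            {
                "model": MODEL_LABELS[name],
                "ide": ie,
                "de": de,
                "total": total,
                "pct_ide": 100.0 * ie / total,
                "ci_low": lo,
                "ci_high": hi,
                "p_raw": boot.p,
                "p_bh": np.nan,
                "estimator": name,
                "design_aware": False,
            }
        )

    score_specs = []
    if "pca" in config.estimators:
        w = pca_weights(stacked[chemicals])
        score_specs.append(("pca", w))
    if "pdm" in config.estimators:
        w = pdm_weights(stacked, chemicals, seed=seeds["pdm"])
        score_specs.append(("pdm", w))
    if "teq" in config.estimators:
        tef = load_tef_csv(config.tef_csv) if config.tef_csv else TEF_TABLE
        score_specs.append(("teq", teq_weights(tef, chemicals)))
        write_tef_csv(tef, out / "tef_table.csv")
    for name, w in score_specs:
        weight_cols[name] = w.weights.reindex(chemicals)
        res = score_mediation(completed if len(completed) > 1 else completed[0], w, design)
        rows.append(
            {
                "model": MODEL_LABELS[name],
                "ide": res.indirect,
                "de": res.direct,
                "total": res.total,
                "pct_ide": res.percent,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
                "p_raw": res.p,
                "p_bh": np.nan,
                "estimator": name,
                "design_aware": True,
            }
        )
        if name == "pca":
            sd_y = float(cohort["y"].std(ddof=1))
            ev = mediation_evalue(res.indirect, res.indirect_se, sd_y)
            evalue_row = {
                "model": MODEL_LABELS["pca"],
                "rr": ev.rr,
                "evalue_point": ev.evalue_point,
                "evalue_ci": ev.evalue_ci,
            }

    if "subclass-pca" in config.estimators:
        class_map = {
            k: [c for c in v if c in chemicals] for k, v in SUBCLASS_SETS.items()
        }
        subclass_df = subclass_pca_mediation(
            completed if len(completed) > 1 else completed[0], design, class_map
        )
        subclass_df["design_aware"] = True

    results = pd.DataFrame(rows)
    results_path = out / "mediation_results.csv"
    results.to_csv(results_path, index=False, float_format="%.8g")

    weights_path = None
    if weight_cols:
        wdf = pd.DataFrame(weight_cols)
        wdf.insert(0, "chemical", wdf.index)
        weights_path = out / "score_weights.csv"
        wdf.to_csv(weights_path, index=False, float_format="%.8g")

    subclass_path = None
    if subclass_df is not None:
        subclass_path = out / "subclass_results.csv"
        subclass_df.to_csv(subclass_path, index=False, float_format="%.8g")

    manifest = {
        "version": __version__,
        "mode": config.mode,
        "master_seed": config.seed,
        "substream_seeds": seeds,
        "estimators": list(config.estimators),
        "design_aware": {e: DESIGN_AWARE[e] for e in config.estimators},
        "m": config.m,
        "n_boot": config.n_boot,
        "n_participants": int(len(cohort)),
        "chemicals_analysed": chemicals,
        "ridge_lambda": None if ridge_spec is None else ridge_spec.lam,
        "evalue": evalue_row,
    }
    if truth is not None:
        manifest["effect_truth"] = truth.to_flat()
        manifest["simulation_config"] = config.simulation.to_dict()
    if filter_props is not None:
        manifest["pct_below_lod"] = {
            c: filter_props.loc[c].to_dict() for c in filter_props.index
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "results": results,
        "subclass": subclass_df,
        "manifest": manifest,
        "paths": {
            "results": results_path,
            "weights": weights_path,
            "subclass": subclass_path,
            "manifest": manifest_path,
        },
    }
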