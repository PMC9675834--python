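import numpy as np
import pandas as pd
import pytest

from popmediate import SimulationConfig, generate_cohort
from popmediate.chemicals import CHEMICAL_NAMES
from popmediate.imputation import (
    LodPanel,
    chemical_filter,
    fit_censored_regression,
    imputation_covariates,
    imputation_quality,
    impute_below_lod,
    pool_rubin,
    rank_by_censoring,
)
from popmediate.mediation import pooled_single_mediation
from popmediate.survey import SurveyDesign


def _panel_from_props(props: dict[str, tuple[float, float]], n=200, seed=0):
    """Panel with given below-LOD proportions per chemical per batch."""
    rng = np.random.default_rng(seed)
    chems = list(props)
    batch = pd.Series(np.repeat([0, 1], n // 2), name="batch")
    conc = pd.DataFrame(
        {c: np.exp(rng.normal(size=n)) for c in chems}
    )
    below = pd.DataFrame(False, index=conc.index, columns=chems)
    rows = []
    for c in chems:
        for b in (0, 1):
            mask = (batch == b).to_numpy()
            q = props[c][b]
            lod = float(np.quantile(conc.loc[mask, c], q)) if q > 0 else 1e-9
            below.loc[mask, c] = conc.loc[mask, c] < lod
            rows.append({"chemical": c, "batch": b, "lod": lod,
                         "percent_below": 100 * q})
    return LodPanel(conc=conc, below_lod=below, lod=pd.DataFrame(rows), batch=batch)


class TestChemicalFilter:
    def test_excluded_when_over_half_in_one_batch(self):
        panel = _panel_from_props({"a": (0.60, 0.10), "b": (0.10, 0.10)})
        retained, props = chemical_filter(panel)
        assert retained == ["b"]
        assert props.loc["a", 0] == pytest.approx(0.60, abs=0.01)

    def test_exactly_half_retained(self):
        panel = _panel_from_props({"a": (0.50, 0.50)})
        retained, _ = chemical_filter(panel)
        assert retained == ["a"]  # exclusion requires strictly more than 50%

    def test_default_panel_keeps_all_fifteen(self, censored_cohort):
        _, _, panel, _ = censored_cohort
        retained, _ = chemical_filter(panel)
        assert retained == CHEMICAL_NAMES
        assert len(retained) == 15

    def test_bad_threshold(self, censored_cohort):
        _, _, panel, _ = censored_cohort
        with pytest.raises(ValueError):
            chemical_filter(panel, threshold=0.0)


class TestRankByCensoring:
    def test_orders_ascending(self):
        panel = _panel_from_props({"a": (0.30, 0.0), "b": (0.10, 0.0), "c": (0.20, 0.0)})
        assert rank_by_censoring(panel, 0) == ["b", "c", "a"]

    def test_reference_batch_percents_order_pcb153_before_pcb74(self, censored_cohort):
        # 16.9% (PCB 153) precedes 30.5% (PCB 74) in the first cycle
        _, _, panel, _ = censored_cohort
        order = rank_by_censoring(panel, 0)
        assert order.index("pcb153") < order.index("pcb74")

    def test_ties_keep_input_order(self):
        panel = _panel_from_props({"a": (0.25, 0.0), "b": (0.25, 0.0)}, n=400)
        # force exactly equal realized proportions
        panel.below_lod["a"] = panel.below_lod["b"].to_numpy()
        assert rank_by_censoring(panel, 0) == ["a", "b"]

    def test_missing_batch(self, censored_cohort):
        _, _, panel, _ = censored_cohort
        with pytest.raises(KeyError):
            rank_by_censoring(panel, reference_batch=9)


class TestCensoredRegression:
    def test_zero_censoring_equals_ols(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        y = X @ [0.5, 1.5] + rng.normal(size=300)
        fit = fit_censored_regression(
            y, X, np.zeros(300, bool), np.full(300, -np.inf)
        )
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(fit.coef.to_numpy() - ols).max() < 1e-8

    def test_intercept_only_recovery_under_censoring(self):
        # true mean 0, sd 1, 30% censored at the 0.3 quantile, n = 2000
        means, sds = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=2000)
            cut = np.quantile(y, 0.3)
            cen = y < cut
            fit = fit_censored_regression(
                y, np.ones((2000, 1)), cen, np.full(2000, cut)
            )
            means.append(fit.coef.iloc[0])
            sds.append(fit.sigma)
        assert np.mean(means) == pytest.approx(0.0, abs=0.05)
        assert np.mean(sds) == pytest.approx(1.0, abs=0.05)

    def test_all_censored_errors(self):
        with pytest.raises(ValueError, match="censored"):
            fit_censored_regression(
                np.zeros(10), np.ones((10, 1)), np.ones(10, bool), np.zeros(10)
            )

    def test_rank_deficient_errors_with_names(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"const": np.ones(50), "x": rng.normal(size=50)})
        X["x_dup"] = X["x"]
        with pytest.raises(ValueError, match="x"):
            fit_censored_regression(
                X.to_numpy() @ [1, 2, 0] + rng.normal(size=50),
                X,
                np.zeros(50, bool),
                np.full(50, -np.inf),
            )

    def test_standard_errors_available(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"const": np.ones(500), "x": rng.normal(size=500)})
        y = X.to_numpy() @ [0.0, 1.0] + rng.normal(size=500)
        cen = y < -0.5
        fit = fit_censored_regression(y, X, cen, np.full(500, -0.5))
        cov = fit.cov()
        assert cov.loc["x", "x"] > 0
        assert fit.n_censored == int(cen.sum())


class TestImputeBelowLod:
    def test_no_censoring_returns_identical_copies(self, complete_cohort):
        _, cohort, panel, _ = complete_cohort
        imputed = impute_below_lod(
            panel, imputation_covariates(cohort), m=3, seed=1
        )
        logs = np.log(panel.conc.to_numpy())
        for p in imputed.panels:
            assert np.allclose(p.to_numpy(), logs)

    def test_observed_cells_never_altered_and_bounds_respected(self, censored_cohort):
        _, cohort, panel, _ = censored_cohort
        imputed = impute_below_lod(
            panel, imputation_covariates(cohort), m=2, seed=2
        )
        logs = np.log(panel.conc.to_numpy())
        below = panel.below_lod.to_numpy()
        bounds = np.zeros_like(logs)
        for b in panel.batches:
            mask = (panel.batch == b).to_numpy()
            for j, chem in enumerate(panel.chemicals):
                bounds[mask, j] = np.log(panel.lod_value(chem, b))
        for p in imputed.panels:
            v = p.to_numpy()
            assert np.array_equal(v[~below], logs[~below])
            assert (v[below] < bounds[below]).all()

    def test_bivariate_recovery(self):
        # two log-normal chemicals, ~25% censoring, n = 2000: pooled means
        # and correlation recovered within 0.05
        rng = np.random.default_rng(3)
        n = 2000
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        logs = rng.multivariate_normal([1.0, 2.0], cov, size=n)
        conc = pd.DataFrame(np.exp(logs), columns=["a", "b"])
        batch = pd.Series(np.zeros(n, int), name="batch")
        below = pd.DataFrame(False, index=conc.index, columns=["a", "b"])
        rows = []
        for c in ["a", "b"]:
            lod = float(np.quantile(conc[c], 0.25))
            below[c] = conc[c] < lod
            rows.append({"chemical": c, "batch": 0, "lod": lod, "percent_below": 25.0})
        panel = LodPanel(conc, below, pd.DataFrame(rows), batch)
        covars = pd.DataFrame({"z": rng.normal(size=n)})
        imputed = impute_below_lod(panel, covars, m=5, seed=4)
        pooled = np.mean([p.to_numpy() for p in imputed.panels], axis=0)
        assert pooled[:, 0].mean() == pytest.approx(1.0, abs=0.05)
        assert pooled[:, 1].mean() == pytest.approx(2.0, abs=0.05)
        assert np.corrcoef(pooled.T)[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_quality_diagnostic_flags_degenerate_draws(self, censored_cohort):
        _, cohort, panel, _ = censored_cohort
        imputed = impute_below_lod(
            panel, imputation_covariates(cohort), m=1, seed=5
        )
        clean = imputation_quality(imputed)
        assert not clean["flagged"].any()
        # shift one chemical's imputed draws far into the tail
        for params in imputed.cell_params:
            df = params[("pcb153", 0)]
            df["value"] = df["mu"] - 4.0 * df["sigma"]
        degraded = imputation_quality(imputed)
        bad = degraded[(degraded["chemical"] == "pcb153") & (degraded["batch"] == 0)]
        assert bad["flagged"].all()

    def test_low_censoring_matches_complete_data_estimates(self):
        # with 1% censoring the pooled mediation estimate is within 0.005 of
        # the complete-data estimate
        cfg = SimulationConfig(
            n_participants=2000,
            seed=21,
            lod_quantiles=np.full((15, 2), 0.01),
        )
        cohort, panel, _ = generate_cohort(cfg)
        design = SurveyDesign.from_cohort(cohort)
        complete = pooled_single_mediation([cohort], design, "pcb153")
        imputed = impute_below_lod(
            panel, imputation_covariates(cohort), m=3, seed=22
        )
        pooled = pooled_single_mediation(
            imputed.completed_cohorts(cohort), design, "pcb153"
        )
        assert pooled.indirect == pytest.approx(complete.indirect, abs=0.005)


class TestPoolRubin:
    def test_single_imputation_is_within_variance(self):
        pooled = pool_rubin([1.5], [0.09])
        assert pooled.estimate == 1.5
        assert pooled.se == pytest.approx(0.3)

    def test_identical_estimates_zero_between(self):
        pooled = pool_rubin(np.full(10, 2.0), np.full(10, 0.04))
        assert pooled.between == 0.0
        assert pooled.se == pytest.approx(0.2)

    def test_hand_computed_example(self):
        # estimates (1.0, 1.2), variances (0.04, 0.04):
        # total = 0.04 + 1.5 x 0.02 = 0.07
        pooled = pool_rubin([1.0, 1.2], [0.04, 0.04])
        assert pooled.estimate == pytest.approx(1.1)
        assert pooled.variance == pytest.approx(0.07)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0, 2.0], [0.1])

    def test_barnard_rubin_df_not_larger_than_classic(self):
        classic = pool_rubin([1.0, 1.1, 1.3], [0.05, 0.05, 0.05])
        small = pool_rubin([1.0, 1.1, 1.3], [0.05, 0.05, 0.05], df_com=50)
        assert small.df < classic.df
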