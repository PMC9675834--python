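import numpy as np
import pandas as pd
import pytest

from popmediate import SimulationConfig, generate_cohort
from popmediate.chemicals import SUBCLASS_SETS, TEF_TABLE, TEF_TABLE_WHO2005
from popmediate.mediation import (
    fit_mediator_model,
    fit_outcome_model,
    fit_total_effect,
    indirect_effect,
)
from popmediate.reference import PCA_ALL_LOADINGS
from popmediate.scores import (
    ScoreWeights,
    _pdm_objective,
    _pdm_precompute,
    pca_weights,
    pdm_weights,
    score_mediation,
    subclass_pca_mediation,
    teq_score,
)
from popmediate.survey import SurveyDesign

from _oracles import pdm_2d_maximum, power_iteration


class TestPcaWeights:
    def test_two_perfectly_correlated_chemicals(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        logs = pd.DataFrame({"a": x, "b": 3.0 * x + 1.0})
        w = pca_weights(logs)
        assert np.allclose(w.weights.to_numpy(), [1 / np.sqrt(2)] * 2, atol=1e-10)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(600, 1))
        logs = pd.DataFrame(
            base + 0.5 * rng.normal(size=(600, 4)), columns=list("abcd")
        )
        w = pca_weights(logs)
        oracle = power_iteration(np.corrcoef(logs.to_numpy(), rowvar=False))
        assert np.abs(w.weights.to_numpy() - oracle).max() < 1e-6

    def test_unit_norm_and_positive_orientation(self, complete_cohort):
        cfg, cohort, _, _ = complete_cohort
        w = pca_weights(cohort[cfg.chemicals])
        assert np.linalg.norm(w.weights) == pytest.approx(1.0, abs=1e-12)
        assert w.weights.sum() > 0

    def test_zero_variance_errors(self):
        logs = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.raises(ValueError, match="zero-variance"):
            pca_weights(logs)

    def test_published_all_toxicant_loadings_have_unit_norm(self):
        norm2 = sum(v**2 for v in PCA_ALL_LOADINGS.values())
        assert norm2 == pytest.approx(1.0, abs=1e-3)


class TestPdmWeights:
    def test_single_chemical_weight_is_one(self, complete_cohort):
        _, cohort, _, _ = complete_cohort
        w = pdm_weights(cohort, ["pcb153"], seed=0)
        assert w.weights.tolist() == [1.0]

    def test_objective_dominates_pca(self, complete_cohort):
        cfg, cohort, _, _ = complete_cohort
        _, _, a, b, C = _pdm_precompute(cohort, cfg.chemicals)
        w_pdm = pdm_weights(cohort, cfg.chemicals, seed=1)
        w_pca = pca_weights(cohort[cfg.chemicals])
        obj_pdm = abs(_pdm_objective(w_pdm.weights.to_numpy(), a, b, C))
        obj_pca = abs(_pdm_objective(w_pca.weights.to_numpy(), a, b, C))
        assert obj_pdm >= obj_pca - 1e-12

    def test_matches_two_dimensional_closed_form(self, complete_cohort):
        cfg, cohort, _, _ = complete_cohort
        _, _, a, b, C = _pdm_precompute(cohort, cfg.chemicals)
        w = pdm_weights(cohort, cfg.chemicals, seed=2)
        found = abs(_pdm_objective(w.weights.to_numpy(), a, b, C))
        oracle = pdm_2d_maximum(a, b, C)
        assert found == pytest.approx(oracle, rel=1e-5)

    def test_recovers_concentrated_signal(self):
        # mediation flows only through the first chemical; all others are
        # pure noise (no group shift, no outcome path, independent)
        beta = np.zeros(15)
        beta[0] = 0.05
        alpha = np.zeros(15)
        alpha[0] = 0.5
        cfg = SimulationConfig(
            n_participants=5000,
            seed=3,
            mediator_effects=beta,
            mediator_group_shifts=alpha,
            chemical_log_cov=np.eye(15) * 0.36,
        )
        cohort, _, _ = generate_cohort(cfg)
        w = pdm_weights(cohort, cfg.chemicals, seed=3)
        assert abs(w.weights.iloc[0]) > 0.9

    def test_deterministic_under_seed(self, complete_cohort):
        cfg, cohort, _, _ = complete_cohort
        w1 = pdm_weights(cohort, cfg.chemicals, seed=9)
        w2 = pdm_weights(cohort, cfg.chemicals, seed=9)
        assert np.array_equal(w1.weights.to_numpy(), w2.weights.to_numpy())


class TestTeqScore:
    def test_unit_concentrations_sum_the_tefs(self):
        conc = pd.DataFrame({c: [1.0] for c in TEF_TABLE})
        s = teq_score(conc, TEF_TABLE)
        assert s.iloc[0] == pytest.approx(0.6803, abs=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        conc = pd.DataFrame({c: rng.lognormal(size=20) for c in TEF_TABLE})
        s1 = teq_score(conc, TEF_TABLE)
        s2 = teq_score(2.0 * conc, TEF_TABLE)
        assert np.allclose(s2, 2.0 * s1)

    def test_chemicals_without_tef_excluded(self):
        conc = pd.DataFrame({"pcb126": [1.0], "pcb153": [100.0]})
        s = teq_score(conc, TEF_TABLE)  # pcb153 carries no TEF
        assert s.iloc[0] == pytest.approx(0.1)

    def test_negative_tef_errors(self):
        with pytest.raises(ValueError, match="negative"):
            teq_score(pd.DataFrame({"a": [1.0]}), {"a": -0.1})

    def test_zero_scores_offset_before_log(self):
        w = ScoreWeights(
            weights=pd.Series({"pcb126": 0.1, "pcb169": 0.03}), method="teq"
        )
        cohort = pd.DataFrame(
            {"pcb126": [-np.inf, 0.0], "pcb169": [-np.inf, 1.0]}
        )  # log-scale -inf -> natural-scale zero
        with pytest.warns(UserWarning, match="offset"):
            s = w.score(cohort)
        assert np.isfinite(s).all()

    def test_who2005_differs_only_for_pcb118(self):
        assert TEF_TABLE["pcb118"] == 0.030
        assert TEF_TABLE_WHO2005["pcb118"] == 0.00003
        for c in TEF_TABLE:
            if c != "pcb118":
                assert TEF_TABLE[c] == TEF_TABLE_WHO2005[c]


class TestScoreMediation:
    def test_indicator_weights_reduce_to_single_mediator(
        self, complete_cohort, design
    ):
        cfg, cohort, _, _ = complete_cohort
        w = ScoreWeights(
            weights=pd.Series({"pcb153": 1.0}),
            method="pca",
            center=pd.Series({"pcb153": 0.0}),
            scale=pd.Series({"pcb153": 1.0}),
        )
        r_score = score_mediation(cohort, w, design)
        a = fit_mediator_model(cohort, design, "pcb153")
        b = fit_outcome_model(cohort, design, "pcb153")
        r_single = indirect_effect(a, b, "pcb153")
        assert r_score.indirect == pytest.approx(r_single.indirect, abs=1e-10)
        assert r_score.direct == pytest.approx(r_single.direct, abs=1e-10)

    def test_scale_invariance_of_indirect_effect(self, complete_cohort, design):
        cfg, cohort, _, _ = complete_cohort
        w = pca_weights(cohort[cfg.chemicals])
        r1 = score_mediation(cohort, w, design)
        w3 = ScoreWeights(
            weights=3.0 * w.weights, method="pca", center=w.center, scale=w.scale
        )
        r3 = score_mediation(cohort, w3, design)
        assert r3.indirect == pytest.approx(r1.indirect, abs=1e-8)

    def test_decomposition_identity(self, complete_cohort, design):
        cfg, cohort, _, _ = complete_cohort
        total = fit_total_effect(cohort, design).coef("group")
        for maker in (lambda: pca_weights(cohort[cfg.chemicals]),
                      lambda: pdm_weights(cohort, cfg.chemicals, seed=5)):
            r = score_mediation(cohort, maker(), design)
            assert r.direct + r.indirect == pytest.approx(total, abs=1e-8)

    def test_pca_score_recovers_global_ie(self):
        # the default signal lies along the dominant (all-positive) PC, so
        # the PCA-score IE tracks the true global IE
        cfg = SimulationConfig(n_participants=5000, seed=6)
        cohort, _, truth = generate_cohort(cfg)
        design = SurveyDesign.from_cohort(cohort)
        w = pca_weights(cohort[cfg.chemicals])
        r = score_mediation(cohort, w, design)
        assert r.indirect == pytest.approx(truth.true_global_indirect, abs=0.005)

    def test_missing_chemicals_error(self, complete_cohort, design):
        _, cohort, _, _ = complete_cohort
        w = ScoreWeights(weights=pd.Series({"nope": 1.0}), method="teq")
        with pytest.raises(ValueError, match="unavailable"):
            score_mediation(cohort, w, design)


class TestSubclassPca:
    def test_single_chemical_subclass_equals_single_mediator(
        self, complete_cohort, design
    ):
        _, cohort, _, _ = complete_cohort
        tab = subclass_pca_mediation(cohort, design, {"only": ["pcb187"]})
        a = fit_mediator_model(cohort, design, "pcb187")
        b = fit_outcome_model(cohort, design, "pcb187")
        r = indirect_effect(a, b, "pcb187")
        assert tab["ide"].iloc[0] == pytest.approx(r.indirect, abs=1e-10)

    def test_two_chemical_subclass_weights_are_equal_magnitude(
        self, complete_cohort, design
    ):
        # the non-ortho subclass has two chemicals: loadings +-1/sqrt(2)
        cfg, cohort, _, _ = complete_cohort
        subset = SUBCLASS_SETS["pca_non_ortho"]
        w = pca_weights(cohort[subset], subset)
        assert np.allclose(np.abs(w.weights.to_numpy()), 1 / np.sqrt(2), atol=1e-12)

    def test_empty_subclass_errors(self, complete_cohort, design):
        _, cohort, _, _ = complete_cohort
        with pytest.raises(ValueError, match="empty"):
            subclass_pca_mediation(cohort, design, {"none": []})

    def test_signal_in_pcb_block_found_only_there(self):
        # outcome signal on PCBs only, blocks independent: the PCB-subclass
        # score mediates, the dioxin/furan scores do not
        cov = np.eye(15) * 0.36
        cov[:9, :9] = 0.36 * (0.3 + 0.7 * np.eye(9))
        cov[9:, 9:] = 0.36 * (0.3 + 0.7 * np.eye(6))
        beta = np.zeros(15)
        beta[:9] = 0.008
        hits_pcb, hits_null = 0, 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_participants=2000, seed=seed,
                chemical_log_cov=cov, mediator_effects=beta,
            )
            cohort, _, _ = generate_cohort(cfg)
            design = SurveyDesign.from_cohort(cohort)
            tab = subclass_pca_mediation(
                cohort, design,
                {k: SUBCLASS_SETS[k] for k in ("pca_all_pcbs", "pca_dioxins")},
            ).set_index("model")
            hits_pcb += tab.loc["pca_all_pcbs", "p_raw"] < 0.05
            hits_null += tab.loc["pca_dioxins", "p_raw"] >= 0.05
        assert hits_pcb >= 8
        assert hits_null >= 8


class TestTefCsvRoundTrip:
    def test_write_then_load(self, tmp_path):
        from popmediate.scores import load_tef_csv, write_tef_csv

        path = tmp_path / "tef.csv"
        write_tef_csv(TEF_TABLE, path)
        assert load_tef_csv(path) == TEF_TABLE

    def test_missing_columns_error(self, tmp_path):
        from popmediate.scores import load_tef_csv

        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="chemical"):
            load_tef_csv(path)
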