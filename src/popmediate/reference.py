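"""Published NHANES 1999-2002 reference estimates shipped as constants.

These are the headline numbers of the original analysis of Black/White
differences in leukocyte telomere length mediated by POP exposure. They are
NOT recomputable from public desk-scale data (the underlying telomere/POP
merge is restricted), so they serve two purposes only:

* internal-arithmetic consistency checks (indirect + direct = total effect,
  unit-norm PCA loadings, potency-weight sums, sample-count bookkeeping);
* calibration targets for the synthetic-cohort defaults, so simulated
  effect magnitudes resemble the real analysis.

Nothing in the estimation code reads this module.
"""
from __future__ import annotations

#: analytic sample sizes by self-reported race
SAMPLE_SIZES = {"white": 930, "black": 321}

#: survey-weighted total effect of race on log LTL (estimate, CI, p)
TOTAL_EFFECT = 0.054
TOTAL_EFFECT_CI = (0.009, 0.099)
TOTAL_EFFECT_P = 0.018

#: chemicals considered for imputation and the post-imputation exclusions
N_CONSIDERED_CHEMICALS = 17
EXCLUDED_POST_IMPUTATION = ("pcb156", "pcb99")

#: indirect effect, direct effect, percent mediated, CI, p per mediation model
#: (single-mediator rows carry Benjamini-Hochberg adjusted p-values)
MEDIATION_TABLE = {
    "pcb74": (0.006, 0.048, 10.7, (-0.001, 0.012), 0.148),
    "pcb118": (0.015, 0.039, 28.6, (0.005, 0.026), 0.011),
    "pcb126": (0.008, 0.046, 21.7, (0.001, 0.015), 0.070),
    "pcb138": (0.018, 0.036, 34.0, (0.008, 0.029), 0.003),
    "pcb153": (0.019, 0.035, 34.5, (0.009, 0.029), 0.002),
    "pcb169": (0.001, 0.053, 2.4, (-0.004, 0.007), 0.671),
    "pcb170": (0.011, 0.043, 20.5, (0.003, 0.019), 0.019),
    "pcb180": (0.010, 0.044, 18.4, (0.002, 0.018), 0.025),
    "pcb187": (0.024, 0.031, 43.4, (0.012, 0.035), 0.002),
    "d03": (0.001, 0.053, 2.3, (-0.002, 0.005), 0.540),
    "d05": (0.004, 0.050, 7.9, (-0.002, 0.011), 0.269),
    "d07": (0.004, 0.050, 7.0, (-0.002, 0.010), 0.283),
    "f03": (-0.001, 0.056, -2.5, (-0.008, 0.005), 0.671),
    "f04": (0.005, 0.049, 9.3, (-0.002, 0.012), 0.260),
    "f08": (0.003, 0.052, 5.0, (-0.004, 0.009), 0.492),
    "unpenalized": (0.011, 0.040, 20.9, (-0.004, 0.025), 0.136),
    "ridge": (0.013, 0.037, 26.0, (0.001, 0.023), 0.034),
    "pca_all": (0.019, 0.035, 34.8, (0.009, 0.029), 0.001),
    "teq": (0.016, 0.039, 28.8, (0.005, 0.026), 0.003),
    "pdm": (0.000, 0.054, 0.6, (-0.001, 0.002), 0.692),
}

#: subclass PCA sensitivity rows: (IE, DE, %IE, CI, p)
SUBCLASS_TABLE = {
    "pca_non_ortho": (0.008, 0.046, 14.4, (0.001, 0.015), 0.025),
    "pca_non_dioxin_like": (0.018, 0.036, 25.9, (0.009, 0.028), 0.001),
    "pca_all_pcbs": (0.020, 0.035, 36.2, (0.010, 0.029), 0.001),
    "pca_dioxins": (0.005, 0.050, 8.6, (-0.002, 0.011), 0.166),
    "pca_furans": (0.006, 0.048, 1.06, (0.000, 0.012), 0.069),
}

#: first-principal-component loadings over all 15 chemicals
PCA_ALL_LOADINGS = {
    "pcb74": 0.285,
    "pcb118": 0.283,
    "pcb126": 0.224,
    "pcb138": 0.294,
    "pcb153": 0.298,
    "pcb169": 0.275,
    "pcb170": 0.292,
    "pcb180": 0.286,
    "pcb187": 0.290,
    "d03": 0.213,
    "d05": 0.216,
    "d07": 0.232,
    "f03": 0.243,
    "f04": 0.246,
    "f08": 0.145,
}

#: mediation E-value for the PCA summary-score model (point, CI lower bound)
EVALUE_PCA = (1.35, 1.22)
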