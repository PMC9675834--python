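"""Registry of the 15 analysed serum POPs (9 PCBs, 3 dioxins, 3 furans).

Concentrations are lipid-adjusted (ng/g or pg/g lipid) and modelled on the
log scale throughout. Each chemical carries its NHANES 1999-2002 percent of
observations below the limit of detection (used as the default censoring
target of the synthetic cohort), its chemical family and dioxin-likeness
subclass (used for the subclass PCA sensitivity analysis), and two toxic
equivalency factor (TEF) tables: the values used in the original TEQ score
construction and the WHO 2005 consensus values (which differ for PCB 118).
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Chemical:
    name: str
    label: str
    family: str  # "pcb" | "dioxin" | "furan"
    subclass: str  # "non_dioxin_like" | "non_ortho" | "mono_ortho" | ""
    pct_below_lod: float  # percent of observations below LOD (1999-2002)
    tef: float | None  # TEF as used in the default TEQ construction
    tef_who2005: float | None  # WHO 2005 consensus TEF


CHEMICALS: tuple[Chemical, ...] = (
    Chemical("pcb74", "PCB 74", "pcb", "non_dioxin_like", 30.5, None, None),
    Chemical("pcb118", "PCB 118", "pcb", "mono_ortho", 28.4, 0.030, 0.00003),
    Chemical("pcb126", "PCB 126", "pcb", "non_ortho", 21.7, 0.100, 0.1),
    Chemical("pcb138", "PCB 138", "pcb", "non_dioxin_like", 20.3, None, None),
    Chemical("pcb153", "PCB 153", "pcb", "non_dioxin_like", 16.9, None, None),
    Chemical("pcb169", "PCB 169", "pcb", "non_ortho", 17.7, 0.030, 0.03),
    Chemical("pcb170", "PCB 170", "pcb", "non_dioxin_like", 26.4, None, None),
    Chemical("pcb180", "PCB 180", "pcb", "non_dioxin_like", 17.7, None, None),
    Chemical("pcb187", "PCB 187", "pcb", "non_dioxin_like", 32.1, None, None),
    Chemical("d03", "D03 (1,2,3,6,7,8-hxcdd)", "dioxin", "", 20.9, 0.100, 0.1),
    Chemical("d05", "D05 (1,2,3,4,6,7,8-hpcdd)", "dioxin", "", 13.3, 0.010, 0.01),
    Chemical("d07", "D07 (1,2,3,4,6,7,8,9-ocdd)", "dioxin", "", 20.5, 0.0003, 0.0003),
    Chemical("f03", "F03 (2,3,4,7,8-pncdf)", "furan", "", 36.9, 0.300, 0.3),
    Chemical("f04", "F04 (1,2,3,4,7,8-hxcdf)", "furan", "", 27.3, 0.100, 0.1),
    Chemical("f08", "F08 (1,2,3,4,6,7,8-hxcdf)", "furan", "", 25.3, 0.010, 0.01),
)

CHEMICAL_NAMES: list[str] = [c.name for c in CHEMICALS]

BY_NAME: dict[str, Chemical] = {c.name: c for c in CHEMICALS}

#: default TEF table (as used for the shipped TEQ score)
TEF_TABLE: dict[str, float] = {c.name: c.tef for c in CHEMICALS if c.tef is not None}

#: alternative WHO 2005 consensus TEF table
TEF_TABLE_WHO2005: dict[str, float] = {
    c.name: c.tef_who2005 for c in CHEMICALS if c.tef_who2005 is not None
}

#: chemical subsets for the subclass PCA sensitivity analysis
SUBCLASS_SETS: dict[str, list[str]] = {
    "pca_all_pcbs": [c.name for c in CHEMICALS if c.family == "pcb"],
    "pca_non_ortho": [c.name for c in CHEMICALS if c.subclass == "non_ortho"],
    "pca_non_dioxin_like": [
        c.name for c in CHEMICALS if c.subclass == "non_dioxin_like"
    ],
    "pca_dioxins": [c.name for c in CHEMICALS if c.family == "dioxin"],
    "pca_furans": [c.name for c in CHEMICALS if c.family == "furan"],
}

#: default per-chemical censoring targets (proportions below LOD)
DEFAULT_LOD_TARGETS: dict[str, float] = {
    c.name: c.pct_below_lod / 100.0 for c in CHEMICALS
}
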