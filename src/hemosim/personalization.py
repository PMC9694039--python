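"""Individual plasma composition from routine coagulation labs.

Factor levels are not measured directly in routine care; they are
inferred from the two global clotting times.  Intrinsic-pathway factor
concentrations scale inversely with the APTT and extrinsic/common
factors inversely with the PT:

    F = F0 * 31.43 / APTT   (fibrinogen, VIII, IX, XI)
    F = F0 * 12.09 / PT     (II, V, VII, X)

where 31.43 s and 12.09 s are the mean normal APTT and PT of the
reference test system and F0 is the normal mean concentration carried
by the network definition.  Antithrombin and fibrinogen, when measured
directly, override the inferred values.  The endogenous procoagulant
lipid pool (VLDL surface) scales proportionally with measured LDL, and
the LMWH level comes from the pharmacokinetic model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

from hemosim.pk_lmwh import PatientRecord
from hemosim.reaction_network.model import ReactionNetwork

APTT_NORMAL_S = 31.43
PT_NORMAL_S = 12.09
VLDL_NORMAL_UM = 200.0
LDL_REF_MMOL_L = 3.0
#: fibrinogen molar mass, g/mol (340 kDa) for g/L -> nM conversion
FIBRINOGEN_MW = 340_000.0

#: inferred factor levels are clipped to this fraction range of normal;
#: a heparin-prolonged APTT would otherwise masquerade as a deep
#: factor deficiency
CLIP_RANGE = (0.01, 4.0)


class MissingLabError(ValueError):
    def __init__(self, fields):
        super().__init__(f"missing mandatory lab value(s): {', '.join(fields)}")
        self.fields = list(fields)


@dataclass
class PlasmaComposition:
    """Per-species initial concentrations plus lipid pools and provenance."""

    species_nM: Dict[str, float]
    pools_um: Dict[str, float] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, v in self.species_nM.items():
            if v < 0:
                raise ValueError(f"negative concentration for {sid}")
        for pid, v in self.pools_um.items():
            if v < 0:
                raise ValueError(f"negative pool capacity for {pid}")

    def to_frame(self):
        import pandas as pd

        rows = [
            {"entry": sid, "value": v, "unit": "nM",
             "provenance": self.provenance.get(sid, "normal default")}
            for sid, v in sorted(self.species_nM.items())
        ]
        rows += [
            {"entry": f"pool:{pid}", "value": v, "unit": "uM",
             "provenance": self.provenance.get(f"pool:{pid}", "normal default")}
            for pid, v in sorted(self.pools_um.items())
        ]
        return pd.DataFrame(rows)


def scale_intrinsic(f0_nM: float, aptt_s: float,
                    aptt_normal_s: float = APTT_NORMAL_S) -> float:
    """Intrinsic-pathway factor level inferred from the APTT."""
    if aptt_s <= 0:
        raise ValueError("APTT must be positive")
    return f0_nM * aptt_normal_s / aptt_s


def scale_extrinsic(f0_nM: float, pt_s: float,
                    pt_normal_s: float = PT_NORMAL_S) -> float:
    """Extrinsic/common-pathway factor level inferred from the PT."""
    if pt_s <= 0:
        raise ValueError("PT must be positive")
    return f0_nM * pt_normal_s / pt_s


def vldl_pool(ldl_mmol_l: float, ldl_ref_mmol_l: float = LDL_REF_MMOL_L,
              vldl_normal_um: float = VLDL_NORMAL_UM) -> float:
    """Endogenous procoagulant phospholipid (uM) proportional to LDL."""
    if ldl_mmol_l < 0:
        raise ValueError("LDL must be non-negative")
    if ldl_ref_mmol_l <= 0:
        raise ValueError("LDL reference must be positive")
    return vldl_normal_um * ldl_mmol_l / ldl_ref_mmol_l


def _clip(scale: float, factor: str) -> float:
    lo, hi = CLIP_RANGE
    if scale < lo or scale > hi:
        warnings.warn(
            f"inferred level of {factor} ({scale:.2%} of normal) clipped to "
            f"[{lo:.0%}, {hi:.0%}]", stacklevel=3)
    return min(max(scale, lo), hi)


def build_composition(patient: PatientRecord, network: ReactionNetwork,
                      lmwh_nM: float = 0.0,
                      ldl_ref_mmol_l: float = LDL_REF_MMOL_L) -> PlasmaComposition:
    """Assemble the personalized plasma composition.

    APTT scales the intrinsic group, PT the extrinsic group (factor
    groups are declared by the network file); measured antithrombin and
    fibrinogen override inference; the VLDL pool follows LDL; LMWH is
    the PK-model output for the sampling time.
    """
    missing = []
    if math.isnan(patient.aptt_s):
        missing.append("APTT")
    if math.isnan(patient.pt_s):
        missing.append("PT")
    if missing:
        raise MissingLabError(missing)

    comp = network.normal_composition()
    prov: Dict[str, str] = {}

    intrinsic = set(network.factor_groups.get("intrinsic", []))
    extrinsic = set(network.factor_groups.get("extrinsic", []))
    s_int = _clip(APTT_NORMAL_S / patient.aptt_s, "intrinsic factors")
    s_ext = _clip(PT_NORMAL_S / patient.pt_s, "extrinsic factors")
    for sid in intrinsic:
        comp[sid] = comp[sid] * s_int
        prov[sid] = "APTT-scaled"
    for sid in extrinsic:
        comp[sid] = comp[sid] * s_ext
        prov[sid] = "PT-scaled"

    if "AT" in comp:
        normal_at = network.normal_composition()["AT"]
        comp["AT"] = normal_at * patient.antithrombin
        prov["AT"] = "measured"

    if not math.isnan(patient.fibrinogen_g_l) and "Fg" in comp:
        comp["Fg"] = patient.fibrinogen_g_l / FIBRINOGEN_MW * 1e9
        prov["Fg"] = "measured"

    comp["H"] = float(lmwh_nM)
    prov["H"] = "PK-derived"

    pools_um: Dict[str, float] = {}
    for pid, pool in network.pools.items():
        if pool.kind == "endogenous_vldl":
            if patient.ldl_mmol_l > 0:
                pools_um[pid] = vldl_pool(patient.ldl_mmol_l, ldl_ref_mmol_l)
                prov[f"pool:{pid}"] = "LDL-scaled"
            else:
                pools_um[pid] = pool.total_sites / 1000.0
                prov[f"pool:{pid}"] = "normal default"

    return PlasmaComposition(species_nM=comp, pools_um=pools_um, provenance=prov)
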