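"""Patient fixtures and synthetic-cohort generation.

The packaged reference cohort mirrors the characteristics table of the
LMWH-treated study group (12 patients: sex, weight, creatinine, lipid
profile, hematocrit).  APTT/PT and antithrombin were measured per
sample in the study but their per-patient values are not published, so
the fixtures carry the normal means; the synthetic generator draws all
fields, including clotting times, from ranges spanning the study's
spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from hemosim.pk_lmwh import PatientRecord
from hemosim.personalization import APTT_NORMAL_S, PT_NORMAL_S

#: published characteristics of the 12-patient reference group:
#: (sex, weight kg, creatinine umol/L, total cholesterol, HDL, LDL mmol/L,
#:  hematocrit %); missing lipid panels are None
REFERENCE_PATIENTS = [
    ("1",  "M", 80, 32,  3.36, 1.08, 1.32, 38.8),
    ("2",  "M", 92, 38,  3.12, 0.75, 1.94, 47.7),
    ("3",  "M", 96, 79,  5.67, 0.87, 2.78, 56.3),
    ("4",  "M", 77, 90,  4.96, 0.82, 3.21, 38.0),
    ("5",  "F", 53, 89,  None, None, None, 32.4),
    ("6",  "F", 78, 47,  4.53, 0.91, 2.93, 47.5),
    ("7",  "M", 82, 83,  3.49, 0.80, 2.42, 23.1),
    ("8",  "M", 92, 83,  3.18, 0.65, 2.01, 19.8),
    ("9",  "M", 79, 40,  3.16, 0.75, 1.90, 51.0),
    ("10", "F", 46, 111, None, None, None, 31.3),
    ("11", "M", 86, 51,  5.39, 1.42, 2.60, 51.1),
    ("12", "M", 89, 55,  6.87, 0.94, 4.62, 40.7),
]


def reference_cohort(dose_iu: float = 4000.0) -> List[PatientRecord]:
    """The packaged 12-patient reference group as PatientRecord fixtures."""
    out = []
    for pid, sex, w, creat, chol, _hdl, ldl, hc in REFERENCE_PATIENTS:
        out.append(PatientRecord(
            patient_id=pid, sex=sex, weight_kg=w, hematocrit=hc / 100.0,
            creatinine_umol_l=creat,
            cholesterol_mmol_l=chol if chol is not None else 0.0,
            ldl_mmol_l=ldl if ldl is not None else 0.0,
            aptt_s=APTT_NORMAL_S, pt_s=PT_NORMAL_S,
            antithrombin=1.0, dose_iu=dose_iu, dose_times_h=(0.0,),
        ))
    return out


@dataclass
class SyntheticCohortSpec:
    """Sampling ranges for virtual patients (uniform within range)."""

    n: int
    seed: int = 0
    weight_kg: Tuple[float, float] = (46.0, 96.0)
    hematocrit: Tuple[float, float] = (0.198, 0.563)
    creatinine_umol_l: Tuple[float, float] = (32.0, 111.0)
    cholesterol_mmol_l: Tuple[float, float] = (3.12, 6.87)
    ldl_mmol_l: Tuple[float, float] = (1.32, 4.62)
    aptt_s: Tuple[float, float] = (25.0, 45.0)
    pt_s: Tuple[float, float] = (10.0, 16.0)
    antithrombin: Tuple[float, float] = (0.7, 1.2)
    female_fraction: float = 0.25
    dose_iu: float = 4000.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be non-negative")
        for name in ("weight_kg", "hematocrit", "creatinine_umol_l",
                     "cholesterol_mmol_l", "ldl_mmol_l", "aptt_s", "pt_s",
                     "antithrombin"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.hematocrit[1] >= 1.0:
            raise ValueError("hematocrit range must stay below 1")


def generate_cohort(spec: SyntheticCohortSpec) -> List[PatientRecord]:
    """Seeded, reproducible virtual patients within the spec's ranges."""
    rng = np.random.default_rng(spec.seed)
    patients = []
    for i in range(spec.n):
        draw = lambda rng_, pair: float(rng_.uniform(*pair))
        patients.append(PatientRecord(
            patient_id=f"S{i + 1}",
            sex="F" if rng.random() < spec.female_fraction else "M",
            weight_kg=draw(rng, spec.weight_kg),
            hematocrit=draw(rng, spec.hematocrit),
            creatinine_umol_l=draw(rng, spec.creatinine_umol_l),
            cholesterol_mmol_l=draw(rng, spec.cholesterol_mmol_l),
            ldl_mmol_l=draw(rng, spec.ldl_mmol_l),
            aptt_s=draw(rng, spec.aptt_s),
            pt_s=draw(rng, spec.pt_s),
            antithrombin=draw(rng, spec.antithrombin),
            dose_iu=spec.dose_iu,
            dose_times_h=(0.0,),
        ))
    return patients


_CSV_COLUMNS = {
    "patient_id": str, "sex": str, "weight_kg": float, "hematocrit": float,
    "creatinine_umol_l": float, "cholesterol_mmol_l": float,
    "ldl_mmol_l": float, "aptt_s": float, "pt_s": float,
    "antithrombin": float, "fibrinogen_g_l": float, "dose_iu": float,
}


def read_patients_csv(path) -> List[PatientRecord]:
    """Read patient records from a CSV mirroring the characteristics table."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, caster in _CSV_COLUMNS.items():
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = caster(row[col])
        kwargs.setdefault("patient_id", str(len(out) + 1))
        out.append(PatientRecord(**kwargs))
    return out


def cohort_to_frame(patients: List[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {col: getattr(p, col) for col in _CSV_COLUMNS}
        for p in patients
    ])
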