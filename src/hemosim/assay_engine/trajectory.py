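"""Trajectory containers for both assay engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Well-mixed simulation output: concentration curves over time."""

    times_min: np.ndarray  # (T,)
    conc: np.ndarray  # (n_species, T), nM
    species_ids: List[str]
    observables: Dict[str, Dict[str, float]] = field(default_factory=dict)
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conc.shape != (len(self.species_ids), len(self.times_min)):
            raise ValueError("concentration array shape inconsistent with labels")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        self._index = {sid: i for i, sid in enumerate(self.species_ids)}

    def curve(self, species_id: str) -> np.ndarray:
        return self.conc[self._index[species_id]]

    def observable(self, name: str) -> np.ndarray:
        out = np.zeros_like(self.times_min, dtype=float)
        for sid, w in self.observables[name].items():
            out += w * self.curve(sid)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time_min, species, value_nM) table."""
        t = np.repeat(self.times_min, len(self.species_ids))
        sp = np.tile(np.array(self.species_ids, dtype=object), len(self.times_min))
        vals = self.conc.T.ravel()
        return pd.DataFrame({"time_min": t, "species": sp, "value_nM": vals})


@dataclass
class SpatialTrajectory:
    """Spatially distributed simulation output.

    ``fields`` holds volume concentrations over the grid,
    shape (n_volume_species, n_nodes, T) in nM; ``surface`` holds the
    activator-surface densities, shape (n_surface_species, T) in
    nmol/m^2.
    """

    times_min: np.ndarray
    x_um: np.ndarray
    fields: np.ndarray
    volume_ids: List[str]
    surface: np.ndarray
    surface_ids: List[str]
    observables: Dict[str, Dict[str, float]] = field(default_factory=dict)
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T, N = len(self.times_min), len(self.x_um)
        if self.fields.shape != (len(self.volume_ids), N, T):
            raise ValueError("field array shape inconsistent with labels")
        if self.surface.shape != (len(self.surface_ids), T):
            raise ValueError("surface array shape inconsistent with labels")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        self._vindex = {sid: i for i, sid in enumerate(self.volume_ids)}
        self._sindex = {sid: i for i, sid in enumerate(self.surface_ids)}

    def field(self, species_id: str) -> np.ndarray:
        """(n_nodes, T) concentration field of one volume species."""
        return self.fields[self._vindex[species_id]]

    def surface_curve(self, species_id: str) -> np.ndarray:
        return self.surface[self._sindex[species_id]]

    def observable_field(self, name: str) -> np.ndarray:
        out = np.zeros((len(self.x_um), len(self.times_min)))
        for sid, w in self.observables[name].items():
            if sid in self._vindex:
                out += w * self.field(sid)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time_min, x_um, species, value_nM) table."""
        n_sp, N, T = self.fields.shape
        t = np.tile(np.repeat(self.times_min, N), n_sp)
        x = np.tile(self.x_um, n_sp * T)
        sp = np.repeat(np.array(self.volume_ids, dtype=object), N * T)
        vals = self.fields.transpose(0, 2, 1).ravel()
        return pd.DataFrame({"species": sp, "time_min": t, "x_um": x, "value_nM": vals})
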