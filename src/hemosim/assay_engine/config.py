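"""Assay configuration and spatial grid types."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple


@dataclass
class AssayConfig:
    """Configuration of a global hemostasis assay run.

    ``mode`` selects the engine: ``homogeneous`` is the thrombin
    generation assay (TF-bearing reagent vesicles mixed into diluted
    plasma), ``spatial`` is the clot-growth assay (undiluted plasma in
    contact with an immobilized TF surface).

    Units follow the assays' conventions: TF in pM (bulk) or pmol/m^2
    (surface), phospholipid and substrate in uM, horizon in minutes,
    output cadence in seconds.  ``dilution`` is the plasma:reagent
    volume ratio applied to plasma-borne species (2:1 by default for
    the homogeneous assay; the spatial assay uses lyophilized reagents
    and runs undiluted).
    """

    mode: str = "homogeneous"
    tf_bulk: float = 0.0  # pM, homogeneous mode
    tf_surface: float = 0.0  # pmol/m^2, spatial mode
    artificial_lipid: float = 0.0  # uM phospholipid vesicles
    substrate: float = 0.0  # uM fluorogenic substrate
    dilution: Optional[Tuple[float, float]] = None  # plasma:reagent
    horizon: float = 60.0  # min
    output_interval: Optional[float] = None  # s; engine default if None
    rtol: Optional[float] = None
    atol_factor: Optional[float] = None  # scaled absolute tolerance factor
    tf_species: str = "TF"
    substrate_species: str = "S"

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "spatial"):
            raise ValueError(f"unknown assay mode {self.mode!r}")
        if self.mode == "homogeneous" and self.tf_surface:
            raise ValueError("tf_surface is a spatial-mode dose")
        if self.mode == "spatial" and self.tf_bulk:
            raise ValueError("tf_bulk is a homogeneous-mode dose")
        for name in ("tf_bulk", "tf_surface", "artificial_lipid", "substrate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.dilution is None:
            self.dilution = (2.0, 1.0) if self.mode == "homogeneous" else (1.0, 0.0)

    @property
    def plasma_fraction(self) -> float:
        p, r = self.dilution
        return p / (p + r)


@dataclass
class SpatialGrid:
    """Equidistant 1-D grid with the activator surface at x = 0."""

    length_um: float = 4000.0
    nodes: int = 400

    def __post_init__(self) -> None:
        if self.nodes < 3:
            raise ValueError("grid needs at least 3 nodes")
        if self.length_um <= 0:
            raise ValueError("grid length must be positive")

    @property
    def spacing_um(self) -> float:
        return self.length_um / (self.nodes - 1)

    @property
    def x_um(self):
        import numpy as np

        return np.linspace(0.0, self.length_um, self.nodes)
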