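"""Domain types for the plasma-coagulation reaction network.

Internal unit conventions
-------------------------
* volume concentrations: nM
* surface (activator-bound) densities: nmol/m^2
* time: seconds
* diffusion coefficients: m^2/s
* lipid pool capacities: nM of phospholipid head groups
  (1 uM phospholipid = 1000 nM head groups)

A species may belong to a lipid *pool*; such a species represents a
membrane-assembled form and occupies ``footprint`` phospholipid head
groups per bound molecule.  The free (reactive) site density of a pool
is the algebraic quantity ``total_sites - sum(footprint_s * [s])``;
membrane-binding reaction rates are proportional to it, which is how
competition for the lipid surface between coagulation complexes enters
the kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple


class NetworkSchemaError(ValueError):
    """Raised when a network definition file is inconsistent."""


class NetworkValidationError(ValueError):
    """Raised when a structurally valid network violates an invariant."""


@dataclass(frozen=True)
class Species:
    """A chemical state variable of the coagulation model."""

    id: str
    name: str = ""
    phase: str = "volume"  # "volume" | "surface" (activator-bound)
    diffusion_coefficient: float = 0.0  # m^2/s; meaningful for volume species
    initial_normal: float = 0.0  # nM at 100% normal plasma (volume species)
    pool: Optional[str] = None  # lipid pool id for membrane-bound species
    footprint: float = 0.0  # head groups occupied per bound molecule

    def __post_init__(self) -> None:
        if self.phase not in ("volume", "surface"):
            raise NetworkSchemaError(
                f"species {self.id!r}: phase must be volume or surface"
            )
        if self.diffusion_coefficient < 0:
            raise NetworkValidationError(
                f"species {self.id!r}: negative diffusion coefficient"
            )
        if self.phase == "surface" and self.diffusion_coefficient != 0.0:
            raise NetworkValidationError(
                f"species {self.id!r}: surface species carry no diffusion coefficient"
            )
        if self.initial_normal < 0:
            raise NetworkValidationError(
                f"species {self.id!r}: negative initial concentration"
            )


@dataclass(frozen=True)
class LipidPool:
    """A class of procoagulant phospholipid surface.

    Three kinds occur in the assays: lipoprotein (VLDL) surface
    endogenous to the plasma sample, the phospholipid carried by the
    tissue-factor reagent, and artificial vesicles added to boost the
    assay signal.  Extrinsic tenase (VIIa:TF) can only assemble on the
    activator-bound pool; intrinsic tenase, prothrombinase and
    prothrombin binding occur on all three.
    """

    id: str
    kind: str  # endogenous_vldl | activator_bound | artificial
    total_sites: float  # nM head groups (volume pools); nmol/m^2 for activator pool in spatial mode
    activity: float = 1.0  # procoagulant quality factor scaling binding rates

    def __post_init__(self) -> None:
        if self.kind not in ("endogenous_vldl", "activator_bound", "artificial"):
            raise NetworkSchemaError(f"pool {self.id!r}: unknown kind {self.kind!r}")
        if self.total_sites < 0:
            raise NetworkValidationError(f"pool {self.id!r}: negative total_sites")


@dataclass(frozen=True)
class Reaction:
    """A single reaction with mass-action or Michaelis-Menten kinetics.

    ``reactants`` and ``products`` map species ids to stoichiometric
    coefficients.  For ``rate="michaelis"`` the rate is
    ``k * [enzyme] * [substrate] / (km + [substrate])`` and the enzyme
    is untouched; reactants must then be exactly ``{substrate: 1}``.
    ``site_pool`` names a lipid pool whose free-site density multiplies
    the rate (membrane-binding step).
    """

    id: str
    reactants: Mapping[str, float]
    products: Mapping[str, float]
    k: float
    rate: str = "mass_action"  # "mass_action" | "michaelis"
    km: float = 0.0
    enzyme: Optional[str] = None
    site_pool: Optional[str] = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise NetworkValidationError(f"reaction {self.id!r}: negative constant")
        if self.rate not in ("mass_action", "michaelis"):
            raise NetworkSchemaError(f"reaction {self.id!r}: unknown rate law")
        if self.rate == "michaelis":
            if self.enzyme is None or self.km <= 0:
                raise NetworkSchemaError(
                    f"reaction {self.id!r}: michaelis law needs enzyme and km > 0"
                )


@dataclass
class ReactionNetwork:
    """A validated, simulable coagulation chemistry."""

    species: List[Species]
    pools: Dict[str, LipidPool]
    reactions: List[Reaction]
    observables: Dict[str, Dict[str, float]] = field(default_factory=dict)
    scaffolds: Dict[str, Dict[str, float]] = field(default_factory=dict)
    factor_groups: Dict[str, List[str]] = field(default_factory=dict)
    name: str = ""
    lipid_per_tf: float = 5000.0  # phospholipid molecules per TF molecule in the reagent

    def __post_init__(self) -> None:
        self._index = {s.id: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise NetworkSchemaError("duplicate species ids")
        for s in self.species:
            if s.pool is not None and s.pool not in self.pools:
                raise NetworkSchemaError(
                    f"species {s.id!r} references undeclared pool {s.pool!r}"
                )
        for r in self.reactions:
            for sid in (*r.reactants, *r.products):
                if sid not in self._index:
                    raise NetworkSchemaError(
                        f"reaction {r.id!r} references undeclared species {sid!r}"
                    )
            if r.enzyme is not None and r.enzyme not in self._index:
                raise NetworkSchemaError(
                    f"reaction {r.id!r} references undeclared enzyme {r.enzyme!r}"
                )
            if r.site_pool is not None and r.site_pool not in self.pools:
                raise NetworkSchemaError(
                    f"reaction {r.id!r} references undeclared pool {r.site_pool!r}"
                )
        for obs, weights in self.observables.items():
            for sid in weights:
                if sid not in self._index:
                    raise NetworkSchemaError(
                        f"observable {obs!r} references undeclared species {sid!r}"
                    )

    # -- indexing helpers -------------------------------------------------

    def index(self, species_id: str) -> int:
        return self._index[species_id]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._index

    @property
    def volume_species(self) -> List[Species]:
        return [s for s in self.species if s.phase == "volume"]

    @property
    def surface_species(self) -> List[Species]:
        return [s for s in self.species if s.phase == "surface"]

    @property
    def n_homogeneous(self) -> int:
        """State dimension of the well-mixed projection (all species)."""
        return len(self.species)

    def dimension_summary(self) -> str:
        return (
            f"{self.name or 'network'}: {len(self.volume_species)} volume + "
            f"{len(self.surface_species)} surface species "
            f"({self.n_homogeneous} homogeneous), {len(self.reactions)} reactions, "
            f"{len(self.pools)} lipid pools"
        )

    def normal_composition(self) -> Dict[str, float]:
        """Initial concentrations (nM) of 100% normal pooled plasma."""
        return {s.id: s.initial_normal for s in self.species}


def tf_reagent_lipid(tf_conc_pm: float, lipid_per_tf: float = 5000.0) -> float:
    """Phospholipid (uM) carried into the sample by the TF reagent.

    The activator reagent is phospholipid vesicles with incorporated
    recombinant TF at roughly ``lipid_per_tf`` phospholipid molecules
    per TF molecule (5000 by default).

    Parameters
    ----------
    tf_conc_pm : TF dose in pM.

    Returns
    -------
    Phospholipid concentration in uM.
    """
    if tf_conc_pm < 0:
        raise ValueError("TF concentration must be non-negative")
    # pM * molecules/TF = pM lipid; 1 uM = 1e6 pM
    return lipid_per_tf * tf_conc_pm * 1e-6


def free_site_fraction(pool: LipidPool, occupancy: Mapping[str, float],
                       footprints: Mapping[str, float]) -> float:
    """Fraction of a pool's phospholipid sites not occupied by bound complexes.

    ``occupancy`` maps bound-species ids to their concentrations (same
    units as ``pool.total_sites`` per footprint); ``footprints`` gives
    head groups per bound molecule.  Surface assembly rates scale with
    this fraction, so crowding of the lipid surface slows further
    binding.
    """
    if pool.total_sites == 0:
        return 1.0 if not any(occupancy.values()) else 0.0
    occupied = sum(footprints.get(k, 0.0) * v for k, v in occupancy.items())
    if occupied > pool.total_sites * (1 + 1e-9):
        raise ValueError(
            f"pool {pool.id!r}: occupied sites {occupied} exceed capacity "
            f"{pool.total_sites}"
        )
    return max(0.0, (pool.total_sites - occupied) / pool.total_sites)


def observable_thrombin(iia: float, iia_a2m: float, a2m_weight: float = 0.6) -> float:
    """Substrate-cleaving thrombin activity in nM equivalents.

    The fluorogenic substrate is hydrolysed both by free thrombin and by
    the thrombin-alpha2-macroglobulin complex; the complex cleaves it
    with reduced efficiency, so the registered signal corresponds to
    ``IIa + 0.6 * IIa:a2M``.
    """
    if iia < 0 or iia_a2m < 0:
        raise ValueError("concentrations must be non-negative")
    return iia + a2m_weight * iia_a2m
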