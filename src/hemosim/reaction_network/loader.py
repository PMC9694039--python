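"""Load a reaction-network definition file (YAML) into a ReactionNetwork.

The schema mirrors how the chemistry is written on paper:

.. code-block:: yaml

    name: my network
    constants:          # named rate constants, referenced by reactions
      kon: 3.2e-3
    pools:              # lipid surfaces; capacities in uM phospholipid
      - {id: vl, kind: endogenous_vldl, total_um: 200.0, activity: 0.2}
    species:            # initial concentrations in nM (100% normal plasma)
      - {id: X, name: factor X, initial: 170.0, diffusion: 6.0e-11}
      - {id: "Xa@vl", pool: vl, footprint: 100}
      - {id: TF, phase: surface}
    reactions:
      - {id: b1, eq: "Xa -> Xa@vl", k: kon, kr: 0.1, sites: vl}
      - {id: f1, eq: "Fg -> Fn1", rate: michaelis, enzyme: IIa, k: 84, km: 7200}
    observables:
      thrombin: {IIa: 1.0, "IIa:A2M": 0.6}
    scaffolds:          # conserved protein backbones, for mass-balance checks
      prothrombin: {II: 1, IIa: 1, ...}
    factor_groups:
      intrinsic: [Fg, VIII, IX, XI]

``eq`` strings use ``A + 2 B -> C``; ``kr`` adds the reverse reaction;
``sites: <pool>`` multiplies the rate by the pool's free phospholipid
site density (membrane binding).  Constants may be numbers or names
from the ``constants`` table.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Mapping, Tuple, Union

import yaml

from hemosim.reaction_network.model import (
    LipidPool,
    NetworkSchemaError,
    Reaction,
    ReactionNetwork,
    Species,
)

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str, rxn_id: str) -> Dict[str, float]:
    terms: Dict[str, float] = {}
    side = side.strip()
    if side in ("", "0", "âˆ…"):
        return terms
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise NetworkSchemaError(f"reaction {rxn_id!r}: cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        sid = m.group(2)
        terms[sid] = terms.get(sid, 0.0) + coef
    return terms


def parse_equation(eq: str, rxn_id: str = "?") -> Tuple[Dict[str, float], Dict[str, float]]:
    """Parse ``"A + 2 B -> C"`` into reactant and product stoichiometries."""
    if "->" not in eq:
        raise NetworkSchemaError(f"reaction {rxn_id!r}: missing '->' in {eq!r}")
    lhs, rhs = eq.split("->", 1)
    return _parse_side(lhs, rxn_id), _parse_side(rhs, rxn_id)


def _resolve_k(value: Union[str, float, int], constants: Mapping[str, float],
               rxn_id: str) -> float:
    if isinstance(value, str):
        if value not in constants:
            raise NetworkSchemaError(
                f"reaction {rxn_id!r}: unknown constant {value!r}"
            )
        return float(constants[value])
    return float(value)


def load_network(path: Union[str, Path]) -> ReactionNetwork:
    """Load and validate a network-definition YAML file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise NetworkSchemaError(f"{path}: not a mapping")

    constants: Dict[str, float] = {
        k: float(v) for k, v in (doc.get("constants") or {}).items()
    }

    pools: Dict[str, LipidPool] = {}
    for p in doc.get("pools") or []:
        pool = LipidPool(
            id=p["id"],
            kind=p["kind"],
            total_sites=float(p.get("total_um", 0.0)) * 1000.0,  # uM -> nM head groups
            activity=float(p.get("activity", 1.0)),
        )
        pools[pool.id] = pool

    species: List[Species] = []
    for s in doc.get("species") or []:
        species.append(
            Species(
                id=s["id"],
                name=s.get("name", ""),
                phase=s.get("phase", "volume"),
                diffusion_coefficient=float(s.get("diffusion", 0.0)),
                initial_normal=float(s.get("initial", 0.0)),
                pool=s.get("pool"),
                footprint=float(s.get("footprint", 0.0)),
            )
        )

    reactions: List[Reaction] = []
    for r in doc.get("reactions") or []:
        rid = r.get("id") or f"r{len(reactions)}"
        reactants, products = parse_equation(r["eq"], rid)
        rate = r.get("rate", "mass_action")
        rxn = Reaction(
            id=rid,
            reactants=reactants,
            products=products,
            k=_resolve_k(r["k"], constants, rid),
            rate=rate,
            km=_resolve_k(r.get("km", 0.0), constants, rid),
            enzyme=r.get("enzyme"),
            site_pool=r.get("sites"),
        )
        reactions.append(rxn)
        if "kr" in r:
            if rate != "mass_action":
                raise NetworkSchemaError(f"reaction {rid!r}: kr on non-mass-action law")
            reactions.append(
                Reaction(
                    id=rid + "_r",
                    reactants=products,
                    products=reactants,
                    k=_resolve_k(r["kr"], constants, rid),
                    # reverse of a site-binding step releases the sites; the
                    # free-site factor applies to the forward direction only
                )
            )

    net = ReactionNetwork(
        species=species,
        pools=pools,
        reactions=reactions,
        observables={
            k: {sid: float(w) for sid, w in v.items()}
            for k, v in (doc.get("observables") or {}).items()
        },
        scaffolds={
            k: {sid: float(w) for sid, w in v.items()}
            for k, v in (doc.get("scaffolds") or {}).items()
        },
        factor_groups={
            k: list(v) for k, v in (doc.get("factor_groups") or {}).items()
        },
        name=doc.get("name", path.stem),
        lipid_per_tf=float(doc.get("lipid_per_tf", 5000.0)),
    )
    return net


def builtin_network_path(name: str = "plasma") -> Path:
    """Path of a packaged network file (``plasma`` or ``mini``)."""
    here = Path(__file__).resolve().parent.parent / "networks"
    p = here / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no packaged network named {name!r}")
    return p
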