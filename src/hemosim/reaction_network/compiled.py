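"""Compilation of a ReactionNetwork into vectorized rate evaluators.

Both simulation engines consume the same compiled form:

* the well-mixed engine evaluates every reaction as a bulk reaction on a
  single state vector (surface species become ordinary concentrations:
  in the thrombin generation assay the TF reagent vesicles are
  suspended in the sample volume);
* the spatial engine splits reactions into bulk reactions, evaluated at
  every grid node, and boundary reactions (those touching a surface
  species or the activator lipid pool), evaluated at the activation
  surface only.  Surface densities are tracked in nmol/m^2; a boundary
  reaction converting volume species removes/adds them from the first
  grid cell.

Bimolecular rate constants are shared between the two modes: the
capture rate per surface molecule, ``k * C``, does not depend on whether
the molecule sits on a suspended vesicle or on the wall, so a constant
expressed in 1/(nM s) applies to both ``nM * nM`` and ``nmol/m^2 * nM``
products.  A boundary reaction must therefore carry exactly one
surface-unit factor; this is validated during compilation.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from hemosim.reaction_network.model import (
    NetworkSchemaError,
    Reaction,
    ReactionNetwork,
)

#: nmol/m^3 expressed in nM (1 nM = 1 nmol/L = 1000 nmol/m^3)
_NMOL_M3_TO_NM = 1e-3

#: concentration cap (nM) applied inside rate evaluation: far above any
#: physical plasma concentration, it only engages on the implicit
#: solver's polynomial-predictor trial states, whose excursions would
#: otherwise overflow rate products into non-finite Jacobian entries
_CONC_CAP = 1e7


class CompiledNetwork:
    """Index-based, vectorized form of a ReactionNetwork."""

    def __init__(self, network: ReactionNetwork):
        self.network = network
        vol = [s for s in network.species if s.phase == "volume"]
        surf = [s for s in network.species if s.phase == "surface"]
        self.vol_ids = [s.id for s in vol]
        self.surf_ids = [s.id for s in surf]
        self.n_v = len(vol)
        self.n_u = len(surf)
        self.n_s = self.n_v + self.n_u
        # global index: volume species first, then surface
        self.gidx = {sid: i for i, sid in enumerate(self.vol_ids + self.surf_ids)}
        self.is_surface = np.zeros(self.n_s, dtype=bool)
        self.is_surface[self.n_v:] = True

        self.diffusion = np.array(
            [s.diffusion_coefficient for s in vol], dtype=float
        )

        # lipid pools
        self.pool_ids = list(network.pools)
        self.pool_index = {pid: i for i, pid in enumerate(self.pool_ids)}
        self.pool_kind = {pid: network.pools[pid].kind for pid in self.pool_ids}
        self.activator_pools = {
            pid for pid in self.pool_ids
            if network.pools[pid].kind == "activator_bound"
        }
        # occupancy matrix: head groups bound per species (n_pools x n_s)
        occ = np.zeros((len(self.pool_ids), self.n_s))
        for s in network.species:
            if s.pool is not None and s.footprint > 0:
                occ[self.pool_index[s.pool], self.gidx[s.id]] = s.footprint
        self.occupancy = occ

        self._compile_reactions()
        self._compile_scaffolds()

    # ------------------------------------------------------------------

    def _reaction_record(self, r: Reaction):
        """(factor indices, k_eff, mm substrate idx or -1, km, pool idx or -1)."""
        factors: List[int] = []
        if r.rate == "michaelis":
            factors.append(self.gidx[r.enzyme])
            (sub, coef), = r.reactants.items()
            if coef != 1:
                raise NetworkSchemaError(
                    f"reaction {r.id!r}: michaelis substrate stoichiometry must be 1"
                )
            factors.append(self.gidx[sub])
            mm_sub = self.gidx[sub]
        else:
            for sid, coef in r.reactants.items():
                if coef != int(coef):
                    raise NetworkSchemaError(
                        f"reaction {r.id!r}: non-integer stoichiometry in rate law"
                    )
                factors.extend([self.gidx[sid]] * int(coef))
            mm_sub = -1
        k_eff = r.k
        pool_idx = -1
        if r.site_pool is not None:
            pool_idx = self.pool_index[r.site_pool]
            k_eff = r.k * self.network.pools[r.site_pool].activity
        return factors, k_eff, mm_sub, r.km, pool_idx

    def _is_boundary(self, r: Reaction) -> bool:
        touches_surface = any(
            self.is_surface[self.gidx[sid]]
            for sid in (*r.reactants, *r.products, *( [r.enzyme] if r.enzyme else []))
        )
        site_activator = r.site_pool in self.activator_pools
        return touches_surface or site_activator

    def _compile_group(self, reactions: Sequence[Reaction], local_index: Dict[str, int],
                       n_rows: int):
        """Compile a reaction subset against a local species indexing."""
        n_r = len(reactions)
        records = [self._reaction_record(r) for r in reactions]
        max_ord = max((len(f) for f, *_ in records), default=1)
        dummy = len(local_index)  # augmented index holding constant 1.0
        F = np.full((n_r, max_ord), dummy, dtype=np.intp)
        k = np.zeros(n_r)
        mm_rows, mm_sub, mm_km = [], [], []
        site_rows, site_pool = [], []
        S = sp.lil_matrix((n_rows, n_r))
        for j, (r, (factors, k_eff, sub, km, pidx)) in enumerate(zip(reactions, records)):
            for a, gi in enumerate(factors):
                F[j, a] = local_index[self._gid_to_sid(gi)]
            k[j] = k_eff
            if sub >= 0:
                mm_rows.append(j)
                mm_sub.append(local_index[self._gid_to_sid(sub)])
                mm_km.append(km)
            if pidx >= 0:
                site_rows.append(j)
                site_pool.append(pidx)
            for sid, coef in r.reactants.items():
                S[local_index[sid], j] -= coef
            for sid, coef in r.products.items():
                S[local_index[sid], j] += coef
        return {
            "F": F,
            "k": k,
            "mm_rows": np.array(mm_rows, dtype=np.intp),
            "mm_sub": np.array(mm_sub, dtype=np.intp),
            "mm_km": np.array(mm_km, dtype=float),
            "site_rows": np.array(site_rows, dtype=np.intp),
            "site_pool": np.array(site_pool, dtype=np.intp),
            "S": S.tocsr(),
            "reactions": list(reactions),
        }

    def _gid_to_sid(self, gi: int) -> str:
        return (self.vol_ids + self.surf_ids)[gi]

    def _compile_reactions(self) -> None:
        net = self.network
        # homogeneous: every species is a bulk concentration
        hom_index = {sid: i for i, sid in enumerate(self.vol_ids + self.surf_ids)}
        self.hom = self._compile_group(net.reactions, hom_index, self.n_s)

        # spatial: split bulk / boundary
        bulk = [r for r in net.reactions if not self._is_boundary(r)]
        bnd = [r for r in net.reactions if self._is_boundary(r)]
        vol_index = {sid: i for i, sid in enumerate(self.vol_ids)}
        self.bulk = self._compile_group(bulk, vol_index, self.n_v)
        # boundary reactions act on [volume at node 0] + [surface] states
        self.bnd = self._compile_group(bnd, hom_index, self.n_s)
        for r in bnd:
            n_surf_factors = sum(
                coef for sid, coef in r.reactants.items()
                if self.is_surface[self.gidx[sid]]
            )
            if r.enzyme is not None and self.is_surface[self.gidx[r.enzyme]]:
                n_surf_factors += 1
            if r.site_pool in self.activator_pools:
                n_surf_factors += 1
            if n_surf_factors != 1:
                raise NetworkSchemaError(
                    f"boundary reaction {r.id!r} must carry exactly one "
                    f"surface-unit factor (found {n_surf_factors})"
                )

    def _compile_scaffolds(self) -> None:
        net = self.network
        mats = {}
        for name, weights in net.scaffolds.items():
            w = np.zeros(self.n_s)
            for sid, coef in weights.items():
                w[self.gidx[sid]] = coef
            mats[name] = w
        self.scaffold_weights = mats

    # ------------------------------------------------------------------
    # rate evaluation

    def _rates(self, group, ya: np.ndarray, free_sites: Optional[np.ndarray]):
        """Evaluate reaction rates for one compiled group.

        ``ya`` is the augmented concentration array with a trailing row
        of ones; shape (n_local+1,) or (n_local+1, N).  ``free_sites``
        has shape (n_pools,) or (n_pools, N).
        """
        fac = ya[group["F"]]
        rates = fac.prod(axis=1)
        if group["mm_rows"].size:
            # substrate clipped at 0 so the denominator stays off its pole
            # even on wild Newton/finite-difference trial states
            sub = np.clip(ya[group["mm_sub"]], 0.0, None)
            rates[group["mm_rows"]] = rates[group["mm_rows"]] / (
                group["mm_km"][..., None] + sub if sub.ndim == 2 else group["mm_km"] + sub
            )
        if rates.ndim == 2:
            rates *= group["k"][:, None]
        else:
            rates *= group["k"]
        if group["site_rows"].size and free_sites is not None:
            rates[group["site_rows"]] *= free_sites[group["site_pool"]]
        return rates

    def free_sites(self, totals: np.ndarray, y: np.ndarray,
                   occupancy: Optional[np.ndarray] = None) -> np.ndarray:
        """Free phospholipid site density per pool (clipped at 0)."""
        occ = self.occupancy if occupancy is None else occupancy
        if y.ndim == 2:
            bound = occ @ y
            return np.clip(totals[:, None] - bound, 0.0, None)
        return np.clip(totals - occ @ y, 0.0, None)

    # -- homogeneous ----------------------------------------------------

    def homogeneous_rhs(self, pool_totals: np.ndarray):
        """Right-hand side f(t, y) for the well-mixed 78-variable system."""
        group = self.hom
        S = group["S"]

        def rhs(t, y):
            yc = np.clip(y, 0.0, _CONC_CAP)
            ya = np.append(yc, 1.0)
            free = self.free_sites(pool_totals, yc)
            rates = self._rates(group, ya, free)
            return S @ rates

        return rhs

    # -- spatial --------------------------------------------------------

    def spatial_rhs(self, pool_totals_volume: np.ndarray,
                    activator_totals: np.ndarray, n_nodes: int, dx_m: float):
        """Right-hand side for the 1-D method-of-lines system.

        State layout: volume species node-major per species
        (``y[i*N + j]`` = species i at node j), then surface densities.
        ``pool_totals_volume`` gives volume-pool capacities in nM head
        groups (activator pools 0); ``activator_totals`` gives activator
        pool capacities in nmol/m^2 (volume pools 0).
        """
        n_v, n_u, N = self.n_v, self.n_u, n_nodes
        bulk, bnd = self.bulk, self.bnd
        Sb, Sd = bulk["S"], bnd["S"]
        D_over_h2 = self.diffusion / dx_m**2
        conv = _NMOL_M3_TO_NM / dx_m  # nmol/m^2/s -> nM/s in the first cell
        ones_row = np.ones((1, N))
        occ_vol = self.occupancy[:, :n_v]

        def rhs(t, y):
            Yv = np.clip(y[: n_v * N].reshape(n_v, N), 0.0, _CONC_CAP)
            sig = np.clip(y[n_v * N:], 0.0, _CONC_CAP)
            # bulk chemistry at every node
            ya = np.vstack((Yv, ones_row))
            free = self.free_sites(pool_totals_volume, Yv, occupancy=occ_vol)
            rates_b = self._rates(bulk, ya, free)
            dY = Sb @ rates_b
            # diffusion (zero-flux at both ends)
            lap = np.empty_like(Yv)
            lap[:, 1:-1] = Yv[:, :-2] - 2.0 * Yv[:, 1:-1] + Yv[:, 2:]
            lap[:, 0] = Yv[:, 1] - Yv[:, 0]
            lap[:, -1] = Yv[:, -2] - Yv[:, -1]
            dY += D_over_h2[:, None] * lap
            # boundary chemistry at the activation surface (node 0)
            z = np.concatenate((Yv[:, 0], sig))
            za = np.append(z, 1.0)
            free_act = self.free_sites(activator_totals, z)
            rates_d = self._rates(bnd, za, free_act)
            dz = Sd @ rates_d
            dY[:, 0] += conv * dz[:n_v]
            return np.concatenate((dY.ravel(), dz[n_v:]))

        return rhs

    # -- jacobian sparsity ---------------------------------------------

    def _coupling(self, group, n_local: int) -> sp.csr_matrix:
        """(affected, influencer) pattern of one reaction group."""
        rows, cols = [], []
        S = group["S"].tocoo()
        affected_by_rxn: Dict[int, List[int]] = {}
        for i, j in zip(S.row, S.col):
            affected_by_rxn.setdefault(j, []).append(i)
        influencers_by_rxn: Dict[int, set] = {}
        for j, r in enumerate(group["reactions"]):
            infl = {group["F"][j, a] for a in range(group["F"].shape[1])}
            infl.discard(n_local)  # dummy
            if r.site_pool is not None:
                pidx = self.pool_index[r.site_pool]
                infl.update(np.nonzero(self.occupancy[pidx])[0].tolist())
            influencers_by_rxn[j] = infl
        for j, affected in affected_by_rxn.items():
            for i in affected:
                for a in influencers_by_rxn.get(j, ()):
                    if a < n_local:
                        rows.append(i)
                        cols.append(a)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n_local, n_local))

    def spatial_jac_sparsity(self, n_nodes: int) -> sp.csr_matrix:
        """Structural Jacobian of the method-of-lines system."""
        n_v, n_u, N = self.n_v, self.n_u, n_nodes
        n_tot = n_v * N + n_u
        P_bulk = self._coupling(self.bulk, n_v).tocoo()
        rows, cols = [], []
        # bulk reactions: same-node coupling
        for i, a in zip(P_bulk.row, P_bulk.col):
            base_i = i * N
            base_a = a * N
            idx = np.arange(N)
            rows.append(base_i + idx)
            cols.append(base_a + idx)
        # diffusion: neighbours and self
        for i in range(n_v):
            base = i * N
            idx = np.arange(N)
            rows.append(base + idx)
            cols.append(base + idx)
            rows.append(base + idx[:-1])
            cols.append(base + idx[1:])
            rows.append(base + idx[1:])
            cols.append(base + idx[:-1])
        rows = [np.concatenate(rows)]
        cols = [np.concatenate(cols)]
        # boundary reactions: coupling within [node-0 volume + surface] block
        P_bnd = self._coupling(self.bnd, self.n_s).tocoo()

        def zidx(i: int) -> int:
            return i * N if i < n_v else n_v * N + (i - n_v)

        rows.append(np.array([zidx(i) for i in P_bnd.row], dtype=int))
        cols.append(np.array([zidx(a) for a in P_bnd.col], dtype=int))
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        return sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(n_tot, n_tot))

    # -- analytic Jacobians ---------------------------------------------

    def _jac_terms(self, group, ya, free_sites, site_base):
        """Per-reaction derivative terms d(rate_j)/d(y_a).

        Returns a list of (slot_species (n_r,), values (n_r,) or (n_r, N))
        pairs plus site-competition terms.  ``ya`` is the augmented
        concentration array, ``site_base`` the rates without the
        free-site factor (for the occupancy derivative).
        """
        F = group["F"]
        n_r, max_ord = F.shape
        k = group["k"]
        fac = ya[F]
        mm_mask = np.zeros(n_r, dtype=bool)
        mm_mask[group["mm_rows"]] = True
        site_factor = np.ones_like(fac[:, 0])
        if group["site_rows"].size and free_sites is not None:
            site_factor = np.ones(fac.shape[0::2] if fac.ndim == 3 else n_r)
            if fac.ndim == 3:
                site_factor = np.ones((n_r, fac.shape[2]))
            site_factor[group["site_rows"]] = free_sites[group["site_pool"]]

        terms = []
        for s_ in range(max_ord):
            others = [o for o in range(max_ord) if o != s_]
            d = k if fac.ndim == 2 else k[:, None]
            d = d * site_factor
            for o in others:
                d = d * fac[:, o]
            # mm rows handled separately; dummy slots dropped by caller
            terms.append((F[:, s_], np.where(mm_mask if d.ndim == 1
                                             else mm_mask[:, None], 0.0, d)))
        # Michaelis rows: slots are (enzyme, substrate)
        mm = group["mm_rows"]
        if mm.size:
            km = group["mm_km"]
            sub = np.clip(ya[group["mm_sub"]], 0.0, None)
            enz = fac[mm, 0]
            kmm = k[mm] if sub.ndim == 1 else k[mm, None]
            sf = site_factor[mm]
            if sub.ndim == 2:
                km = km[:, None]
            denom = km + sub
            d_enz = kmm * sf * sub / denom
            d_sub = kmm * sf * enz * km / denom**2
            terms.append(("mm_enz", mm, F[mm, 0], d_enz, F[mm, 1], d_sub))
        return terms, site_factor

    def homogeneous_jac(self, pool_totals: np.ndarray):
        """Dense analytic Jacobian of the well-mixed system."""
        group = self.hom
        S = group["S"].tocsc()
        n = self.n_s
        F = group["F"]
        dummy = n
        occ = self.occupancy

        def jac(t, y):
            yc = np.clip(y, 0.0, _CONC_CAP)
            ya = np.append(yc, 1.0)
            free = self.free_sites(pool_totals, yc)
            J = np.zeros((n, n))
            dR = np.zeros((len(group["reactions"]), n))
            terms, site_factor = self._jac_terms(group, ya, free, None)
            for term in terms:
                if isinstance(term[0], str):
                    _, mm, a_e, d_e, a_s, d_s = term
                    for jj, ae, de, as_, ds in zip(mm, a_e, d_e, a_s, d_s):
                        if ae < n:
                            dR[jj, ae] += de
                        if as_ < n:
                            dR[jj, as_] += ds
                    continue
                cols, vals = term
                valid = cols < dummy
                for jj in np.nonzero(valid)[0]:
                    dR[jj, cols[jj]] += vals[jj]
            # site-competition: occupancy reduces free sites (derivative
            # vanishes where the pool is saturated and free sites clip to 0)
            if group["site_rows"].size:
                fac = ya[F]
                base = group["k"] * fac.prod(axis=1)
                for jj, pidx in zip(group["site_rows"], group["site_pool"]):
                    if free[pidx] <= 0.0:
                        continue
                    bound = np.nonzero(occ[pidx, :n])[0]
                    dR[jj, bound] += -occ[pidx, bound] * base[jj]
            J = S @ dR
            return J

        return jac

    def spatial_jac(self, pool_totals_volume: np.ndarray,
                    activator_totals: np.ndarray, n_nodes: int, dx_m: float):
        """Sparse analytic Jacobian of the method-of-lines system."""
        n_v, n_u, N = self.n_v, self.n_u, n_nodes
        n_tot = n_v * N + n_u
        bulk, bnd = self.bulk, self.bnd
        Sb = bulk["S"].tocoo()
        Sd = bnd["S"].tocoo()
        D_over_h2 = self.diffusion / dx_m**2
        conv = _NMOL_M3_TO_NM / dx_m
        occ_vol = self.occupancy[:, :n_v]
        occ_all = self.occupancy
        idx_N = np.arange(N)

        # precompute static index lists
        bulk_rows_by_rxn = {}
        for i, j, v in zip(Sb.row, Sb.col, Sb.data):
            bulk_rows_by_rxn.setdefault(j, []).append((i, v))
        bnd_rows_by_rxn = {}
        for i, j, v in zip(Sd.row, Sd.col, Sd.data):
            bnd_rows_by_rxn.setdefault(j, []).append((i, v))

        def zidx(i):
            return i * N if i < n_v else n_v * N + (i - n_v)

        def jac(t, y):
            Yv = np.clip(y[: n_v * N].reshape(n_v, N), 0.0, _CONC_CAP)
            sig = np.clip(y[n_v * N:], 0.0, _CONC_CAP)
            rows, cols, data = [], [], []

            # bulk chemistry, vectorized across nodes
            ya = np.vstack((Yv, np.ones((1, N))))
            free = self.free_sites(pool_totals_volume, Yv, occupancy=occ_vol)
            terms, _ = self._jac_terms(bulk, ya, free, None)
            dummy = n_v
            for term in terms:
                if isinstance(term[0], str):
                    _, mm, a_e, d_e, a_s, d_s = term
                    for t_i in range(len(mm)):
                        jj = mm[t_i]
                        for i, v in bulk_rows_by_rxn.get(jj, ()):
                            if a_e[t_i] < dummy:
                                rows.append(i * N + idx_N)
                                cols.append(a_e[t_i] * N + idx_N)
                                data.append(v * d_e[t_i])
                            if a_s[t_i] < dummy:
                                rows.append(i * N + idx_N)
                                cols.append(a_s[t_i] * N + idx_N)
                                data.append(v * d_s[t_i])
                    continue
                cc, vals = term
                for jj in range(len(cc)):
                    if cc[jj] >= dummy:
                        continue
                    for i, v in bulk_rows_by_rxn.get(jj, ()):
                        rows.append(i * N + idx_N)
                        cols.append(cc[jj] * N + idx_N)
                        data.append(v * vals[jj])
            # bulk site-competition derivatives (zero where pool saturated)
            if bulk["site_rows"].size:
                fac = ya[bulk["F"]]
                base = bulk["k"][:, None] * fac.prod(axis=1)
                open_sites = free > 0.0
                for jj, pidx in zip(bulk["site_rows"], bulk["site_pool"]):
                    bound = np.nonzero(occ_vol[pidx])[0]
                    masked = (-1.0) * base[jj] * open_sites[pidx]
                    for b in bound:
                        for i, v in bulk_rows_by_rxn.get(jj, ()):
                            rows.append(i * N + idx_N)
                            cols.append(b * N + idx_N)
                            data.append(v * occ_vol[pidx, b] * masked)

            # diffusion
            for i in range(n_v):
                d = D_over_h2[i]
                if d == 0:
                    continue
                base = i * N
                main = np.full(N, -2.0 * d)
                main[0] = -d
                main[-1] = -d
                rows.append(base + idx_N); cols.append(base + idx_N); data.append(main)
                rows.append(base + idx_N[:-1]); cols.append(base + idx_N[1:]); data.append(np.full(N - 1, d))
                rows.append(base + idx_N[1:]); cols.append(base + idx_N[:-1]); data.append(np.full(N - 1, d))

            # boundary chemistry at node 0
            z = np.concatenate((Yv[:, 0], sig))
            za = np.append(z, 1.0)
            free_act = self.free_sites(activator_totals, z, occupancy=occ_all)
            terms_d, _ = self._jac_terms(bnd, za, free_act, None)
            dummy_d = self.n_s

            def add_bnd(jj, col_local, dval):
                for i, v in bnd_rows_by_rxn.get(jj, ()):
                    scale = conv if i < n_v else 1.0
                    rows.append(np.array([zidx(i)]))
                    cols.append(np.array([zidx(col_local)]))
                    data.append(np.array([v * dval * scale]))

            for term in terms_d:
                if isinstance(term[0], str):
                    _, mm, a_e, d_e, a_s, d_s = term
                    for t_i in range(len(mm)):
                        jj = mm[t_i]
                        if a_e[t_i] < dummy_d:
                            add_bnd(jj, a_e[t_i], d_e[t_i])
                        if a_s[t_i] < dummy_d:
                            add_bnd(jj, a_s[t_i], d_s[t_i])
                    continue
                cc, vals = term
                for jj in range(len(cc)):
                    if cc[jj] < dummy_d:
                        add_bnd(jj, cc[jj], vals[jj])
            if bnd["site_rows"].size:
                fac = za[bnd["F"]]
                base = bnd["k"] * fac.prod(axis=1)
                for jj, pidx in zip(bnd["site_rows"], bnd["site_pool"]):
                    if free_act[pidx] <= 0.0:
                        continue
                    bound = np.nonzero(occ_all[pidx])[0]
                    for b in bound:
                        add_bnd(jj, b, -occ_all[pidx, b] * base[jj])

            r = np.concatenate(rows)
            c = np.concatenate(cols)
            d = np.concatenate(data)
            return sp.csc_matrix((d, (r, c)), shape=(n_tot, n_tot))

        return jac

    # -- observables ----------------------------------------------------

    def observable_weights(self, name: str) -> np.ndarray:
        w = np.zeros(self.n_s)
        for sid, coef in self.network.observables[name].items():
            w[self.gidx[sid]] = coef
        return w
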