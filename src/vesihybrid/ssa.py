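"""Voxel-based stochastic reaction-diffusion engine.

Gillespie's direct method over tetrahedral voxels, with diffusion treated
as first-order inter-voxel events at the finite-volume rate

    d*_{k,l} = D_i A_{k,l} / (V*_k dx_{k,l})

where V*_k is the tet volume reduced by vesicle occupancy.  Second-order
reaction propensities use the analogous reduced-volume rate constant

    c* = K / (N_A V*_j)

so the space vesicles occupy is not part of the well-mixed voxel volume;
unimolecular rates are unaffected.  Diffusion into a fully overlapped
voxel is forbidden, and as V*_k -> 0 the outbound rate is capped at the
value for V*_k = 1e-3 V_k so event timestamps stay finite.

For pure-diffusion occupancy statistics the module also provides
``diffusion_occupancy``: molecules do not interact under pure diffusion,
so the product CTMC factorizes and can be propagated for all molecules at
once by uniformization of the same d* rates.  This is statistically
identical to the event loop and orders of magnitude faster, which the
binomial-occupancy validation needs for its noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AVOGADRO", "Species", "Reaction", "TetSsa",
    "corrected_diffusion_rate", "corrected_reaction_propensity",
    "second_order_rate", "diffusion_occupancy", "binomial_fit_error",
    "FULL_OVERLAP_FRACTION", "RATE_CAP_FRACTION",
]

AVOGADRO = 6.02214076e23

#: below this fraction of the full tet volume a voxel counts as fully
#: overlapped: diffusion into it is forbidden
FULL_OVERLAP_FRACTION = 1e-9
#: the V* used in outbound-rate denominators is floored at this fraction
#: of the full tet volume (the "high rate" stand-in for V* -> 0)
RATE_CAP_FRACTION = 1e-3


@dataclass
class Species:
    """A point-molecule species.  ``D`` is the macroscopic diffusion
    coefficient in m^2/s (may be overridden per compartment/patch by the
    model layer)."""
    name: str
    D: float = 0.0

    def __post_init__(self):
        if self.D < 0:
            raise ValueError(f"species {self.name}: D must be >= 0")


@dataclass
class Reaction:
    """A volume reaction (order <= 2) in a compartment, or a surface
    reaction coupling patch-triangle species with the owning tet.

    ``reactants``/``products`` map species name -> stoichiometry.  Species
    in ``surface_reactants``/``surface_products`` live on patch triangles.
    ``rate`` is K in s^-1 (first order) or M^-1 s^-1 (second order).
    """
    name: str
    rate: float
    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    surface_reactants: dict[str, int] = field(default_factory=dict)
    surface_products: dict[str, int] = field(default_factory=dict)
    compartment: str | None = None
    patch: str | None = None

    @property
    def order(self) -> int:
        return sum(self.reactants.values()) + sum(self.surface_reactants.values())

    def __post_init__(self):
        if self.order > 2:
            raise ValueError(f"reaction {self.name}: order > 2 unsupported")
        if self.rate < 0:
            raise ValueError(f"reaction {self.name}: negative rate")


def corrected_diffusion_rate(D: float, A_kl: float, V_star: float,
                             dx_kl: float, V_full: float | None = None
                             ) -> float:
    """Vesicle-occupancy-corrected inter-voxel diffusion rate d* (1/s).

    With zero occupancy this is the classic finite-volume rate
    D A / (V dx); reduced source volume raises the rate proportionally.
    At V* -> 0 the rate is capped at the V* = RATE_CAP_FRACTION * V value
    (requires ``V_full``).
    """
    if D < 0 or A_kl < 0 or dx_kl <= 0 or V_star < 0:
        raise ValueError("negative input to corrected_diffusion_rate")
    floor = RATE_CAP_FRACTION * V_full if V_full is not None else 0.0
    v = max(V_star, floor)
    if v <= 0.0:
        raise ValueError("V* = 0 requires V_full for the rate cap")
    return D * A_kl / (v * dx_kl)


def second_order_rate(K: float, V_star: float) -> float:
    """c* = K / (N_A V*): stochastic rate constant (1/s) of a
    second-order reaction with K in M^-1 s^-1 and V* in m^3."""
    if V_star <= 0.0:
        return 0.0
    return K / (AVOGADRO * V_star * 1e3)   # V* m^3 -> liters


def corrected_reaction_propensity(rule: Reaction, counts: dict[str, int],
                                  V_star: float) -> float:
    """Propensity (1/s) of ``rule`` in a voxel with the given species
    counts and reduced volume.  First-order rules use K unchanged;
    second-order rules use c* = K/(N_A V*) times the distinct reactant
    pair count.  V* = 0 forces zero (no reactants can be present)."""
    order = rule.order
    names = {**rule.reactants, **rule.surface_reactants}
    if order == 0:
        return rule.rate
    if order == 1:
        (name, _), = names.items()
        return rule.rate * counts.get(name, 0)
    if V_star <= 0.0:
        return 0.0
    c = second_order_rate(rule.rate, V_star)
    if len(names) == 2:
        a, b = names
        return c * counts.get(a, 0) * counts.get(b, 0)
    (name, _), = names.items()
    n = counts.get(name, 0)
    return c * n * (n - 1) / 2.0


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class TetSsa:
    """Direct-method SSA over the tets (and patch triangles) of a mesh.

    Diffusion propensities are maintained incrementally; reaction and
    injected kinetic-process channels are refreshed after every firing
    (their numbers are small in the models this engine targets).
    External code must call :meth:`set_occupancy` and
    :meth:`refresh_propensities` whenever vesicle state changes.
    """

    def __init__(self, mesh, species: list[Species],
                 reactions: list[Reaction] = ()):
        self.mesh = mesh
        self.species = list(species)
        self.s_index = {s.name: i for i, s in enumerate(self.species)}
        ns = len(self.species)
        self.counts = np.zeros((mesh.n_tets, ns), dtype=np.int64)
        self.tri_counts = np.zeros((mesh.n_tris, ns), dtype=np.int64)
        self.V_star = mesh.tet_volume.copy()
        self.time = 0.0
        self.reactions = list(reactions)
        self.extra_channels: list = []   # kinetic processes (duck-typed)
        self._neighbor_ok = mesh.tet_neighbors >= 0
        self._build_diffusion()
        self._rxn_locs = [self._reaction_locations(r) for r in self.reactions]

    # -- setup ---------------------------------------------------------
    def _build_diffusion(self):
        mesh = self.mesh
        self._diff_species = [i for i, s in enumerate(self.species)
                              if s.D > 0.0]
        # d_base[k, f] = A_{k,l} / dx_{k,l}, 0 on boundary faces
        with np.errstate(invalid="ignore", divide="ignore"):
            base = np.where(self._neighbor_ok,
                            mesh.face_area / mesh.neighbor_dx, 0.0)
        base = np.nan_to_num(base)
        self._d_base = base
        self._update_diffusion_rates()

    def _update_diffusion_rates(self):
        mesh = self.mesh
        vfull = mesh.tet_volume
        v_eff = np.maximum(self.V_star, RATE_CAP_FRACTION * vfull)
        dest = mesh.tet_neighbors
        dest_blocked = np.zeros_like(self._d_base, dtype=bool)
        ok = self._neighbor_ok
        dest_v = np.where(ok, self.V_star[np.where(ok, dest, 0)], 1.0)
        dest_full = np.where(ok, mesh.tet_volume[np.where(ok, dest, 0)], 1.0)
        dest_blocked = ok & (dest_v <= FULL_OVERLAP_FRACTION * dest_full)
        # per-species rate per face: D * A/dx / V*_k, zero to blocked dest
        rates = self._d_base / v_eff[:, None]
        rates = np.where(dest_blocked, 0.0, rates)
        self._face_rates = rates                       # (n_tet, 4), per D=1
        self._out_rate = rates.sum(axis=1)             # (n_tet,)

    def _reaction_locations(self, r: Reaction) -> np.ndarray:
        mesh = self.mesh
        if r.patch is not None:
            return np.asarray(mesh.patches[r.patch].tris, int)
        if r.compartment is not None:
            return np.asarray(mesh.compartments[r.compartment].tets, int)
        return np.arange(mesh.n_tets)

    # -- state manipulation -------------------------------------------
    def set_counts(self, species: str, where, n: int, *, surface=False):
        arr = self.tri_counts if surface else self.counts
        arr[where, self.s_index[species]] = n

    def add_count(self, species: str, where, dn: int, *, surface=False):
        arr = self.tri_counts if surface else self.counts
        arr[where, self.s_index[species]] += dn
        if arr[where, self.s_index[species]] < 0:
            raise RuntimeError("negative species count")

    def distribute(self, species: str, n: int, rng, compartment=None,
                   weights=None):
        """Place n molecules multinomially over tets, weighted by V*."""
        tets = (np.arange(self.mesh.n_tets) if compartment is None
                else np.asarray(self.mesh.compartments[compartment].tets))
        w = self.V_star[tets] if weights is None else np.asarray(weights)
        p = w / w.sum()
        placed = rng.multinomial(n, p)
        self.counts[tets, self.s_index[species]] += placed

    def total(self, species: str) -> int:
        i = self.s_index[species]
        return int(self.counts[:, i].sum() + self.tri_counts[:, i].sum())

    def set_occupancy(self, overlap_by_tet: dict[int, float] | np.ndarray):
        """Set vesicle overlap volumes per tet; V* = V - overlap."""
        if isinstance(overlap_by_tet, dict):
            occ = np.zeros(self.mesh.n_tets)
            for k, v in overlap_by_tet.items():
                occ[k] = v
        else:
            occ = np.asarray(overlap_by_tet, float)
        self.V_star = np.clip(self.mesh.tet_volume - occ, 0.0, None)
        self._update_diffusion_rates()

    def refresh_propensities(self):
        """Recompute diffusion rate tables (call after set_occupancy or a
        vesicle-state change that affects channel propensities)."""
        self._update_diffusion_rates()

    # -- propensities --------------------------------------------------
    def _reaction_propensities(self, r: Reaction, locs: np.ndarray
                               ) -> np.ndarray:
        order = r.order
        if r.patch is None:
            vol = np.maximum(self.V_star[locs], 0.0)
            get = lambda name: self.counts[locs, self.s_index[name]]
        else:
            own = self.mesh.tri_owner[locs]
            vol = np.maximum(self.V_star[own], 0.0)

            def get(name, _own=own, _locs=locs):
                if name in r.surface_reactants:
                    return self.tri_counts[_locs, self.s_index[name]]
                return self.counts[_own, self.s_index[name]]
        names = list(r.reactants) + list(r.surface_reactants)
        stoich = {**r.reactants, **r.surface_reactants}
        if order == 1:
            return r.rate * get(names[0]).astype(float)
        with np.errstate(divide="ignore"):
            c = np.where(vol > 0, r.rate / (AVOGADRO * vol * 1e3), 0.0)
        if len(names) == 2:
            return c * get(names[0]) * get(names[1])
        n = get(names[0])
        return c * n * (n - 1) / 2.0

    def _execute_reaction(self, r: Reaction, loc: int):
        if r.patch is None:
            for name, st in r.reactants.items():
                self.counts[loc, self.s_index[name]] -= st
            for name, st in r.products.items():
                self.counts[loc, self.s_index[name]] += st
        else:
            own = self.mesh.tri_owner[loc]
            for name, st in r.reactants.items():
                self.counts[own, self.s_index[name]] -= st
            for name, st in r.products.items():
                self.counts[own, self.s_index[name]] += st
            for name, st in r.surface_reactants.items():
                self.tri_counts[loc, self.s_index[name]] -= st
            for name, st in r.surface_products.items():
                self.tri_counts[loc, self.s_index[name]] += st
        if (self.counts < 0).any() or (self.tri_counts < 0).any():
            raise RuntimeError(f"negative count after reaction {r.name}")

    # -- main loop -----------------------------------------------------
    def advance(self, until: float, rng) -> None:
        """Exact SSA to ``until`` (direct method).

        Diffusion propensities are maintained incrementally across
        diffusion hops and rebuilt after any reaction or kinetic-process
        firing (those are rare relative to hops)."""
        if until < self.time:
            raise ValueError("until must be >= current time")
        mesh = self.mesh
        nb = mesh.tet_neighbors
        sidx = self._diff_species
        nd = len(sidx)
        D = [self.species[i].D for i in sidx]
        out_rate = self._out_rate
        # occupied diffusion sites: (tet, diff-species) pairs with
        # counts > 0 -- propensity vectors stay O(number of molecules)
        site_k: list[int] = []
        site_s: list[int] = []
        site_p: list[float] = []
        site_pos: dict[tuple[int, int], int] = {}
        rebuild = True
        since_rebuild = 0

        def _rebuild_sites():
            site_k.clear()
            site_s.clear()
            site_p.clear()
            site_pos.clear()
            tot = 0.0
            for d_i, s in enumerate(sidx):
                ks = np.flatnonzero(self.counts[:, s])
                for k in ks:
                    k = int(k)
                    p = float(self.counts[k, s]) * out_rate[k] * D[d_i]
                    site_pos[(k, d_i)] = len(site_k)
                    site_k.append(k)
                    site_s.append(d_i)
                    site_p.append(p)
                    tot += p
            return tot

        def _site_add(k, d_i, delta):
            nonlocal p_diff_tot
            key = (k, d_i)
            pos = site_pos.get(key)
            dp = delta * out_rate[k] * D[d_i]
            if pos is None:
                site_pos[key] = len(site_k)
                site_k.append(k)
                site_s.append(d_i)
                site_p.append(dp)
            else:
                site_p[pos] += dp
                if self.counts[k, sidx[d_i]] == 0:
                    # swap-pop the emptied site
                    last = len(site_k) - 1
                    site_pos.pop(key)
                    if pos != last:
                        site_k[pos] = site_k[last]
                        site_s[pos] = site_s[last]
                        site_p[pos] = site_p[last]
                        site_pos[(site_k[pos], site_s[pos])] = pos
                    site_k.pop()
                    site_s.pop()
                    site_p.pop()
            p_diff_tot += dp

        p_diff_tot = 0.0
        while True:
            if rebuild or since_rebuild > 200_000:
                p_diff_tot = _rebuild_sites() if nd else 0.0
                rebuild = False
                since_rebuild = 0
            p_rxn = [self._reaction_propensities(r, locs)
                     for r, locs in zip(self.reactions, self._rxn_locs)]
            p_rxn_tot = [float(p.sum()) for p in p_rxn]
            p_extra = [max(ch.propensity(self), 0.0)
                       for ch in self.extra_channels]
            total = p_diff_tot + sum(p_rxn_tot) + sum(p_extra)
            if total <= 0.0:
                self.time = until
                return
            dt = rng.exponential(1.0 / total)
            if self.time + dt > until:
                self.time = until
                return
            self.time += dt
            since_rebuild += 1
            u = rng.random() * total
            if u < p_diff_tot:
                acc = 0.0
                pos = len(site_p) - 1
                for i, p in enumerate(site_p):
                    acc += p
                    if u < acc:
                        pos = i
                        break
                k = site_k[pos]
                d_i = site_s[pos]
                s = sidx[d_i]
                w = self._face_rates[k]
                wsum = w[0] + w[1] + w[2] + w[3]
                uu = rng.random() * wsum
                if uu < w[0]:
                    f = 0
                elif uu < w[0] + w[1]:
                    f = 1
                elif uu < w[0] + w[1] + w[2]:
                    f = 2
                else:
                    f = 3
                l = int(nb[k, f])
                self.counts[k, s] -= 1
                self.counts[l, s] += 1
                _site_add(k, d_i, -1)
                _site_add(l, d_i, +1)
                continue
            u -= p_diff_tot
            fired = False
            for r, locs, p, ptot in zip(self.reactions, self._rxn_locs,
                                        p_rxn, p_rxn_tot):
                if u < ptot:
                    j = int(np.searchsorted(np.cumsum(p), u))
                    j = min(j, len(p) - 1)
                    self._execute_reaction(r, int(locs[j]))
                    fired = True
                    break
                u -= ptot
            if fired:
                rebuild = True
                continue
            for ch, p in zip(self.extra_channels, p_extra):
                if u < p:
                    ch.execute(self, rng)
                    # a kinetic process may have moved surface molecules
                    # other channels have cached; re-sync them all
                    for ch2 in self.extra_channels:
                        ch2.sync(self)
                    fired = True
                    break
                u -= p
            rebuild = True


# ---------------------------------------------------------------------------
# vectorized pure-diffusion occupancy sampler
# ---------------------------------------------------------------------------

def diffusion_occupancy(mesh, V_star, D: float, n_molecules: int,
                        rng, *, relax_rounds: int = 200,
                        sample_rounds: int = 2000, thin: int = 1
                        ) -> np.ndarray:
    """Time-averaged occupancy probability per tet of molecules diffusing
    with the corrected rates d* = D A / (V* dx).

    Molecules are independent under pure diffusion, so all are propagated
    at once by the uniformized jump chain of the same CTMC the event-loop
    engine simulates (transition matrix P = I + Q/Lambda, which shares the
    CTMC's stationary law).  Occupancy is accumulated every ``thin``-th
    round after ``relax_rounds`` burn-in rounds.

    Returns ``p_hat`` of shape (n_tets,), the mean occupancy fraction.
    """
    V_star = np.asarray(V_star, float)
    vfull = mesh.tet_volume
    v_eff = np.maximum(V_star, RATE_CAP_FRACTION * vfull)
    ok = mesh.tet_neighbors >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        base = np.where(ok, mesh.face_area / mesh.neighbor_dx, 0.0)
    base = np.nan_to_num(base)
    dest = np.where(ok, mesh.tet_neighbors, 0)
    blocked = ok & (V_star[dest] <= FULL_OVERLAP_FRACTION * vfull[dest])
    rates = np.where(blocked, 0.0, D * base / v_eff[:, None])
    out = rates.sum(axis=1)
    if out.max() <= 0.0:
        raise ValueError("no diffusion possible (D = 0 or single tet)")
    # embedded jump chain with exponential dwell weighting: every round
    # is one jump per molecule, and the time average over dwells is the
    # stationary occupancy estimator
    with np.errstate(divide="ignore"):
        inv_out = np.where(out > 0, 1.0 / out, 0.0)
    cum = np.cumsum(rates, axis=1)
    cum = cum / np.maximum(cum[:, -1:], 1e-300)
    dest_tab = np.where(ok, mesh.tet_neighbors,
                        np.arange(mesh.n_tets)[:, None])

    open_tets = np.flatnonzero(V_star > FULL_OVERLAP_FRACTION * vfull)
    p0 = V_star[open_tets] / V_star[open_tets].sum()
    state = rng.choice(open_tets, size=n_molecules, p=p0)

    acc = np.zeros(mesh.n_tets)
    total_rounds = relax_rounds + sample_rounds
    for rnd in range(total_rounds):
        if rnd >= relax_rounds:
            dwell = rng.standard_exponential(n_molecules) * inv_out[state]
            acc += np.bincount(state, weights=dwell,
                               minlength=mesh.n_tets)
        u = rng.random(n_molecules)
        f = (u[:, None] > cum[state]).sum(axis=1)
        state = dest_tab[state, np.minimum(f, 3)]
    return acc / acc.sum()


def binomial_fit_error(p_hat: np.ndarray, V_star: np.ndarray,
                       min_p: float = 0.0) -> float:
    """Maximum relative deviation (in %) of measured per-tet occupancy
    from the binomial expectation p_k = V*_k / sum V*."""
    V_star = np.asarray(V_star, float)
    p = V_star / V_star.sum()
    mask = p > max(min_p, 0.0)
    return float(np.max(np.abs(p_hat[mask] - p[mask]) / p[mask]) * 100.0)
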