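"""Vesicle- and raft-specific kinetic processes inside the SSA.

Each process is an SSA channel with a propensity and an execute action,
injected into the reaction-diffusion engine next to ordinary reactions
and diffusion.  The bookkeeping contract: entities listed as consumed are
decremented, produced entities incremented, and a process has zero
propensity while its species dependencies are unmet or any
anti-dependency is present (at or above its threshold count, default 1).

Channels cache the geometric part of their propensity (which tetrahedron
each vesicle-surface molecule currently falls in, which vesicles are in
reach of a membrane) and must be re-synced via :meth:`sync` whenever
vesicle or raft geometry changes — the simulation loop does this on every
vesicle clock tick and each channel re-syncs itself after firing.

Second-order rates between a vesicle-surface molecule and a cytosolic
molecule use the reduced-volume rate constant c* = K/(N_A V*) of the tet
hosting the surface molecule.  Vesicle binding uses a stochastic per
eligible-pair rate (s^-1), with eligibility meaning the resulting link
length would lie within its bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import point_in_tet
from .ssa import AVOGADRO, second_order_rate
from .vesicles import Vesicle, VesicleState, VesicleType, Link

__all__ = [
    "VesicleSurfaceReaction", "BindingRule", "UnbindingRule",
    "ExocytosisRule", "EndocytosisRule",
    "RaftType", "Raft", "RaftState", "RaftSurfaceReaction",
    "RaftEndocytosis", "RaftGeneration", "RaftDissolution",
    "SurfaceReactionChannel", "BindingChannel", "UnbindingChannel",
    "ExocytosisChannel", "EndocytosisChannel", "RaftReactionChannel",
    "RaftEndocytosisChannel", "RaftGenerationChannel",
    "RaftDissolutionChannel", "raft_step",
]


class ConfigError(Exception):
    pass


def _deps_met(counts: dict[str, int], deps: dict[str, int]) -> bool:
    return all(counts.get(s, 0) >= n for s, n in deps.items())


def _antideps_clear(counts: dict[str, int], anti: dict[str, int]) -> bool:
    return all(counts.get(s, 0) < n for s, n in anti.items())


# ---------------------------------------------------------------------------
# rule definitions
# ---------------------------------------------------------------------------

@dataclass
class VesicleSurfaceReaction:
    """Reaction with reactants on a vesicle surface and optionally in the
    overlapped cytosol or on a membrane patch; products may also appear in
    the vesicle lumen.  Order <= 2.  ``max_distance`` (m) restricts the
    reaction to vesicles whose surface lies within that distance of the
    ``patch``; ``dock_delta`` immobilizes (+1) or mobilizes (-1) the
    vesicle on firing."""
    name: str
    rate: float                       # s^-1 (1st order) or M^-1 s^-1 (2nd)
    vesicle_type: str | None = None
    surface_reactants: dict[str, int] = field(default_factory=dict)
    volume_reactants: dict[str, int] = field(default_factory=dict)
    membrane_reactants: dict[str, int] = field(default_factory=dict)
    surface_products: dict[str, int] = field(default_factory=dict)
    volume_products: dict[str, int] = field(default_factory=dict)
    lumen_products: dict[str, int] = field(default_factory=dict)
    membrane_products: dict[str, int] = field(default_factory=dict)
    patch: str | None = None
    max_distance: float | None = None
    dock_delta: int = 0

    @property
    def order(self) -> int:
        return (sum(self.surface_reactants.values())
                + sum(self.volume_reactants.values())
                + sum(self.membrane_reactants.values()))

    def __post_init__(self):
        if self.order > 2:
            raise ConfigError(f"{self.name}: order > 2 unsupported")
        if self.max_distance is not None and self.max_distance < 0:
            raise ConfigError(f"{self.name}: negative max_distance")
        if (self.membrane_reactants or self.membrane_products or
                self.max_distance is not None) and self.patch is None:
            raise ConfigError(f"{self.name}: membrane terms require a patch")


@dataclass
class BindingRule:
    """Vesicle binding: a surface species on each of two vesicles becomes
    a link species pair, permitted only when the resulting link length is
    within [l_min, l_max].  ``rate`` is the stochastic rate per eligible
    pair (s^-1)."""
    name: str
    species_a: str
    species_b: str
    link_species: str
    rate: float
    l_min: float
    l_max: float

    def __post_init__(self):
        if not (0 < self.l_min < self.l_max):
            raise ConfigError(f"{self.name}: need 0 < l_min < l_max")


@dataclass
class UnbindingRule:
    """Reverse of binding: a link dissolves back into the two surface
    species at its endpoint positions; ``rate`` per link (s^-1)."""
    name: str
    link_species: str
    species_a: str
    species_b: str
    rate: float


@dataclass
class ExocytosisRule:
    """Fusion of a vesicle with a membrane patch.

    ``mode="full_collapse"``: vesicle removed, surface species deposited
    on the nearest overlapped patch triangles (or into a newly created
    raft if ``raft_type`` is set), luminal species released to the outer
    compartment if one is declared, else tallied in the released ledger.
    ``mode="preserve"`` (kiss-and-run / open-closed): the vesicle remains;
    a binomial ``release_fraction`` of each luminal species is released,
    and the vesicle is undocked if ``undock`` is true."""
    name: str
    rate: float
    patch: str
    mode: str = "full_collapse"
    release_fraction: float = 1.0
    dependencies: dict[str, int] = field(default_factory=dict)
    anti_dependencies: dict[str, int] = field(default_factory=dict)
    vesicle_type: str | None = None
    max_distance: float | None = None
    raft_type: str | None = None
    undock: bool = True

    def __post_init__(self):
        if not 0.0 <= self.release_fraction <= 1.0:
            raise ConfigError(f"{self.name}: release fraction not in [0,1]")
        if self.mode not in ("full_collapse", "preserve"):
            raise ConfigError(f"{self.name}: unknown mode {self.mode!r}")
        if self.mode == "full_collapse":
            self.release_fraction = 1.0
        if self.raft_type is not None and self.mode == "preserve":
            raise ConfigError(f"{self.name}: raft creation requires "
                              "full-collapse fusion")


@dataclass
class EndocytosisRule:
    """Vesicle creation from an endocytic zone (set of patch triangles).

    The propensity is ``rate`` times the number of complete dependency
    sets present on the zone triangles (so each event internalizes one
    dependency set and the dependent species decays exponentially); with
    no dependencies the propensity is just ``rate``.  On firing, the
    spherical space just inside the zone is reserved; if it is blocked by
    another vesicle the attempt is rejected.  All species on the zone
    triangles move onto the new vesicle's surface, positioned by radial
    projection from their triangles."""
    name: str
    zone: str
    rate: float
    vesicle_type: str = ""
    dependencies: dict[str, int] = field(default_factory=dict)
    anti_dependencies: dict[str, int] = field(default_factory=dict)


@dataclass
class RaftType:
    name: str
    radius: float
    D: float = 0.0                 # surface diffusion coefficient m^2/s

    def __post_init__(self):
        if self.radius <= 0 or self.D < 0:
            raise ConfigError(f"raft type {self.name}: bad radius or D")


class Raft:
    """A membrane raft: an exclusive fixed-radius subdomain anchored on a
    surface triangle with well-mixed surface counts.  Raft molecules have
    no exact position; for SSA coupling they are sampled into the raft's
    overlap triangles."""

    def __init__(self, rid: int, rtype: RaftType, anchor_tri: int, mesh):
        self.id = rid
        self.rtype = rtype
        self.anchor_tri = int(anchor_tri)
        self.counts: dict[str, int] = {}
        self.overlap_tris: list[int] = []
        self._grow_overlap(mesh)

    def _grow_overlap(self, mesh):
        """Geodesic growth over triangle adjacency from the anchor: every
        triangle whose barycenter lies within the raft radius."""
        c = mesh.tri_barycenter[self.anchor_tri]
        r = self.rtype.radius
        seen = {self.anchor_tri}
        out = [self.anchor_tri]
        frontier = [self.anchor_tri]
        while frontier:
            nxt = []
            for t in frontier:
                for nb in mesh.tri_neighbors[t]:
                    if nb >= 0 and nb not in seen:
                        seen.add(int(nb))
                        if np.linalg.norm(mesh.tri_barycenter[nb] - c) <= r:
                            out.append(int(nb))
                            nxt.append(int(nb))
            frontier = nxt
        self.overlap_tris = sorted(out)


class RaftState:
    """All rafts plus the triangle registry enforcing exclusivity."""

    def __init__(self, mesh):
        self.mesh = mesh
        self.rafts: dict[int, Raft] = {}
        self.tri_raft: dict[int, int] = {}
        self._next_id = 0

    def add_raft(self, rtype: RaftType, anchor_tri: int) -> Raft | None:
        raft = Raft(self._next_id, rtype, anchor_tri, self.mesh)
        for t in raft.overlap_tris:
            if t in self.tri_raft:
                return None
        self._next_id += 1
        self.rafts[raft.id] = raft
        for t in raft.overlap_tris:
            self.tri_raft[t] = raft.id
        return raft

    def remove_raft(self, rid: int) -> Raft:
        raft = self.rafts.pop(rid)
        for t in raft.overlap_tris:
            self.tri_raft.pop(t, None)
        return raft

    def move_raft(self, rid: int, new_anchor: int) -> bool:
        raft = self.rafts[rid]
        old_anchor = raft.anchor_tri
        old_tris = raft.overlap_tris
        for t in old_tris:
            self.tri_raft.pop(t, None)
        raft.anchor_tri = int(new_anchor)
        raft._grow_overlap(self.mesh)
        if any(t in self.tri_raft for t in raft.overlap_tris):
            raft.anchor_tri = old_anchor
            raft.overlap_tris = old_tris
            for t in old_tris:
                self.tri_raft[t] = rid
            return False
        for t in raft.overlap_tris:
            self.tri_raft[t] = rid
        return True


def _shared_edge_length(mesh, t0: int, t1: int) -> float:
    a = set(mesh.surface_tris[t0].tolist())
    b = set(mesh.surface_tris[t1].tolist())
    shared = list(a & b)
    if len(shared) != 2:
        return 0.0
    return float(np.linalg.norm(mesh.vertices[shared[0]]
                                - mesh.vertices[shared[1]]))


def raft_step(rafts: RaftState, dt: float, rng) -> None:
    """Advance raft anchors for one vesicle clock tick.

    The anchor hops between adjacent surface triangles with the 2D
    finite-volume rate D L_{k,l} / (A_k dx_{k,l}) (L the shared edge
    length); each raft's hop chain is simulated exactly over dt, with
    hops that would violate raft-raft exclusivity rejected."""
    mesh = rafts.mesh
    order = list(rafts.rafts)
    rng.shuffle(order)
    for rid in order:
        raft = rafts.rafts[rid]
        D = raft.rtype.D
        if D <= 0.0:
            continue
        t = 0.0
        while True:
            k = raft.anchor_tri
            nbs = [int(nb) for nb in mesh.tri_neighbors[k] if nb >= 0]
            if not nbs:
                break
            rates = np.array([
                D * _shared_edge_length(mesh, k, nb)
                / (mesh.tri_area[k]
                   * np.linalg.norm(mesh.tri_barycenter[nb]
                                    - mesh.tri_barycenter[k]))
                for nb in nbs])
            total = float(rates.sum())
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= dt:
                break
            j = int(np.searchsorted(np.cumsum(rates),
                                    rng.random() * total))
            rafts.move_raft(rid, nbs[min(j, len(nbs) - 1)])


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

class _Channel:
    """Base: SSA channel over vesicle/raft state (duck-typed for TetSsa)."""

    def sync(self, ssa) -> None:          # geometry re-cache hook
        pass

    def propensity(self, ssa) -> float:
        raise NotImplementedError

    def execute(self, ssa, rng) -> None:
        raise NotImplementedError


def _surface_point_tets(mesh, ves: Vesicle, species: str) -> list[int]:
    """Tet index hosting each surface point of ``species`` (from the
    vesicle's overlap map; ties resolved to the nearest containing tet).

    Candidates are tested nearest-barycenter-first, so the containment
    test almost always succeeds within the first couple of tets even
    when a vesicle overlaps hundreds of them."""
    pts = ves.surface.get(species, ())
    if not pts:
        return []
    tets = np.fromiter(ves.overlap.entries.keys(), dtype=np.int64)
    if len(tets) == 0:
        return [-1] * len(pts)
    bary = mesh.tet_barycenter[tets]
    out = []
    for rel in pts:
        p = ves.center + rel
        d2 = ((bary - p) ** 2).sum(axis=1)
        order = np.argsort(d2)
        found = int(tets[order[0]])
        for j in order:
            k = int(tets[j])
            if point_in_tet(mesh.vertices[mesh.tets[k]], p, tol=1e-7):
                found = k
                break
        out.append(found)
    return out


class SurfaceReactionChannel(_Channel):
    """One VesicleSurfaceReaction summed over all eligible vesicles."""

    def __init__(self, rule: VesicleSurfaceReaction, state: VesicleState):
        self.rule = rule
        self.state = state
        self._per_ves: list[tuple[int, np.ndarray, np.ndarray]] = []
        self._fast = False
        self._pt_tet = np.empty(0, int)
        self._pt_ref: list[tuple[int, int]] = []
        self._c_pt = None

    def _eligible(self, ves: Vesicle) -> bool:
        r = self.rule
        if r.vesicle_type is not None and ves.vtype.name != r.vesicle_type:
            return False
        if r.patch is not None and r.max_distance is not None:
            mesh = self.state.mesh
            tris = mesh.patches[r.patch].tris
            d = np.linalg.norm(mesh.tri_barycenter[tris] - ves.center,
                               axis=1).min()
            if d - ves.radius > r.max_distance:
                return False
        return True

    def sync(self, ssa) -> None:
        r = self.rule
        self._per_ves = []
        # fast path: one surface reactant coupled to at most one volume
        # reactant -- flat per-point arrays, one vector op per propensity
        self._fast = (sum(r.surface_reactants.values()) == 1
                      and not r.membrane_reactants
                      and sum(r.volume_reactants.values()) <= 1)
        if self._fast:
            sp = next(iter(r.surface_reactants))
            pt_tet = []
            pt_ref = []
            for vid, ves in self.state.vesicles.items():
                if not self._eligible(ves):
                    continue
                tets = _surface_point_tets(self.state.mesh, ves, sp)
                for i, k in enumerate(tets):
                    pt_tet.append(k)
                    pt_ref.append((vid, i))
            self._pt_tet = np.asarray(pt_tet, int)
            self._pt_ref = pt_ref
            if r.volume_reactants and len(self._pt_tet):
                vstar = np.maximum(ssa.V_star[self._pt_tet], 0.0)
                with np.errstate(divide="ignore"):
                    self._c_pt = np.where(
                        vstar > 0, r.rate / (AVOGADRO * vstar * 1e3), 0.0)
            else:
                self._c_pt = None
            return
        for vid, ves in self.state.vesicles.items():
            if not self._eligible(ves):
                continue
            if r.surface_reactants:
                sp = next(iter(r.surface_reactants))
                pts = _surface_point_tets(self.state.mesh, ves, sp)
                tets, cnts = np.unique([p for p in pts if p >= 0],
                                       return_counts=True)
            else:
                tets = np.array(list(ves.overlap.entries), int)
                cnts = np.zeros(len(tets))
            self._per_ves.append((vid, tets.astype(int), cnts))

    def _vesicle_propensity(self, ssa, vid, tets, cnts) -> float:
        r = self.rule
        ves = self.state.vesicles.get(vid)
        if ves is None:
            return 0.0
        order = r.order
        n_surf_terms = sum(r.surface_reactants.values())
        if order == 1:
            if n_surf_terms == 1:
                sp = next(iter(r.surface_reactants))
                return r.rate * ves.surface_count(sp)
            sp = next(iter(r.volume_reactants))
            n = ssa.counts[tets, ssa.s_index[sp]].sum() if len(tets) else 0
            return r.rate * float(n)
        # second order
        if n_surf_terms == 1 and r.volume_reactants:
            spv = next(iter(r.volume_reactants))
            if len(tets) == 0:
                return 0.0
            vstar = np.maximum(ssa.V_star[tets], 0.0)
            with np.errstate(divide="ignore"):
                c = np.where(vstar > 0,
                             r.rate / (AVOGADRO * vstar * 1e3), 0.0)
            nvol = ssa.counts[tets, ssa.s_index[spv]]
            return float((c * cnts * nvol).sum())
        if n_surf_terms == 1 and r.membrane_reactants:
            spm = next(iter(r.membrane_reactants))
            sp = next(iter(r.surface_reactants))
            mesh = self.state.mesh
            tris = mesh.patches[r.patch].tris
            nmem = ssa.tri_counts[tris, ssa.s_index[spm]].sum()
            own = mesh.tri_owner[tris[0]] if len(tris) else 0
            c = second_order_rate(r.rate, float(ssa.V_star[own]))
            return c * ves.surface_count(sp) * float(nmem)
        if n_surf_terms == 2:
            names = list(r.surface_reactants)
            if len(names) == 2:
                npairs = (ves.surface_count(names[0])
                          * ves.surface_count(names[1]))
            else:
                n = ves.surface_count(names[0])
                npairs = n * (n - 1) / 2
            vtot = float(sum(ves.overlap.entries.values()))
            return second_order_rate(r.rate, max(vtot, 1e-30)) * npairs
        raise ConfigError(f"{r.name}: unsupported reactant combination")

    def _fast_weights(self, ssa):
        r = self.rule
        if len(self._pt_tet) == 0:
            return None
        if self._c_pt is not None:
            spv = next(iter(r.volume_reactants))
            return self._c_pt * ssa.counts[self._pt_tet, ssa.s_index[spv]]
        return np.full(len(self._pt_tet), r.rate)

    def propensity(self, ssa) -> float:
        if self._fast:
            w = self._fast_weights(ssa)
            return float(w.sum()) if w is not None else 0.0
        return sum(self._vesicle_propensity(ssa, vid, tets, cnts)
                   for vid, tets, cnts in self._per_ves)

    def _execute_fast(self, ssa, rng) -> None:
        r = self.rule
        w = self._fast_weights(ssa)
        if w is None:
            return
        total = float(w.sum())
        if total <= 0:
            return
        idx = int(np.searchsorted(np.cumsum(w), rng.random() * total))
        idx = min(idx, len(w) - 1)
        vid, i = self._pt_ref[idx]
        ves = self.state.vesicles[vid]
        sp = next(iter(r.surface_reactants))
        site_rel = ves.surface[sp].pop(i)
        site_tet = int(self._pt_tet[idx])
        for spv, st in r.volume_reactants.items():
            ssa.counts[site_tet, ssa.s_index[spv]] -= st
            if ssa.counts[site_tet, ssa.s_index[spv]] < 0:
                raise RuntimeError("negative count in surface reaction")
        self._apply_products(ssa, rng, ves, site_rel, site_tet)
        self.sync(ssa)

    def _apply_products(self, ssa, rng, ves, site_rel, site_tet):
        r = self.rule
        for sp, st in r.surface_products.items():
            for _ in range(st):
                if site_rel is not None:
                    ves.surface.setdefault(sp, []).append(site_rel.copy())
                else:
                    ves.add_surface_point(sp, rng.standard_normal(3))
        for sp, st in r.lumen_products.items():
            ves.lumen[sp] = ves.lumen.get(sp, 0) + st
        for sp, st in r.volume_products.items():
            k = site_tet if site_tet is not None else ves.anchor_tet
            ssa.counts[k, ssa.s_index[sp]] += st
        for sp, st in r.membrane_products.items():
            mesh = self.state.mesh
            tris = mesh.patches[r.patch].tris
            d = np.linalg.norm(mesh.tri_barycenter[tris] - ves.center, axis=1)
            tri = int(tris[int(np.argmin(d))])
            ssa.tri_counts[tri, ssa.s_index[sp]] += st
        if r.dock_delta:
            ves.dock_count = max(0, ves.dock_count + r.dock_delta)

    def execute(self, ssa, rng) -> None:
        if self._fast:
            self._execute_fast(ssa, rng)
            return
        weights = [self._vesicle_propensity(ssa, vid, tets, cnts)
                   for vid, tets, cnts in self._per_ves]
        total = sum(weights)
        u = rng.random() * total
        acc = 0.0
        chosen = None
        for (vid, tets, cnts), w in zip(self._per_ves, weights):
            acc += w
            if u < acc:
                chosen = (vid, tets, cnts)
                break
        if chosen is None:
            return
        vid, tets, cnts = chosen
        ves = self.state.vesicles[vid]
        r = self.rule
        site_tet = None
        site_rel = None
        # consume surface reactants (random molecule of each species)
        for sp, st in r.surface_reactants.items():
            for _ in range(st):
                pts = ves.surface[sp]
                i = rng.integers(len(pts))
                site_rel = pts.pop(i)
        # pick the hosting tet for volume coupling
        if site_rel is not None:
            hosts = _surface_point_tets_point(self.state.mesh, ves, site_rel)
            site_tet = hosts
        elif len(tets):
            site_tet = int(tets[rng.integers(len(tets))])
        for sp, st in r.volume_reactants.items():
            k = site_tet
            if ssa.counts[k, ssa.s_index[sp]] < st:
                # molecule may be in another overlapped tet; take weighted
                cand = [t for t in ves.overlap.entries
                        if ssa.counts[t, ssa.s_index[sp]] >= st]
                if not cand:
                    self.sync(ssa)
                    return
                k = cand[int(rng.integers(len(cand)))]
            ssa.counts[k, ssa.s_index[sp]] -= st
        for sp, st in r.membrane_reactants.items():
            mesh = self.state.mesh
            tris = mesh.patches[r.patch].tris
            have = ssa.tri_counts[tris, ssa.s_index[sp]]
            cand = tris[have >= st]
            if len(cand) == 0:
                self.sync(ssa)
                return
            tri = int(cand[rng.integers(len(cand))])
            ssa.tri_counts[tri, ssa.s_index[sp]] -= st
        # products
        for sp, st in r.surface_products.items():
            for _ in range(st):
                if site_rel is not None:
                    ves.surface.setdefault(sp, []).append(site_rel.copy())
                else:
                    ves.add_surface_point(sp, rng.standard_normal(3))
        for sp, st in r.lumen_products.items():
            ves.lumen[sp] = ves.lumen.get(sp, 0) + st
        for sp, st in r.volume_products.items():
            k = site_tet if site_tet is not None else ves.anchor_tet
            ssa.counts[k, ssa.s_index[sp]] += st
        for sp, st in r.membrane_products.items():
            mesh = self.state.mesh
            tris = mesh.patches[r.patch].tris
            d = np.linalg.norm(mesh.tri_barycenter[tris] - ves.center, axis=1)
            tri = int(tris[int(np.argmin(d))])
            ssa.tri_counts[tri, ssa.s_index[sp]] += st
        if r.dock_delta:
            ves.dock_count = max(0, ves.dock_count + r.dock_delta)
        self.sync(ssa)


def _surface_point_tets_point(mesh, ves: Vesicle, rel) -> int:
    p = ves.center + rel
    for k in ves.overlap.entries:
        if point_in_tet(mesh.vertices[mesh.tets[k]], p, tol=1e-7):
            return int(k)
    return int(ves.anchor_tet)


class BindingChannel(_Channel):
    def __init__(self, rule: BindingRule, state: VesicleState):
        self.rule = rule
        self.state = state
        self._pairs: list[tuple[int, int, int, int]] = []

    def sync(self, ssa) -> None:
        """Enumerate eligible (vesicle, point, vesicle, point) pairs whose
        link length would fall within bounds."""
        r = self.rule
        self._pairs = []
        vs = list(self.state.vesicles.values())
        for i, va in enumerate(vs):
            pa = va.surface.get(r.species_a, [])
            if not pa:
                continue
            for vb in vs:
                if vb.id == va.id:
                    continue
                pb = vb.surface.get(r.species_b, [])
                if not pb:
                    continue
                if (r.species_a == r.species_b and vb.id < va.id):
                    continue
                for ia, ra in enumerate(pa):
                    qa = va.center + ra
                    for ib, rb in enumerate(pb):
                        qb = vb.center + rb
                        d = float(np.linalg.norm(qa - qb))
                        if r.l_min <= d <= r.l_max:
                            self._pairs.append((va.id, ia, vb.id, ib))

    def propensity(self, ssa) -> float:
        return self.rule.rate * len(self._pairs)

    def execute(self, ssa, rng) -> None:
        if not self._pairs:
            return
        va_id, ia, vb_id, ib = self._pairs[rng.integers(len(self._pairs))]
        r = self.rule
        va = self.state.vesicles[va_id]
        vb = self.state.vesicles[vb_id]
        ra = va.surface[r.species_a].pop(ia)
        rb = vb.surface[r.species_b].pop(ib)
        ln = Link(species=r.link_species, ves_a=va_id, ves_b=vb_id,
                  rel_a=ra, rel_b=rb, l_min=r.l_min, l_max=r.l_max)
        va.links.append(ln)
        vb.links.append(ln)
        self.sync(ssa)


class UnbindingChannel(_Channel):
    def __init__(self, rule: UnbindingRule, state: VesicleState,
                 binding_channels: list[BindingChannel] = ()):
        self.rule = rule
        self.state = state
        self._linked = binding_channels

    def _links(self):
        seen = []
        ids = set()
        for ves in self.state.vesicles.values():
            for ln in ves.links:
                if ln.species == self.rule.link_species and id(ln) not in ids:
                    ids.add(id(ln))
                    seen.append(ln)
        return seen

    def propensity(self, ssa) -> float:
        return self.rule.rate * len(self._links())

    def execute(self, ssa, rng) -> None:
        links = self._links()
        if not links:
            return
        ln = links[rng.integers(len(links))]
        va = self.state.vesicles[ln.ves_a]
        vb = self.state.vesicles[ln.ves_b]
        va.links.remove(ln)
        vb.links.remove(ln)
        va.surface.setdefault(self.rule.species_a, []).append(ln.rel_a)
        vb.surface.setdefault(self.rule.species_b, []).append(ln.rel_b)
        for bc in self._linked:
            bc.sync(ssa)


class ExocytosisChannel(_Channel):
    def __init__(self, rule: ExocytosisRule, state: VesicleState,
                 rafts: RaftState | None = None,
                 raft_types: dict[str, RaftType] | None = None,
                 outer_compartment: str | None = None):
        self.rule = rule
        self.state = state
        self.rafts = rafts
        self.raft_types = raft_types or {}
        self.outer = outer_compartment
        self.released: dict[str, int] = {}     # ledger when no outer comp
        self._eligible: list[int] = []

    def _check(self, ves: Vesicle) -> bool:
        r = self.rule
        if r.vesicle_type is not None and ves.vtype.name != r.vesicle_type:
            return False
        counts = {sp: ves.surface_count(sp) for sp in
                  set(r.dependencies) | set(r.anti_dependencies)}
        if not _deps_met(counts, r.dependencies):
            return False
        if not _antideps_clear(counts, r.anti_dependencies):
            return False
        if r.max_distance is not None:
            mesh = self.state.mesh
            tris = mesh.patches[r.patch].tris
            d = np.linalg.norm(mesh.tri_barycenter[tris] - ves.center,
                               axis=1).min()
            if d - ves.radius > r.max_distance:
                return False
        return True

    def sync(self, ssa) -> None:
        self._eligible = [vid for vid, v in self.state.vesicles.items()
                          if self._check(v)]

    def propensity(self, ssa) -> float:
        self._eligible = [v for v in self._eligible
                          if v in self.state.vesicles]
        return self.rule.rate * len(self._eligible)

    def execute(self, ssa, rng) -> None:
        if not self._eligible:
            return
        vid = self._eligible[rng.integers(len(self._eligible))]
        ves = self.state.vesicles[vid]
        r = self.rule
        mesh = self.state.mesh
        tris = np.asarray(mesh.patches[r.patch].tris, int)
        # luminal release
        for sp, n in list(ves.lumen.items()):
            k = int(rng.binomial(n, r.release_fraction)) \
                if r.release_fraction < 1.0 else n
            ves.lumen[sp] = n - k
            if self.outer is not None:
                ssa.distribute(sp, k, rng, compartment=self.outer)
            else:
                self.released[sp] = self.released.get(sp, 0) + k
        if r.mode == "preserve":
            if r.undock:
                ves.dock_count = 0
            self.sync(ssa)
            return
        # full collapse
        if r.raft_type is not None and self.rafts is not None:
            d = np.linalg.norm(mesh.tri_barycenter[tris] - ves.center, axis=1)
            anchor = int(tris[int(np.argmin(d))])
            raft = self.rafts.add_raft(self.raft_types[r.raft_type], anchor)
            if raft is not None:
                for sp, pts in ves.surface.items():
                    raft.counts[sp] = raft.counts.get(sp, 0) + len(pts)
                for ln in list(ves.links):
                    pass
        else:
            for sp, pts in ves.surface.items():
                si = ssa.s_index.get(sp)
                if si is None:
                    continue
                for rel in pts:
                    p = ves.center + rel
                    d = np.linalg.norm(mesh.tri_barycenter[tris] - p, axis=1)
                    tri = int(tris[int(np.argmin(d))])
                    ssa.tri_counts[tri, si] += 1
        # sever any links (partner keeps its species back)
        for ln in list(ves.links):
            other = self.state.vesicles[ln.ves_b if ln.ves_a == vid
                                        else ln.ves_a]
            other.links.remove(ln)
        self.state.remove_vesicle(vid)
        ssa.set_occupancy(self.state.occupancy_by_tet())
        self.sync(ssa)


class EndocytosisChannel(_Channel):
    def __init__(self, rule: EndocytosisRule, state: VesicleState,
                 vesicle_types: dict[str, VesicleType]):
        self.rule = rule
        self.state = state
        self.vesicle_types = vesicle_types
        self.n_events = 0

    def _zone_tris(self):
        return np.asarray(self.state.mesh.zones[self.rule.zone].tris, int)

    def _zone_counts(self, ssa) -> dict[str, int]:
        tris = self._zone_tris()
        return {s.name: int(ssa.tri_counts[tris, i].sum())
                for i, s in enumerate(ssa.species)}

    def propensity(self, ssa) -> float:
        r = self.rule
        counts = self._zone_counts(ssa)
        if not _antideps_clear(counts, r.anti_dependencies):
            return 0.0
        if not r.dependencies:
            return r.rate
        mult = min(counts.get(sp, 0) // n
                   for sp, n in r.dependencies.items())
        return r.rate * mult

    def execute(self, ssa, rng) -> None:
        r = self.rule
        mesh = self.state.mesh
        tris = self._zone_tris()
        vtype = self.vesicle_types[r.vesicle_type]
        # reserve the spherical space just inside the zone
        w = mesh.tri_area[tris]
        centroid = (mesh.tri_barycenter[tris] * w[:, None]).sum(0) / w.sum()
        normal = mesh.tri_normal[tris].mean(axis=0)
        normal /= np.linalg.norm(normal)
        center = centroid - normal * vtype.radius * 1.02
        ves = self.state.add_vesicle(vtype, center)
        if ves is None:
            return                       # blocked: rejected this attempt
        self.n_events += 1
        # one dependency set is internalized per event
        for sp, n in r.dependencies.items():
            si = ssa.s_index[sp]
            left = n
            for tri in rng.permutation(tris):
                take = min(left, int(ssa.tri_counts[tri, si]))
                ssa.tri_counts[tri, si] -= take
                for _ in range(take):
                    ves.add_surface_point(sp, mesh.tri_barycenter[tri]
                                          - ves.center)
                left -= take
                if left == 0:
                    break
        # remaining zone species move onto the vesicle surface too
        for si, spec in enumerate(ssa.species):
            for tri in tris:
                n = int(ssa.tri_counts[tri, si])
                if n:
                    ssa.tri_counts[tri, si] = 0
                    for _ in range(n):
                        ves.add_surface_point(
                            spec.name, mesh.tri_barycenter[tri] - ves.center)
        ssa.set_occupancy(self.state.occupancy_by_tet())


# -- raft channels ----------------------------------------------------------

@dataclass
class RaftSurfaceReaction:
    """Reaction among raft species, optionally coupled to triangle-surface
    or cytosolic species in/under the raft's overlap triangles (order <= 2,
    second-order volume coupling via c* of the pooled owner-tet V*)."""
    name: str
    rate: float
    raft_type: str | None = None
    raft_reactants: dict[str, int] = field(default_factory=dict)
    volume_reactants: dict[str, int] = field(default_factory=dict)
    tri_reactants: dict[str, int] = field(default_factory=dict)
    raft_products: dict[str, int] = field(default_factory=dict)
    volume_products: dict[str, int] = field(default_factory=dict)
    tri_products: dict[str, int] = field(default_factory=dict)

    @property
    def order(self):
        return (sum(self.raft_reactants.values())
                + sum(self.volume_reactants.values())
                + sum(self.tri_reactants.values()))

    def __post_init__(self):
        if self.order > 2:
            raise ConfigError(f"{self.name}: order > 2 unsupported")


@dataclass
class RaftEndocytosis:
    """Raft converts to a vesicle carrying the raft's species counts."""
    name: str
    rate: float
    raft_type: str | None = None
    vesicle_type: str = ""
    dependencies: dict[str, int] = field(default_factory=dict)
    anti_dependencies: dict[str, int] = field(default_factory=dict)


@dataclass
class RaftGeneration:
    """A triangle whose species counts meet the signature becomes the
    anchor of a new raft; the signature species move into the raft."""
    name: str
    rate: float
    raft_type: str = ""
    signature: dict[str, int] = field(default_factory=dict)


@dataclass
class RaftDissolution:
    """A raft whose composition is below the threshold disperses its
    counts uniformly over its overlap triangles and is deleted."""
    name: str
    rate: float
    raft_type: str | None = None
    below: dict[str, int] = field(default_factory=dict)


class RaftReactionChannel(_Channel):
    def __init__(self, rule: RaftSurfaceReaction, rafts: RaftState):
        self.rule = rule
        self.rafts = rafts

    def _applies(self, raft: Raft) -> bool:
        return (self.rule.raft_type is None
                or raft.rtype.name == self.rule.raft_type)

    def _raft_propensity(self, ssa, raft: Raft) -> float:
        r = self.rule
        mesh = self.rafts.mesh
        tris = np.asarray(raft.overlap_tris, int)
        owners = np.unique(mesh.tri_owner[tris])
        get_raft = lambda sp: raft.counts.get(sp, 0)
        get_vol = lambda sp: int(ssa.counts[owners, ssa.s_index[sp]].sum())
        get_tri = lambda sp: int(ssa.tri_counts[tris, ssa.s_index[sp]].sum())
        if r.order == 1:
            for sp in r.raft_reactants:
                return r.rate * get_raft(sp)
            for sp in r.tri_reactants:
                return r.rate * get_tri(sp)
            for sp in r.volume_reactants:
                return r.rate * get_vol(sp)
        vstar = float(np.maximum(ssa.V_star[owners], 0.0).sum())
        c = second_order_rate(r.rate, max(vstar, 1e-30))
        terms = []
        for sp, st in r.raft_reactants.items():
            terms += [get_raft(sp)] * st
        for sp, st in r.tri_reactants.items():
            terms += [get_tri(sp)] * st
        for sp, st in r.volume_reactants.items():
            terms += [get_vol(sp)] * st
        if len(terms) == 2:
            if (len(r.raft_reactants) == 1
                    and list(r.raft_reactants.values()) == [2]):
                n = terms[0]
                return c * n * (n - 1) / 2.0
            return c * terms[0] * terms[1]
        raise ConfigError(f"{r.name}: unsupported reactant combination")

    def propensity(self, ssa) -> float:
        return sum(self._raft_propensity(ssa, raft)
                   for raft in self.rafts.rafts.values()
                   if self._applies(raft))

    def execute(self, ssa, rng) -> None:
        rs = [r for r in self.rafts.rafts.values() if self._applies(r)]
        weights = [self._raft_propensity(ssa, r) for r in rs]
        total = sum(weights)
        if total <= 0:
            return
        u = rng.random() * total
        acc = 0.0
        raft = rs[-1]
        for rr, w in zip(rs, weights):
            acc += w
            if u < acc:
                raft = rr
                break
        r = self.rule
        mesh = self.rafts.mesh
        tris = np.asarray(raft.overlap_tris, int)
        for sp, st in r.raft_reactants.items():
            raft.counts[sp] = raft.counts.get(sp, 0) - st
            if raft.counts[sp] < 0:
                raise RuntimeError("negative raft count")
        for sp, st in r.tri_reactants.items():
            si = ssa.s_index[sp]
            have = ssa.tri_counts[tris, si]
            cand = tris[have >= st]
            tri = int(cand[rng.integers(len(cand))])
            ssa.tri_counts[tri, si] -= st
        for sp, st in r.volume_reactants.items():
            si = ssa.s_index[sp]
            owners = np.unique(mesh.tri_owner[tris])
            have = ssa.counts[owners, si]
            cand = owners[have >= st]
            k = int(cand[rng.integers(len(cand))])
            ssa.counts[k, si] -= st
        for sp, st in r.raft_products.items():
            raft.counts[sp] = raft.counts.get(sp, 0) + st
        for sp, st in r.tri_products.items():
            tri = int(tris[rng.integers(len(tris))])
            ssa.tri_counts[tri, ssa.s_index[sp]] += st
        for sp, st in r.volume_products.items():
            owners = np.unique(mesh.tri_owner[tris])
            k = int(owners[rng.integers(len(owners))])
            ssa.counts[k, ssa.s_index[sp]] += st


class RaftEndocytosisChannel(_Channel):
    def __init__(self, rule: RaftEndocytosis, rafts: RaftState,
                 state: VesicleState,
                 vesicle_types: dict[str, VesicleType]):
        self.rule = rule
        self.rafts = rafts
        self.state = state
        self.vesicle_types = vesicle_types

    def _eligible(self):
        r = self.rule
        out = []
        for raft in self.rafts.rafts.values():
            if r.raft_type is not None and raft.rtype.name != r.raft_type:
                continue
            if not _deps_met(raft.counts, r.dependencies):
                continue
            if not _antideps_clear(raft.counts, r.anti_dependencies):
                continue
            out.append(raft)
        return out

    def propensity(self, ssa) -> float:
        return self.rule.rate * len(self._eligible())

    def execute(self, ssa, rng) -> None:
        el = self._eligible()
        if not el:
            return
        raft = el[rng.integers(len(el))]
        mesh = self.rafts.mesh
        vtype = self.vesicle_types[self.rule.vesicle_type]
        tri = raft.anchor_tri
        center = (mesh.tri_barycenter[tri]
                  - mesh.tri_normal[tri] * vtype.radius * 1.02)
        ves = self.state.add_vesicle(vtype, center)
        if ves is None:
            return
        for sp, n in raft.counts.items():
            for _ in range(n):
                ves.add_surface_point(sp, rng.standard_normal(3))
        self.rafts.remove_raft(raft.id)
        ssa.set_occupancy(self.state.occupancy_by_tet())


class RaftGenerationChannel(_Channel):
    def __init__(self, rule: RaftGeneration, rafts: RaftState,
                 raft_types: dict[str, RaftType], patch: str | None = None):
        self.rule = rule
        self.rafts = rafts
        self.raft_types = raft_types
        self.patch = patch

    def _candidate_tris(self, ssa) -> np.ndarray:
        mesh = self.rafts.mesh
        tris = (np.asarray(mesh.patches[self.patch].tris, int)
                if self.patch else np.arange(mesh.n_tris))
        ok = np.ones(len(tris), bool)
        for sp, n in self.rule.signature.items():
            ok &= ssa.tri_counts[tris, ssa.s_index[sp]] >= n
        return tris[ok]

    def propensity(self, ssa) -> float:
        return self.rule.rate * len(self._candidate_tris(ssa))

    def execute(self, ssa, rng) -> None:
        cand = self._candidate_tris(ssa)
        if len(cand) == 0:
            return
        tri = int(cand[rng.integers(len(cand))])
        raft = self.rafts.add_raft(self.raft_types[self.rule.raft_type], tri)
        if raft is None:
            return                        # exclusivity blocked
        for sp, n in self.rule.signature.items():
            ssa.tri_counts[tri, ssa.s_index[sp]] -= n
            raft.counts[sp] = raft.counts.get(sp, 0) + n


class RaftDissolutionChannel(_Channel):
    def __init__(self, rule: RaftDissolution, rafts: RaftState):
        self.rule = rule
        self.rafts = rafts

    def _eligible(self):
        r = self.rule
        out = []
        for raft in self.rafts.rafts.values():
            if r.raft_type is not None and raft.rtype.name != r.raft_type:
                continue
            if all(raft.counts.get(sp, 0) < n for sp, n in r.below.items()) \
                    or not r.below:
                out.append(raft)
        return out

    def propensity(self, ssa) -> float:
        return self.rule.rate * len(self._eligible())

    def execute(self, ssa, rng) -> None:
        el = self._eligible()
        if not el:
            return
        raft = el[rng.integers(len(el))]
        tris = np.asarray(raft.overlap_tris, int)
        for sp, n in raft.counts.items():
            si = ssa.s_index.get(sp)
            if si is None or n == 0:
                continue
            dest = rng.integers(len(tris), size=n)
            np.add.at(ssa.tri_counts[:, si], tris[dest], 1)
        self.rafts.remove_raft(raft.id)
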