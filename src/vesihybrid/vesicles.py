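"""Vesicles and their motion.

Vesicles are hard spheres living inside the tetrahedral mesh.  On a fixed
user clock (default 1 ms) each free vesicle proposes a Brownian step with
component displacements r * sqrt(2 D dt) (r standard normal); the step is
accepted only if the new position keeps the sphere fully inside the mesh
(coverage fraction 1) and outside every other vesicle, and keeps every
attached link species within its length bounds.  Rejected steps leave the
vesicle in place, which preserves detailed balance for the hard-sphere
dynamics.  Update order is shuffled every step.

Molecules on a vesicle surface carry exact positions, stored in the body
frame (relative to the center) so translation is free; they move over the
sphere via an approximate spherical diffusion propagator: the polar
displacement angle is drawn from the exact heat-kernel series on the
sphere (truncated and tabulated/inverted), the azimuth uniformly.

Active transport: branched polyline Paths capture passing free vesicles,
which then advance by fixed-size steps with stochastically sampled
dwelltimes (single-exponential by default; two-stage or mixture
double-exponential optional), so total distance / total dwelltime
realizes the configured speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import OverlapMap, compute_overlap, position_valid, point_in_tet

__all__ = [
    "VesicleType", "Vesicle", "Link", "VesiclePath", "VesicleState",
    "SphericalPropagator", "brownian_step", "diffuse_all_vesicles",
    "path_capture_and_advance", "surface_diffuse", "apply_link_constraints",
    "place_vesicles",
]


@dataclass
class VesicleType:
    """A class of vesicles sharing diameter and diffusion coefficient."""
    name: str
    diameter: float                 # m
    D: float = 0.0                  # m^2/s
    surface_species: tuple = ()     # species permitted on the surface
    luminal_species: tuple = ()

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("vesicle diameter must be > 0")
        if self.D < 0:
            raise ValueError("vesicle D must be >= 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3


@dataclass
class Link:
    """A link species: a paired surface complex tethering two vesicles.

    ``rel_a``/``rel_b`` are body-frame endpoint positions (on the sphere
    surfaces); the end-to-end length must stay in [l_min, l_max]."""
    species: str
    ves_a: int
    ves_b: int
    rel_a: np.ndarray
    rel_b: np.ndarray
    l_min: float
    l_max: float

    def length(self, state: "VesicleState") -> float:
        pa = state.vesicles[self.ves_a].center + self.rel_a
        pb = state.vesicles[self.ves_b].center + self.rel_b
        return float(np.linalg.norm(pa - pb))


class Vesicle:
    """One vesicle instance."""

    def __init__(self, vid: int, vtype: VesicleType, center, overlap: OverlapMap,
                 anchor_tet: int):
        self.id = vid
        self.vtype = vtype
        self.center = np.asarray(center, float)
        self.overlap = overlap
        self.anchor_tet = anchor_tet
        self.surface: dict[str, list[np.ndarray]] = {}   # body-frame points
        self.lumen: dict[str, int] = {}
        self.links: list[Link] = []
        self.dock_count = 0          # > 0 => immobile (docked/tethered)
        self.path_state = None       # (VesiclePath, arc position, next jump t)

    @property
    def radius(self) -> float:
        return self.vtype.radius

    @property
    def volume(self) -> float:
        return self.vtype.volume

    @property
    def free(self) -> bool:
        return self.dock_count == 0 and self.path_state is None

    def add_surface_point(self, species: str, direction) -> np.ndarray:
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d) * self.radius
        self.surface.setdefault(species, []).append(d)
        return d

    def surface_count(self, species: str) -> int:
        return len(self.surface.get(species, ()))

    def surface_points_abs(self, species: str) -> np.ndarray:
        pts = self.surface.get(species, [])
        if not pts:
            return np.empty((0, 3))
        return self.center + np.asarray(pts)


@dataclass
class VesiclePath:
    """Polyline path (cytoskeletal filament) for active transport.

    ``dwell_law`` is ``("single_exp",)``, ``("double_exp", tau1, tau2)``
    (two sequential rate-limiting stages) or
    ``("double_exp_mixture", p, tau1, tau2)``.  Law parameters fix the
    shape only; dwell means are normalized to stepsize/speed so that total
    distance over total dwelltime equals the configured speed.
    """
    name: str
    nodes: np.ndarray               # (n, 3) m
    speed: float                    # m/s
    stepsize: float                 # m
    dwell_law: tuple = ("single_exp",)
    capture_radius: float | None = None   # default: vesicle radius
    capture_prob: float = 1.0

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        if self.speed <= 0 or self.stepsize <= 0:
            raise ValueError("path speed and stepsize must be > 0")
        seg = np.diff(self.nodes, axis=0)
        self._seg_len = np.linalg.norm(seg, axis=1)
        if (self._seg_len == 0).any():
            raise ValueError("consecutive path nodes must be distinct")
        self._cum = np.concatenate([[0.0], np.cumsum(self._seg_len)])
        if self.stepsize > self.length:
            raise ValueError("stepsize exceeds path length")

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    def point_at(self, s: float) -> np.ndarray:
        s = min(max(s, 0.0), self.length)
        i = int(np.searchsorted(self._cum, s, side="right")) - 1
        i = min(i, len(self._seg_len) - 1)
        t = (s - self._cum[i]) / self._seg_len[i]
        return self.nodes[i] + t * (self.nodes[i + 1] - self.nodes[i])

    def project(self, p) -> tuple[float, float]:
        """(arc position, distance) of the closest point of the polyline."""
        p = np.asarray(p, float)
        best = (0.0, math.inf)
        for i in range(len(self._seg_len)):
            a, b = self.nodes[i], self.nodes[i + 1]
            ab = b - a
            t = float(np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0))
            q = a + t * ab
            d = float(np.linalg.norm(p - q))
            if d < best[1]:
                best = (float(self._cum[i] + t * self._seg_len[i]), d)
        return best

    def sample_dwell(self, rng) -> float:
        mean = self.stepsize / self.speed
        law = self.dwell_law
        if law[0] == "single_exp":
            return rng.exponential(mean)
        if law[0] == "double_exp":
            t1, t2 = law[1], law[2]
            s = (t1 + t2)
            return rng.exponential(mean * t1 / s) + rng.exponential(mean * t2 / s)
        if law[0] == "double_exp_mixture":
            p, t1, t2 = law[1], law[2], law[3]
            m = p * t1 + (1 - p) * t2
            tau = t1 if rng.random() < p else t2
            return rng.exponential(mean * tau / m)
        raise ValueError(f"unknown dwell law {law[0]!r}")


class VesicleState:
    """All vesicles in a simulation plus the tet -> vesicle registry the
    position-validity search uses."""

    def __init__(self, mesh):
        self.mesh = mesh
        self.vesicles: dict[int, Vesicle] = {}
        self.tet_vesicles: dict[int, set[int]] = {}
        self.paths: list[VesiclePath] = []
        self._next_id = 0
        self.time = 0.0

    # -- registry ------------------------------------------------------
    def _register(self, ves: Vesicle):
        for k in ves.overlap.entries:
            self.tet_vesicles.setdefault(k, set()).add(ves.id)

    def _unregister(self, ves: Vesicle):
        for k in ves.overlap.entries:
            s = self.tet_vesicles.get(k)
            if s:
                s.discard(ves.id)

    def add_vesicle(self, vtype: VesicleType, center, *, dock=0) -> Vesicle | None:
        """Add a vesicle at ``center`` if the position is valid; returns
        None otherwise."""
        center = np.asarray(center, float)
        k = self.locate(center)
        if k < 0:
            return None
        omap = compute_overlap(self.mesh, center, vtype.radius, [k])
        if not omap.complete:
            return None
        # neighbor exclusion via the tet registry (overlapped tets plus
        # one adjacency ring)
        cand_ids = set()
        for t in omap.entries:
            cand_ids.update(self.tet_vesicles.get(t, ()))
            for nb in self.mesh.tet_neighbors[t]:
                if nb >= 0:
                    cand_ids.update(self.tet_vesicles.get(int(nb), ()))
        for vid2 in cand_ids:
            other = self.vesicles[vid2]
            if np.linalg.norm(center - other.center) < \
                    vtype.radius + other.radius:
                return None
        vid = self._next_id
        self._next_id += 1
        omap.vesicle = vid
        ves = Vesicle(vid, vtype, center, omap, k)
        ves.dock_count = dock
        self.vesicles[vid] = ves
        self._register(ves)
        return ves

    def remove_vesicle(self, vid: int):
        ves = self.vesicles.pop(vid)
        self._unregister(ves)
        return ves

    def move_vesicle(self, vid: int, new_center, omap: OverlapMap):
        ves = self.vesicles[vid]
        self._unregister(ves)
        ves.center = np.asarray(new_center, float)
        ves.overlap = omap
        for k in omap.entries:
            if point_in_tet(self.mesh.vertices[self.mesh.tets[k]],
                            ves.center, tol=1e-9):
                ves.anchor_tet = k
                break
        self._register(ves)

    def locate(self, point) -> int:
        """Tet containing point (brute force over candidate tets near the
        barycenter ordering; exact)."""
        mesh = self.mesh
        d = np.linalg.norm(mesh.tet_barycenter - np.asarray(point, float),
                           axis=1)
        for k in np.argsort(d)[:64]:
            if point_in_tet(mesh.vertices[mesh.tets[k]], point, tol=1e-9):
                return int(k)
        return -1

    def occupancy_by_tet(self) -> np.ndarray:
        occ = np.zeros(self.mesh.n_tets)
        for ves in self.vesicles.values():
            for k, v in ves.overlap.entries.items():
                occ[k] += v
        return occ

    def total_vesicle_volume(self) -> float:
        return sum(v.volume for v in self.vesicles.values())


# ---------------------------------------------------------------------------
# Brownian motion
# ---------------------------------------------------------------------------

def brownian_step(ves: Vesicle, dt: float, rng) -> np.ndarray:
    """Candidate center after one Brownian step of duration dt."""
    sigma = math.sqrt(2.0 * ves.vtype.D * dt)
    return ves.center + sigma * rng.standard_normal(3)


def apply_link_constraints(state: VesicleState, vid: int, candidate) -> bool:
    """True iff moving vesicle ``vid`` rigidly to ``candidate`` keeps all
    attached link species within their length bounds."""
    ves = state.vesicles[vid]
    candidate = np.asarray(candidate, float)
    for ln in ves.links:
        if ln.ves_a == vid:
            pa = candidate + ln.rel_a
            pb = state.vesicles[ln.ves_b].center + ln.rel_b
        else:
            pa = state.vesicles[ln.ves_a].center + ln.rel_a
            pb = candidate + ln.rel_b
        d = float(np.linalg.norm(pa - pb))
        if d < ln.l_min or d > ln.l_max:
            return False
    return True


def diffuse_all_vesicles(state: VesicleState, dt: float, rng) -> int:
    """One vesicle-clock diffusion update: every free vesicle proposes one
    Brownian step, accepted iff valid; update order is shuffled.  Returns
    the number of accepted moves."""
    ids = [vid for vid, v in state.vesicles.items()
           if v.free and v.vtype.D > 0.0]
    rng.shuffle(ids)
    accepted = 0
    for vid in ids:
        ves = state.vesicles[vid]
        candidate = brownian_step(ves, dt, rng)
        if not apply_link_constraints(state, vid, candidate):
            continue
        ok, omap = position_valid(state, vid, candidate)
        if ok:
            state.move_vesicle(vid, candidate, omap)
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# active transport on paths
# ---------------------------------------------------------------------------

def path_capture_and_advance(state: VesicleState, dt: float, rng) -> None:
    """Capture free vesicles crossing paths and advance bound vesicles.

    A bound vesicle waits a sampled dwelltime, then jumps ``stepsize``
    along the path (hard-sphere validity still enforced; a blocked jump is
    dropped and a fresh dwelltime sampled).  At the path end the vesicle
    is released to the free state.
    """
    now = state.time
    # capture
    for vid, ves in list(state.vesicles.items()):
        if not ves.free:
            continue
        for path in state.paths:
            cap = path.capture_radius
            if cap is None:
                cap = ves.radius
            s, d = path.project(ves.center)
            if d <= ves.radius + cap and rng.random() < path.capture_prob:
                ves.path_state = (path, s, now + path.sample_dwell(rng))
                break
    # advance
    for vid, ves in list(state.vesicles.items()):
        if ves.path_state is None:
            continue
        path, s, t_next = ves.path_state
        while t_next <= now + dt:
            s_new = s + path.stepsize
            if s_new >= path.length:
                ves.path_state = None
                break
            candidate = path.point_at(s_new) + (ves.center - path.point_at(s))
            if apply_link_constraints(state, vid, candidate):
                ok, omap = position_valid(state, vid, candidate)
                if ok:
                    state.move_vesicle(vid, candidate, omap)
                    s = s_new
            t_next = t_next + path.sample_dwell(rng)
        else:
            ves.path_state = (path, s, t_next)


# ---------------------------------------------------------------------------
# surface diffusion (spherical propagator)
# ---------------------------------------------------------------------------

class SphericalPropagator:
    """Sampler of the polar diffusion angle on a sphere after time t.

    Uses the heat-kernel Legendre series on the unit sphere at
    tau = D t / r^2, truncated where terms fall below 1e-14, integrated to
    a CDF on a theta grid and inverted by interpolation.  Accuracy of the
    first two angular moments is limited only by the grid (2048 points).
    """

    _cache: dict[float, "SphericalPropagator"] = {}

    def __init__(self, tau: float, n_grid: int = 2048):
        if tau <= 0:
            raise ValueError("tau must be > 0")
        self.tau = tau
        theta = np.linspace(0.0, math.pi, n_grid)
        u = np.cos(theta)
        lmax = int(min(6000, max(30, 8.0 / math.sqrt(tau))))
        # sum (2l+1) exp(-l(l+1) tau) P_l(u) via upward recurrence
        p_prev = np.ones_like(u)
        p_cur = u.copy()
        series = 1.0 * p_prev
        series = series + 3.0 * math.exp(-2.0 * tau) * p_cur
        for l in range(2, lmax + 1):
            p_next = ((2 * l - 1) * u * p_cur - (l - 1) * p_prev) / l
            w = math.exp(-l * (l + 1) * tau)
            series = series + (2 * l + 1) * w * p_next
            p_prev, p_cur = p_cur, p_next
            if w < 1e-14:
                break
        dens = 0.5 * np.sin(theta) * series      # density in theta
        dens = np.clip(dens, 0.0, None)
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(theta))])
        cdf /= cdf[-1]
        self._theta = theta
        self._cdf = cdf

    @classmethod
    def for_tau(cls, tau: float) -> "SphericalPropagator":
        key = round(math.log(tau), 6)
        got = cls._cache.get(key)
        if got is None:
            got = cls(tau)
            cls._cache[key] = got
        return got

    def sample(self, rng, n: int = 1) -> np.ndarray:
        u = rng.random(n)
        return np.interp(u, self._cdf, self._theta)

    def moments(self) -> tuple[float, float]:
        """(mean, std) of the polar displacement angle."""
        pdf = np.gradient(self._cdf, self._theta)
        m1 = np.trapezoid(self._theta * pdf, self._theta)
        m2 = np.trapezoid(self._theta ** 2 * pdf, self._theta)
        return float(m1), float(math.sqrt(max(m2 - m1 * m1, 0.0)))


def _rotate_by_angle(rel: np.ndarray, theta: float, psi: float,
                     radius: float) -> np.ndarray:
    """Move a body-frame surface point by polar angle theta in tangent
    direction psi, staying on the sphere."""
    u = rel / np.linalg.norm(rel)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    t = math.cos(psi) * e1 + math.sin(psi) * e2
    return radius * (u * math.cos(theta) + t * math.sin(theta))


def surface_diffuse(state_or_ves, dt: float, rng,
                    D_surface: dict[str, float]) -> None:
    """Diffuse surface point species (and link endpoints) of one vesicle
    or of all vesicles in a state for one vesicle timestep."""
    if isinstance(state_or_ves, VesicleState):
        for ves in state_or_ves.vesicles.values():
            _surface_diffuse_one(state_or_ves, ves, dt, rng, D_surface)
    else:
        _surface_diffuse_one(None, state_or_ves, dt, rng, D_surface)


def _surface_diffuse_one(state, ves: Vesicle, dt: float, rng,
                         D_surface: dict[str, float]) -> None:
    r = ves.radius
    for species, pts in ves.surface.items():
        D = D_surface.get(species, 0.0)
        if D <= 0.0 or not pts:
            continue
        prop = SphericalPropagator.for_tau(D * dt / (r * r))
        thetas = prop.sample(rng, len(pts))
        psis = rng.uniform(0.0, 2.0 * math.pi, len(pts))
        for i in range(len(pts)):
            pts[i] = _rotate_by_angle(pts[i], float(thetas[i]),
                                      float(psis[i]), r)
    # link endpoints move only if the link stays within bounds
    if state is None:
        return
    for ln in ves.links:
        D = D_surface.get(ln.species, 0.0)
        if D <= 0.0:
            continue
        prop = SphericalPropagator.for_tau(D * dt / (r * r))
        mine = ln.rel_a if ln.ves_a == ves.id else ln.rel_b
        cand = _rotate_by_angle(mine, float(prop.sample(rng, 1)[0]),
                                float(rng.uniform(0, 2 * math.pi)), r)
        if ln.ves_a == ves.id:
            pa = ves.center + cand
            pb = state.vesicles[ln.ves_b].center + ln.rel_b
        else:
            pa = state.vesicles[ln.ves_a].center + ln.rel_a
            pb = ves.center + cand
        d = float(np.linalg.norm(pa - pb))
        if ln.l_min <= d <= ln.l_max:
            if ln.ves_a == ves.id:
                ln.rel_a = cand
            else:
                ln.rel_b = cand


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_vesicles(state: VesicleState, vtype: VesicleType, n: int, rng, *,
                   method: str = "rsa", dock: int = 0,
                   max_attempts: int = 200) -> list[Vesicle]:
    """Place ``n`` vesicles with hard-sphere exclusion.

    ``method="rsa"`` does random sequential addition (practical up to
    ~30% volume occupancy); ``method="lattice"`` uses a jittered FCC
    lattice, needed for the dense-crowding regimes.
    """
    placed: list[Vesicle] = []
    mesh = state.mesh
    if method == "rsa":
        vols = mesh.tet_volume / mesh.total_volume
        attempts = 0
        while len(placed) < n and attempts < max_attempts * n:
            attempts += 1
            k = rng.choice(mesh.n_tets, p=vols)
            lam = rng.dirichlet(np.ones(4))
            p = lam @ mesh.vertices[mesh.tets[k]]
            ves = state.add_vesicle(vtype, p, dock=dock)
            if ves is not None:
                placed.append(ves)
        if len(placed) < n:
            raise RuntimeError(
                f"placed only {len(placed)}/{n} vesicles by RSA; "
                "use method='lattice' for dense packings")
        return placed
    if method == "lattice":
        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        d = vtype.diameter
        # FCC packing: choose cell size a so that the lattice offers
        # comfortably more candidate sites than n
        a = d * 2 ** 0.5 * 1.015   # nearest-neighbor slack for the jitter
        sites = []
        base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5],
                         [0, 0.5, 0.5]])
        nx = np.ceil((hi - lo) / a).astype(int) + 1
        for ix in range(nx[0]):
            for iy in range(nx[1]):
                for iz in range(nx[2]):
                    for b in base:
                        sites.append(lo + a * (np.array([ix, iy, iz]) + b))
        sites = np.asarray(sites)
        rng.shuffle(sites)
        for p in sites:
            if len(placed) >= n:
                break
            jit = rng.uniform(-0.005 * d, 0.005 * d, 3)
            ves = state.add_vesicle(vtype, p + jit, dock=dock)
            if ves is not None:
                placed.append(ves)
        if len(placed) < n:
            raise RuntimeError(
                f"lattice placement reached only {len(placed)}/{n}")
        return placed
    raise ValueError(f"unknown placement method {method!r}")
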