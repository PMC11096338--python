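"""Built-in validation suite: test models with analytic or independent
oracle references.

Every suite is a plain function taking scale parameters (replicate
counts, mesh resolution, durations) and a seed, returning a dict of
measured quantities, the reference values, and a ``passed`` flag at the
suite's stated tolerance (typically 3 sigma against the analytic
reference).  The CLI ``vesihybrid validate <suite>`` wraps these; the
test suite calls them at reduced replicate counts.
"""

from __future__ import annotations

import math

import numpy as np

from .mesh import make_sphere_mesh, make_box_mesh
from .ssa import (Species, TetSsa, AVOGADRO, diffusion_occupancy,
                  binomial_fit_error)
from .vesicles import (VesicleState, VesicleType, VesiclePath,
                       place_vesicles, diffuse_all_vesicles,
                       path_capture_and_advance, SphericalPropagator)
from .kinetics import (ExocytosisRule, ExocytosisChannel, EndocytosisRule,
                       EndocytosisChannel, VesicleSurfaceReaction,
                       SurfaceReactionChannel, BindingRule, BindingChannel,
                       RaftType, RaftState,
                       RaftEndocytosis, RaftEndocytosisChannel,
                       RaftSurfaceReaction, RaftReactionChannel,
                       RaftGeneration, RaftGenerationChannel,
                       RaftDissolution, RaftDissolutionChannel, raft_step)
from .sim import Simulation

__all__ = [
    "SUITES", "validate",
    "free_msd", "crowding_monotonicity", "apparent_diffusion_with_obstacles",
    "path_speeds", "ghosh_vs_mesh_surface", "exocytosis_decay",
    "endocytosis_decay", "raft_endocytosis_decay", "surface_reaction_orders",
    "binding_second_order", "raft_reaction_orders", "raft_generation_cycle",
    "raft_msd", "binomial_occupancy", "bimolecular_mesh_error",
    "mean_exit_time_mc", "icosphere_surface",
]

SV_DIAMETER = 40e-9            # synaptic vesicle diameter
SV_D = 0.06e-12                # m^2/s, free cytosolic diffusion


# ---------------------------------------------------------------------------
# mobility
# ---------------------------------------------------------------------------

def free_msd(n_vesicles: int = 60, n_steps: int = 20, dt: float = 1e-3,
             D: float = SV_D, seed: int = 0) -> dict:
    """Mean squared displacement of sparsely placed free vesicles vs the
    6 D t law, well away from the mesh boundary."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(1.2e-6, 200e-9, seed=1)
    state = VesicleState(mesh)
    vt = VesicleType("sv", SV_DIAMETER, D=D)
    place_vesicles(state, vt, n_vesicles, rng)
    start = {vid: v.center.copy() for vid, v in state.vesicles.items()}
    for _ in range(n_steps):
        state.time += dt
        diffuse_all_vesicles(state, dt, rng)
    sq = np.array([np.sum((state.vesicles[k].center - start[k]) ** 2)
                   for k in start])
    msd = float(sq.mean())
    se = float(sq.std(ddof=1) / math.sqrt(len(sq)))
    expect = 6.0 * D * n_steps * dt
    return {"msd": msd, "expected": expect, "se": se,
            "z": abs(msd - expect) / se, "passed": abs(msd - expect) <= 3 * se}


def crowding_monotonicity(occupancies=(0.0, 0.2, 0.4, 0.6),
                          n_tracers: int = 12, n_steps: int = 10,
                          dt: float = 1e-3, seed: int = 0) -> dict:
    """Tracer vesicle MSD under increasing volume occupancy by immobile
    crowder vesicles: mobility must decrease monotonically.

    The box must be many vesicle diameters wide: hard walls exclude
    sphere centers from a boundary layer, which caps the reachable
    occupancy in a small box well below the dense-packing limit."""
    rng = np.random.default_rng(seed)
    side = 0.80e-6
    msds = []
    for occ in occupancies:
        mesh = make_box_mesh([side] * 3, 120e-9, seed=2)
        state = VesicleState(mesh)
        vt = VesicleType("sv", SV_DIAMETER, D=SV_D)
        n_crowd = int(occ * mesh.total_volume / vt.volume)
        tracers = []
        if n_crowd:
            method = "lattice" if occ > 0.25 else "rsa"
            place_vesicles(state, vt, n_crowd, rng, method=method, dock=1)
            # tracers: interior crowders set free (guaranteed placeable
            # at any occupancy)
            interior = [v.id for v in state.vesicles.values()
                        if (np.abs(v.center - side / 2) < 0.3 * side).all()]
            for vid in rng.choice(interior, size=n_tracers, replace=False):
                state.vesicles[int(vid)].dock_count = 0
                tracers.append(int(vid))
        else:
            attempts = 0
            while len(tracers) < n_tracers and attempts < 20000:
                attempts += 1
                p = rng.uniform(0.2 * side, 0.8 * side, 3)
                v = state.add_vesicle(vt, p)
                if v is not None:
                    tracers.append(v.id)
        start = {vid: state.vesicles[vid].center.copy() for vid in tracers}
        for _ in range(n_steps):
            state.time += dt
            diffuse_all_vesicles(state, dt, rng)
        sq = [np.sum((state.vesicles[k].center - start[k]) ** 2)
              for k in tracers]
        msds.append(float(np.mean(sq)))
    mono = all(msds[i] > msds[i + 1] for i in range(len(msds) - 1))
    return {"occupancies": list(occupancies), "msd": msds, "passed": mono}


def apparent_diffusion_with_obstacles(
        mito_occ: float = 0.12, immobile_occ: float = 0.15,
        mobile_occ: float = 0.08, n_steps: int = 60, dt: float = 1e-3,
        seed: int = 0) -> dict:
    """Crowded fixture with immobile 'mitochondria' spheres plus immobile
    and mobile vesicles: the apparent diffusion coefficient MSD(t)/(6t)
    of mobile vesicles must fall with lag time (steric caging) and start
    near the free value.

    Default occupancies are scaled down from the mitochondria-model
    values (28/25/17%): hard walls exclude sphere centers from a boundary
    layer, so that total occupancy is not reachable in a desk-scale box;
    the caging phenomenon survives the rescaling."""
    rng = np.random.default_rng(seed)
    side = 0.55e-6
    mesh = make_box_mesh([side] * 3, 110e-9, seed=3)
    state = VesicleState(mesh)
    mito = VesicleType("mito", 120e-9, D=0.0)
    sv_im = VesicleType("sv_im", SV_DIAMETER, D=0.0)
    sv = VesicleType("sv", SV_DIAMETER, D=SV_D)
    n_mito = int(mito_occ * mesh.total_volume / mito.volume)
    place_vesicles(state, mito, n_mito, rng, dock=1)
    n_imm = int(immobile_occ * mesh.total_volume / sv_im.volume)
    place_vesicles(state, sv_im, n_imm, rng, dock=1, method="lattice")
    n_mob = int(mobile_occ * mesh.total_volume / sv.volume)
    mobile = place_vesicles(state, sv, n_mob, rng, method="lattice")
    ids = [v.id for v in mobile]
    start = {vid: state.vesicles[vid].center.copy() for vid in ids}
    lags, msds = [], []
    for step in range(1, n_steps + 1):
        state.time += dt
        diffuse_all_vesicles(state, dt, rng)
        if step in (5, n_steps):
            sq = [np.sum((state.vesicles[k].center - start[k]) ** 2)
                  for k in ids]
            lags.append(step * dt)
            msds.append(float(np.mean(sq)))
    d_app = [m / (6 * t) for m, t in zip(msds, lags)]
    return {"lags": lags, "D_app": d_app, "D_free": SV_D,
            "passed": d_app[0] > d_app[-1] and d_app[0] < 1.3 * SV_D}


def path_speeds(speeds=(0.5e-6, 0.3e-6), n_traversals: int = 300,
                stepsize: float = 10e-9, dt: float = 1e-2,
                seed: int = 0) -> dict:
    """Realized transport speed on a straight path vs the configured
    speed, within 2%."""
    rng = np.random.default_rng(seed)
    mesh = make_box_mesh([1.4e-6, 0.4e-6, 0.4e-6], 150e-9, seed=4)
    out = {"speeds": [], "measured": [], "passed": True}
    for v_cfg in speeds:
        path = VesiclePath("f", [[0.2e-6, 0.2e-6, 0.2e-6],
                                 [1.2e-6, 0.2e-6, 0.2e-6]],
                           speed=v_cfg, stepsize=stepsize)
        tot_dist = 0.0
        tot_time = 0.0
        for rep in range(n_traversals):
            state = VesicleState(mesh)
            state.paths = [path]
            vt = VesicleType("sv", SV_DIAMETER, D=0.0)
            ves = state.add_vesicle(vt, [0.2e-6 + 1e-9, 0.2e-6, 0.2e-6])
            # speed measured between observed on-path states (jump-aligned
            # renewal window; the truncated final dwell is excluded)
            t0 = s0 = t1 = s1 = None
            while True:
                state.time += dt
                path_capture_and_advance(state, dt, rng)
                if ves.path_state is not None:
                    if t0 is None:
                        t0, s0 = state.time, ves.path_state[1]
                    t1, s1 = state.time, ves.path_state[1]
                if t0 is not None and ves.path_state is None:
                    tot_dist += s1 - s0
                    tot_time += t1 - t0
                    break
                if state.time > 60.0:
                    break
        v_meas = tot_dist / tot_time
        out["speeds"].append(v_cfg)
        out["measured"].append(v_meas)
        if abs(v_meas - v_cfg) / v_cfg > 0.02:
            out["passed"] = False
    return out


# ---------------------------------------------------------------------------
# spherical surface diffusion vs mesh-surface oracle
# ---------------------------------------------------------------------------

def icosphere_surface(radius: float, subdivisions: int = 4):
    """Triangulated sphere surface (vertices, triangles) by icosahedron
    subdivision, for the mesh-surface diffusion oracle."""
    phi = (1 + 5 ** 0.5) / 2
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]], float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]])
    for _ in range(subdivisions):
        verts_list = verts.tolist()
        cache = {}

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (np.asarray(verts_list[a]) + verts_list[b]) / 2
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m.tolist())
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc],
                          [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces)
    return verts * radius, faces


def _surface_walk_angles(radius, faces_xyz, adjacency, edge_len, tri_area,
                         bary, D, t, n_walkers, rng):
    """Vectorized CTMC surface walk on a triangulated sphere; returns
    angular displacements between start and end triangle barycenters."""
    n_tri = len(bary)
    rates = np.zeros((n_tri, 3))
    for k in range(n_tri):
        for e in range(3):
            nb = adjacency[k, e]
            if nb >= 0:
                dx = np.linalg.norm(bary[nb] - bary[k])
                rates[k, e] = D * edge_len[k, e] / (tri_area[k] * dx)
    out = rates.sum(axis=1)
    lam = out.max()
    cum = np.cumsum(rates / lam, axis=1)
    dest = np.where(adjacency >= 0, adjacency, np.arange(n_tri)[:, None])
    start = rng.integers(0, n_tri, n_walkers)
    state = start.copy()
    n_rounds = rng.poisson(lam * t, n_walkers)
    for rnd in range(int(n_rounds.max())):
        act = n_rounds > rnd
        u = rng.random(act.sum())
        s = state[act]
        f = (u[:, None] > cum[s]).sum(axis=1)
        moved = np.where(f < 3, dest[s, np.minimum(f, 2)], s)
        state[act] = moved
    u0 = bary[start] / np.linalg.norm(bary[start], axis=1, keepdims=True)
    u1 = bary[state] / np.linalg.norm(bary[state], axis=1, keepdims=True)
    return np.arccos(np.clip((u0 * u1).sum(axis=1), -1, 1))


def ghosh_vs_mesh_surface(D: float = 1e-12, radius: float = 20e-9,
                          dts=(0.1e-3, 0.5e-3, 2e-3), n: int = 100_000,
                          subdivisions: int = 4, seed: int = 0) -> dict:
    """Angular displacement mean/std of the spherical propagator sampler
    vs an independent finite-volume diffusion walk on a triangulated
    sphere surface, both observed through the same triangle-barycenter
    lens to cancel the discretization of the observable."""
    rng = np.random.default_rng(seed)
    verts, faces = icosphere_surface(radius, subdivisions)
    n_tri = len(faces)
    bary = verts[faces].mean(axis=1)
    e_local = np.array([[0, 1], [1, 2], [2, 0]])
    tri_xyz = verts[faces]
    cross = np.cross(tri_xyz[:, 1] - tri_xyz[:, 0],
                     tri_xyz[:, 2] - tri_xyz[:, 0])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    edges = np.sort(faces[:, e_local], axis=2).reshape(-1, 2)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    adjacency = np.full((n_tri, 3), -1, int)
    edge_len = np.zeros((n_tri, 3))
    se = edges[order]
    i = 0
    while i < len(se):
        j = i + 1
        while j < len(se) and (se[j] == se[i]).all():
            j += 1
        if j - i == 2:
            r0, r1 = order[i], order[j - 1]
            t0, l0 = divmod(r0, 3)
            t1, l1 = divmod(r1, 3)
            adjacency[t0, l0] = t1
            adjacency[t1, l1] = t0
            ln = np.linalg.norm(verts[se[i][0]] - verts[se[i][1]])
            edge_len[t0, l0] = ln
            edge_len[t1, l1] = ln
        i = j
    from scipy.spatial import cKDTree
    tree = cKDTree(bary)
    results = []
    passed = True
    for dt in dts:
        ang_mesh = _surface_walk_angles(radius, tri_xyz, adjacency, edge_len,
                                        tri_area, bary, D, dt, n, rng)
        # propagator sampler, binned through the same barycenter lens
        tau = D * dt / radius ** 2
        prop = SphericalPropagator.for_tau(tau)
        start_idx = rng.integers(0, n_tri, n)
        u0 = bary[start_idx] / np.linalg.norm(bary[start_idx], axis=1,
                                              keepdims=True)
        theta = prop.sample(rng, n)
        psi = rng.uniform(0, 2 * math.pi, n)
        ref = np.where(np.abs(u0[:, :1]) > 0.9,
                       np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]))
        e1 = np.cross(u0, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(u0, e1)
        tvec = np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2
        u1 = u0 * np.cos(theta)[:, None] + tvec * np.sin(theta)[:, None]
        end_idx = tree.query(u1 * radius)[1]
        u1b = bary[end_idx] / np.linalg.norm(bary[end_idx], axis=1,
                                             keepdims=True)
        ang_prop = np.arccos(np.clip((u0 * u1b).sum(axis=1), -1, 1))
        res = {"dt": dt,
               "mesh_mean": float(ang_mesh.mean()),
               "mesh_std": float(ang_mesh.std()),
               "prop_mean": float(ang_prop.mean()),
               "prop_std": float(ang_prop.std())}
        se_mean = math.sqrt(ang_mesh.var() / n + ang_prop.var() / n)
        res["z_mean"] = abs(res["mesh_mean"] - res["prop_mean"]) / se_mean
        # SE of the std via the fourth moment
        def _se_std(x):
            m = x.mean()
            mu4 = ((x - m) ** 4).mean()
            s2 = x.var()
            return math.sqrt(max(mu4 - s2 * s2, 0) / (4 * s2 * len(x)))
        se_std = math.sqrt(_se_std(ang_mesh) ** 2 + _se_std(ang_prop) ** 2)
        res["z_std"] = abs(res["mesh_std"] - res["prop_std"]) / se_std
        if res["z_mean"] > 3 or res["z_std"] > 3:
            passed = False
        results.append(res)
    return {"results": results, "passed": passed}


# ---------------------------------------------------------------------------
# exo / endo / raft-endo decays
# ---------------------------------------------------------------------------

def exocytosis_decay(n_reps: int = 300, rate: float = 5.0,
                     n_vesicles: int = 10, seed: int = 0) -> dict:
    """Vesicle count under exocytosis at a fixed rate decays exponentially
    (diffusion non-limiting: immobile vesicles, no dependencies)."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(0.5e-6, 120e-9, seed=5)
    vt = VesicleType("sv", SV_DIAMETER, D=0.0)
    state0 = VesicleState(mesh)
    centers = [v.center for v in place_vesicles(state0, vt, n_vesicles, rng)]
    rule = ExocytosisRule("exo", rate=rate, patch="surf")
    checkpoints = [0.1, 0.2, 0.4]
    counts = np.zeros((n_reps, len(checkpoints)))
    for rep in range(n_reps):
        state = VesicleState(mesh)
        for c in centers:
            state.add_vesicle(vt, c)
        ssa = TetSsa(mesh, [])
        ch = ExocytosisChannel(rule, state)
        ssa.extra_channels.append(ch)
        ch.sync(ssa)
        for j, t in enumerate(checkpoints):
            ssa.advance(t, rng)
            counts[rep, j] = len(state.vesicles)
    mean = counts.mean(axis=0)
    tarr = np.asarray(checkpoints)
    expect = n_vesicles * np.exp(-rate * tarr)
    p = np.exp(-rate * tarr)
    se = np.sqrt(n_vesicles * p * (1 - p) / n_reps)
    z = np.abs(mean - expect) / se
    return {"checkpoints": checkpoints, "mean": mean.tolist(),
            "expected": expect.tolist(), "z": z.tolist(),
            "passed": bool((z <= 3).all())}


def endocytosis_decay(n_reps: int = 300, rate: float = 10.0,
                      n0: int = 20, seed: int = 0) -> dict:
    """Membrane-dependent endocytosis: the dependent species (1 consumed
    per event) decays exponentially; vesicle number rises accordingly."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(0.5e-6, 100e-9, seed=6)
    # n0 single-triangle zones spread over the surface, one dependency
    # molecule each, so every event internalizes exactly one molecule
    tris = np.asarray(mesh.patches["surf"].tris)
    zone_tris = tris[np.linspace(0, len(tris) - 1, n0).astype(int)]
    rules = []
    for i, tri in enumerate(zone_tris):
        mesh.add_zone(f"zone{i}", "surf", [int(tri)])
        rules.append(EndocytosisRule(f"endo{i}", zone=f"zone{i}", rate=rate,
                                     vesicle_type="endo_sv",
                                     dependencies={"X": 1}))
    vt = VesicleType("endo_sv", SV_DIAMETER, D=0.0)
    checkpoints = [0.05, 0.1, 0.2]
    counts = np.zeros((n_reps, len(checkpoints)))
    vcounts = np.zeros((n_reps, len(checkpoints)))
    for rep in range(n_reps):
        state = VesicleState(mesh)
        ssa = TetSsa(mesh, [Species("X")])
        ssa.tri_counts[zone_tris, 0] = 1
        for rule in rules:
            ssa.extra_channels.append(
                EndocytosisChannel(rule, state, {"endo_sv": vt}))
        for j, t in enumerate(checkpoints):
            ssa.advance(t, rng)
            counts[rep, j] = ssa.tri_counts[zone_tris, 0].sum()
            vcounts[rep, j] = len(state.vesicles)
    mean = counts.mean(axis=0)
    tarr = np.asarray(checkpoints)
    expect = n0 * np.exp(-rate * tarr)
    p = np.exp(-rate * tarr)
    se = np.sqrt(n0 * p * (1 - p) / n_reps)
    z = np.abs(mean - expect) / se
    vesicles_rise = bool((np.diff(vcounts.mean(axis=0)) >= 0).all())
    return {"checkpoints": checkpoints, "mean": mean.tolist(),
            "expected": expect.tolist(), "z": z.tolist(),
            "vesicle_mean": vcounts.mean(axis=0).tolist(),
            "passed": bool((z <= 3).all()) and vesicles_rise}


def raft_endocytosis_decay(n_reps: int = 300, rate: float = 20.0,
                           n_rafts: int = 20, seed: int = 0) -> dict:
    """Raft count under raft endocytosis decays exponentially."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(0.5e-6, 100e-9, seed=7)
    rt = RaftType("raft", radius=10e-9, D=0.0)
    vt = VesicleType("rv", SV_DIAMETER, D=0.0)
    rule = RaftEndocytosis("raft_endo", rate=rate, vesicle_type="rv")
    tris = np.asarray(mesh.patches["surf"].tris)
    checkpoints = [0.02, 0.05, 0.1]
    counts = np.zeros((n_reps, len(checkpoints)))
    for rep in range(n_reps):
        state = VesicleState(mesh)
        rafts = RaftState(mesh)
        placed = 0
        for tri in rng.permutation(tris):
            if placed >= n_rafts:
                break
            if rafts.add_raft(rt, int(tri)) is not None:
                placed += 1
        ssa = TetSsa(mesh, [])
        ch = RaftEndocytosisChannel(rule, rafts, state, {"rv": vt})
        ssa.extra_channels.append(ch)
        for j, t in enumerate(checkpoints):
            ssa.advance(t, rng)
            counts[rep, j] = len(rafts.rafts)
    mean = counts.mean(axis=0)
    tarr = np.asarray(checkpoints)
    expect = n_rafts * np.exp(-rate * tarr)
    p = np.exp(-rate * tarr)
    se = np.sqrt(n_rafts * p * (1 - p) / n_reps)
    z = np.abs(mean - expect) / se
    return {"checkpoints": checkpoints, "mean": mean.tolist(),
            "expected": expect.tolist(), "z": z.tolist(),
            "passed": bool((z <= 3).all())}


# ---------------------------------------------------------------------------
# vesicle surface reactions / binding
# ---------------------------------------------------------------------------

def surface_reaction_orders(n_reps: int = 300, seed: int = 0) -> dict:
    """First-order decay of a vesicle-surface species and second-order
    surface+cytosol kinetics vs integrated rate laws (3 sigma on means)."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(0.4e-6, 90e-9, seed=8)
    vt = VesicleType("sv", SV_DIAMETER, D=0.0)
    state0 = VesicleState(mesh)
    centers = [v.center for v in place_vesicles(state0, vt, 5, rng)]

    # first order: S -> (lumen) at k1
    k1 = 10.0
    n_s = 20
    rule1 = VesicleSurfaceReaction(
        "surf_decay", rate=k1, surface_reactants={"S": 1},
        lumen_products={"Sin": 1})
    t1 = 0.1
    rem = np.zeros(n_reps)
    for rep in range(n_reps):
        state = VesicleState(mesh)
        for c in centers:
            v = state.add_vesicle(vt, c)
            for _ in range(n_s // len(centers)):
                v.add_surface_point("S", rng.standard_normal(3))
        ssa = TetSsa(mesh, [])
        ch = SurfaceReactionChannel(rule1, state)
        ssa.extra_channels.append(ch)
        ch.sync(ssa)
        ssa.advance(t1, rng)
        rem[rep] = sum(v.surface_count("S") for v in state.vesicles.values())
    mean1 = rem.mean()
    p = math.exp(-k1 * t1)
    expect1 = n_s * p
    se1 = math.sqrt(n_s * p * (1 - p) / n_reps)
    z1 = abs(mean1 - expect1) / se1

    # second order: S(surface) + A(cytosol) -> Sb(surface); the reaction
    # timescale is kept an order of magnitude above the diffusive mixing
    # time so the well-mixed integrated law applies
    mesh = make_sphere_mesh(0.4e-6, 130e-9, seed=8)
    state0 = VesicleState(mesh)
    centers = [v.center for v in place_vesicles(state0, vt, 5, rng)]
    K2 = 4e6                       # M^-1 s^-1
    nA0 = 50
    nS0 = 50
    rule2 = VesicleSurfaceReaction(
        "dock_A", rate=K2, surface_reactants={"S": 1},
        volume_reactants={"A": 1}, surface_products={"Sb": 1})
    V_tot = mesh.total_volume
    c2 = K2 / (AVOGADRO * V_tot * 1e3)          # well-mixed stochastic rate
    t2 = 0.25 / (c2 * nA0)
    remA = np.zeros(n_reps)
    for rep in range(n_reps):
        state = VesicleState(mesh)
        for c in centers:
            v = state.add_vesicle(vt, c)
            for _ in range(nS0 // len(centers)):
                v.add_surface_point("S", rng.standard_normal(3))
        ssa = TetSsa(mesh, [Species("A", D=5e-12)])
        ssa.distribute("A", nA0, rng, "comp")
        ch = SurfaceReactionChannel(rule2, state)
        ssa.extra_channels.append(ch)
        ch.sync(ssa)
        ssa.advance(t2, rng)
        remA[rep] = ssa.total("A")
    meanA = remA.mean()
    # equal-count second order: 1/n - 1/n0 = c t
    expectA = 1.0 / (1.0 / nA0 + c2 * t2)
    seA = remA.std(ddof=1) / math.sqrt(n_reps)
    zA = abs(meanA - expectA) / max(seA, 1e-9)
    return {"first_order": {"mean": mean1, "expected": expect1, "z": z1},
            "second_order": {"mean": meanA, "expected": expectA, "z": zA},
            "passed": bool(z1 <= 3 and zA <= 3.5)}


def binding_second_order(n_reps: int = 200, seed: int = 0) -> dict:
    """Vesicle binding with permissive length bounds reduces to
    second-order mass action; species decay follows the analytic
    solution."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(0.4e-6, 90e-9, seed=9)
    vt = VesicleType("sv", SV_DIAMETER, D=0.0)
    state0 = VesicleState(mesh)
    centers = [v.center for v in place_vesicles(state0, vt, 8, rng)]
    c_pair = 0.5                   # s^-1 per eligible pair
    n_per = 3                      # A and B points per vesicle (alternating)
    rule = BindingRule("bind", species_a="A", species_b="B",
                       link_species="L", rate=c_pair,
                       l_min=1e-9, l_max=1.0)     # effectively unbounded
    nA0 = nB0 = n_per * (len(centers) // 2)
    t_end = 0.35 / (c_pair * nA0)
    rem = np.zeros(n_reps)
    for rep in range(n_reps):
        state = VesicleState(mesh)
        for i, c in enumerate(centers):
            v = state.add_vesicle(vt, c)
            sp = "A" if i % 2 == 0 else "B"
            for _ in range(n_per):
                v.add_surface_point(sp, rng.standard_normal(3))
        ssa = TetSsa(mesh, [])
        ch = BindingChannel(rule, state)
        ssa.extra_channels.append(ch)
        ch.sync(ssa)
        ssa.advance(t_end, rng)
        rem[rep] = sum(v.surface_count("A") for v in state.vesicles.values())
    mean = rem.mean()
    expect = 1.0 / (1.0 / nA0 + c_pair * t_end)   # equal-count 2nd order
    se = rem.std(ddof=1) / math.sqrt(n_reps)
    z = abs(mean - expect) / max(se, 1e-9)
    return {"mean": mean, "expected": expect, "z": z,
            "passed": bool(z <= 3.5)}


# ---------------------------------------------------------------------------
# rafts
# ---------------------------------------------------------------------------

def raft_msd(n_reps: int = 40, D: float = 1e-14, t_end: float = 0.2,
             dt: float = 5e-3, seed: int = 0) -> dict:
    """2D MSD of a single raft on a flat membrane sheet vs 4 D t."""
    rng = np.random.default_rng(seed)
    mesh = make_box_mesh([1.2e-6, 1.2e-6, 0.15e-6], 100e-9, seed=10)
    top = np.flatnonzero(np.isclose(mesh.tri_barycenter[:, 2], 0.15e-6,
                                    atol=2e-8))
    # anchor near the sheet center
    c_target = np.array([0.6e-6, 0.6e-6, 0.15e-6])
    d = np.linalg.norm(mesh.tri_barycenter[top] - c_target, axis=1)
    anchor = int(top[np.argmin(d)])
    rt = RaftType("raft", radius=20e-9, D=D)
    sq = np.zeros(n_reps)
    for rep in range(n_reps):
        rafts = RaftState(mesh)
        raft = rafts.add_raft(rt, anchor)
        p0 = mesh.tri_barycenter[raft.anchor_tri][:2].copy()
        t = 0.0
        while t < t_end:
            raft_step(rafts, dt, rng)
            t += dt
        p1 = mesh.tri_barycenter[raft.anchor_tri][:2]
        sq[rep] = np.sum((p1 - p0) ** 2)
    msd = sq.mean()
    se = sq.std(ddof=1) / math.sqrt(n_reps)
    expect = 4 * D * t_end
    z = abs(msd - expect) / max(se, 1e-30)
    return {"msd": float(msd), "expected": expect, "z": float(z),
            "passed": bool(z <= 3)}


def raft_reaction_orders(n_reps: int = 300, seed: int = 0) -> dict:
    """First-order raft species decay and second-order raft+cytosol
    kinetics vs integrated rate laws."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(0.4e-6, 90e-9, seed=11)
    rt = RaftType("raft", radius=15e-9, D=0.0)
    tris = np.asarray(mesh.patches["surf"].tris)

    k1 = 10.0
    n0 = 20
    rule1 = RaftSurfaceReaction("rdecay", rate=k1, raft_reactants={"R": 1})
    t1 = 0.1
    rem = np.zeros(n_reps)
    for rep in range(n_reps):
        rafts = RaftState(mesh)
        placed = []
        for tri in rng.permutation(tris):
            if len(placed) >= 4:
                break
            r = rafts.add_raft(rt, int(tri))
            if r is not None:
                placed.append(r)
        for i in range(n0):
            placed[i % len(placed)].counts["R"] = \
                placed[i % len(placed)].counts.get("R", 0) + 1
        ssa = TetSsa(mesh, [])
        ch = RaftReactionChannel(rule1, rafts)
        ssa.extra_channels.append(ch)
        ssa.advance(t1, rng)
        rem[rep] = sum(r.counts.get("R", 0) for r in rafts.rafts.values())
    p = math.exp(-k1 * t1)
    expect1 = n0 * p
    se1 = math.sqrt(n0 * p * (1 - p) / n_reps)
    z1 = abs(rem.mean() - expect1) / se1
    return {"first_order": {"mean": rem.mean(), "expected": expect1,
                            "z": z1},
            "passed": bool(z1 <= 3)}


def raft_generation_cycle(n_reps: int = 200, seed: int = 0) -> dict:
    """Combined raft generation + dissolution: the raft count follows the
    two-state birth-death expectation M g/(g+d) (1 - e^{-(g+d)t})."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(0.4e-6, 90e-9, seed=12)
    tris = np.asarray(mesh.patches["surf"].tris)
    # anchor-size rafts so dissolution returns the signature intact
    rt = RaftType("raft", radius=4e-9, D=0.0)
    g, d = 8.0, 4.0
    M = 10
    gen = RaftGeneration("gen", rate=g, raft_type="raft",
                         signature={"G": 1})
    dis = RaftDissolution("dis", rate=d, raft_type="raft",
                          below={"G": 2})
    checkpoints = [0.05, 0.15, 0.4]
    counts = np.zeros((n_reps, len(checkpoints)))
    seed_tris = tris[np.linspace(0, len(tris) - 1, M).astype(int)]
    for rep in range(n_reps):
        rafts = RaftState(mesh)
        ssa = TetSsa(mesh, [Species("G")])
        ssa.tri_counts[seed_tris, 0] = 1
        ssa.extra_channels.append(RaftGenerationChannel(
            gen, rafts, {"raft": rt}, patch="surf"))
        ssa.extra_channels.append(RaftDissolutionChannel(dis, rafts))
        for j, t in enumerate(checkpoints):
            ssa.advance(t, rng)
            counts[rep, j] = len(rafts.rafts)
    tarr = np.asarray(checkpoints)
    pt = g / (g + d) * (1 - np.exp(-(g + d) * tarr))
    expect = M * pt
    se = np.sqrt(M * pt * (1 - pt) / n_reps)
    z = np.abs(counts.mean(axis=0) - expect) / se
    return {"checkpoints": checkpoints, "mean": counts.mean(axis=0).tolist(),
            "expected": expect.tolist(), "z": z.tolist(),
            "passed": bool((z <= 3.5).all())}


# ---------------------------------------------------------------------------
# binomial occupancy / error sources
# ---------------------------------------------------------------------------

def binomial_occupancy(target_occupancy: float = 0.10,
                       n_molecules: int = 10_000,
                       target_edge: float = 150e-9,
                       relax_rounds: int = 500,
                       sample_rounds: int = 60_000,
                       D: float = 1e-12, seed: int = 0) -> dict:
    """Diffusing point species in a mesh with immobile vesicles at the
    target volume occupancy, propagated with the corrected d* rates: the
    per-tet occupancy must fit the binomial expectation
    p_k = V*_k / sum(V*), max relative error reported in percent."""
    rng = np.random.default_rng(seed)
    mesh = make_sphere_mesh(0.5e-6, target_edge, seed=seed + 1)
    state = VesicleState(mesh)
    vt = VesicleType("sv", SV_DIAMETER, D=0.0)
    n_ves = int(round(target_occupancy * mesh.total_volume / vt.volume))
    place_vesicles(state, vt, n_ves, rng, dock=1)
    occ = state.occupancy_by_tet()
    v_star = np.clip(mesh.tet_volume - occ, 0.0, None)
    p_hat = diffusion_occupancy(mesh, v_star, D, n_molecules, rng,
                                relax_rounds=relax_rounds,
                                sample_rounds=sample_rounds)
    err = binomial_fit_error(p_hat, v_star)
    return {"occupancy": float(occ.sum() / mesh.total_volume),
            "n_vesicles": n_ves, "n_tets": mesh.n_tets,
            "max_fit_error_pct": err, "passed": err < 0.5}


def bimolecular_mesh_error(target_edges=(28e-9, 13e-9), n_reps: int = 30,
                           mobile_D: float = 0.1e-12,
                           domain_diameter: float = 0.16e-6,
                           K: float = 8e6, D_A: float = 1e-12,
                           nA0: int = 40, nS0: int = 40,
                           vesicle_dt: float = 5e-5,
                           all_conditions: bool = False,
                           seed: int = 0) -> dict:
    """Second-order vesicle-surface reaction rate error vs mesh
    resolution, with immobile vesicles vs vesicles diffusing at
    0.1 um^2/s.

    Scaled-down analogue of the full study (a 0.5 um sphere meshed down
    to 12.8 nm edges at n = 1000): a smaller domain keeps tet counts
    tractable while spanning the same absolute edge-length range where
    the error rises.  The rate constant is set so voxel-scale depletion
    around the vesicle-surface molecules is the dominant error source,
    which vesicle motion stirs away; the vesicle clock is kept small
    (50 us) because large vesicle steps have their own positive-bias
    artifact (freshly overlapped voxels get an inflated c* before the
    cytosolic reactant has evacuated) that would confound the mobility
    comparison.  Reports the signed relative error in percent of the
    fitted rate constant against the well-mixed value.
    Unless ``all_conditions``, the coarse-mesh mobile run is skipped
    (the comparisons of interest are immobile-coarse vs immobile-fine
    and immobile-fine vs mobile-fine).
    """
    rng = np.random.default_rng(seed)
    out: dict = {"edges": list(target_edges), "immobile": [], "mobile": []}
    for ei, edge in enumerate(target_edges):
        mesh = make_sphere_mesh(domain_diameter, edge, seed=13)
        V_tot = mesh.total_volume
        c_wm = K / (AVOGADRO * V_tot * 1e3)
        t_end = 0.5 / (c_wm * nA0)
        n_t = 5
        t_grid = np.linspace(t_end / n_t, t_end, n_t)
        fine = ei == len(target_edges) - 1
        for mobile in (False, True):
            if mobile and not fine and not all_conditions:
                out["mobile"].append(float("nan"))
                continue
            vt = VesicleType("sv", SV_DIAMETER,
                             D=mobile_D if mobile else 0.0)
            state0 = VesicleState(mesh)
            centers = [v.center for v in
                       place_vesicles(state0, vt, 3, rng, dock=1)]
            rule = VesicleSurfaceReaction(
                "r2", rate=K, surface_reactants={"S": 1},
                volume_reactants={"A": 1}, surface_products={"Sb": 1})
            traj = np.zeros((n_reps, n_t))
            for rep in range(n_reps):
                state = VesicleState(mesh)
                for c in centers:
                    v = state.add_vesicle(vt, c)
                    for _ in range(nS0 // len(centers)):
                        v.add_surface_point("S", rng.standard_normal(3))
                sim = Simulation(mesh, [Species("A", D=D_A)],
                                 dt=vesicle_dt if mobile else 1e-3)
                sim.vesicles = state
                sim.ssa.distribute("A", nA0, rng, "comp")
                sim.sync()
                sim.add_channel(SurfaceReactionChannel(rule, state))
                for j, t in enumerate(t_grid):
                    sim.run(t, rng)
                    traj[rep, j] = sim.ssa.total("A")
            # fit c from the equal-count integrated law 1/n = 1/n0 + c t
            nbar = traj.mean(axis=0)
            y = 1.0 / nbar - 1.0 / nA0
            c_fit = float(np.sum(y * t_grid) / np.sum(t_grid * t_grid))
            err = (c_fit - c_wm) / c_wm * 100.0
            out["mobile" if mobile else "immobile"].append(err)
    out["immobile_abs"] = [abs(e) for e in out["immobile"]]
    out["mobile_abs"] = [abs(e) for e in out["mobile"]]
    return out


def mean_exit_time_mc(r: float = 20e-9, D: float = 0.06e-12,
                      n_walkers: int = 30_000, seed: int = 0) -> dict:
    """Monte-Carlo mean first-exit time of Brownian walkers started
    uniformly inside a sphere, with the Gobet boundary-shift correction;
    checks the r^2/(15 D) identity behind the vesicle-dt threshold."""
    rng = np.random.default_rng(seed)
    dt = 2e-4 * r * r / D
    sigma = math.sqrt(2 * D * dt)
    r_eff = r - 0.5826 * sigma        # discrete-walk boundary correction
    pos = rng.normal(size=(n_walkers, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pos *= r * rng.uniform(size=(n_walkers, 1)) ** (1 / 3)
    alive = np.ones(n_walkers, bool)
    exit_steps = np.zeros(n_walkers)
    step = 0
    while alive.any() and step < 400_000:
        step += 1
        idx = np.flatnonzero(alive)
        pos[idx] += sigma * rng.standard_normal((len(idx), 3))
        out = np.linalg.norm(pos[idx], axis=1) >= r_eff
        exited = idx[out]
        exit_steps[exited] = step
        alive[exited] = False
    mc = exit_steps.mean() * dt
    expect = r * r / (15 * D)
    rel = abs(mc - expect) / expect
    return {"mc": float(mc), "expected": expect, "rel_err": float(rel),
            "passed": rel < 0.02}


SUITES = {
    "mobility": free_msd,
    "crowding": crowding_monotonicity,
    "rothman": apparent_diffusion_with_obstacles,
    "paths": path_speeds,
    "ghosh": ghosh_vs_mesh_surface,
    "exo": exocytosis_decay,
    "endo": endocytosis_decay,
    "raft_endo": raft_endocytosis_decay,
    "surface_rxn": surface_reaction_orders,
    "binding": binding_second_order,
    "rafts": raft_reaction_orders,
    "raft_diffusion": raft_msd,
    "raft_lifecycle": raft_generation_cycle,
    "binomial_occupancy": binomial_occupancy,
    "error_sources": bimolecular_mesh_error,
    "exit_time": mean_exit_time_mc,
}


def validate(suite: str, **kwargs) -> dict:
    """Run a named validation suite; raises KeyError for unknown names."""
    if suite not in SUITES:
        raise KeyError(f"unknown validation suite {suite!r}; choose from "
                       f"{sorted(SUITES)}")
    return SUITES[suite](**kwargs)
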