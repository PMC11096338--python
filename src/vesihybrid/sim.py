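"""Simulation orchestration: the hybrid SSA / vesicle-clock timeline.

The engine alternates exact SSA integration of reaction-diffusion (plus
all injected kinetic-process channels) with vesicle and raft updates on a
fixed clock dt (default 1 ms): between ticks the SSA runs exactly; on a
tick vesicles diffuse (hard-sphere accept/reject), path transport and
surface diffusion advance, rafts hop, reduced tet volumes V* are
recomputed from the new overlaps and all channel propensity caches are
refreshed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh
from .ssa import Species, Reaction, TetSsa
from .vesicles import (VesicleState, VesicleType, diffuse_all_vesicles,
                       path_capture_and_advance, surface_diffuse)
from .kinetics import RaftState, raft_step

__all__ = ["Simulation", "Recorder", "export_trajectory"]

DEFAULT_VESICLE_DT = 1e-3      # s


@dataclass
class Recorder:
    """Samples quantities every ``period`` seconds of simulated time.

    ``probes`` maps a column name to a callable(sim) -> float.
    """
    period: float
    probes: dict = field(default_factory=dict)
    times: list = field(default_factory=list)
    rows: list = field(default_factory=list)
    _next: float = 0.0

    def maybe_record(self, sim, t):
        while t >= self._next - 1e-15:
            self.times.append(self._next)
            self.rows.append([f(sim) for f in self.probes.values()])
            self._next += self.period

    def as_dict(self):
        cols = list(self.probes)
        arr = np.asarray(self.rows) if self.rows else np.empty((0, len(cols)))
        out = {"time": np.asarray(self.times)}
        for j, c in enumerate(cols):
            out[c] = arr[:, j]
        return out


class Simulation:
    """One hybrid simulation over a mesh."""

    def __init__(self, mesh: Mesh, species: list[Species],
                 reactions: list[Reaction] = (), *,
                 dt: float = DEFAULT_VESICLE_DT,
                 surface_D: dict[str, float] | None = None):
        if dt <= 0:
            raise ValueError("vesicle dt must be > 0")
        self.mesh = mesh
        self.ssa = TetSsa(mesh, species, reactions)
        self.vesicles = VesicleState(mesh)
        self.rafts = RaftState(mesh)
        self.dt = dt
        self.surface_D = dict(surface_D or {})
        self.vesicle_types: dict[str, VesicleType] = {}
        self.time = 0.0
        self.frames: list[dict] = []      # optional trajectory frames

    # -- setup ----------------------------------------------------------
    def add_vesicle_type(self, vt: VesicleType):
        self.vesicle_types[vt.name] = vt
        return vt

    def add_channel(self, ch):
        self.ssa.extra_channels.append(ch)
        ch.sync(self.ssa)
        return ch

    def sync(self):
        """Recompute V* from vesicle overlaps and refresh all caches."""
        self.ssa.set_occupancy(self.vesicles.occupancy_by_tet())
        for ch in self.ssa.extra_channels:
            ch.sync(self.ssa)

    # -- main loop ------------------------------------------------------
    def run(self, until: float, rng, recorders: list[Recorder] = (),
            record_positions: bool = False):
        """Advance to ``until`` interleaving SSA and vesicle updates."""
        has_vesicle_work = bool(self.vesicles.vesicles or self.rafts.rafts
                                or self.vesicles.paths)
        for rec in recorders:
            rec.maybe_record(self, self.time)
        while self.time < until - 1e-15:
            t_next = min(self.time + self.dt, until)
            self.ssa.advance(t_next, rng)
            self.time = t_next
            self.vesicles.time = t_next
            if has_vesicle_work or self.vesicles.vesicles:
                diffuse_all_vesicles(self.vesicles, self.dt, rng)
                if self.vesicles.paths:
                    path_capture_and_advance(self.vesicles, self.dt, rng)
                if self.surface_D:
                    surface_diffuse(self.vesicles, self.dt, rng,
                                    self.surface_D)
                if self.rafts.rafts:
                    raft_step(self.rafts, self.dt, rng)
                self.sync()
            if record_positions:
                self.frames.append({
                    "time": self.time,
                    "ids": [vid for vid in self.vesicles.vesicles],
                    "types": [v.vtype.name for v in
                              self.vesicles.vesicles.values()],
                    "pos": np.array([v.center for v in
                                     self.vesicles.vesicles.values()])
                    if self.vesicles.vesicles else np.empty((0, 3)),
                })
            for rec in recorders:
                rec.maybe_record(self, self.time)
        return self


def export_trajectory(sim: Simulation, path, recorders=()) -> None:
    """Write the recorded trajectory to HDF5.

    Layout: /mesh/vertices, /mesh/tets; /vesicles/time (T,), /vesicles/ids
    (N,), /vesicles/positions (T, N, 3) NaN-padded for vesicles absent in
    a frame; /species/<name> per-tet counts of the final state;
    /recorders/<quantity> time series with /recorders/time in seconds.
    """
    import h5py
    with h5py.File(path, "w") as f:
        gm = f.create_group("mesh")
        gm.create_dataset("vertices", data=sim.mesh.vertices)
        gm.create_dataset("tets", data=sim.mesh.tets)
        if sim.frames:
            all_ids = sorted({vid for fr in sim.frames for vid in fr["ids"]})
            idx = {vid: i for i, vid in enumerate(all_ids)}
            T = len(sim.frames)
            pos = np.full((T, len(all_ids), 3), np.nan)
            times = np.empty(T)
            for t, fr in enumerate(sim.frames):
                times[t] = fr["time"]
                for vid, p in zip(fr["ids"], fr["pos"]):
                    pos[t, idx[vid]] = p
            type_of: dict[int, str] = {}
            for fr in sim.frames:
                for vid, tn in zip(fr["ids"], fr.get("types", ())):
                    type_of[vid] = tn
            gv = f.create_group("vesicles")
            gv.create_dataset("time", data=times)
            gv.create_dataset("ids", data=np.asarray(all_ids))
            gv.create_dataset("positions", data=pos)
            gv.create_dataset(
                "types",
                data=np.array([type_of.get(v, "") for v in all_ids],
                              dtype="S32"))
        gs = f.create_group("species")
        for name, i in sim.ssa.s_index.items():
            gs.create_dataset(name, data=sim.ssa.counts[:, i])
        if recorders:
            gr = f.create_group("recorders")
            for rec in recorders:
                for col, series in rec.as_dict().items():
                    key = col if col not in gr else f"{col}_{id(rec):x}"
                    gr.create_dataset(key, data=np.asarray(series))
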