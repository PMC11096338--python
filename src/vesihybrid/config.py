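"""YAML model configuration: parsing and simulation assembly.

A model file declares the mesh (generated fixture or file), species,
vesicle and raft types with initial populations, reactions and the
vesicle/raft kinetic processes, plus run settings.  All quantities are
SI: meters, seconds, m^2/s, s^-1 or M^-1 s^-1 for rates.  The loader
validates against a light schema and returns a ready
:class:`~vesihybrid.sim.Simulation`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .mesh import load_mesh, make_sphere_mesh, make_box_mesh
from .ssa import Species, Reaction
from .sim import Simulation, Recorder, DEFAULT_VESICLE_DT
from .vesicles import VesicleType, VesiclePath, place_vesicles
from .kinetics import (VesicleSurfaceReaction, BindingRule, UnbindingRule,
                       ExocytosisRule, EndocytosisRule, RaftType,
                       SurfaceReactionChannel, BindingChannel,
                       UnbindingChannel, ExocytosisChannel,
                       EndocytosisChannel, RaftSurfaceReaction,
                       RaftReactionChannel, RaftEndocytosis,
                       RaftEndocytosisChannel, RaftGeneration,
                       RaftGenerationChannel, RaftDissolution,
                       RaftDissolutionChannel)

__all__ = ["ModelConfigError", "load_config", "build_simulation"]


class ModelConfigError(Exception):
    pass


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ModelConfigError("model file must be a YAML mapping")
    return cfg


def _build_mesh(cfg: dict, base_dir: Path):
    m = cfg.get("mesh")
    if m is None:
        raise ModelConfigError("missing 'mesh' section")
    if "generate" in m:
        g = m["generate"]
        shape = g.get("shape", "sphere")
        if shape == "sphere":
            return make_sphere_mesh(float(g["diameter"]),
                                    float(g["target_edge"]),
                                    seed=int(g.get("seed", 0)))
        if shape == "box":
            return make_box_mesh([float(x) for x in g["lengths"]],
                                 float(g["target_edge"]),
                                 seed=int(g.get("seed", 0)))
        raise ModelConfigError(f"unknown generated shape {shape!r}")
    if "file" in m:
        return load_mesh(base_dir / m["file"], m.get("format", "gmsh2"),
                         float(m.get("scale", 1.0)))
    raise ModelConfigError("mesh section needs 'generate' or 'file'")


def _counts(d) -> dict[str, int]:
    return {str(k): int(v) for k, v in (d or {}).items()}


def build_simulation(cfg: dict, rng, base_dir: Path | None = None
                     ) -> tuple[Simulation, list[Recorder]]:
    """Assemble a Simulation (mesh, species, vesicles, rafts, channels,
    initial conditions and recorders) from a parsed model config."""
    base_dir = Path(base_dir or ".")
    mesh = _build_mesh(cfg, base_dir)

    species = [Species(s["name"], float(s.get("D", 0.0)))
               for s in cfg.get("species", [])]
    reactions = []
    for r in cfg.get("reactions", []):
        reactions.append(Reaction(
            r["name"], float(r["rate"]),
            reactants=_counts(r.get("reactants")),
            products=_counts(r.get("products")),
            surface_reactants=_counts(r.get("surface_reactants")),
            surface_products=_counts(r.get("surface_products")),
            compartment=r.get("compartment"), patch=r.get("patch")))

    run = cfg.get("run", {})
    dt = float(run.get("dt", DEFAULT_VESICLE_DT))
    sim = Simulation(mesh, species, reactions, dt=dt,
                     surface_D={k: float(v) for k, v in
                                (cfg.get("surface_diffusion") or {}).items()})

    for z in cfg.get("zones", []):
        mesh.add_zone(z["name"], z.get("patch", "surf"),
                      [int(t) for t in z["tris"]])

    for p in cfg.get("paths", []):
        law = p.get("dwell_law", ["single_exp"])
        sim.vesicles.paths.append(VesiclePath(
            p["name"], np.asarray(p["nodes"], float),
            speed=float(p["speed"]), stepsize=float(p["stepsize"]),
            dwell_law=tuple(law) if isinstance(law, (list, tuple))
            else (law,),
            capture_radius=(float(p["capture_radius"])
                            if "capture_radius" in p else None),
            capture_prob=float(p.get("capture_prob", 1.0))))

    # species initial counts
    for s in cfg.get("species", []):
        n = int(s.get("count", 0))
        if n:
            sim.ssa.distribute(s["name"], n, rng,
                               s.get("compartment") or None)

    # vesicles
    for v in cfg.get("vesicle_types", []):
        vt = sim.add_vesicle_type(VesicleType(
            v["name"], float(v["diameter"]), float(v.get("D", 0.0))))
        n = int(v.get("count", 0))
        if n:
            placed = place_vesicles(
                sim.vesicles, vt, n, rng,
                method=v.get("placement", "rsa"),
                dock=int(v.get("dock", 0)))
            for ves in placed:
                for sp, k in _counts(v.get("surface_init")).items():
                    for _ in range(k):
                        ves.add_surface_point(sp, rng.standard_normal(3))
                for sp, k in _counts(v.get("lumen_init")).items():
                    ves.lumen[sp] = k

    # rafts
    raft_types = {}
    for r in cfg.get("raft_types", []):
        rt = RaftType(r["name"], float(r["radius"]), float(r.get("D", 0.0)))
        raft_types[rt.name] = rt
        n = int(r.get("count", 0))
        tris = np.asarray(mesh.patches[r.get("patch", "surf")].tris)
        placed = 0
        for tri in rng.permutation(tris):
            if placed >= n:
                break
            raft = sim.rafts.add_raft(rt, int(tri))
            if raft is not None:
                raft.counts.update(_counts(r.get("counts_init")))
                placed += 1
        if placed < n:
            raise ModelConfigError(
                f"could not place {n} rafts of type {rt.name!r}")

    # kinetic processes
    vs = sim.vesicles
    for r in cfg.get("vesicle_surface_reactions", []):
        rule = VesicleSurfaceReaction(
            r["name"], float(r["rate"]),
            vesicle_type=r.get("vesicle_type"),
            surface_reactants=_counts(r.get("surface_reactants")),
            volume_reactants=_counts(r.get("volume_reactants")),
            membrane_reactants=_counts(r.get("membrane_reactants")),
            surface_products=_counts(r.get("surface_products")),
            volume_products=_counts(r.get("volume_products")),
            lumen_products=_counts(r.get("lumen_products")),
            membrane_products=_counts(r.get("membrane_products")),
            patch=r.get("patch"),
            max_distance=(float(r["max_distance"])
                          if "max_distance" in r else None),
            dock_delta=int(r.get("dock_delta", 0)))
        sim.add_channel(SurfaceReactionChannel(rule, vs))
    binding_channels = []
    for r in cfg.get("binding", []):
        rule = BindingRule(r["name"], r["species_a"], r["species_b"],
                           r["link_species"], float(r["rate"]),
                           float(r["l_min"]), float(r["l_max"]))
        binding_channels.append(
            sim.add_channel(BindingChannel(rule, vs)))
    for r in cfg.get("unbinding", []):
        rule = UnbindingRule(r["name"], r["link_species"], r["species_a"],
                             r["species_b"], float(r["rate"]))
        sim.add_channel(UnbindingChannel(rule, vs, binding_channels))
    for r in cfg.get("exocytosis", []):
        rule = ExocytosisRule(
            r["name"], float(r["rate"]), r.get("patch", "surf"),
            mode=r.get("mode", "full_collapse"),
            release_fraction=float(r.get("release_fraction", 1.0)),
            dependencies=_counts(r.get("dependencies")),
            anti_dependencies=_counts(r.get("anti_dependencies")),
            vesicle_type=r.get("vesicle_type"),
            max_distance=(float(r["max_distance"])
                          if "max_distance" in r else None),
            raft_type=r.get("raft_type"))
        sim.add_channel(ExocytosisChannel(
            rule, vs, rafts=sim.rafts, raft_types=raft_types,
            outer_compartment=r.get("outer_compartment")))
    for r in cfg.get("endocytosis", []):
        rule = EndocytosisRule(
            r["name"], r["zone"], float(r["rate"]),
            vesicle_type=r["vesicle_type"],
            dependencies=_counts(r.get("dependencies")),
            anti_dependencies=_counts(r.get("anti_dependencies")))
        sim.add_channel(EndocytosisChannel(rule, vs, sim.vesicle_types))
    for r in cfg.get("raft_surface_reactions", []):
        rule = RaftSurfaceReaction(
            r["name"], float(r["rate"]), raft_type=r.get("raft_type"),
            raft_reactants=_counts(r.get("raft_reactants")),
            volume_reactants=_counts(r.get("volume_reactants")),
            tri_reactants=_counts(r.get("tri_reactants")),
            raft_products=_counts(r.get("raft_products")),
            volume_products=_counts(r.get("volume_products")),
            tri_products=_counts(r.get("tri_products")))
        sim.add_channel(RaftReactionChannel(rule, sim.rafts))
    for r in cfg.get("raft_endocytosis", []):
        rule = RaftEndocytosis(
            r["name"], float(r["rate"]), raft_type=r.get("raft_type"),
            vesicle_type=r["vesicle_type"],
            dependencies=_counts(r.get("dependencies")),
            anti_dependencies=_counts(r.get("anti_dependencies")))
        sim.add_channel(RaftEndocytosisChannel(rule, sim.rafts, vs,
                                               sim.vesicle_types))
    for r in cfg.get("raft_generation", []):
        rule = RaftGeneration(r["name"], float(r["rate"]),
                              raft_type=r["raft_type"],
                              signature=_counts(r.get("signature")))
        sim.add_channel(RaftGenerationChannel(rule, sim.rafts, raft_types,
                                              patch=r.get("patch")))
    for r in cfg.get("raft_dissolution", []):
        rule = RaftDissolution(r["name"], float(r["rate"]),
                               raft_type=r.get("raft_type"),
                               below=_counts(r.get("below")))
        sim.add_channel(RaftDissolutionChannel(rule, sim.rafts))

    sim.sync()

    # recorders
    recorders = []
    rec = run.get("record", [])
    if rec:
        period = float(run.get("record_period", dt * 10))
        probes = {}
        for name in rec:
            if name == "vesicles":
                probes["n_vesicles"] = \
                    (lambda s: float(len(s.vesicles.vesicles)))
            elif name == "rafts":
                probes["n_rafts"] = (lambda s: float(len(s.rafts.rafts)))
            else:
                probes[name] = \
                    (lambda s, _n=name: float(s.ssa.total(_n)))
        recorders.append(Recorder(period=period, probes=probes))
    return sim, recorders
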