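"""Pre-simulation model checks and quantitative error-source warnings.

Every check returns structured Warning_ records with machine-readable
codes; nothing here raises for a bad model (a strict mode in the CLI can
promote warnings to errors).

The quantitative checks:

* fraction of Brownian steps longer than a distance d: the squared step
  length over 2 D dt is chi-square with 3 degrees of freedom, so the
  fraction is 1 - F(3 d^2 / (6 D dt); 3);
* a vesicle timestep threshold dt_theta = r_tet^2 / (15 D), the mean time
  for a uniformly initialized Brownian point to exit the sphere whose
  volume equals the mean tet volume — above it, vesicle-surface species
  dwell too long per voxel and bimolecular rates are underestimated;
* a mesh-resolution check flagging when more than 10% of tets are smaller
  than 20 nm (mean edge length), which also catches unit-scaling errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mesh import Mesh, tet_edge_means

__all__ = [
    "Warning_", "step_fraction_over", "suggest_vesicle_dt",
    "check_vesicle_dt", "check_mesh_size", "vesicle_dt_threshold",
    "check_vesicle_dt_threshold", "static_model_checks", "run_all_checks",
]

MESH_SIZE_THRESHOLD = 20e-9     # m
MESH_SIZE_FRACTION = 0.10
STEP_FRACTION_LIMIT = 0.05


@dataclass
class Warning_:
    code: str
    severity: str                # "info" | "warn"
    message: str
    remedy: str | None = None

    def __str__(self):
        s = f"[{self.severity}:{self.code}] {self.message}"
        if self.remedy:
            s += f" Suggestion: {self.remedy}"
        return s


def step_fraction_over(d: float, D: float, dt: float) -> float:
    """Fraction of Brownian steps of duration dt longer than distance d:
    1 - F(3 d^2/(6 D dt); 3), F the chi-square CDF with 3 dof."""
    if d < 0:
        raise ValueError("d must be >= 0")
    if D <= 0 or dt <= 0:
        raise ValueError("D and dt must be > 0")
    return float(stats.chi2.sf(3.0 * d * d / (6.0 * D * dt), df=3))


def suggest_vesicle_dt(d: float, D: float,
                       limit: float = STEP_FRACTION_LIMIT) -> float:
    """Largest dt with step_fraction_over(d, D, dt) <= limit (chi-square
    quantile inversion)."""
    q = stats.chi2.isf(limit, df=3)
    return 3.0 * d * d / (6.0 * D * q)


def check_vesicle_dt(vesicle_types, dt: float,
                     limit: float = STEP_FRACTION_LIMIT) -> list[Warning_]:
    """Warn when a vesicle type is expected to jump farther than its own
    diameter plus the smallest other diameter in more than ``limit`` of
    its diffusion steps (it could then pass through other vesicles,
    underestimating crowding)."""
    out: list[Warning_] = []
    vts = list(vesicle_types)
    for vt in vts:
        if vt.D <= 0:
            continue
        others = [o.diameter for o in vts if o is not vt] or [vt.diameter]
        d = vt.diameter + min(others)
        frac = step_fraction_over(d, vt.D, dt)
        if frac > limit:
            dt_ok = suggest_vesicle_dt(d, vt.D, limit)
            out.append(Warning_(
                code="vesicle-step-too-long", severity="warn",
                message=(f"vesicle type {vt.name!r}: {frac:.1%} of diffusion "
                         f"steps exceed {d * 1e9:.0f} nm at dt={dt:g} s"),
                remedy=f"use a vesicle dt <= {dt_ok:.3g} s"))
    return out


def check_mesh_size(mesh: Mesh, threshold: float = MESH_SIZE_THRESHOLD,
                    fraction: float = MESH_SIZE_FRACTION) -> list[Warning_]:
    """Warn iff strictly more than ``fraction`` of tets have mean edge
    length below ``threshold`` (default 10% below 20 nm)."""
    em = tet_edge_means(mesh)
    frac = float(np.mean(em < threshold))
    if frac > fraction:
        return [Warning_(
            code="mesh-tets-too-small", severity="warn",
            message=(f"{frac:.1%} of tetrahedrons are below "
                     f"{threshold * 1e9:.0f} nm (mean edge); small voxels "
                     "inflate bimolecular rate errors and this often "
                     "indicates a unit-scaling mistake"),
            remedy="check the mesh scale factor or remesh coarser")]
    return []


def vesicle_dt_threshold(mesh: Mesh, D: float) -> float:
    """dt_theta = r_tet^2 / (15 D): mean exit time of a uniformly started
    Brownian point from the sphere whose volume equals the mean tet
    volume."""
    if D <= 0:
        raise ValueError("D must be > 0")
    v_mean = float(mesh.tet_volume.mean())
    r_tet = (3.0 * v_mean / (4.0 * math.pi)) ** (1.0 / 3.0)
    return r_tet * r_tet / (15.0 * D)


def check_vesicle_dt_threshold(mesh: Mesh, vesicle_types,
                               dt: float) -> list[Warning_]:
    out = []
    for vt in vesicle_types:
        if vt.D <= 0:
            continue
        dt_theta = vesicle_dt_threshold(mesh, vt.D)
        if dt > dt_theta:
            out.append(Warning_(
                code="vesicle-dt-above-threshold", severity="warn",
                message=(f"vesicle type {vt.name!r}: dt={dt:g} s exceeds "
                         f"dt_theta={dt_theta:.3g} s; surface species dwell "
                         "too long per voxel and bimolecular rates will be "
                         "underestimated"),
                remedy=f"use a vesicle dt <= {dt_theta:.3g} s"))
    return out


def static_model_checks(species=None, reactions=(), vesicle_types=(),
                        raft_radii=(), mesh: Mesh | None = None,
                        surface_D: dict | None = None,
                        dt: float = 1e-3) -> list[Warning_]:
    """Structural sanity checks on a model definition.

    Flags: species that only ever appear as products (nothing consumes
    them); vesicles/rafts larger than the mesh; surface diffusion so fast
    that one vesicle dt randomizes the position on the sphere (RMS angular
    step sqrt(2 D dt)/r > pi); reaction rates more than 3 decades from the
    median of same-order reactions (likely typos).
    """
    out: list[Warning_] = []

    consumed, produced = set(), set()
    for r in reactions:
        consumed |= set(r.reactants) | set(getattr(r, "surface_reactants", {}))
        produced |= set(r.products) | set(getattr(r, "surface_products", {}))
    for name in sorted(produced - consumed):
        out.append(Warning_(
            code="produce-only-species", severity="warn",
            message=f"species {name!r} only appears on the right-hand side "
                    "of reactions; nothing in the model consumes it"))

    if mesh is not None:
        rmesh = mesh.bounding_radius()
        for vt in vesicle_types:
            if vt.radius > rmesh:
                out.append(Warning_(
                    code="vesicle-larger-than-mesh", severity="warn",
                    message=f"vesicle type {vt.name!r} radius "
                            f"{vt.radius:g} m exceeds mesh bounding radius "
                            f"{rmesh:g} m"))
        for i, rr in enumerate(raft_radii):
            if rr > rmesh:
                out.append(Warning_(
                    code="raft-larger-than-mesh", severity="warn",
                    message=f"raft radius {rr:g} m exceeds mesh bounding "
                            f"radius {rmesh:g} m"))

    if surface_D:
        for vt in vesicle_types:
            for name, Dv in surface_D.items():
                if Dv <= 0:
                    continue
                if math.sqrt(2.0 * Dv * dt) / vt.radius > math.pi:
                    out.append(Warning_(
                        code="surface-D-too-high", severity="warn",
                        message=(f"surface species {name!r} on vesicle type "
                                 f"{vt.name!r}: RMS angular step exceeds pi "
                                 "per vesicle dt; positions are effectively "
                                 "randomized"),
                        remedy="reduce the vesicle dt or the surface D"))

    by_order: dict[int, list] = {}
    for r in reactions:
        if r.rate > 0:
            by_order.setdefault(r.order, []).append(r)
    for order, rs in by_order.items():
        if len(rs) < 3:
            continue
        logs = np.log10([r.rate for r in rs])
        med = np.median(logs)
        for r, lg in zip(rs, logs):
            if abs(lg - med) > 3.0:
                out.append(Warning_(
                    code="rate-outlier", severity="info",
                    message=(f"reaction {r.name!r} rate {r.rate:g} is "
                             f">3 decades from the median of order-{order} "
                             "reactions; check for a typo")))
    return out


def run_all_checks(mesh, species, reactions, vesicle_types, dt,
                   surface_D=None, raft_radii=()) -> list[Warning_]:
    out = []
    out += check_mesh_size(mesh)
    out += check_vesicle_dt(vesicle_types, dt)
    out += check_vesicle_dt_threshold(mesh, vesicle_types, dt)
    out += static_model_checks(species, reactions, vesicle_types,
                               raft_radii, mesh, surface_D, dt)
    return out
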