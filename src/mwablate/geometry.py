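"""Constructive geometry of the ablation domain and antenna.

Builds region-labelled axisymmetric meshes of a liver cylinder with an
embedded single-slot coaxial antenna (conductive core, dielectric, slotted
outer conductor, catheter sheath) and an optional spherical tumor centred on
the ring slot.  The exact internal dimensions of the clinical applicator are
proprietary; defaults follow the standard published single-slot coaxial
benchmark and every dimension is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import yaml

from .mesh import TriMesh, graded_segment, structured_mesh

__all__ = ["Region", "AntennaGeometry", "MeshResolution", "SimulationDomain",
           "build_domain", "build_coax_segment"]

MM = 1e-3


class Region(IntEnum):
    LIVER = 0
    TUMOR = 1
    DIELECTRIC = 2   # coax dielectric (PTFE)
    CATHETER = 3
    SLOT = 4         # air gap in the outer conductor
    CONDUCTOR = 5    # metal, excluded from both solvers

    @classmethod
    def tissue(cls):
        return (cls.LIVER, cls.TUMOR)


@dataclass(frozen=True)
class AntennaGeometry:
    """Single-slot coaxial antenna, dimensions in mm, driven at ``frequency``.

    The slot is an annular interruption of the outer conductor with its
    centre ``slot_distance_from_tip`` above the short-circuited tip.
    """

    frequency: float = 915e6             # Hz
    power: float = 60.0                  # W
    inner_conductor_radius: float = 0.135   # mm
    dielectric_outer_radius: float = 0.470  # mm
    catheter_outer_radius: float = 0.895    # mm
    outer_conductor_thickness: float = 0.125  # mm
    slot_width: float = 1.0              # mm
    slot_distance_from_tip: float = 5.5  # mm, slot centre above tip
    insertion_depth: float = 65.0        # mm
    tip_cap_length: float = 0.5          # mm of catheter below the short
    short_length: float = 0.5            # mm, short-circuit plug
    eps_dielectric: float = 2.03         # PTFE
    eps_catheter: float = 2.60
    eps_slot: float = 1.0                # air

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        r1 = self.inner_conductor_radius
        r2 = self.dielectric_outer_radius
        r3 = r2 + self.outer_conductor_thickness
        r4 = self.catheter_outer_radius
        if not (0 < r1 < r2 < r3 < r4):
            raise ValueError("antenna radii must be strictly increasing")
        if not (0 < self.slot_width and
                self.slot_distance_from_tip - self.slot_width / 2 >
                self.tip_cap_length + self.short_length):
            raise ValueError("slot must lie above the short-circuited tip")
        if self.slot_distance_from_tip + self.slot_width / 2 >= self.insertion_depth:
            raise ValueError("slot must lie within the inserted length")

    @property
    def outer_conductor_inner_radius(self) -> float:
        return self.dielectric_outer_radius

    @property
    def outer_conductor_outer_radius(self) -> float:
        return self.dielectric_outer_radius + self.outer_conductor_thickness

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AntennaGeometry":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def replace(self, **kw) -> "AntennaGeometry":
        return replace(self, **kw)


@dataclass(frozen=True)
class MeshResolution:
    """Target element sizes in mm; ``scale`` multiplies all of them."""

    slot: float = 0.1      # axial spacing inside the slot
    near: float = 0.25     # near-field (first few mm around the antenna)
    mid: float = 1.0       # heated region
    far: float = 3.0       # domain periphery
    scale: float = 1.0

    def sizes(self) -> tuple[float, float, float, float]:
        s = self.scale
        return self.slot * s, self.near * s, self.mid * s, self.far * s


@dataclass
class SimulationDomain:
    """Region-labelled axisymmetric mesh plus named boundary sets.

    Boundary sets: ``port`` (coax cross-section at the entry surface),
    ``exterior`` (scattering / body-temperature wall), ``axis`` (r = 0),
    ``cooling`` (antenna-tissue interface carrying the saline-cooling flux).
    """

    mesh: TriMesh
    geometry: AntennaGeometry
    mode: str = "axisymmetric_rz"
    z_tip: float = 0.0       # m
    z_slot: float = 0.0      # m, slot centre
    extents: tuple[float, float] = (0.0, 0.0)   # (R, H) in m
    tumor_center: tuple[float, float] | None = None
    tumor_radius: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def probe_point(self) -> tuple[float, float]:
        """Default temperature probe: 5 mm radially from the slot centre."""
        return (5 * MM, self.z_slot)


def _z_lines(geom: AntennaGeometry, H: float, res: MeshResolution) -> np.ndarray:
    h_slot, h_near, h_mid, h_far = (s * MM for s in res.sizes())
    z_tip = H - geom.insertion_depth * MM
    z_cap = z_tip + geom.tip_cap_length * MM
    z_short = z_cap + geom.short_length * MM
    z_lo = z_tip + (geom.slot_distance_from_tip - geom.slot_width / 2) * MM
    z_hi = z_tip + (geom.slot_distance_from_tip + geom.slot_width / 2) * MM
    parts = [np.array([0.0])]
    anchors = [
        (z_tip - 30 * MM, h_far, h_mid),
        (z_tip - 4 * MM, h_mid, h_near),
        (z_tip, h_near, h_near),
        (z_cap, h_near, h_near),
        (z_short, h_near, h_near),
        (z_lo, h_near, h_slot),
        (z_hi, h_slot, h_slot),
        (z_hi + 3 * MM, h_slot * 2, h_near),
        (z_hi + 30 * MM, h_near * 2, h_mid),
        (H, h_mid, h_far),
    ]
    cur = 0.0
    for zb, h0, h1 in anchors:
        if zb <= cur + 1e-12:
            continue
        parts.append(graded_segment(cur, zb, h0, h1))
        cur = zb
    return np.concatenate(parts)


def _r_lines(geom: AntennaGeometry, R: float, res: MeshResolution) -> np.ndarray:
    h_slot, h_near, h_mid, h_far = (s * MM for s in res.sizes())
    r1 = geom.inner_conductor_radius * MM
    r2 = geom.dielectric_outer_radius * MM
    r3 = geom.outer_conductor_outer_radius * MM
    r4 = geom.catheter_outer_radius * MM
    parts = [np.array([0.0])]
    for a, b, n in ((0, r1, 2), (r1, r2, 4), (r2, r3, 2), (r3, r4, 3)):
        parts.append(np.linspace(a, b, n + 1)[1:])
    parts.append(graded_segment(r4, r4 + 5 * MM, h_near * 0.7, h_near * 2))
    parts.append(graded_segment(r4 + 5 * MM, min(25 * MM, R), h_near * 2, h_mid * 1.5))
    if R > 25 * MM:
        parts.append(graded_segment(25 * MM, R, h_mid * 1.5, h_far))
    return np.concatenate(parts)


def build_domain(
    geom: AntennaGeometry | None = None,
    liver_radius_mm: float = 40.0,
    liver_height_mm: float = 100.0,
    tumor_diameter_mm: float | None = None,
    tumor_center_mm: tuple[float, float] | None = None,
    resolution: MeshResolution | None = None,
    mode: str = "axisymmetric_rz",
    min_clearance_mm: float = 30.0,
) -> SimulationDomain:
    """Labelled axisymmetric mesh of liver + antenna (+ optional tumor).

    The antenna enters through the top surface (z = H) on the axis and its
    tip sits ``insertion_depth`` below it.  The exterior boundary must clear
    the antenna by ``min_clearance_mm`` in all directions so the fixed
    body-temperature wall stays ablation-inert.
    """
    if mode == "full_3d":
        raise NotImplementedError(
            "full 3D domains require patient-specific segmentations; "
            "only the axisymmetric desk-scale pathway is implemented")
    if mode != "axisymmetric_rz":
        raise ValueError(f"unknown mode {mode!r}")
    geom = geom or AntennaGeometry()
    res = resolution or MeshResolution()
    R = liver_radius_mm * MM
    H = liver_height_mm * MM
    z_tip = H - geom.insertion_depth * MM
    if R < geom.catheter_outer_radius * MM + min_clearance_mm * MM or z_tip < min_clearance_mm * MM:
        raise ValueError("exterior boundary closer than the required clearance to the antenna")

    mesh = structured_mesh(_r_lines(geom, R, res), _z_lines(geom, H, res))
    c = mesh.centroids()
    r, z = c[:, 0], c[:, 1]

    r1 = geom.inner_conductor_radius * MM
    r2 = geom.dielectric_outer_radius * MM
    r3 = geom.outer_conductor_outer_radius * MM
    r4 = geom.catheter_outer_radius * MM
    z_cap = z_tip + geom.tip_cap_length * MM
    z_short = z_cap + geom.short_length * MM
    z_lo = z_tip + (geom.slot_distance_from_tip - geom.slot_width / 2) * MM
    z_hi = z_tip + (geom.slot_distance_from_tip + geom.slot_width / 2) * MM
    z_slot = 0.5 * (z_lo + z_hi)

    regions = np.full(mesh.n_elements, int(Region.LIVER))
    inside = z > z_tip
    regions[inside & (r < r4)] = Region.CATHETER           # tip cap + sheath default
    regions[(z > z_short) & (r < r1)] = Region.CONDUCTOR   # inner conductor
    regions[(z > z_short) & (r > r1) & (r < r2)] = Region.DIELECTRIC
    shield = (z > z_cap) & (r > r2) & (r < r3)
    regions[shield] = Region.CONDUCTOR
    regions[shield & (z > z_lo) & (z < z_hi)] = Region.SLOT
    regions[(z > z_cap) & (z < z_short) & (r < r2)] = Region.CONDUCTOR  # short plug

    tumor_radius = None
    tumor_center = None
    if tumor_diameter_mm is not None:
        tumor_radius = tumor_diameter_mm / 2 * MM
        if tumor_center_mm is None:
            tumor_center = (0.0, z_slot)
        else:
            tumor_center = (tumor_center_mm[0] * MM, tumor_center_mm[1] * MM)
        if (tumor_center[0] + tumor_radius > R or tumor_center[1] + tumor_radius > H
                or tumor_center[1] - tumor_radius < 0):
            raise ValueError("tumor does not fit inside the liver domain")
        d2 = (r - tumor_center[0]) ** 2 + (z - tumor_center[1]) ** 2
        regions[(regions == Region.LIVER) & (d2 < tumor_radius ** 2)] = Region.TUMOR

    n_slot = int(np.sum(regions == Region.SLOT))
    if n_slot < 10:
        raise ValueError(f"resolution too coarse: only {n_slot} elements across the slot")

    mesh.regions = regions
    _classify_boundaries(mesh, geom, R, H, z_tip)
    return SimulationDomain(
        mesh=mesh, geometry=geom, mode=mode, z_tip=z_tip, z_slot=z_slot,
        extents=(R, H), tumor_center=tumor_center, tumor_radius=tumor_radius,
        meta={"z_lo": z_lo, "z_hi": z_hi},
    )


def _classify_boundaries(mesh: TriMesh, geom: AntennaGeometry, R: float, H: float,
                         z_tip: float) -> None:
    tol = 1e-9
    r1 = geom.inner_conductor_radius * MM
    r2 = geom.dielectric_outer_radius * MM
    r4 = geom.catheter_outer_radius * MM

    active = ~mesh.element_mask(Region.CONDUCTOR)
    bedges = mesh.boundary_edges(active)
    mid = 0.5 * (mesh.nodes[bedges[:, 0]] + mesh.nodes[bedges[:, 1]])
    rm, zm = mid[:, 0], mid[:, 1]

    on_axis = rm < tol
    on_top = zm > H - tol
    port = on_top & (rm > r1) & (rm < r2)
    exterior = ((rm > R - tol) | (zm < tol) | (on_top & (rm > r4))) & ~port
    mesh.edges["port"] = bedges[port]
    mesh.edges["axis"] = bedges[on_axis]
    mesh.edges["exterior"] = bedges[exterior]

    # cooling: boundary of the tissue subset lying on the antenna surface
    tissue = mesh.element_mask(list(Region.tissue()))
    tedges = mesh.boundary_edges(tissue)
    tmid = 0.5 * (mesh.nodes[tedges[:, 0]] + mesh.nodes[tedges[:, 1]])
    rm, zm = tmid[:, 0], tmid[:, 1]
    cooling = ((np.abs(rm - r4) < tol) & (zm > z_tip)) | \
              ((np.abs(zm - z_tip) < tol) & (rm < r4 + tol))
    wall = (rm > R - tol) | (zm < tol) | ((zm > H - tol) & (rm > r4))
    mesh.edges["cooling"] = tedges[cooling]
    mesh.edges["wall"] = tedges[wall]


def build_coax_segment(
    length_mm: float = 20.0,
    inner_radius_mm: float = 0.135,
    outer_radius_mm: float = 0.470,
    eps_r: float = 2.03,
    sigma: float = 0.0,
    n_r: int = 12,
    h_z_mm: float = 0.1,
    termination: str = "matched",
) -> SimulationDomain:
    """Straight coaxial line segment for solver verification.

    The port sits at the top (z = L); the bottom is either ``matched``
    (first-order absorbing, tagged as ``exterior``) or ``short`` (perfect
    electric conductor, the natural boundary condition).  The annulus is
    filled with a homogeneous medium (``eps_r``, ``sigma``) labelled as the
    coax dielectric.
    """
    if termination not in ("matched", "short"):
        raise ValueError("termination must be 'matched' or 'short'")
    a, b, L = inner_radius_mm * MM, outer_radius_mm * MM, length_mm * MM
    mesh = structured_mesh(np.linspace(a, b, n_r + 1),
                           np.linspace(0, L, max(2, round(L / (h_z_mm * MM))) + 1))
    mesh.regions[:] = Region.DIELECTRIC
    bedges = mesh.boundary_edges(np.ones(mesh.n_elements, bool))
    mid = 0.5 * (mesh.nodes[bedges[:, 0]] + mesh.nodes[bedges[:, 1]])
    tol = 1e-12
    mesh.edges["port"] = bedges[mid[:, 1] > L - tol]
    bottom = bedges[mid[:, 1] < tol]
    mesh.edges["exterior"] = bottom if termination == "matched" else bottom[:0]
    mesh.edges["axis"] = bedges[:0]
    geom = AntennaGeometry(inner_conductor_radius=inner_radius_mm,
                           dielectric_outer_radius=outer_radius_mm,
                           eps_dielectric=eps_r)
    dom = SimulationDomain(mesh=mesh, geometry=geom, z_tip=0.0, z_slot=0.0,
                           extents=(b, L), meta={"coax_sigma": sigma})
    return dom
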