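"""Transient Pennes bioheat solver with Arrhenius thermal-damage tracking.

Solves ``rho cp dT/dt = div(k grad T) - rho_b cp_b omega_b (T - T_b) + SAR``
on the tissue subset of the simulation domain by backward Euler (lumped mass,
unconditionally stable), with a fixed body-temperature wall on the exterior,
a convective saline-cooling flux on the antenna surface, and the
electromagnetic heat source held constant in time (material properties are
temperature-independent).  The perfusion term is a heat sink toward blood
temperature — the standard Pennes form.

Thermal injury accumulates as the Arrhenius integral
``alpha(t) = int A exp(-dE/(R T(t))) dt`` (trapezoidal in time); the damaged
fraction is ``theta_d = 1 - exp(-alpha)`` and tissue with ``theta_d > 0.98``
is counted as necrotic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import CONSTANTS, PhysicalConstants
from .geometry import Region, SimulationDomain
from .materials import TissueProperties
from .mesh import P1Assembler, TriMesh, edge_load, edge_mass

__all__ = [
    "CoolingBC", "ThermalSnapshot", "ThermalHistory", "AblationMetrics",
    "simulate", "arrhenius_step", "damage_fraction", "necrotic_metrics",
    "ellipsoid_margin", "NECROSIS_THRESHOLD",
]

#: damaged-fraction threshold indicating cell necrosis
NECROSIS_THRESHOLD = 0.98


@dataclass(frozen=True)
class CoolingBC:
    """Convective saline-cooling flux ``-k dT/dn = h (T - T_ext)``."""

    h: float = 980.0        # W/(m^2 K)
    T_ext: float = 293.15   # K (20 degC saline)


@dataclass
class ThermalSnapshot:
    t: float                 # s
    T: np.ndarray            # K, nodal
    alpha: np.ndarray        # damage integral, nodal


@dataclass
class ThermalHistory:
    """Time history of a bioheat simulation on one domain.

    ``snapshots`` are retained every ``snapshot_interval`` seconds;
    ``probe_trace`` records every time step at the probe points as rows
    ``(t_s, dose_J, T_probe_K...)``.
    """

    domain: SimulationDomain
    assembler: P1Assembler
    node_active: np.ndarray          # indices of tissue nodes
    snapshots: list[ThermalSnapshot] = field(default_factory=list)
    probe_trace: list[tuple] = field(default_factory=list)
    probe_points: list[tuple] = field(default_factory=list)
    dt: float = 0.5
    power: float = 60.0

    @property
    def final(self) -> ThermalSnapshot:
        return self.snapshots[-1]


def arrhenius_step(
    alpha: np.ndarray,
    T_old: np.ndarray,
    T_new: np.ndarray,
    dt: float,
    A: float | np.ndarray,
    dE: float | np.ndarray,
    R: float = CONSTANTS.R_gas,
) -> np.ndarray:
    """Advance the Arrhenius damage integral by one trapezoidal step.

    Temperatures are in kelvin; ``A`` (1/s) and ``dE`` (J/mol) may be scalar
    or nodal.  Returns ``alpha + dt * (rate(T_old) + rate(T_new)) / 2``.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    T_old = np.asarray(T_old, float)
    T_new = np.asarray(T_new, float)
    if np.any(T_old <= 0) or np.any(T_new <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    if dt == 0:
        return np.asarray(alpha, float).copy()
    rate_old = A * np.exp(-dE / (R * T_old))
    rate_new = A * np.exp(-dE / (R * T_new))
    return alpha + 0.5 * dt * (rate_old + rate_new)


def damage_fraction(alpha) -> np.ndarray | float:
    """Damaged tissue fraction ``theta_d = 1 - exp(-alpha)``, in [0, 1)."""
    a = np.asarray(alpha, float)
    if np.any(a < 0):
        raise ValueError("damage integral must be >= 0")
    out = -np.expm1(-a)
    return float(out) if np.isscalar(alpha) else out


def simulate(
    domain: SimulationDomain,
    props: dict,
    sar: np.ndarray | None,
    duration: float = 900.0,
    dt: float = 0.5,
    cooling: CoolingBC | None = CoolingBC(),
    T_wall: float | None = 310.15,
    probes: list[tuple] | None = None,
    snapshot_interval: float = 15.0,
    constants: PhysicalConstants = CONSTANTS,
    power: float = 60.0,
    perfusion_override: dict | None = None,
    T_init: float | np.ndarray | None = None,
) -> ThermalHistory:
    """Run the transient bioheat problem on the tissue regions.

    ``props`` maps tissue region labels to :class:`TissueProperties`;
    ``sar`` is the element-wise heat source on the *tissue* element subset
    (W/m^3, or None for no source).  ``T_wall`` is the fixed exterior wall
    temperature (None disables the Dirichlet wall, leaving it insulated);
    ``cooling=None`` disables the antenna cooling flux.
    ``perfusion_override`` maps region labels to absolute perfusion rates
    (1/s) replacing the property value.  ``duration`` must be a multiple of
    ``snapshot_interval``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_snap = snapshot_interval / dt
    if abs(n_snap - round(n_snap)) > 1e-9:
        raise ValueError("snapshot_interval must be a multiple of dt")
    n_snap = round(n_snap)
    if abs(duration / snapshot_interval - round(duration / snapshot_interval)) > 1e-9:
        raise ValueError("duration must be a multiple of snapshot_interval")

    mesh = domain.mesh
    tissue = mesh.element_mask(list(Region.tissue()))
    asm = P1Assembler(mesh, tissue)
    reg = mesh.regions[asm.elems]
    labels = np.unique(reg)
    missing = [int(l) for l in labels if int(l) not in {int(k) for k in props}]
    if missing:
        raise ValueError(f"no tissue properties for region(s) {missing}")
    props = {int(k): v for k, v in props.items()}

    k_e = np.empty(len(reg))
    rhocp_e = np.empty(len(reg))
    perf_e = np.empty(len(reg))
    A_n = np.zeros(mesh.n_nodes)
    dE_n = np.full(mesh.n_nodes, np.inf)
    for lab in labels:
        p: TissueProperties = props[int(lab)]
        sel = reg == lab
        k_e[sel] = p.k
        rhocp_e[sel] = p.rho * p.cp
        omega = p.omega_b
        if perfusion_override and int(lab) in {int(k) for k in perfusion_override}:
            omega = {int(k): v for k, v in perfusion_override.items()}[int(lab)]
            if omega < 0:
                raise ValueError("perfusion override must be >= 0")
        perf_e[sel] = constants.rho_blood * constants.cp_blood * omega
        nodes_lab = np.unique(asm.tris[sel])
        A_n[nodes_lab] = p.A
        dE_n[nodes_lab] = p.dE

    if sar is None:
        sar = np.zeros(len(reg))
    sar = np.asarray(sar, float)
    if sar.shape != (len(reg),):
        raise ValueError("SAR field does not match the tissue element subset")

    K = asm.stiffness(k_e) + asm.mass(perf_e)
    M = asm.mass(rhocp_e, lumped=True)
    F = asm.load(sar) + asm.load(perf_e) * constants.T_body

    if cooling is not None:
        cool_edges = mesh.edges.get("cooling")
        if cool_edges is not None and len(cool_edges):
            K = K + edge_mass(mesh, cool_edges, cooling.h)
            F = F + edge_load(mesh, cool_edges,
                              lambda r, z: cooling.h * cooling.T_ext * np.ones_like(r)).real

    active_nodes = np.unique(asm.tris)
    if T_wall is not None:
        wall_edges = mesh.edges.get("wall")
        fixed = np.unique(wall_edges) if wall_edges is not None and len(wall_edges) else np.array([], int)
    else:
        fixed = np.array([], int)
    free = np.setdiff1d(active_nodes, fixed)

    if T_init is None:
        T = np.full(mesh.n_nodes, constants.T_body)
    elif np.isscalar(T_init):
        T = np.full(mesh.n_nodes, float(T_init))
    else:
        T = np.asarray(T_init, float).copy()
    if T_wall is not None:
        T[fixed] = T_wall
    alpha = np.zeros(mesh.n_nodes)

    Asys = (M / dt + K).tocsr()
    Aff = Asys[np.ix_(free, free)].tocsc()
    Afc = Asys[np.ix_(free, fixed)]
    lu = spla.splu(Aff)
    Mdiag = M.diagonal()

    probe_pts = list(probes) if probes else [domain.probe_point]
    pnodes = [_nearest_node(mesh, active_nodes, p) for p in probe_pts]

    hist = ThermalHistory(domain=domain, assembler=asm, node_active=active_nodes,
                          dt=dt, power=power, probe_points=probe_pts)
    hist.snapshots.append(ThermalSnapshot(0.0, T.copy(), alpha.copy()))
    hist.probe_trace.append((0.0, 0.0, *[T[n] for n in pnodes]))

    n_steps = round(duration / dt)
    for step in range(1, n_steps + 1):
        rhs = Mdiag[free] / dt * T[free] + F[free]
        if len(fixed):
            rhs = rhs - Afc @ T[fixed]
        T_new = T.copy()
        T_new[free] = lu.solve(rhs)
        if not np.all(np.isfinite(T_new[free])):
            raise RuntimeError("bioheat solve diverged (non-finite temperatures)")
        alpha[active_nodes] = arrhenius_step(
            alpha[active_nodes], T[active_nodes], T_new[active_nodes], dt,
            A_n[active_nodes], dE_n[active_nodes], constants.R_gas)
        T = T_new
        t = step * dt
        hist.probe_trace.append((t, power * t, *[T[n] for n in pnodes]))
        if step % n_snap == 0:
            hist.snapshots.append(ThermalSnapshot(t, T.copy(), alpha.copy()))
    return hist


def _nearest_node(mesh: TriMesh, candidates: np.ndarray, point) -> int:
    d = np.linalg.norm(mesh.nodes[candidates] - np.asarray(point), axis=1)
    return int(candidates[np.argmin(d)])


@dataclass
class AblationMetrics:
    """Size metrics of the necrotic (theta_d above threshold) region."""

    necrotic_volume: float          # cm^3
    long_axis_diameter: float       # cm, extent along the antenna axis
    short_axis_diameter: float      # cm, max diameter perpendicular to it
    trajectory: list[tuple] = field(default_factory=list)   # (dose kJ, cm^3)
    ellipsoid_margin: tuple | None = None


def necrotic_metrics(
    theta,
    mesh: TriMesh | None = None,
    threshold: float = NECROSIS_THRESHOLD,
    rule: str = "vertices",
    spacing: tuple | None = None,
    axis: int = 2,
) -> AblationMetrics:
    """Volume and axis diameters of the super-threshold damage region.

    Axisymmetric mode (``mesh`` given, ``theta`` nodal): an element counts as
    necrotic when all its vertices (``rule='vertices'``, conservative) or its
    centroid value (``rule='centroid'``) pass the threshold; the volume is
    the revolution ``2 pi int r dA`` of the necrotic elements; the long axis
    is the z-extent of their nodes and the short axis twice their maximal
    radius.  Voxel mode (``spacing`` given, ``theta`` a 3D array): volume is
    the voxel count times the voxel volume; the long axis is the extent
    along ``axis``.  Empty super-threshold sets give all-zero metrics.
    """
    if (mesh is None) == (spacing is None):
        raise ValueError("give exactly one of mesh (axisymmetric) or spacing (voxel)")
    theta = np.asarray(theta, float)
    if mesh is not None:
        pass_node = theta >= threshold
        if rule == "vertices":
            elem_pass = np.all(pass_node[mesh.tris], axis=1)
        elif rule == "centroid":
            elem_pass = theta[mesh.tris].mean(axis=1) >= threshold
        else:
            raise ValueError("rule must be 'vertices' or 'centroid'")
        elem_pass &= mesh.element_mask(list(Region.tissue()))
        if not elem_pass.any():
            return AblationMetrics(0.0, 0.0, 0.0)
        vol = mesh.revolved_volume(elem_pass) * 1e6          # m^3 -> cm^3
        nodes = mesh.nodes[np.unique(mesh.tris[elem_pass])]
        long_axis = (nodes[:, 1].max() - nodes[:, 1].min()) * 100.0
        short_axis = 2 * nodes[:, 0].max() * 100.0
        return AblationMetrics(vol, long_axis, short_axis)

    if theta.ndim != 3:
        raise ValueError("voxel mode expects a 3D damage field")
    mask = theta >= threshold
    if not mask.any():
        return AblationMetrics(0.0, 0.0, 0.0)
    spacing = np.asarray(spacing, float)
    vol = mask.sum() * np.prod(spacing) * 1e-3               # mm^3 -> cm^3
    idx = np.argwhere(mask)
    ext = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing  # mm
    long_axis = ext[axis] / 10.0
    short_axis = max(e for i, e in enumerate(ext) if i != axis) / 10.0
    return AblationMetrics(float(vol), float(long_axis), float(short_axis))


def ellipsoid_margin(long_cm: float, short_cm: float) -> tuple[float, float, float]:
    """Prolate-spheroid semi-axes (cm) fitted to the ablation diameters.

    The long diameter lies along the antenna axis; the zone is rotationally
    symmetric so both transverse semi-axes equal half the short diameter.
    """
    if long_cm <= 0 or short_cm <= 0:
        raise ValueError("diameters must be positive")
    return (long_cm / 2, short_cm / 2, short_cm / 2)
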