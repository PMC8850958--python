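"""Time-harmonic electromagnetic solver for the slot-antenna ablation domain.

Axisymmetric TM0 formulation: the unknown is the azimuthal magnetic field
H_phi, governed by the curl-curl reduction of the vector wave equation with
complex relative permittivity ``eps_r - j sigma/(omega eps0)``.  Metallic
surfaces (conductor regions are excluded from the mesh) carry the natural
perfect-electric-conductor condition; the coax cross-section is driven by the
TEM mode through a matched modal port; the exterior carries a first-order
scattering condition with the wavenumber of the local medium.  After the
sparse direct solve the field is rescaled so the net time-averaged power
entering the port equals the requested drive power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import CONSTANTS, PhysicalConstants
from .geometry import Region, SimulationDomain
from .materials import TissueProperties
from .mesh import P1Assembler, edge_load_invr, edge_mass_invr

__all__ = ["EMDrive", "EMSolution", "solve_harmonic", "sar_field", "s_parameter"]


@dataclass(frozen=True)
class EMDrive:
    frequency: float = 915e6
    input_power: float = 60.0
    power_reference: str = "net"   # "net" or "incident"

    def __post_init__(self) -> None:
        if self.input_power <= 0 or self.frequency <= 0:
            raise ValueError("frequency and input_power must be positive")
        if self.power_reference not in ("net", "incident"):
            raise ValueError("power_reference must be 'net' or 'incident'")

    @property
    def omega(self) -> float:
        return 2 * np.pi * self.frequency


@dataclass
class EMSolution:
    """Solved azimuthal magnetic field with derived quantities.

    ``H_phi`` is nodal (zero on nodes outside the active region); ``E_r``,
    ``E_z`` and ``sar`` are element-wise on the active elements.
    """

    domain: SimulationDomain
    drive: EMDrive
    assembler: P1Assembler
    H_phi: np.ndarray
    E_r: np.ndarray
    E_z: np.ndarray
    sar: np.ndarray            # W/m^3, element-wise, >= 0
    sigma_elem: np.ndarray
    eps_tilde_elem: np.ndarray
    s11: complex
    incident_power: float      # W
    delivered_power: float     # W (net through the port)
    port_info: dict = field(default_factory=dict)

    def absorbed_power(self) -> float:
        """Total Joule heating (W): volume integral of the SAR field."""
        return _absorbed_power(self)

    def exterior_poynting_power(self) -> float:
        """Power (W) leaving through the exterior scattering boundary."""
        return _exterior_power(self)

    def power_budget(self) -> dict[str, float]:
        """Delivered vs absorbed-plus-radiated power accounting (W)."""
        absorbed = self.absorbed_power()
        radiated = self.exterior_poynting_power()
        return {
            "delivered": self.delivered_power,
            "absorbed": absorbed,
            "radiated": radiated,
            "imbalance": self.delivered_power - absorbed - radiated,
        }

    def port_poynting_power(self) -> float:
        """Net power (W) entering the port by surface integration.

        Independent check of the modal power accounting: integrates the
        radial electric field recovered from the port boundary relation
        against H_phi* over the coax cross-section.
        """
        pi = self.port_info
        r, u = pi["r"], pi["u"]
        k, C = pi["k"], pi["C"]
        w = u * r                      # scaled field, linear per port interval
        coef = -0.5 * 2 * np.pi * k / (self.drive.omega * CONSTANTS.eps0 * pi["eps_d"])
        # integrand = Re[coef * (w - 2C) w*] / r with w piecewise linear:
        # integrate each interval exactly (quadratic numerator over r)
        total = 0.0
        for i in range(len(r) - 1):
            r0, r1 = r[i], r[i + 1]
            s = (w[i + 1] - w[i]) / (r1 - r0)
            a0 = w[i] - s * r0
            # g(r) = (a0 + s r - 2C)(a0 + s r)* = q0 + q1 r + q2 r^2
            b0 = a0 - 2 * C
            q0 = b0 * np.conj(a0)
            q1 = b0 * np.conj(s) + s * np.conj(a0)
            q2 = s * np.conj(s)
            val = q0 * np.log(r1 / r0) + q1 * (r1 - r0) + q2 * (r1**2 - r0**2) / 2
            total += np.real(coef * val)
        return float(total)


def _absorbed_power(sol: "EMSolution") -> float:
    asm = sol.assembler
    return float(2 * np.pi * np.sum(sol.sar * asm.r_cent * asm.area))


def _exterior_power(sol: "EMSolution") -> float:
    mesh = sol.domain.mesh
    ext = mesh.edges.get("exterior")
    if ext is None or len(ext) == 0:
        return 0.0
    owner = _edge_owner_elements(sol.assembler, ext)
    om = sol.drive.omega
    k0 = om / CONSTANTS.c0
    kap = k0 * np.sqrt(sol.eps_tilde_elem[owner])
    p0, p1 = mesh.nodes[ext[:, 0]], mesh.nodes[ext[:, 1]]
    vec = p1 - p0
    L = np.linalg.norm(vec, axis=1)
    mid = 0.5 * (p0 + p1)
    radial = np.abs(vec[:, 1]) > np.abs(vec[:, 0])
    curv = np.where(radial & (mid[:, 0] > 0), 1 / np.maximum(mid[:, 0], 1e-12), 0.0)
    # outward Poynting flux via the scattering relation the discrete system
    # enforces on this boundary: S.n = Re[(j kappa + c)|H|^2/(j w eps)]/2
    coef = (1j * kap + curv) / (1j * om * CONSTANTS.eps0 * sol.eps_tilde_elem[owner])
    gp = (0.5 - 0.5 / np.sqrt(3), 0.5 + 0.5 / np.sqrt(3))
    total = 0.0
    for t in gp:
        r = (1 - t) * p0[:, 0] + t * p1[:, 0]
        u = (1 - t) * sol.H_phi[ext[:, 0]] + t * sol.H_phi[ext[:, 1]]
        total += np.sum(0.5 * np.real(coef * np.abs(u) ** 2) * 0.5 * L * 2 * np.pi * r)
    return float(total)


def _region_dielectric(props: dict, domain: SimulationDomain) -> dict[int, tuple[float, float]]:
    geom = domain.geometry
    out = {
        int(Region.DIELECTRIC): (geom.eps_dielectric, 0.0),
        int(Region.CATHETER): (geom.eps_catheter, 0.0),
        int(Region.SLOT): (geom.eps_slot, 0.0),
    }
    for key, val in props.items():
        k = int(key)
        if isinstance(val, TissueProperties):
            out[k] = (val.eps_r, val.sigma)
        else:
            eps_r, sigma = val
            out[k] = (float(eps_r), float(sigma))
    return out


def solve_harmonic(
    domain: SimulationDomain,
    props: dict,
    drive: EMDrive | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> EMSolution:
    """Solve the driven time-harmonic problem on the labelled domain.

    ``props`` maps region labels to :class:`TissueProperties` (or bare
    ``(eps_r, sigma)`` pairs); the antenna dielectric/catheter/slot default
    to the lossless values stored on the antenna geometry.  Raises if an
    active region has no properties or the port is absent.
    """
    drive = drive or EMDrive(frequency=domain.geometry.frequency,
                             input_power=domain.geometry.power)
    mesh = domain.mesh
    port_edges = mesh.edges.get("port")
    if port_edges is None or len(port_edges) == 0:
        raise ValueError("domain has no port boundary")

    diel = _region_dielectric(props, domain)
    active = ~mesh.element_mask(Region.CONDUCTOR)
    labels = np.unique(mesh.regions[active])
    missing = [int(l) for l in labels if int(l) not in diel]
    if missing:
        raise ValueError(f"no properties for region(s) {missing}")

    omega = drive.omega
    k0 = omega / constants.c0
    asm = P1Assembler(mesh, active)
    reg = mesh.regions[asm.elems]
    eps_t = np.empty(len(reg), dtype=complex)
    sigma_e = np.empty(len(reg))
    for lab in labels:
        eps_r, sigma = diel[int(lab)]
        sel = reg == lab
        sigma_e[sel] = sigma
        eps_t[sel] = eps_r - 1j * sigma / (omega * constants.eps0)

    # solve for the scaled field w = r * H_phi: the coax TEM mode (H ~ 1/r)
    # becomes exactly constant, so the P1 space carries it without a spurious
    # discrete cutoff at sub-millimetre coax radii
    A = asm.stiffness_invr(1.0 / eps_t) - k0**2 * asm.mass_invr(np.ones(len(reg))).astype(complex)

    # port: matched TEM drive with unit mode amplitude (w_inc = C, constant)
    eps_d = complex(domain.geometry.eps_dielectric)
    k_port = k0 * np.sqrt(eps_d).real
    A = A + edge_mass_invr(mesh, port_edges, np.full(len(port_edges), 1j * k_port / eps_d))

    # exterior: first-order scattering with the local medium wavenumber,
    # curvature term 1/r retained on radially-facing facets
    ext = mesh.edges.get("exterior")
    if ext is not None and len(ext):
        owner = _edge_owner_elements(asm, ext)
        kappa = k0 * np.sqrt(eps_t[owner])
        vec = mesh.nodes[ext[:, 1]] - mesh.nodes[ext[:, 0]]
        radial_normal = np.abs(vec[:, 1]) > np.abs(vec[:, 0])
        rmid = 0.5 * (mesh.nodes[ext[:, 0], 0] + mesh.nodes[ext[:, 1], 0])
        curv = np.where(radial_normal & (rmid > 0), 1.0 / np.maximum(rmid, 1e-12), 0.0)
        A = A + edge_mass_invr(mesh, ext, (1j * kappa + curv) / eps_t[owner])

    C0 = 1.0
    rhs = edge_load_invr(mesh, port_edges, lambda r, z: 2j * k_port * C0 / eps_d * np.ones_like(r))

    # Dirichlet w = 0 on the symmetry axis (H_phi regular, w = r H_phi)
    active_nodes = np.unique(asm.tris)
    on_axis = active_nodes[mesh.nodes[active_nodes, 0] < 1e-12]
    w = np.zeros(mesh.n_nodes, dtype=complex)
    free = np.setdiff1d(active_nodes, on_axis)
    Aff = A[np.ix_(free, free)].tocsc()
    try:
        lu = spla.splu(Aff)
    except RuntimeError as exc:   # pragma: no cover - singular systems
        raise RuntimeError(f"singular electromagnetic system: {exc}") from exc
    w[free] = lu.solve(rhs[free])

    # modal reflection coefficient on the port
    port_nodes = np.unique(port_edges)
    order = np.argsort(mesh.nodes[port_nodes, 0])
    r_port = mesh.nodes[port_nodes[order], 0]
    w_port = w[port_nodes[order]]
    a, b = r_port[0], r_port[-1]
    log_ba = np.log(b / a)
    # project the reflected field on the TEM mode, integrating (w - C)/r
    # exactly per interval (w is piecewise linear)
    num = 0.0 + 0.0j
    for i in range(len(r_port) - 1):
        r0, r1 = r_port[i], r_port[i + 1]
        s = (w_port[i + 1] - w_port[i]) / (r1 - r0)
        a0 = w_port[i] - s * r0
        num += (a0 - C0) * np.log(r1 / r0) + s * (r1 - r0)
    gamma = num / (C0 * log_ba)

    Z_w = np.sqrt(constants.mu0 / (constants.eps0 * eps_d.real))
    P_inc = np.pi * Z_w * abs(C0) ** 2 * log_ba
    P_net = P_inc * (1 - abs(gamma) ** 2)
    ref = P_net if drive.power_reference == "net" else P_inc
    if ref <= 0:
        raise RuntimeError("non-positive port power; cannot normalize drive")
    scale = np.sqrt(drive.input_power / ref)
    w *= scale

    # nodal H_phi (H = w / r; zero by regularity on the axis)
    r_nodes = mesh.nodes[:, 0]
    u = np.zeros(mesh.n_nodes, dtype=complex)
    off_axis = r_nodes > 1e-12
    u[off_axis] = w[off_axis] / r_nodes[off_axis]

    # element-wise E field and SAR from the curl of H:
    # E_r = -(1/r) dw/dz / (j w eps), E_z = (1/r) dw/dr / (j w eps)
    grad = asm.gradient(w)
    jweps = 1j * omega * constants.eps0 * eps_t
    E_r = -grad[:, 1] / asm.r_cent / jweps
    E_z = grad[:, 0] / asm.r_cent / jweps
    sar = 0.5 * sigma_e * (np.abs(E_r) ** 2 + np.abs(E_z) ** 2)

    return EMSolution(
        domain=domain, drive=drive, assembler=asm, H_phi=u,
        E_r=E_r, E_z=E_z, sar=sar, sigma_elem=sigma_e, eps_tilde_elem=eps_t,
        s11=complex(gamma),
        incident_power=float(P_inc * scale**2),
        delivered_power=float(P_net * scale**2),
        port_info={"r": r_port, "u": u[port_nodes[order]], "C": C0 * scale,
                   "k": k_port, "eps_d": eps_d},
    )


def _edge_owner_elements(asm: P1Assembler, edges: np.ndarray) -> np.ndarray:
    """Index (into the assembler's element subset) owning each boundary edge."""
    lookup: dict[tuple[int, int], int] = {}
    tris = asm.tris
    for m in range(len(tris)):
        t = tris[m]
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            lookup[(min(a, b), max(a, b))] = m
    return np.array([lookup[(min(a, b), max(a, b))] for a, b in edges])


def sar_field(sol: EMSolution, sigma: np.ndarray | None = None) -> np.ndarray:
    """Volumetric heat source 0.5*sigma*|E|^2 (W/m^3), element-wise.

    ``sigma`` overrides the per-element conductivity (must match the active
    element count); by default the solution's own conductivities are used.
    """
    if sigma is None:
        return sol.sar.copy()
    sigma = np.asarray(sigma, float)
    if sigma.shape != sol.sar.shape:
        raise ValueError("sigma field does not match the solution mesh")
    return 0.5 * sigma * (np.abs(sol.E_r) ** 2 + np.abs(sol.E_z) ** 2)


def s_parameter(sol: EMSolution) -> complex:
    """Modal reflection coefficient S11 of the coax port."""
    if not sol.port_info:
        raise ValueError("solution has no stored port decomposition")
    return sol.s11
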