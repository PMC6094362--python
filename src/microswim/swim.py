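"""Force-free/torque-free swimming of the head+flagellum assembly.

The motor prescribes the relative angular rate ``omega = Omega_head -
Omega_flagellum`` about the +x axis; the unknowns are the swimming speed
``U`` (axial, signed) and the head angular rate ``Omega``.  Two routes are
implemented:

* the additive approximation (AA): head and flagellum resistance
  coefficients are computed in isolation and summed (Purcell's momentum
  balance), giving the closed forms

      U     = C0 B w / ((C0+C)(A0+A) - B^2)
      Omega = (1 - (A0+A) C0 / ((C0+C)(A0+A) - B^2)) w

* the global approach (GA): the partwise resistance blocks are computed in
  the presence of the other part and the exact axial 2x2 balance is solved;
  the same solution is cross-checked against its closed form.

A phase-resolved free-swimming solve (rigid velocities from an augmented
collocation system with explicit zero-force/zero-torque rows) and a rigid
trajectory integrator complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .geometry import Discretization, FLAGELLUM_LABEL, HEAD_LABEL
from .stokes import (
    PartwiseResistance,
    StokesSolver,
    build_system_matrix,
    net_force_torque,
)


@dataclass
class SwimSolution:
    """Swimming state under a prescribed motor rate."""

    U: float                   # axial swimming speed, signed
    Omega: float               # head angular rate about x, signed
    T_motor: float             # motor torque magnitude
    omega: float               # prescribed relative rate
    method: str                # "additive" | "global" | "rft-..."
    residual_force: float = 0.0
    residual_torque: float = 0.0
    U_vec: np.ndarray | None = None
    Omega_vec: np.ndarray | None = None
    coefficients: dict = field(default_factory=dict)


@dataclass
class RigidMotion:
    """Instantaneous rigid velocity about a reference pole."""

    linear: np.ndarray
    angular: np.ndarray
    pole: np.ndarray

    def velocity_at(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.linear + np.cross(self.angular, pts - self.pole)


def _axial_denominator(A0, C0, A, B, C) -> float:
    return (C0 + C) * (A0 + A) - B * B


def solve_additive(A0, C0, A, B, C, omega, method: str = "additive") -> SwimSolution:
    """Purcell's additive approximation from isolated-body axial scalars.

    ``A0, C0`` are the head drag/torque coefficients; ``A, B, C`` the
    flagellum drag, coupling and torque coefficients computed in isolation.
    """
    den = _axial_denominator(A0, C0, A, B, C)
    if den <= 0:
        raise ValueError(
            "degenerate coefficient set: (C0+C)(A0+A) - B^2 must be positive"
        )
    U = C0 * B * omega / den
    Omega = (1.0 - (A0 + A) * C0 / den) * omega
    T_motor = abs(C0 * Omega)
    return SwimSolution(
        U=float(U),
        Omega=float(Omega),
        T_motor=float(T_motor),
        omega=float(omega),
        method=method,
        coefficients={"A0": A0, "C0": C0, "A": A, "B": B, "C": C},
    )


def global_closed_form(parts: PartwiseResistance, omega) -> tuple[float, float]:
    """Closed-form U, Omega of the coupled axial balance.

    Algebraically identical to the 2x2 solve; kept as an independent path
    for cross-checking.
    """
    A12 = parts.A1 + parts.A2
    C12 = parts.C1 + parts.C2
    B12 = parts.B_sum
    den = C12 * A12 - B12 * B12
    U = B12 * (C12 * parts.Bhat2 / B12 - parts.C2) / den * omega
    Omega = (parts.Bhat2 / B12 - A12 * (C12 * parts.Bhat2 / B12 - parts.C2) / den) * omega
    return float(U), float(Omega)


def solve_global(
    parts: PartwiseResistance,
    omega: float,
    disc: Discretization | None = None,
    mu: float | None = None,
    n_phase: int = 1,
    solver: StokesSolver | None = None,
) -> SwimSolution:
    """Coupled (global) swimming solve from partwise resistance blocks.

    Solves the axial 2x2 system ``(R1+R2)(U, Omega) = R2 (0, omega)`` built
    from the partwise blocks, cross-checks the closed form, and, when the
    assembly discretization is supplied, computes the motor torque from the
    tractions of the fully resolved flow (axial viscous torque integrated
    over the flagellum nodes, stroke averaged).  Without a discretization
    the motor torque falls back to the partwise estimate
    ``|Bbar2 U + C2 (Omega - omega)|``.
    """
    M = np.array(
        [[parts.A1 + parts.A2, parts.Bhat1 + parts.Bhat2],
         [parts.Bbar1 + parts.Bbar2, parts.C1 + parts.C2]]
    )
    rhs = np.array([parts.Bhat2 * omega, parts.C2 * omega])
    U, Omega = np.linalg.solve(M, rhs)

    Ucf, Ocf = global_closed_form(parts, omega)
    scale = max(abs(U), abs(Omega), 1e-300)
    if abs(U - Ucf) > 1e-8 * scale or abs(Omega - Ocf) > 1e-8 * scale:
        raise RuntimeError("closed-form and direct global solutions disagree")

    if disc is not None:
        T_motor = _motor_torque_from_tractions(
            disc, mu if mu is not None else parts.mu, U, Omega, omega,
            parts.pole, n_phase, solver=solver,
        )
    else:
        # torque the motor must exert on the flagellum to sustain the motion
        T_motor = abs(parts.Bbar2 * U + parts.C2 * (Omega - omega))

    res = M @ np.array([U, Omega]) - rhs
    return SwimSolution(
        U=float(U),
        Omega=float(Omega),
        T_motor=float(T_motor),
        omega=float(omega),
        method="global",
        residual_force=abs(res[0]),
        residual_torque=abs(res[1]),
        coefficients={
            "A1": parts.A1, "A2": parts.A2,
            "Bhat1": parts.Bhat1, "Bhat2": parts.Bhat2,
            "Bbar1": parts.Bbar1, "Bbar2": parts.Bbar2,
            "C1": parts.C1, "C2": parts.C2,
        },
    )


def _motor_torque_from_tractions(
    disc: Discretization, mu: float, U, Omega, omega, pole, n_phase: int,
    solver: StokesSolver | None = None,
) -> float:
    """Axial viscous torque on the flagellum in the solved swimming flow."""
    from .stokes import _rotate_about_x

    if solver is not None and n_phase != 1:
        raise ValueError("a prebuilt solver can only be reused with n_phase=1")
    pole = np.asarray(pole, dtype=float)
    e_x = np.array([1.0, 0.0, 0.0])
    acc = 0.0
    for j in range(n_phase):
        d = _rotate_about_x(disc, 2.0 * np.pi * j / n_phase) if j else disc
        solver = StokesSolver(d, mu) if (solver is None or j) else solver
        head = d.labels == HEAD_LABEL
        rel = d.nodes - pole
        u = U * e_x + Omega * np.cross(e_x, rel)
        u[~head] += -omega * np.cross(e_x, rel[~head])
        g = solver.solve(u)
        T_flag = np.cross(rel[~head], g[~head]).sum(axis=0)[0]
        acc += abs(T_flag)
    return acc / n_phase


def analyze_assembly(
    disc: Discretization,
    omega: float,
    mu: float = 1.0,
    pole=(0.0, 0.0, 0.0),
    n_phase: int = 1,
) -> tuple[PartwiseResistance, SwimSolution]:
    """Partwise resistance blocks and the coupled swimming solution.

    With ``n_phase == 1`` the dense factorization is built once and shared
    between the partwise solves and the motor-torque traction solve.
    """
    from .stokes import partwise_resistance

    solver = StokesSolver(disc, mu) if n_phase == 1 else None
    parts = partwise_resistance(disc, pole=pole, mu=mu, n_phase=n_phase,
                                solver=solver)
    sol = solve_global(parts, omega, disc=disc, mu=mu, n_phase=n_phase,
                       solver=solver)
    return parts, sol


def solve_free_swimming(
    disc: Discretization,
    shape_velocity: np.ndarray,
    mu: float,
    pole=(0.0, 0.0, 0.0),
) -> RigidMotion:
    """Instantaneous rigid motion of a force-free, torque-free swimmer.

    ``shape_velocity`` (n, 3) is the prescribed velocity of each node
    relative to the swimmer frame (for the robotic swimmer: rotation of the
    flagellum nodes at rate ``-omega`` about x relative to the head).  Solves
    the augmented system of collocation equations plus six zero net
    force/torque constraints for the nodal forces and the six rigid
    velocities.
    """
    pole = np.asarray(pole, dtype=float)
    n = disc.n_nodes
    G = build_system_matrix(disc, mu)
    rel = disc.nodes - pole

    # u_i = G g - (V + W x r_i)  must equal shape velocity; plus sum g = 0
    # and sum r x g = 0.
    M = np.zeros((3 * n + 6, 3 * n + 6))
    M[: 3 * n, : 3 * n] = G
    for k in range(3):
        col = np.zeros((n, 3))
        col[:, k] = -1.0
        M[: 3 * n, 3 * n + k] = col.reshape(-1)
        w = np.zeros(3)
        w[k] = 1.0
        M[: 3 * n, 3 * n + 3 + k] = -np.cross(w, rel).reshape(-1)
    # constraint rows: net force and net torque of the point forces vanish
    for k in range(3):
        row = np.zeros((n, 3))
        row[:, k] = 1.0
        M[3 * n + k, : 3 * n] = row.reshape(-1)
    # torque rows: (r x g)_k = eps_kab r_a g_b
    eps = np.zeros((3, 3, 3))
    eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1.0
    eps[0, 2, 1] = eps[1, 0, 2] = eps[2, 1, 0] = -1.0
    for k in range(3):
        row = np.einsum("ab,na->nb", eps[k], rel)
        M[3 * n + 3 + k, : 3 * n] = row.reshape(-1)

    rhs = np.zeros(3 * n + 6)
    rhs[: 3 * n] = np.asarray(shape_velocity, dtype=float).reshape(-1)

    sol = scipy.linalg.solve(M, rhs)
    V = sol[3 * n : 3 * n + 3]
    W = sol[3 * n + 3 :]
    return RigidMotion(linear=V, angular=W, pole=pole)


def swimmer_shape_velocity(disc: Discretization, omega: float, pole=(0, 0, 0)) -> np.ndarray:
    """Shape velocity of the robotic swimmer: flagellum spins at -omega
    about x relative to the head (so that omega = Omega_head - Omega_flag)."""
    pole = np.asarray(pole, dtype=float)
    v = np.zeros_like(disc.nodes)
    mask = disc.labels == FLAGELLUM_LABEL
    e_x = np.array([1.0, 0.0, 0.0])
    v[mask] = -omega * np.cross(e_x, disc.nodes[mask] - pole)
    return v


def integrate_trajectory(motions, dt: float, x0=(0.0, 0.0, 0.0)):
    """Integrate a sequence of body-frame rigid motions into a lab path.

    ``motions`` is an iterable of (linear, angular) velocity pairs expressed
    in the body frame; each is applied for a time ``dt``.  The orientation is
    advanced by the exponential map (axis-angle) and the position by the
    midpoint rule.  Returns ``(positions, rotations)`` with one entry per
    step boundary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x0, dtype=float).copy()
    Q = np.eye(3)
    positions = [x.copy()]
    rotations = [Q.copy()]
    for lin, ang in motions:
        lin = np.asarray(lin, dtype=float)
        ang = np.asarray(ang, dtype=float)
        v_lab = Q @ lin
        w_lab = Q @ ang
        Q_new = _rotation_exp(w_lab * dt) @ Q
        v_lab_end = Q_new @ lin
        x = x + 0.5 * dt * (v_lab + v_lab_end)
        Q = Q_new
        positions.append(x.copy())
        rotations.append(Q.copy())
    return np.array(positions), np.array(rotations)


def _rotation_exp(w: np.ndarray) -> np.ndarray:
    """Rotation matrix exp([w]x) by Rodrigues' formula."""
    theta = np.linalg.norm(w)
    if theta < 1e-300:
        return np.eye(3)
    k = w / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
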