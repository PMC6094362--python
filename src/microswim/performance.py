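"""Correcting factor, performance measures, and flagellar-length optimization.

The additive approximation overpredicts the swimming speed because it
ignores hydrodynamic screening between head and flagellum.  A single
geometry-only scalar repairs most of the error:

    upsilon = (A0 + A)(B1 + B2) / ((A1 + A2) B),

where ``A0, A, B`` are isolated-body axial coefficients (head drag,
flagellum drag and coupling) and ``(A1+A2), (B1+B2)`` the corresponding
sums of partwise coefficients computed on the coupled system.  The
corrected speed is ``upsilon * U_additive``; since every performance
measure below depends on U through a fixed power, its corrected variant
scales with the matching power of upsilon.

Six measures are tracked, each in global / additive / corrected variants:

* energetic efficiencies ``eta_en1 = A0 U^2/(T w)`` (useful work = moving
  the head) and ``eta_en2 = (A1+A2) U^2/(T w)`` (drag of the whole swimmer),
* propulsion efficiencies ``eta_pr1 = U/(w - Omega)`` (distance per
  flagellar revolution) and ``eta_pr2 = U/w`` (distance per motor
  revolution),
* swimming efficiency ``eta_sw = U/(T w)`` (distance per unit work) and its
  inverse ``w_work = T w / U`` (work per traveled distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AssemblySpec, FilamentSpec, assemble, filament_nodes
from .rft import axial_scalars, drag_coefficients, filament_resistance_rft
from .stokes import PartwiseResistance, resistance_matrix
from .swim import SwimSolution, analyze_assembly, solve_additive

MEASURES = ("eta_en1", "eta_en2", "eta_pr1", "eta_pr2", "eta_sw", "w_work")

#: Additive-family method tags understood by the sweep.
ADDITIVE_METHODS = ("additive", "rft-gh", "rft-lighthill")


def correction_factor(A0: float, A: float, B: float, parts: PartwiseResistance) -> float:
    """Geometry-only correcting factor for the additive swimming speed.

    ``A0`` head drag coefficient, ``A``/``B`` isolated flagellum drag and
    coupling, ``parts`` the coupled partwise blocks.  Independent of the
    motor rate and of viscosity (all coefficients scale linearly with mu).
    """
    if B == 0:
        raise ValueError("degenerate propeller: isolated coupling B = 0")
    A12 = parts.A1 + parts.A2
    if A12 == 0:
        raise ValueError("degenerate assembly: A1 + A2 = 0")
    return (A0 + A) * parts.B_sum / (A12 * B)


def sphere_axial_scalars(R: float, mu: float = 1.0) -> tuple[float, float]:
    """Closed-form head coefficients (A0, C0) = (6 pi mu R, 8 pi mu R^3)."""
    return 6.0 * np.pi * mu * R, 8.0 * np.pi * mu * R**3


@dataclass
class EfficiencyReport:
    """upsilon and the six performance measures by variant.

    ``variants`` maps ``"global" | "additive" | "corrected"`` to a dict of
    the measures in :data:`MEASURES`.  ``w_work`` is ``math.inf`` when the
    swimmer does not translate.
    """

    upsilon: float | None
    variants: dict

    def __getitem__(self, variant: str) -> dict:
        return self.variants[variant]


def _measures_from_solution(U, Omega, T_motor, omega, A0, A_total) -> dict:
    """Eqs. of the global variant evaluated from a swimming state."""
    if T_motor <= 0:
        raise ValueError("motor torque must be positive to form efficiencies")
    power = T_motor * omega
    return {
        "eta_en1": A0 * U**2 / power,
        "eta_en2": A_total * U**2 / power,
        "eta_pr1": U / (omega - Omega),
        "eta_pr2": U / omega,
        "eta_sw": U / power,
        "w_work": power / U if U != 0 else math.inf,
    }


def _measures_additive(A0, C0, A, B, C, omega) -> dict:
    """Closed-form additive variants of the six measures."""
    den = (A + A0) * (C + C0) - B * B
    den_sw = C * (A + A0) - B * B
    return {
        "eta_en1": A0 * C0 * B**2 / (den_sw * den),
        "eta_en2": (A + A0) * C0 * B**2 / (den_sw * den),
        "eta_pr1": B / (A + A0),
        "eta_pr2": C0 * B / den,
        "eta_sw": B / (den_sw * omega),
        "w_work": den_sw * omega / B if B != 0 else math.inf,
    }


def efficiencies(
    solution: SwimSolution,
    A0: float,
    C0: float,
    A: float,
    B: float,
    C: float,
    parts: PartwiseResistance | None = None,
    upsilon: float | None = None,
) -> EfficiencyReport:
    """All variants of the six performance measures.

    The global variant is evaluated from the supplied swimming solution
    (U, Omega, T_motor); the additive variant from the isolated-body
    closed forms; the corrected variant scales the additive one with
    upsilon (computed from ``parts`` unless given): quadratically for the
    energetic efficiencies, linearly for the propulsion and swimming
    efficiencies, inversely for the work per distance.
    """
    omega = solution.omega
    A_total = (parts.A1 + parts.A2) if parts is not None else (A0 + A)
    out = {
        "global": _measures_from_solution(
            solution.U, solution.Omega, solution.T_motor, omega, A0, A_total
        ),
        "additive": _measures_additive(A0, C0, A, B, C, omega),
    }
    if upsilon is None and parts is not None:
        upsilon = correction_factor(A0, A, B, parts)
    if upsilon is not None:
        add = out["additive"]
        out["corrected"] = {
            "eta_en1": upsilon**2 * add["eta_en1"],
            "eta_en2": upsilon**2 * add["eta_en2"],
            "eta_pr1": upsilon * add["eta_pr1"],
            "eta_pr2": upsilon * add["eta_pr2"],
            "eta_sw": upsilon * add["eta_sw"],
            "w_work": add["w_work"] / upsilon if upsilon != 0 else math.inf,
        }
    return EfficiencyReport(upsilon=upsilon, variants=out)


# ----------------------------------------------------------------------------
# length sweep
# ----------------------------------------------------------------------------

def _isolated_flagellum_scalars(
    fil: FilamentSpec, x0: float, mu: float, spacing_factor: float, n_phase: int
):
    """(A, B, C) of the flagellum alone, from the coupled solver."""
    disc = filament_nodes(fil, x0=x0)
    if spacing_factor != 1.0:
        from .geometry import default_filament_node_count

        n = default_filament_node_count(fil, spacing_factor)
        disc = filament_nodes(fil, n_nodes=n, x0=x0)
    R = resistance_matrix(disc, pole=(0.0, 0.0, 0.0), mu=mu, n_phase=n_phase)
    return R[0, 0], R[0, 3], R[3, 3]


def evaluate_assembly(
    assembly: AssemblySpec,
    methods=("global", "additive"),
    n_head_nodes: int = 600,
    spacing_factor: float = 1.0,
    n_phase: int = 1,
) -> dict:
    """Solve one geometry with every requested method.

    Returns a dict with the partwise blocks, the isolated coefficients,
    upsilon and one :class:`~microswim.swim.SwimSolution` plus
    :class:`EfficiencyReport` per method.
    """
    mu = assembly.viscosity
    omega = assembly.motor_rate
    R_head = assembly.head.radius
    A0, C0 = sphere_axial_scalars(R_head, mu)

    disc = assemble(assembly, n_head_nodes=n_head_nodes, spacing_factor=spacing_factor)
    parts, sol_global = analyze_assembly(disc, omega, mu=mu, n_phase=n_phase)

    A, B, C = _isolated_flagellum_scalars(
        assembly.filament, R_head + assembly.gap, mu, spacing_factor, n_phase
    )

    out = {
        "parts": parts,
        "isolated": {"A0": A0, "C0": C0, "A": A, "B": B, "C": C},
        "solutions": {},
        "reports": {},
        "upsilon": {},
    }
    for method in methods:
        if method == "global":
            sol = sol_global
            ups = correction_factor(A0, A, B, parts)
            rep = efficiencies(sol, A0, C0, A, B, C, parts=parts, upsilon=ups)
        elif method == "additive":
            sol = solve_additive(A0, C0, A, B, C, omega)
            ups = correction_factor(A0, A, B, parts)
            rep = efficiencies(sol, A0, C0, A, B, C, parts=parts, upsilon=ups)
        elif method in ("rft-gh", "rft-lighthill"):
            model_id = "gray_hancock" if method == "rft-gh" else "lighthill"
            model = drag_coefficients(
                model_id, assembly.filament.pitch, assembly.filament.radius, mu
            )
            Ar, Br, Cr = axial_scalars(
                filament_resistance_rft(assembly.filament, model)
            )
            sol = solve_additive(A0, C0, Ar, Br, Cr, omega, method=method)
            ups = correction_factor(A0, Ar, Br, parts)
            rep = efficiencies(sol, A0, C0, Ar, Br, Cr, parts=parts, upsilon=ups)
        else:
            raise ValueError(f"unknown method {method!r}")
        out["solutions"][method] = sol
        out["reports"][method] = rep
        out["upsilon"][method] = ups
    return out


def sweep_lengths(
    template: AssemblySpec,
    n_turns_grid,
    methods=("global", "additive"),
    n_head_nodes: int = 600,
    spacing_factor: float = 1.0,
    n_phase: int = 1,
) -> pd.DataFrame:
    """Length sweep at fixed pitch, amplitude, head size and motor rate.

    One row per (n_turns, method) with the swimming state, upsilon, the
    partwise axial scalars and all six performance measures (the variant
    matching the method, plus the corrected variant for additive-family
    methods).  Failed points are recorded with ``ok = False`` and the sweep
    continues.
    """
    rows = []
    for n_turns in n_turns_grid:
        try:
            fil = template.filament.with_turns(float(n_turns))
            asm = AssemblySpec(
                head=template.head,
                filament=fil,
                gap=template.gap,
                motor_rate=template.motor_rate,
                viscosity=template.viscosity,
            )
            res = evaluate_assembly(
                asm,
                methods=methods,
                n_head_nodes=n_head_nodes,
                spacing_factor=spacing_factor,
                n_phase=n_phase,
            )
        except Exception as exc:  # noqa: BLE001 - sweep robustness by contract
            for method in methods:
                rows.append({"n_turns": n_turns, "method": method,
                             "ok": False, "error": str(exc)})
            continue
        parts = res["parts"]
        iso = res["isolated"]
        for method in methods:
            sol = res["solutions"][method]
            rep = res["reports"][method]
            variant = "global" if method == "global" else "additive"
            row = {
                "n_turns": float(n_turns),
                "L_over_lambda": float(n_turns),
                "method": method,
                "ok": True,
                "error": "",
                "U": sol.U,
                "Omega": sol.Omega,
                "T_motor": sol.T_motor,
                "upsilon": res["upsilon"][method],
                "U_corrected": res["upsilon"][method] * sol.U
                if variant == "additive" else sol.U,
                "A0": iso["A0"], "C0": iso["C0"],
                "A": iso["A"], "B": iso["B"], "C": iso["C"],
                "A1": parts.A1, "A2": parts.A2,
                "B1_plus_B2": parts.B_sum,
                "Bhat2": parts.Bhat2,
                "C1": parts.C1, "C2": parts.C2,
            }
            for name in MEASURES:
                row[name] = rep[variant][name]
            if variant == "additive":
                for name in MEASURES:
                    row[f"{name}_corrected"] = rep["corrected"][name]
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------------
# length optimization
# ----------------------------------------------------------------------------

def optimize_length(
    metric,
    bracket=(1.0, 20.0),
    tolerance: float = 0.05,
    n_grid: int = 12,
):
    """Maximize ``metric(n_turns)`` over the bracket.

    Coarse grid scan followed by golden-section refinement around the best
    grid point.  Returns ``(n_turns_star, value, interior)`` where
    ``interior`` is False when the maximum sits on the bracket boundary
    (monotone metric: no interior optimum).
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not hi > lo:
        raise ValueError("empty bracket")
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([metric(x) for x in grid])
    i = int(np.argmax(vals))
    if i == 0 or i == n_grid - 1:
        return float(grid[i]), float(vals[i]), False

    a, b = grid[i - 1], grid[i + 1]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = metric(c), metric(d)
    while (b - a) > tolerance:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = metric(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = metric(d)
    x = 0.5 * (a + b)
    return float(x), float(metric(x)), True


def assembly_metric(
    template: AssemblySpec,
    measure: str,
    method: str = "global",
    n_head_nodes: int = 400,
    spacing_factor: float = 1.0,
    n_phase: int = 1,
):
    """Callable ``n_turns -> metric value`` for :func:`optimize_length`.

    ``measure`` is ``"speed"`` (|U|) or one of :data:`MEASURES`; the
    measure is evaluated with the requested method's variant.
    """
    if measure != "speed" and measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")

    def metric(n_turns: float) -> float:
        fil = template.filament.with_turns(float(n_turns))
        asm = AssemblySpec(
            head=template.head, filament=fil, gap=template.gap,
            motor_rate=template.motor_rate, viscosity=template.viscosity,
        )
        res = evaluate_assembly(
            asm, methods=(method,), n_head_nodes=n_head_nodes,
            spacing_factor=spacing_factor, n_phase=n_phase,
        )
        if measure == "speed":
            return abs(res["solutions"][method].U)
        variant = "global" if method == "global" else "additive"
        val = res["reports"][method][variant][measure]
        return abs(val) if np.isfinite(val) else -np.inf

    return metric
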