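"""Correcting factor, performance measures, sweeps and optimization."""

import math

import numpy as np
import pytest

from microswim import (
    AssemblySpec,
    FilamentSpec,
    HeadSpec,
    correction_factor,
    efficiencies,
    evaluate_assembly,
    optimize_length,
    solve_additive,
    sweep_lengths,
)
from microswim.performance import MEASURES, assembly_metric, sphere_axial_scalars
from microswim.stokes import PartwiseResistance

from conftest import COARSE, split_sweep


def _parts(A1, A2, Bh1, Bh2, Bb1, Bb2, C1, C2):
    R1, R2 = np.zeros((6, 6)), np.zeros((6, 6))
    R1[0, 0], R1[0, 3], R1[3, 0], R1[3, 3] = A1, Bh1, Bb1, C1
    R2[0, 0], R2[0, 3], R2[3, 0], R2[3, 3] = A2, Bh2, Bb2, C2
    return PartwiseResistance(R1=R1, R2=R2, pole=np.zeros(3), mu=1.0)


A0, C0, A, B, C = 37.7, 201.1, 27.4, -7.76, 48.9


class TestCorrectionFactor:
    def test_identity_for_isolated_blocks(self):
        parts = _parts(A0, A, 0.0, B, 0.0, B, C0, C)
        assert correction_factor(A0, A, B, parts) == pytest.approx(1.0, rel=1e-12)

    def test_zero_coupling_rejected(self):
        parts = _parts(A0, A, 0.0, B, 0.0, B, C0, C)
        with pytest.raises(ValueError, match="degenerate"):
            correction_factor(A0, A, 0.0, parts)

    def test_invariant_under_viscosity_and_motor_rescaling(self, sweep_assembly):
        # all resistance coefficients scale linearly with mu, omega does not
        # enter: upsilon is geometry-only
        asm1 = sweep_assembly
        asm2 = AssemblySpec(asm1.head, asm1.filament, gap=asm1.gap,
                            motor_rate=4.0, viscosity=3.0)
        ups = []
        for asm in (asm1, asm2):
            res = evaluate_assembly(asm, methods=("additive",), **COARSE)
            ups.append(res["upsilon"]["additive"])
        assert ups[0] == pytest.approx(ups[1], rel=1e-9)


class TestEfficiencies:
    def _solution(self, omega=1.0):
        return solve_additive(A0, C0, A, B, C, omega)

    def test_distance_per_motor_revolution_definition(self):
        sol = self._solution(omega=2.0)
        rep = efficiencies(sol, A0, C0, A, B, C)
        assert rep["global"]["eta_pr2"] == pytest.approx(sol.U / 2.0)

    def test_additive_closed_forms_equal_definitions(self):
        # evaluating the definition-based formulas with the additive solution
        # must reproduce the additive closed forms exactly
        sol = self._solution()
        rep = efficiencies(sol, A0, C0, A, B, C)
        for name in MEASURES:
            assert rep["global"][name] == pytest.approx(
                rep["additive"][name], rel=1e-10), name

    def test_zero_coupling_propeller(self):
        sol = solve_additive(A0, C0, A, 0.0, C, 1.0)
        rep = efficiencies(sol, A0, C0, A, 0.0, C)
        assert rep["global"]["eta_en1"] == 0.0
        assert rep["global"]["eta_pr2"] == 0.0
        assert rep["global"]["eta_sw"] == 0.0
        assert rep["global"]["w_work"] == math.inf
        assert rep["additive"]["w_work"] == math.inf

    def test_zero_motor_torque_rejected(self):
        sol = self._solution()
        sol.T_motor = 0.0
        with pytest.raises(ValueError, match="torque"):
            efficiencies(sol, A0, C0, A, B, C)

    def test_corrected_variant_scalings(self):
        sol = self._solution()
        parts = _parts(30.0, 20.0, 0.1, -5.4, 3.0, -8.5, 200.0, 46.0)
        rep = efficiencies(sol, A0, C0, A, B, C, parts=parts)
        ups = rep.upsilon
        add = rep["additive"]
        cor = rep["corrected"]
        assert cor["eta_en1"] == pytest.approx(ups**2 * add["eta_en1"])
        assert cor["eta_en2"] == pytest.approx(ups**2 * add["eta_en2"])
        assert cor["eta_pr1"] == pytest.approx(ups * add["eta_pr1"])
        assert cor["eta_pr2"] == pytest.approx(ups * add["eta_pr2"])
        assert cor["eta_sw"] == pytest.approx(ups * add["eta_sw"])
        assert cor["w_work"] == pytest.approx(add["w_work"] / ups)

    def test_omega_scaling_of_measures(self):
        # velocity-per-revolution measures are omega-invariant; work-based
        # ones scale as stated by their definitions
        r1 = efficiencies(self._solution(1.0), A0, C0, A, B, C)["global"]
        r2 = efficiencies(self._solution(2.0), A0, C0, A, B, C)["global"]
        for name in ("eta_en1", "eta_en2", "eta_pr1", "eta_pr2"):
            assert r2[name] == pytest.approx(r1[name], rel=1e-12)
        assert r2["eta_sw"] == pytest.approx(r1["eta_sw"] / 2.0, rel=1e-12)
        assert r2["w_work"] == pytest.approx(r1["w_work"] * 2.0, rel=1e-12)

    def test_global_energetic_efficiency_in_unit_interval(self, bench_results):
        rep = bench_results["reports"]["global"]
        assert 0.0 < rep["global"]["eta_en1"] <= 1.0
        assert 0.0 < rep["global"]["eta_en2"] <= 1.0


class TestSweep:
    def test_table_columns_and_failure_recording(self, sweep_assembly):
        df = sweep_lengths(sweep_assembly, [1.0, -3.0], methods=("additive",),
                           **COARSE)
        assert set(["n_turns", "method", "ok", "U", "upsilon"]) <= set(df.columns)
        good = df[df.n_turns == 1.0]
        bad = df[~df.ok]
        assert len(good) == 1 and bool(good.ok.iloc[0])
        assert len(bad) == 1 and "n_turns" in bad.error.iloc[0]

    def test_angular_velocity_error_small_and_decreasing(self, length_sweep):
        g, a = split_sweep(length_sweep)
        err = (a.Omega - g.Omega).abs() / g.Omega.abs()
        # the additive approximation is accurate for the rotation rate on
        # short flagella where the speed error is large...
        errU = (a.U - g.U).abs() / g.U.abs()
        for n in (1.0, 2.0, 3.0, 4.0, 5.0):
            assert err[n] < errU[n]
        # ... and decays quickly with tail length
        assert err[20.0] < err[10.0] < err[3.0] < err[1.0]
        assert err[err.index > 5].max() < 0.05

    def test_speed_maxima_at_different_lengths(self, length_sweep):
        g, a = split_sweep(length_sweep)
        n_g = g.U.abs().idxmax()
        n_a = a.U.abs().idxmax()
        assert 1.0 < n_g < 20.0 and 1.0 < n_a < 20.0
        assert n_g != n_a

    def test_energetic_efficiency_maximum_only_in_global(self, length_sweep):
        g, a = split_sweep(length_sweep)
        n_star = g.eta_en1.idxmax()
        assert 1.0 < n_star < 20.0
        # additive variant is monotone over the sweep: no interior maximum
        diffs = np.diff(a.eta_en1.values)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_propulsion_efficiency_monotone_in_global(self, length_sweep):
        g, _ = split_sweep(length_sweep)
        assert (np.diff(g.eta_pr1.abs().values) > 0).all()


class TestOptimizeLength:
    def test_recovers_concave_maximum(self):
        x, val, interior = optimize_length(lambda n: -(n - 7.3) ** 2 + 2.0,
                                           bracket=(1.0, 20.0), tolerance=0.01)
        assert interior
        assert x == pytest.approx(7.3, abs=0.01)
        assert val == pytest.approx(2.0, abs=1e-3)

    def test_monotone_metric_flags_boundary(self):
        x, _, interior = optimize_length(lambda n: n, bracket=(1.0, 20.0))
        assert not interior
        assert x == 20.0

    def test_speed_has_interior_optimum(self, sweep_assembly):
        metric = assembly_metric(sweep_assembly, "speed", method="global",
                                 n_head_nodes=200, spacing_factor=3.0)
        x, _, interior = optimize_length(metric, bracket=(4.0, 16.0),
                                         tolerance=0.5, n_grid=7)
        assert interior
        assert 4.0 < x < 16.0


def test_sphere_scalars_closed_forms():
    A0_, C0_ = sphere_axial_scalars(2.0, mu=1.5)
    assert A0_ == pytest.approx(6.0 * np.pi * 1.5 * 2.0)
    assert C0_ == pytest.approx(8.0 * np.pi * 1.5 * 8.0)
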