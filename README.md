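# microswim

Hydrodynamics and swimming performance of a model "robotic bacterium": a
rigid spherical head of radius `R` propelled by a rotating helical flagellum
(amplitude `b`, pitch `λ`, `N` turns, filament radius `r`) at zero Reynolds
number. The package is for people studying microswimmer propulsion and
optimal propeller design who want to compare, on the same geometry:

* **RFT** — resistive force theory (local drag coefficients `C_T`, `C_N`
  per unit filament length; Gray–Hancock and Lighthill variants),
* **AA** — Purcell's additive approximation (head and flagellum resistance
  coefficients computed in isolation and summed), and
* **GA** — the fully coupled solution from a regularized-Stokeslet
  boundary-integral solve, where each part's resistance blocks are computed
  in the presence of the other.

## The core model

In Stokes flow, forces and torques depend linearly on velocities through a
6×6 resistance matrix. With axial scalars `A0, C0` (head drag/torque),
`A, B, C` (flagellum drag, coupling, torque) and a motor prescribing the
relative rotation rate `ω = Ω_head − Ω_flagellum`, the force-free,
torque-free balance of the additive model gives

```
U = C0·B·ω / ((C0+C)(A0+A) − B²),      Ω = (1 − (A0+A)·C0/((C0+C)(A0+A) − B²))·ω.
```

The coupled route replaces the isolated coefficients with partwise blocks
`A1, A2, B̂i, B̄i, Ci` (force/torque on the *whole* assembly from the motion
of one part with the other held fixed; their sum is the true assembly
resistance matrix). Because each part moves in the other's wake
(hydrodynamic screening), AA and RFT overpredict the speed. A single
geometry-only scalar repairs most of the error:

```
υ = (A0 + A)(B1 + B2) / ((A1 + A2)·B),        U_corrected = υ · U_additive,
```

and the six tracked performance measures (two energetic efficiencies, two
propulsion efficiencies, swimming efficiency, work per traveled distance)
are corrected with the matching power of υ. See `docs/methods.md` for the
full account.

## Worked example

Benchmark swimmer — two-turn helix, `b = 1`, `λ = 8b`, `r = b/16`, head
`R = 2b`, `μ = ω = 1`:

```
$ microswim swim --config examples/benchmark_swimmer.yaml --out out
```

prints (abridged):

| method        |        U |       Ω | T_motor |      υ | υ·U       |
|---------------|---------:|--------:|--------:|-------:|----------:|
| global        | −0.08760 | 0.18739 |  40.651 |      — |         — |
| additive      | −0.09626 | 0.19274 |  38.753 | 0.8772 |  −0.08444 |
| rft-gh        | −0.10099 | 0.14772 |  29.700 | 0.8828 |  −0.08915 |
| rft-lighthill | −0.12476 | 0.22004 |  44.242 | 0.6539 |  −0.08158 |

Units are nondimensional (`b = μ = ω = 1`); the sign of `U` says this
right-handed helix driven at `ω > 0` swims toward −x. Reading the table:
the additive approximation overpredicts the speed by 9.9%, Gray–Hancock RFT
by 15.3%, Lighthill RFT by 42.4%; after multiplying by υ the corrected
predictions land within 3.6%, 1.8% and 6.9% of the coupled solution — the
correction recovers most of what the simplified models miss, using only two
numbers from one coupled solve.

Other entry points:

```
$ microswim sweep     --config examples/length_sweep.yaml --out out   # CSV per (N, method)
$ microswim optimize  --config examples/optimal_speed.yaml --out out  # best N for a measure
$ microswim benchmark --out out                                       # validation cases
```

The benchmark task regenerates every validation case from scratch: sphere
drag/torque vs the Stokes closed forms, two-sphere screening vs the exact
bispherical series and a reflections series, the sparse stroke-averaged
helix resistance pattern, the RFT quadrature vs slender-helix closed forms,
and the speed-comparison table above.

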