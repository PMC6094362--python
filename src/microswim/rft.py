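"""Resistive force theory: local drag models for a slender helical filament.

RFT assigns independent tangential and normal drag coefficients per unit
length of the centerline, ``df = [C_T tt + C_N (I - tt)] u ds`` (``df`` the
force exerted on the fluid), and the filament resistance matrix follows by
integrating over the six unit rigid motions.

Two coefficient families are provided.  ``gray_hancock`` uses the reference
length ``q = pitch``; by default the classical signs

    C_T = 2 pi mu / (ln(2q/r) - 1/2),    C_N = 4 pi mu / (ln(2q/r) + 1/2),

are used (``sign_convention="classical"``); the variant with the +-1/2 swapped
between the two denominators circulates in parts of the literature and is
available as ``sign_convention="swapped"``.  ``lighthill`` uses ``q = 0.09
pitch`` with Lighthill's replacement expressions

    C_T = 2 pi mu / ln(2q/r),            C_N = 4 pi mu / (ln(2q/r) + 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FilamentSpec, helix_centerline

MODEL_IDS = ("gray_hancock", "lighthill")


@dataclass(frozen=True)
class DragModel:
    """Per-unit-length drag coefficients of a local (RFT) model."""

    model_id: str
    C_T: float
    C_N: float
    q: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.C_N > self.C_T > 0):
            raise ValueError("invalid drag model: need C_N > C_T > 0")


def drag_coefficients(
    model_id: str,
    pitch: float,
    radius: float,
    mu: float = 1.0,
    sign_convention: str = "classical",
) -> DragModel:
    """Tangential/normal drag coefficients for one of the RFT models.

    Raises if the filament is not slender enough for the chosen model
    (non-positive logarithmic denominator).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; choose from {MODEL_IDS}")
    if sign_convention not in ("classical", "swapped"):
        raise ValueError("sign_convention must be 'classical' or 'swapped'")
    if pitch <= 0 or radius <= 0 or mu <= 0:
        raise ValueError("pitch, radius and viscosity must be positive")

    if model_id == "gray_hancock":
        q = pitch
        log = np.log(2.0 * q / radius)
        if sign_convention == "classical":
            den_T, den_N = log - 0.5, log + 0.5
        else:
            den_T, den_N = log + 0.5, log - 0.5
    else:  # lighthill
        q = 0.09 * pitch
        log = np.log(2.0 * q / radius)
        den_T, den_N = log, log + 0.5

    if den_T <= 0 or den_N <= 0:
        raise ValueError(
            f"filament not slender enough for {model_id}: "
            f"ln(2q/r) = {log:.3f} makes a drag denominator non-positive"
        )
    return DragModel(
        model_id=model_id,
        C_T=2.0 * np.pi * mu / den_T,
        C_N=4.0 * np.pi * mu / den_N,
        q=q,
        mu=mu,
    )


def filament_resistance_rft(
    spec: FilamentSpec,
    model: DragModel,
    n_segments: int | None = None,
    pole=None,
    n_phase: int = 8,
) -> np.ndarray:
    """Stroke-averaged 6x6 RFT resistance matrix of the helix about ``pole``.

    Integrates the local drag law along the centerline for the six unit
    rigid motions, averaged over ``n_phase`` equally spaced stroke phases.
    The default pole is the axial midpoint of the filament projected on the
    axis, which together with stroke averaging produces the sparse block
    pattern of a rotating helix (the instantaneous matrix carries
    phase-dependent couplings, e.g. axial force from transverse rotation,
    that vanish in the stroke mean).  Same sign convention as the coupled
    solver: the matrix maps rigid velocities to minus the viscous
    force/torque and is positive definite.

    Tapered filaments are not supported under RFT.
    """
    if spec.taper_rate != 0.0:
        raise ValueError("RFT filament resistance supports untapered helices only")
    if n_segments is None:
        n_segments = max(int(np.ceil(64 * spec.n_turns)), 64)
    if n_segments < 16 * spec.n_turns:
        raise ValueError(
            f"n_segments={n_segments} undersamples the helix: need at least "
            f"16 per turn"
        )
    if n_phase < 1:
        raise ValueError("n_phase must be >= 1")

    if pole is None:
        pole = np.array([spec.axial_length / 2.0, 0.0, 0.0])
    pole = np.asarray(pole, dtype=float)

    acc = np.zeros((6, 6))
    for j in range(n_phase):
        phase = spec.phase + 2.0 * np.pi * j / n_phase
        pts, tangents, ds = helix_centerline(spec, n_nodes=n_segments, phase=phase)
        rel = pts - pole

        # per-node local drag tensor: C_T t t + C_N (I - t t)
        tt = np.einsum("ni,nj->nij", tangents, tangents)
        D = model.C_N * (np.eye(3)[None, :, :] - tt) + model.C_T * tt

        R = np.zeros((6, 6))
        for k in range(6):
            U = np.zeros(3)
            W = np.zeros(3)
            if k < 3:
                U[k] = 1.0
            else:
                W[k - 3] = 1.0
            u = U + np.cross(W, rel)
            df = np.einsum("nij,nj->ni", D, u) * ds[:, None]
            R[:3, k] = df.sum(axis=0)
            R[3:, k] = np.cross(rel, df).sum(axis=0)
        acc += R
    return acc / n_phase


def axial_scalars(R: np.ndarray) -> tuple[float, float, float]:
    """(A, B, C): axial drag, coupling and torque coefficients of a 6x6."""
    return float(R[0, 0]), float(R[0, 3]), float(R[3, 3])


def closed_form_axial_scalars(spec: FilamentSpec, model: DragModel):
    """Slender-helix closed forms for (A, B, C) under a local drag law.

    With pitch angle ``theta`` (cos theta = pitch / turn arc length) and
    total contour length ``Lam``:

        A = Lam (C_T cos^2 + C_N sin^2),
        B = -chi Lam b sin cos (C_N - C_T),
        C = Lam b^2 (C_N cos^2 + C_T sin^2).

    Used as an independent oracle for the quadrature in
    :func:`filament_resistance_rft`; valid for untapered helices.
    """
    if spec.taper_rate != 0.0:
        raise ValueError("closed forms hold for untapered helices only")
    ell = np.hypot(spec.pitch, 2.0 * np.pi * spec.amplitude)
    c = spec.pitch / ell
    s = 2.0 * np.pi * spec.amplitude / ell
    Lam = spec.n_turns * ell
    b = spec.amplitude
    A = Lam * (model.C_T * c**2 + model.C_N * s**2)
    B = -spec.chirality * Lam * b * s * c * (model.C_N - model.C_T)
    C = Lam * b**2 * (model.C_N * c**2 + model.C_T * s**2)
    return A, B, C
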