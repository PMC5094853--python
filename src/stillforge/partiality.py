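"""Partiality model shared by the simulator, the scaler and the refiner.

On a still image a reflection is recorded only partially: the recorded
fraction p depends on how far its reciprocal lattice point sits from the
Ewald sphere (the offset δ) relative to the reflecting range r_s, an
effective width absorbing mosaic spread, beam divergence and spectral
dispersion.  The model pinned here is a Lorentzian rocking curve

    p(δ) = r_s² / (r_s² + 4 δ²),      r_s(s) = γ0 + γe · (s / 2)

with γ0 the resolution-independent term (Å⁻¹) and γe a dimensionless
resolution-dependent coefficient.  p(0) = 1 and p = 1/2 at |δ| = r_s/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Frame, ewald_offsets, predict_positions, reciprocal_matrix

__all__ = [
    "PartialityParams",
    "reflecting_range",
    "partiality_fraction",
    "ObservationModel",
    "observation_model",
    "correct_intensities",
]

# Observations with partiality below this floor are excluded from merging:
# dividing by a vanishing p would blow noise up without adding information.
P_FLOOR = 1e-3


@dataclass(frozen=True)
class PartialityParams:
    """Reflecting-range parameters γ0 (Å⁻¹) and γe (dimensionless)."""

    gamma0: float
    gamma_e: float

    def __post_init__(self) -> None:
        if self.gamma0 <= 0 or self.gamma_e < 0:
            raise ValueError("gamma0 must be > 0 and gamma_e >= 0")


def reflecting_range(params: PartialityParams, s) -> np.ndarray:
    """r_s = γ0 + γe·(s/2); strictly increasing in s when γe > 0."""
    return params.gamma0 + params.gamma_e * (np.asarray(s, dtype=float) / 2.0)


def partiality_fraction(delta, r_s) -> np.ndarray:
    """Lorentzian partiality p = r_s²/(r_s² + 4δ²) ∈ (0, 1]."""
    delta = np.asarray(delta, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    return r_s**2 / (r_s**2 + 4.0 * delta**2)


@dataclass
class ObservationModel:
    """Per-observation derived arrays for one frame under its current model."""

    hkl: np.ndarray  # (N, 3) int
    s: np.ndarray  # 1/d, Å⁻¹
    delta: np.ndarray  # Ewald offsets, Å⁻¹
    p: np.ndarray  # partiality fractions
    i_raw: np.ndarray
    sigma_raw: np.ndarray
    xy_obs: np.ndarray  # (N, 2) mm
    xy_pred: np.ndarray  # (N, 2) mm
    i_corr: np.ndarray  # partiality-corrected, scaled intensities
    sigma_corr: np.ndarray
    usable: np.ndarray  # bool; p above floor


def correct_intensities(
    i_raw: np.ndarray,
    sigma_raw: np.ndarray,
    p: np.ndarray,
    g: float,
    b: float,
    s: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Full-intensity correction I_full = I_raw / (G·exp(−B·s²/2)·p).

    σ is divided by the same factor, so I/σ is invariant; negative raw
    intensities pass through with their sign preserved.
    """
    denom = g * np.exp(-b * s**2 / 2.0) * np.maximum(p, P_FLOOR)
    return i_raw / denom, sigma_raw / denom


def observation_model(frame: Frame, predict: bool = True) -> ObservationModel:
    """Evaluate s, δ, p, corrected intensities and predicted positions for
    every observation of ``frame`` under its current per-frame model."""
    hkl = frame.hkl_array()
    a_matrix = reciprocal_matrix(frame.cell, frame.orientation)
    q = hkl @ a_matrix.T
    s = np.linalg.norm(q, axis=1)
    delta = ewald_offsets(a_matrix, hkl, frame.beam)
    params = PartialityParams(frame.gamma0, frame.gamma_e)
    p = partiality_fraction(delta, reflecting_range(params, s))
    i_raw, sigma_raw = frame.intensity_arrays()
    i_corr, sigma_corr = correct_intensities(i_raw, sigma_raw, p, frame.g, frame.b, s)
    xy_obs = frame.position_array()
    if predict and len(hkl):
        xy_pred = predict_positions(a_matrix, hkl, frame.beam, frame.detector)
    else:
        xy_pred = np.zeros_like(xy_obs)
    return ObservationModel(
        hkl=hkl,
        s=s,
        delta=delta,
        p=p,
        i_raw=i_raw,
        sigma_raw=sigma_raw,
        xy_obs=xy_obs,
        xy_pred=xy_pred,
        i_corr=i_corr,
        sigma_corr=sigma_corr,
        usable=p >= P_FLOOR,
    )
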