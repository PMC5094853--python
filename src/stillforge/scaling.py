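"""Wilson-statistics intensity scaling of still frames.

Pseudo-Wilson scaling puts every still image on the scale of an ideal
random-atom crystal: the partiality-corrected intensities of one frame are
averaged in equal-volume resolution shells, divided by the squared
scattering-factor sum of the asymmetric-unit contents, and the line

    ln( ⟨I_full⟩ / Σ fᵢ²(s) ) = ln G0 − B0·s²/2

is fitted by least squares.  The intercept gives the frame's linear scale
G0, the slope its temperature factor B0; dividing the frame by
G0·exp(−B0·s²/2) flattens its Wilson plot onto the ideal reference.  The
denominator defaults to Σfᵢ² (the form demanded by Wilson statistics); the
``denominator="f"`` switch reproduces a literal Σfᵢ normalisation instead.

The legacy per-dataset alternative, mean-intensity scaling, is retained for
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .formfactors import PROTEIN_RESIDUE_COMPOSITION, form_factor
from .geometry import Frame
from .merging import MergedDataset, ResolutionShells, equivolume_shells
from .partiality import observation_model

__all__ = [
    "ScatteringTable",
    "WilsonFit",
    "scattering_sum",
    "pseudo_wilson_scale",
    "mean_intensity_scale",
    "wilson_plot",
]

# Pseudo-Wilson scaling fits only reflections above this I/σ(I); weak and
# negative measurements destabilise shell means on a single still.
WILSON_SELECTION_ISIGMA = 0.5
MIN_REFLECTIONS_PER_SHELL = 5


@dataclass
class ScatteringTable:
    """Asymmetric-unit composition and its scattering-factor sums.

    ``composition`` maps element symbols to atom counts per asymmetric
    unit.  The default is the average protein residue stoichiometry times
    ``n_residues``.
    """

    composition: dict[str, float] = field(default_factory=dict)

    @classmethod
    def protein(cls, n_residues: float = 100.0) -> "ScatteringTable":
        comp = {e: n * n_residues for e, n in PROTEIN_RESIDUE_COMPOSITION.items()}
        return cls(comp)

    def sum_f2(self, s) -> np.ndarray:
        """Σᵢ fᵢ²(s) over the composition."""
        if not self.composition:
            raise ValueError("empty composition")
        s = np.asarray(s, dtype=float)
        total = np.zeros_like(s)
        for element, count in self.composition.items():
            total = total + count * form_factor(element, s) ** 2
        return total

    def sum_f(self, s) -> np.ndarray:
        """Σᵢ fᵢ(s) (the literal reading of the scaling relation)."""
        if not self.composition:
            raise ValueError("empty composition")
        s = np.asarray(s, dtype=float)
        total = np.zeros_like(s)
        for element, count in self.composition.items():
            total = total + count * form_factor(element, s)
        return total


def scattering_sum(s, table: ScatteringTable, denominator: str = "f2") -> np.ndarray:
    """Scattering normalisation Σf²(s) (default) or Σf(s)."""
    if denominator == "f2":
        return table.sum_f2(s)
    if denominator == "f":
        return table.sum_f(s)
    raise ValueError("denominator must be 'f' or 'f2'")


@dataclass
class WilsonFit:
    """Result of a (pseudo-)Wilson fit: scale G0, temperature factor B0
    (Å²), the shell points (s̄², ln⟨I⟩/Σf²) used, and the reflection count."""

    g0: float
    b0: float
    s2: np.ndarray
    log_ratio: np.ndarray
    n_reflections: int


def _fit_line(s2: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """OLS (or weighted) fit y = intercept + slope·s²; returns (G0, B0)."""
    w = np.ones_like(s2) if weights is None else weights
    W = np.sum(w)
    xm = np.sum(w * s2) / W
    ym = np.sum(w * y) / W
    slope = np.sum(w * (s2 - xm) * (y - ym)) / np.sum(w * (s2 - xm) ** 2)
    intercept = ym - slope * xm
    return float(np.exp(intercept)), float(-2.0 * slope)


def _shell_points(
    s: np.ndarray,
    i_full: np.ndarray,
    table: ScatteringTable,
    shells: ResolutionShells,
    denominator: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    ks = shells.assign(s)
    # normalise per reflection before shell-averaging so the curvature of
    # Σf² across a wide shell does not bias the fitted slope
    norm = i_full / scattering_sum(s, table, denominator)
    s2_pts, y_pts, n_pts = [], [], []
    n_used = 0
    for k in range(shells.n_shells):
        sel = ks == k
        if np.sum(sel) < MIN_REFLECTIONS_PER_SHELL:
            continue
        mean_ratio = float(np.mean(norm[sel]))
        if mean_ratio <= 0:
            continue
        s2_pts.append(float(np.mean(s[sel] ** 2)))
        y_pts.append(math.log(mean_ratio))
        n_pts.append(int(np.sum(sel)))
        n_used += int(np.sum(sel))
    return np.array(s2_pts), np.array(y_pts), np.array(n_pts), n_used


def pseudo_wilson_scale(
    frame: Frame,
    table: ScatteringTable,
    shells: ResolutionShells,
    isigma_min: float = WILSON_SELECTION_ISIGMA,
    denominator: str = "f2",
) -> WilsonFit:
    """Fit one frame's observed Wilson plot against the ideal random-atom
    reference, returning its initial scale G0 and temperature factor B0.

    Partiality-corrected full intensities I_full = I_raw/p (under the
    frame's current partiality model, with G = 1, B = 0 semantics for the
    fit) of reflections with I/σ(I) > ``isigma_min`` are averaged per
    equal-volume shell; shells with fewer than five selected reflections
    are dropped.  Raises if fewer than two shells remain.
    """
    m = observation_model(frame, predict=False)
    keep = m.usable & (m.i_raw / m.sigma_raw > isigma_min)
    # correction with the frame's current G/B deliberately NOT applied:
    # the fit measures them.
    i_full = m.i_raw[keep] / m.p[keep]
    s2, y, npts, n_used = _shell_points(m.s[keep], i_full, table, shells, denominator)
    if len(s2) < 2:
        raise ValueError(f"frame {frame.id}: fewer than 2 populated shells; unscalable")
    g0, b0 = _fit_line(s2, y)
    return WilsonFit(g0, b0, s2, y, n_used)


def mean_intensity_scale(frames: list[Frame]) -> list[float]:
    """Legacy mean-intensity scaling: every frame is scaled to the grand
    mean of all frames' partiality-corrected intensities.  Returns one
    multiplicative scale per frame (NaN for empty frames)."""
    if not frames:
        raise ValueError("no frames")
    means = []
    for frame in frames:
        if not frame.observations:
            means.append(math.nan)
            continue
        m = observation_model(frame, predict=False)
        means.append(float(np.mean(m.i_raw[m.usable] / m.p[m.usable])))
    valid = [v for v in means if not math.isnan(v)]
    grand = float(np.mean(valid))
    return [grand / v if not math.isnan(v) and v != 0 else math.nan for v in means]


def wilson_plot(
    data: MergedDataset | Frame | tuple[np.ndarray, np.ndarray],
    table: ScatteringTable,
    shells: ResolutionShells,
    denominator: str = "f2",
) -> WilsonFit:
    """Wilson plot of a merged dataset (or a single frame, or raw (s, I)
    arrays): shell series of (s̄², ln⟨I⟩/Σf²) plus the fitted overall B."""
    if isinstance(data, MergedDataset):
        s = data.s_values()
        intensities = data.intensity
    elif isinstance(data, Frame):
        m = observation_model(data, predict=False)
        s = m.s[m.usable]
        intensities = m.i_corr[m.usable]
    else:
        s, intensities = data
        s = np.asarray(s, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
    s2, y, npts, n_used = _shell_points(s, intensities, table, shells, denominator)
    if len(s2) < 2:
        raise ValueError("fewer than 2 populated shells for Wilson plot")
    g0, b0 = _fit_line(s2, y)
    return WilsonFit(g0, b0, s2, y, n_used)


def write_wilson_series(fit: WilsonFit, path) -> None:
    """Tab-separated (s², ln I/Σf²) series for plotting."""
    with open(path, "w") as fh:
        fh.write("s2\tln_i_over_sumf2\n")
        for x, y in zip(fit.s2, fit.log_ratio):
            fh.write(f"{x:.8g}\t{y:.8g}\n")
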