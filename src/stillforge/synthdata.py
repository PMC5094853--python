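"""Seeded generator of ground-truth intensities and still frames.

The generator emulates, at reflection-list level, a serial-crystallography
experiment on an orthorhombic protein crystal with shot-to-shot jitter:
uniformly random crystal orientations, wavelength jitter of the stochastic
(SASE-type) source, a broad pulse-intensity distribution, per-frame
temperature-factor spread, additive background noise (producing negative
integrated intensities, as real background-subtracted stills do), an
optional admixture of a second crystal form with a halved c axis, and
optional mis-indexed frames whose Miller indices are shifted by +1 along l
while the recorded beam centre is left untouched — the diagnostic signature
then has to be rediscovered by beam-centre refinement.

True per-index intensities follow acentric Wilson statistics: unit-mean
exponential deviates times Σf²(s)·exp(−B_true·s²/2).  Mosaicity, beam
divergence and spectral dispersion are folded into the effective reflecting
range (γ0, γe) shared with the processing pipeline, which makes parameter
recovery well-posed.  An optional raster renderer paints Gaussian spots on
a pixel grid for spot-finding tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import erf

from .cells import UnitCell
from .geometry import (
    BeamModel,
    DetectorModel,
    Frame,
    Observation,
    Orientation,
    all_reflections,
    asu_indices,
    ewald_offsets,
    is_absent,
    predict_positions,
    reciprocal_basis,
    reciprocal_matrix,
)
from .partiality import PartialityParams, partiality_fraction, reflecting_range
from .scaling import ScatteringTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "FrameTruth",
    "make_ground_truth",
    "simulate_frame",
    "simulate_dataset",
    "render_image",
]

LONG_CELL = UnitCell(69.4, 170.8, 291.2, 90.0, 90.0, 90.0)


@dataclass
class SimConfig:
    """Simulation knobs.

    Defaults reproduce the long-cell still experiment the package targets:
    λ = 1.304735 Å with 0.5%% wavelength jitter and 0.2%% spectral
    dispersion, pulse-intensity jitter of 100%% FWHM (Gaussian, truncated
    positive), an effective reflecting range bracketing refined mosaicity
    values (γ0 = 3·10⁻⁴ Å⁻¹, γe = 3·10⁻³), detector at 299.82 mm.
    """

    cell: UnitCell = LONG_CELL
    spacegroup: str = "P212121"
    d_min: float = 3.5
    n_frames: int = 432
    wavelength: float = 1.304735
    wavelength_jitter: float = 0.005  # fractional sd of λ
    spectral_dispersion: float = 0.002  # Δλ/λ, folded into γe
    intensity_jitter_fwhm: float = 1.0  # FWHM of G as fraction of its mean
    g_mean: float = 1.0
    gamma0_true: float = 3e-4  # Å⁻¹
    gamma_e_true: float = 3e-3  # dimensionless
    b_true: float = 0.0  # Å², Wilson decay of the truth
    b_frame_mean: float = 20.0  # Å², mean per-frame temperature factor
    b_frame_spread: float = 5.0  # Å², sd of per-frame B
    background_sd: float = 0.0  # counts, additive Gaussian noise
    cell_jitter: float = 0.001  # fractional sd of true per-frame cell edges
    orientation_error_deg: float = 0.02  # error of the *recorded* orientation
    misindex_fraction: float = 0.0
    second_form_fraction: float = 0.0
    delta_max_rs: float = 3.0  # observe reflections with |δ| <= this × r_s
    n_residues: float = 100.0  # asymmetric-unit size for the truth scale
    detector_distance: float = 299.82  # mm
    pixel_size: float = 0.1  # mm
    image_extent: int = 2500  # px
    beam_center: tuple[float, float] = (0.0, 0.0)  # mm
    gamma0_init: float | None = None  # initial model values recorded on frames;
    gamma_e_init: float | None = None  # None = start from the true values
    wilson_deviates: bool = True  # False: E ≡ 1 (deterministic envelope truth)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("wavelength_jitter", "spectral_dispersion", "intensity_jitter_fwhm",
                     "b_frame_spread", "background_sd", "cell_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("misindex_fraction", "second_form_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def scattering_table(self) -> ScatteringTable:
        return ScatteringTable.protein(self.n_residues)

    def detector(self) -> DetectorModel:
        return DetectorModel(self.detector_distance, self.pixel_size,
                             self.image_extent, self.image_extent)


@dataclass
class GroundTruth:
    """True merged-scale intensities per unique index, plus the cached
    full-sphere reflection table frames draw from."""

    hkl: np.ndarray  # (M, 3) unique representatives
    intensity: np.ndarray  # I_true >= 0
    cell: UnitCell
    spacegroup: str
    d_min: float
    b_true: float
    sphere_hkl: np.ndarray = field(repr=False, default=None)  # (N, 3) full sphere
    sphere_truth_idx: np.ndarray = field(repr=False, default=None)  # (N,) -> rows of hkl

    def as_dict(self) -> dict[tuple[int, int, int], float]:
        return {tuple(h): float(v) for h, v in zip(self.hkl.tolist(), self.intensity)}


@dataclass
class FrameTruth:
    """Generating parameters of one frame — written for tests and recovery
    scoring only, never read by the processing pipeline."""

    frame_id: str
    g: float
    b: float
    wavelength: float
    cell: UnitCell
    orientation: Orientation
    misindexed: bool
    misindex_operator: np.ndarray | None
    form: int  # 0 = primary form, 1 = second (halved-c) form
    hkl_true: np.ndarray
    partiality: np.ndarray
    delta: np.ndarray
    i_true: np.ndarray


def benchmark_config(seed: int = 1, n_frames: int = 120) -> SimConfig:
    """The standard desk-scale benchmark conditions.

    A 30×40×50 Å P2₁2₁2₁ crystal to 2.5 Å, 120 frames with the usual
    shot-to-shot jitters (0.5% wavelength, 100% FWHM intensity, γ0 = 3·10⁻⁴,
    γe = 3·10⁻³), additive background noise with σ = 5% of the mean recorded
    signal, a 0.05° error on each recorded orientation (typical indexing
    accuracy) and an initial reflecting-range guess that misses the truth by
    +50%/−33% (the mosaicity is never known a priori).  The background level
    is calibrated at run time from a small noiseless pre-simulation.
    """
    import dataclasses as _dc

    base = SimConfig(
        cell=UnitCell(30.0, 40.0, 50.0),
        d_min=2.5,
        n_frames=n_frames,
        background_sd=0.0,
        orientation_error_deg=0.05,
        gamma0_init=4.5e-4,
        gamma_e_init=2e-3,
        seed=seed,
    )
    probe, _, _ = simulate_dataset(_dc.replace(base, n_frames=min(20, n_frames)))
    mean_signal = float(
        np.mean(np.abs(np.concatenate([[o.i_raw for o in f.observations] for f in probe])))
    )
    return _dc.replace(base, background_sd=0.05 * mean_signal)


def make_ground_truth(config: SimConfig, rng: np.random.Generator | None = None,
                      cell: UnitCell | None = None) -> GroundTruth:
    """Draw a Wilson-distributed ground truth for every non-absent unique
    index to d_min: I_true = Σf²(s) · exp(−B_true·s²/2) · E with E a
    unit-mean exponential deviate (acentric Wilson statistics)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cell = cell or config.cell
    sphere = all_reflections(cell, config.d_min)
    absent = np.array([is_absent(h, config.spacegroup) for h in map(tuple, sphere.tolist())])
    sphere = sphere[~absent]
    reps = asu_indices(sphere, config.spacegroup)
    uniq, inverse = np.unique(reps, axis=0, return_inverse=True)
    s = np.linalg.norm(uniq @ reciprocal_basis(cell).T, axis=1)
    table = config.scattering_table()
    envelope = table.sum_f2(s) * np.exp(-config.b_true * s**2 / 2.0)
    if config.wilson_deviates:
        e_dev = rng.exponential(1.0, size=len(uniq))
    else:
        e_dev = np.ones(len(uniq))
    return GroundTruth(
        hkl=uniq,
        intensity=envelope * e_dev,
        cell=cell,
        spacegroup=config.spacegroup,
        d_min=config.d_min,
        b_true=config.b_true,
        sphere_hkl=sphere,
        sphere_truth_idx=inverse,
    )


def _truncated_gaussian(rng: np.random.Generator, mean: float, sd: float,
                        floor: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > floor:
            return float(v)
    return floor  # pragma: no cover - sd pathologically large


def _random_orientation(rng: np.random.Generator, cell: UnitCell,
                        require_c_transverse: bool = False) -> Orientation:
    """Uniform random orientation; optionally resample until the c* axis is
    within 30° of the detector plane (the geometry in which one-index
    mis-assignment along a long c axis physically arises)."""
    bstar = reciprocal_basis(cell)
    c_star = bstar[:, 2] / np.linalg.norm(bstar[:, 2])
    while True:
        u = Rotation.random(random_state=rng).as_matrix()
        if not require_c_transverse:
            return Orientation(u)
        if abs((u @ c_star)[2]) <= 0.5:
            return Orientation(u)


# Mis-indexing is an off-by-one index assignment along the long axis:
# recorded (h, k, l) = true (h, k, l) + (0, 0, 1).
L_SHIFT = np.array([0, 0, 1])


def simulate_frame(
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
    frame_id: str = "frame",
    misindex: bool = False,
) -> tuple[Frame, FrameTruth]:
    """Generate one still frame.

    Physics: true orientation uniform on SO(3); λ, pulse intensity (G),
    per-frame B and cell edges jittered per the config; every non-absent
    reflection with |δ| ≤ 3·r_s and d ≥ d_min is recorded with
    I_raw = G·exp(−B·s²/2)·p·I_true + N(0, background_sd) and
    σ_raw = sqrt(max(I_raw, 0) + background_sd²).  The recorded frame
    carries the true λ and a slightly mis-estimated orientation (the
    pipeline must refine it); mis-indexed frames have all observation l
    indices shifted by +1 with the recorded beam centre left unshifted.
    """
    lam = config.wavelength * (1.0 + rng.normal(0.0, config.wavelength_jitter))
    g_sd = config.intensity_jitter_fwhm * config.g_mean / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g_true = _truncated_gaussian(rng, config.g_mean, g_sd, 0.05 * config.g_mean)
    b_true_frame = rng.normal(config.b_frame_mean, config.b_frame_spread)
    edges = np.array(truth.cell.lengths) * (1.0 + rng.normal(0.0, config.cell_jitter, 3))
    cell_true = UnitCell(*edges, *truth.cell.angles)
    orientation_true = _random_orientation(rng, cell_true, require_c_transverse=misindex)

    beam_true = BeamModel(lam, center=config.beam_center)
    a_true = reciprocal_matrix(cell_true, orientation_true)
    q = truth.sphere_hkl @ a_true.T
    s = np.linalg.norm(q, axis=1)
    delta = np.linalg.norm(q + beam_true.s0, axis=1) - 1.0 / lam
    params = PartialityParams(config.gamma0_true, config.gamma_e_true)
    r_s = reflecting_range(params, s)
    sel = (np.abs(delta) <= config.delta_max_rs * r_s) & (s <= 1.0 / config.d_min)
    hkl_true = truth.sphere_hkl[sel]
    s, delta, r_s = s[sel], delta[sel], r_s[sel]
    p = partiality_fraction(delta, r_s)
    i_true = truth.intensity[truth.sphere_truth_idx[sel]]

    signal = g_true * np.exp(-b_true_frame * s**2 / 2.0) * p * i_true
    noise = rng.normal(0.0, config.background_sd, len(signal)) if config.background_sd > 0 else 0.0
    i_raw = signal + noise
    # σ from the expected signal (true photon flux), not the noisy
    # measurement: a σ that fluctuates with the recorded intensity makes
    # inverse-variance merging systematically biased low
    sigma = np.sqrt(np.maximum(signal, 0.0) + config.background_sd**2)
    sigma = np.maximum(sigma, 1e-6)

    detector = config.detector()
    xy = predict_positions(a_true, hkl_true, beam_true, detector)

    hkl_rec = hkl_true + L_SHIFT if misindex else hkl_true
    observations = [
        Observation(tuple(int(v) for v in h), float(i), float(sg), float(x), float(y))
        for h, i, sg, (x, y) in zip(hkl_rec.tolist(), i_raw, sigma, xy)
    ]

    err = np.radians(config.orientation_error_deg)
    if err > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        wobble = Rotation.from_rotvec(axis * rng.normal(0.0, err)).as_matrix()
    else:
        wobble = np.eye(3)
    orientation_rec = orientation_true.rotated(wobble)

    frame = Frame(
        id=frame_id,
        beam=BeamModel(lam, center=config.beam_center),
        detector=detector,
        cell=cell_true,
        orientation=orientation_rec,
        g=1.0,
        b=0.0,
        gamma0=config.gamma0_init if config.gamma0_init is not None else config.gamma0_true,
        gamma_e=config.gamma_e_init if config.gamma_e_init is not None else config.gamma_e_true,
        observations=observations,
    )
    frame_truth = FrameTruth(
        frame_id=frame_id,
        g=g_true,
        b=float(b_true_frame),
        wavelength=lam,
        cell=cell_true,
        orientation=orientation_true,
        misindexed=misindex,
        misindex_operator=L_SHIFT.copy() if misindex else None,
        form=0,
        hkl_true=hkl_true,
        partiality=p,
        delta=delta,
        i_true=i_true,
    )
    return frame, frame_truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[Frame], GroundTruth, list[FrameTruth]]:
    """Generate a full seeded dataset.

    ``round(n_frames · misindex_fraction)`` frames (of the primary form)
    are mis-indexed; ``round(n_frames · second_form_fraction)`` frames are
    generated on the halved-c second crystal form with an independent
    Wilson truth.  Identical seeds reproduce bit-identical datasets.
    """
    if config.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    truth_seed, assign_seed, frames_seed, truth2_seed = ss.spawn(4)
    truth = make_ground_truth(config, np.random.default_rng(truth_seed))

    n = config.n_frames
    n_form2 = round(n * config.second_form_fraction)
    n_mis = round(n * config.misindex_fraction)
    order = np.random.default_rng(assign_seed).permutation(n)
    form2_set = set(order[:n_form2].tolist())
    mis_set = set(order[n_form2 : n_form2 + n_mis].tolist())

    truth2 = None
    if n_form2:
        short_cell = UnitCell(truth.cell.a, truth.cell.b, truth.cell.c / 2.0, *truth.cell.angles)
        truth2 = make_ground_truth(config, np.random.default_rng(truth2_seed), cell=short_cell)

    frames: list[Frame] = []
    frame_truths: list[FrameTruth] = []
    for j, child in enumerate(frames_seed.spawn(n)):
        rng = np.random.default_rng(child)
        which_truth = truth2 if j in form2_set else truth
        frame, ft = simulate_frame(
            which_truth, config, rng, frame_id=f"sim{j:05d}", misindex=j in mis_set
        )
        if j in form2_set:
            ft = replace(ft, form=1)
        frames.append(frame)
        frame_truths.append(ft)
    return frames, truth, frame_truths


# ---------------------------------------------------------------------------
# Raster renderer (for spot-finding tests)
# ---------------------------------------------------------------------------


def render_image(
    frame: Frame,
    extent: int | None = None,
    pixel_size: float | None = None,
    psf_sd: float = 1.2,
    background_level: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render a frame as a 2-D count array.

    Each observation with positive raw intensity contributes a
    pixel-integrated isotropic Gaussian (total volume = I_raw) centred at
    its detector position; the background is a constant level with
    Poisson noise when an rng/seed is supplied.  Values are clipped at 0.
    """
    extent = frame.detector.nx if extent is None else extent
    pixel_size = frame.detector.pixel_size if pixel_size is None else pixel_size
    if extent <= 0 or pixel_size <= 0:
        raise ValueError("image extent and pixel size must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if background_level > 0 and rng is not None:
        image = rng.poisson(background_level, size=(extent, extent)).astype(float)
    else:
        image = np.full((extent, extent), float(background_level))

    half = extent / 2.0
    win = int(np.ceil(5 * psf_sd))
    for obs in frame.observations:
        if obs.i_raw <= 0:
            continue
        px = obs.x / pixel_size + half
        py = obs.y / pixel_size + half
        ix, iy = int(round(px)), int(round(py))
        x0, x1 = max(ix - win, 0), min(ix + win + 1, extent)
        y0, y1 = max(iy - win, 0), min(iy + win + 1, extent)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        # pixel-integrated Gaussian via erf differences (exact to quadrature)
        fx = 0.5 * (
            erf((xs + 0.5 - px) / (np.sqrt(2) * psf_sd))
            - erf((xs - 0.5 - px) / (np.sqrt(2) * psf_sd))
        )
        fy = 0.5 * (
            erf((ys + 0.5 - py) / (np.sqrt(2) * psf_sd))
            - erf((ys - 0.5 - py) / (np.sqrt(2) * psf_sd))
        )
        image[np.ix_(ys, xs)] += obs.i_raw * np.outer(fy, fx)
    return np.clip(image, 0.0, None)


def write_truth_hkl(truth: GroundTruth, path) -> None:
    """Ground truth as plain 'h k l I' text."""
    with open(path, "w") as fh:
        for h, i in zip(truth.hkl.tolist(), truth.intensity):
            fh.write(f"{h[0]:4d} {h[1]:4d} {h[2]:4d} {i:.6g}\n")


def read_truth_hkl(path, cell: UnitCell, spacegroup: str = "P212121",
                   d_min: float = 0.0, b_true: float = 0.0) -> GroundTruth:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                parts = line.split()
                rows.append((int(parts[0]), int(parts[1]), int(parts[2]), float(parts[3])))
    hkl = np.array([r[:3] for r in rows], dtype=int)
    inten = np.array([r[3] for r in rows])
    return GroundTruth(hkl, inten, cell, spacegroup, d_min, b_true)
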