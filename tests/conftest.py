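"""Shared fixtures: the standard simulated datasets used across the suite.

The "standard" dataset emulates the still-diffraction study conditions at
desk scale: a small orthorhombic P2₁2₁2₁ crystal (30×40×50 Å) to 2.5 Å,
120 frames, 0.5% wavelength jitter, 100% FWHM pulse-intensity jitter,
reflecting range γ0 = 3·10⁻⁴ Å⁻¹ / γe = 3·10⁻³, and additive background
noise with σ equal to 5% of the mean recorded signal.  It is generated
once per session and shared (read-only) by the end-to-end tests.
"""

from __future__ import annotations

import copy
import math

import pytest
from hypothesis import settings

from stillforge.merging import equivolume_shells
from stillforge.postrefine import PostRefinementConfig, run_postrefinement
from stillforge.synthdata import benchmark_config, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

STANDARD_SEED = 1


def standard_config(seed: int = STANDARD_SEED, n_frames: int = 120) -> SimConfig:
    """The package's standard benchmark conditions (see synthdata)."""
    return benchmark_config(seed=seed, n_frames=n_frames)


@pytest.fixture(scope="session")
def standard_dataset():
    """(frames, truth, frame_truths) of the standard noisy simulation."""
    return simulate_dataset(standard_config())


@pytest.fixture(scope="session")
def standard_run(standard_dataset):
    """Ten post-refinement cycles on (a copy of) the standard dataset.

    Returns (frames_after, merged, stats, history, truth, frame_truths).
    """
    frames, truth, fts = standard_dataset
    frames = copy.deepcopy(frames)
    cfg = standard_config()
    merged, stats, history = run_postrefinement(
        frames, cfg.scattering_table(), PostRefinementConfig(cycles=10, d_min=2.5)
    )
    return frames, merged, stats, history, truth, fts


@pytest.fixture(scope="session")
def shells25():
    return equivolume_shells(math.inf, 2.5, 10)
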