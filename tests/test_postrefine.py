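"""Partiality model, per-frame refinement and the iterative engine."""

import copy
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stillforge.cells import UnitCell
from stillforge.geometry import Observation, asu_index
from stillforge.partiality import (
    PartialityParams,
    correct_intensities,
    observation_model,
    partiality_fraction,
    reflecting_range,
)
from stillforge.postrefine import (
    PostRefinementConfig,
    correct_observation,
    refine_frame,
    reject_frames,
    run_postrefinement,
)
from stillforge.synthdata import SimConfig, simulate_dataset

SMALL = UnitCell(30, 40, 50)


class TestReflectingRange:
    def test_reference_parameter_arithmetic(self):
        """With γ0 = 0.00024 Å⁻¹ and γe = 0.00627 (the reference refined
        values) at d = 3.5 Å: r_s = 0.00024 + 0.00627·(1/3.5)/2."""
        params = PartialityParams(0.00024, 0.00627)
        s = 1 / 3.5
        assert reflecting_range(params, s) == pytest.approx(0.00024 + 0.00627 * s / 2, rel=1e-12)
        assert reflecting_range(params, s) == pytest.approx(0.001136, abs=2e-6)

    def test_gamma_e_zero_is_constant(self):
        params = PartialityParams(5e-4, 0.0)
        s = np.linspace(0.05, 0.5, 9)
        assert np.allclose(reflecting_range(params, s), 5e-4)

    def test_strictly_increasing_when_gamma_e_positive(self):
        params = PartialityParams(3e-4, 3e-3)
        s = np.linspace(0.05, 0.5, 50)
        assert np.all(np.diff(reflecting_range(params, s)) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PartialityParams(0.0, 1e-3)
        with pytest.raises(ValueError):
            PartialityParams(1e-4, -1e-3)


class TestPartialityFraction:
    def test_on_sphere_is_full(self):
        assert partiality_fraction(0.0, 1e-3) == 1.0

    def test_half_width_gives_half(self):
        assert partiality_fraction(5e-4, 1e-3) == pytest.approx(0.5)

    @given(st.floats(1e-5, 1e-2), st.integers(0, 1000))
    def test_even_and_monotone_decreasing_in_offset(self, r_s, seed):
        rng = np.random.default_rng(seed)
        deltas = np.sort(rng.uniform(0, 5 * r_s, 20))
        p = partiality_fraction(deltas, r_s)
        assert np.all(np.diff(p) <= 0)
        assert np.allclose(p, partiality_fraction(-deltas, r_s))
        assert np.all((p > 0) & (p <= 1))


class TestCorrectObservation:
    def _noiseless_frame(self, seed=3):
        cfg = SimConfig(cell=SMALL, d_min=2.5, n_frames=1, background_sd=0.0,
                        orientation_error_deg=0.0, cell_jitter=0.0, seed=seed)
        frames, truth, fts = simulate_dataset(cfg)
        return frames[0], truth, fts[0]

    def test_identity_when_no_correction_needed(self):
        i, sig = correct_intensities(np.array([100.0]), np.array([5.0]),
                                     np.array([1.0]), g=1.0, b=0.0, s=np.array([0.2]))
        assert i[0] == 100.0 and sig[0] == 5.0

    def test_single_observation_path_matches_vectorised_model(self):
        frame, _, _ = self._noiseless_frame()
        m = observation_model(frame, predict=False)
        i, sig = correct_observation(frame.observations[0], frame)
        assert i == pytest.approx(m.i_corr[0], rel=1e-12)
        assert sig == pytest.approx(m.sigma_corr[0], rel=1e-12)

    def test_noiseless_observation_corrects_to_truth(self):
        frame, truth, ft = self._noiseless_frame()
        frame = dataclasses.replace(frame, orientation=ft.orientation, cell=ft.cell,
                                    g=ft.g, b=ft.b)
        tmap = truth.as_dict()
        m = observation_model(frame, predict=False)
        expected = np.array([tmap[asu_index(tuple(h))] for h in m.hkl.tolist()])
        assert np.allclose(m.i_corr, expected, rtol=1e-10)

    def test_i_over_sigma_invariant_and_sign_preserved(self):
        rng = np.random.default_rng(0)
        i = rng.normal(0, 50, 200)  # includes negatives
        sig = rng.uniform(1, 10, 200)
        p = rng.uniform(0.05, 1.0, 200)
        s = rng.uniform(0.1, 0.4, 200)
        ic, sc = correct_intensities(i, sig, p, g=2.2, b=15.0, s=s)
        assert np.allclose(ic / sc, i / sig)
        assert np.array_equal(np.sign(ic), np.sign(i))


class TestRefineFrame:
    def _dataset(self, **kw):
        defaults = dict(cell=SMALL, d_min=2.5, n_frames=4, background_sd=0.0,
                        orientation_error_deg=0.0, cell_jitter=0.0, seed=4)
        defaults.update(kw)
        cfg = SimConfig(**defaults)
        return simulate_dataset(cfg), cfg

    def test_truth_parameters_are_a_fixed_point(self):
        (frames, truth, fts), _ = self._dataset()
        frame, ft = frames[0], fts[0]
        frame.g, frame.b = ft.g, ft.b
        frame.orientation, frame.cell = ft.orientation, ft.cell
        res = refine_frame(frame, truth.as_dict(), PostRefinementConfig(d_min=2.5))
        assert res.converged
        assert frame.g == pytest.approx(ft.g, rel=1e-3)
        assert frame.b == pytest.approx(ft.b, abs=0.2)
        assert res.t_pr <= res.t_pr_initial + 1e-12

    def test_recovers_perturbed_scale_and_b(self):
        (frames, truth, fts), _ = self._dataset()
        frame, ft = frames[0], fts[0]
        frame.orientation, frame.cell = ft.orientation, ft.cell
        frame.g, frame.b = ft.g * 1.5, ft.b + 20.0
        refine_frame(frame, truth.as_dict(), PostRefinementConfig(d_min=2.5))
        assert frame.g == pytest.approx(ft.g, rel=0.02)
        assert frame.b == pytest.approx(ft.b, abs=2.0)

    def test_recovers_perturbed_orientation(self):
        from scipy.spatial.transform import Rotation

        (frames, truth, fts), _ = self._dataset(seed=8)
        frame, ft = frames[0], fts[0]
        frame.g, frame.b, frame.cell = ft.g, ft.b, ft.cell
        wobble = Rotation.from_euler("x", 0.05, degrees=True).as_matrix()
        frame.orientation = ft.orientation.rotated(wobble)
        res = refine_frame(frame, truth.as_dict(), PostRefinementConfig(d_min=2.5))
        cosang = (np.trace(ft.orientation.matrix.T @ frame.orientation.matrix) - 1) / 2
        residual = math.degrees(math.acos(min(1.0, cosang)))
        assert residual < 0.01
        assert res.t_pr < res.t_pr_initial

    def test_sparse_frame_flagged_untouched(self):
        (frames, truth, fts), _ = self._dataset()
        frame = frames[0]
        frame.observations = frame.observations[:10]
        g_before = frame.g
        res = refine_frame(frame, truth.as_dict(), PostRefinementConfig(d_min=2.5))
        assert res.flagged and frame.g == g_before

    def test_dataset_scale_identifiability_against_truth_reference(self):
        """Refining every frame of a noisy dataset against the generating
        reference recovers per-frame parameters: median G within 3%, B
        within 5 Å², γ0 and γe within 25% from deliberately wrong starts."""
        (frames, truth, fts), cfg = self._dataset(
            n_frames=30, background_sd=80.0, orientation_error_deg=0.02,
            cell_jitter=0.001, gamma0_init=4.5e-4, gamma_e_init=2e-3, seed=21)
        prc = PostRefinementConfig(d_min=2.5)
        reference = truth.as_dict()
        for frame in frames:
            refine_frame(frame, reference, prc)
            refine_frame(frame, reference, prc)
        ratios = [f.g / ft.g for f, ft in zip(frames, fts)]
        berrs = [abs(f.b - ft.b) for f, ft in zip(frames, fts)]
        assert abs(np.median(ratios) - 1) < 0.03
        assert np.median(berrs) < 5.0
        assert abs(np.median([f.gamma0 for f in frames]) / 3e-4 - 1) < 0.25
        assert abs(np.median([f.gamma_e for f in frames]) / 3e-3 - 1) < 0.25


class TestRejectFrames:
    def _frames(self, n=10, seed=6):
        cfg = SimConfig(cell=SMALL, d_min=3.0, n_frames=n, seed=seed)
        return simulate_dataset(cfg)[0]

    def test_homogeneous_set_keeps_everything(self):
        frames = self._frames()
        assert all(reject_frames(frames))

    def test_single_wrong_c_axis_rejected(self):
        frames = self._frames()
        bad = frames[3]
        bad.cell = UnitCell(bad.cell.a, bad.cell.b, bad.cell.c * 1.05)
        keep = reject_frames(frames)
        assert keep.count(False) == 1 and not keep[3]

    def test_rejection_idempotent(self):
        frames = self._frames()
        frames[3].cell = UnitCell(frames[3].cell.a, frames[3].cell.b, frames[3].cell.c * 1.05)
        kept = [f for f, k in zip(frames, reject_frames(frames)) if k]
        assert all(reject_frames(kept))

    def test_outlier_scale_rejected(self):
        frames = self._frames()
        frames[5].g = 500.0
        keep = reject_frames(frames)
        assert not keep[5]

    def test_fewer_than_five_frames_never_rejects(self):
        frames = self._frames(n=4)
        frames[0].g = 1e3
        assert all(reject_frames(frames))


class TestRunPostrefinement:
    def test_noiseless_exact_model_simulation_merges_to_truth(self):
        """No noise and no per-frame dispersion (the exact model is the
        starting model): the ten-stage machinery must reproduce the truth
        essentially perfectly rather than corrupt it."""
        cfg = SimConfig(cell=SMALL, d_min=2.5, n_frames=20, background_sd=0.0,
                        orientation_error_deg=0.0, cell_jitter=0.0,
                        intensity_jitter_fwhm=0.0, b_frame_mean=0.0,
                        b_frame_spread=0.0, wavelength_jitter=0.0,
                        wilson_deviates=False, seed=13)
        frames, truth, _ = simulate_dataset(cfg)
        merged, stats, history = run_postrefinement(
            frames, cfg.scattering_table(), PostRefinementConfig(cycles=3, d_min=2.5))
        tmap = truth.as_dict()
        pairs = [(i, tmap[tuple(h)]) for h, i in zip(merged.hkl.tolist(), merged.intensity)
                 if tuple(h) in tmap]
        im = np.array([p[0] for p in pairs])
        it = np.array([p[1] for p in pairs])
        assert np.corrcoef(im, it)[0, 1] >= 0.9999

    def test_cc_half_improves_and_stabilises(self, standard_run):
        """CC1/2 of the final merged set is at least that of the initial
        reference, and per-cycle changes shrink below half a point after
        the early cycles."""
        _, _, stats, history, _, _ = standard_run
        assert history[-1]["cc_half"] >= history[0]["cc_half"]
        # once the accepted frame set stops changing, CC1/2 settles: each
        # further cycle moves it by less than half a percentage point
        stable_from = max(i for i in range(1, len(history))
                          if history[i]["n_frames"] != history[i - 1]["n_frames"])
        late_changes = [abs(history[i + 1]["cc_half"] - history[i]["cc_half"])
                        for i in range(stable_from, len(history) - 1)]
        assert late_changes and max(late_changes) < 0.005

    def test_parameter_shifts_decay_over_cycles(self, standard_run):
        _, _, _, history, _, _ = standard_run
        shifts = [h["mean_shift_g"] for h in history[1:]]
        assert shifts[-1] < shifts[0]
        rot = [h["mean_shift_rot_deg"] for h in history[1:]]
        assert rot[-1] < rot[0]

    def test_partiality_correction_beats_unit_partiality(self, standard_run):
        """Merging with the partiality model correlates better with the
        truth than merging the same frames with p forced to 1."""
        frames, merged, _, _, truth, _ = standard_run
        from stillforge.geometry import asu_indices
        from stillforge.merging import merge_observations

        tmap = truth.as_dict()

        def cc_vs_truth(md):
            pairs = [(i, tmap[tuple(h)]) for h, i in zip(md.hkl.tolist(), md.intensity)
                     if tuple(h) in tmap]
            a = np.array([p[0] for p in pairs])
            b = np.array([p[1] for p in pairs])
            return float(np.corrcoef(a, b)[0, 1])

        naive_frames = copy.deepcopy(frames)
        for f in naive_frames:
            f.gamma0, f.gamma_e = 9.9e-3, 0.0  # reflecting range >> any offset: p ≈ 1
        naive_md, _ = merge_observations(naive_frames, isigma_min=-3.0, d_min=2.5)
        assert cc_vs_truth(merged) > cc_vs_truth(naive_md)

    def test_too_few_frames_rejected(self):
        cfg = SimConfig(cell=SMALL, d_min=2.5, n_frames=1, seed=1)
        frames, _, _ = simulate_dataset(cfg)
        with pytest.raises(ValueError):
            run_postrefinement(frames, cfg.scattering_table(),
                               PostRefinementConfig(cycles=1, d_min=2.5))
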