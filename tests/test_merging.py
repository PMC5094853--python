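"""Merging, resolution shells and still-data quality statistics."""

import math

import numpy as np
import pytest

from stillforge.cells import UnitCell
from stillforge.geometry import unique_reflections
from stillforge.merging import (
    MergedDataset,
    apply_resolution_cutoff,
    cc_half,
    completeness_multiplicity,
    equivolume_shells,
    group_observations,
    merge_observations,
    r_merge_still,
)
from stillforge.synthdata import SimConfig, simulate_dataset

SMALL = UnitCell(30, 40, 50)


def _merged_from_groups(groups, cell=SMALL, d_min=2.5):
    hkl = np.array(sorted(groups), dtype=int)
    i = np.array([np.mean([v[0] for v in groups[tuple(h)]]) for h in hkl.tolist()])
    sig = np.ones(len(hkl))
    mult = np.array([len(groups[tuple(h)]) for h in hkl.tolist()])
    return MergedDataset(hkl, i, sig, mult, cell, "P212121", d_min)


class TestEquivolumeShells:
    def test_two_shell_boundary_closed_form(self):
        shells = equivolume_shells(math.inf, 1.0, 2)
        assert shells.boundaries[1] == pytest.approx(0.5 ** (1 / 3), rel=1e-12)

    def test_reciprocal_volumes_equal(self):
        shells = equivolume_shells(20.0, 2.0, 7)
        vols = np.diff(shells.boundaries**3)
        assert np.allclose(vols, vols[0], rtol=1e-12)

    def test_uniform_volume_points_fill_shells_equally(self):
        rng = np.random.default_rng(0)
        # radii of points uniform in reciprocal volume up to 1/d_min
        r = (rng.uniform(0, 1, 200_000) ** (1 / 3)) / 2.0
        shells = equivolume_shells(math.inf, 2.0, 10)
        counts = np.bincount(shells.assign(r), minlength=10)
        assert counts.std() < 3 * math.sqrt(counts.mean())

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            equivolume_shells(2.0, 5.0, 4)
        with pytest.raises(ValueError):
            equivolume_shells(math.inf, 2.0, 1)


class TestMergeObservations:
    def test_inverse_variance_weighted_mean(self):
        groups = {(1, 2, 3): [(10.0, 1.0), (20.0, 1.0)]}
        merged = _merged_from_groups(groups)
        assert merged.intensity[0] == pytest.approx(15.0)
        # through the real merge path σ = sqrt(1/Σw)
        cfg = SimConfig(cell=SMALL, d_min=2.5, n_frames=2, background_sd=0.0, seed=3)
        frames, _, _ = simulate_dataset(cfg)
        m, _ = merge_observations(frames, d_min=2.5)
        assert np.all(m.sigma > 0)

    def test_noiseless_merge_recovers_truth(self):
        cfg = SimConfig(cell=SMALL, d_min=2.5, n_frames=10, background_sd=0.0, seed=6)
        frames, truth, fts = simulate_dataset(cfg)
        for f, ft in zip(frames, fts):
            f.g, f.b, f.orientation, f.cell = ft.g, ft.b, ft.orientation, ft.cell
        merged, _ = merge_observations(frames, d_min=2.5)
        tmap = truth.as_dict()
        for h, i in zip(merged.hkl.tolist(), merged.intensity):
            assert i == pytest.approx(tmap[tuple(h)], rel=1e-9)

    def test_lower_isigma_cut_never_decreases_completeness(self, standard_dataset):
        frames, _, _ = standard_dataset
        sub = frames[:30]
        _, loose = merge_observations(sub, isigma_min=-3.0, d_min=2.5)
        _, tight = merge_observations(sub, isigma_min=0.5, d_min=2.5)
        assert loose.completeness >= tight.completeness

    def test_merged_sigma_bounded_by_smallest_observation_sigma(self, standard_dataset):
        frames, _, _ = standard_dataset
        groups, _ = group_observations(frames[:10], -3.0)
        merged, _ = merge_observations(frames[:10], d_min=2.5)
        gm = {tuple(h): s for h, s in zip(merged.hkl.tolist(), merged.sigma)}
        for rep, vals in groups.items():
            assert gm[rep] <= min(v[1] for v in vals) + 1e-12


class TestCCHalf:
    def test_duplicated_observations_give_unity(self):
        rng = np.random.default_rng(1)
        groups = {}
        for k in range(50):
            i = float(rng.exponential(100))
            groups[(1, k + 1, 2)] = [(i, 1.0), (i, 1.0)]
        merged = _merged_from_groups(groups)
        overall, _ = cc_half(groups, merged, seed=0)
        assert overall == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_gives_zero(self):
        rng = np.random.default_rng(2)
        groups = {}
        n = 2000
        for k in range(n):
            groups[(1, k + 1, 2)] = [(float(rng.normal()), 1.0) for _ in range(4)]
        merged = _merged_from_groups(groups, d_min=2.5)
        overall, _ = cc_half(groups, merged, seed=0)
        assert abs(overall) < 3.0 / math.sqrt(n)

    def test_decreases_with_added_noise(self):
        rng = np.random.default_rng(3)
        base = {(1, k + 1, 2): float(rng.exponential(100)) for k in range(800)}
        ccs = []
        for sd_frac in (0.0, 0.5, 2.0):
            groups = {
                h: [(v + float(rng.normal(0, sd_frac * 100)), 1.0) for _ in range(4)]
                for h, v in base.items()
            }
            merged = _merged_from_groups(groups)
            ccs.append(cc_half(groups, merged, seed=0)[0])
        assert ccs[0] > ccs[1] > ccs[2]

    def test_split_seed_stability(self):
        """Two different half-split seeds move CC1/2 by < 2 points."""
        rng = np.random.default_rng(4)
        groups = {(1, k + 1, 2): [(float(rng.exponential(100) + rng.normal(0, 20)), 20.0)
                                  for _ in range(6)] for k in range(1500)}
        md = _merged_from_groups(groups)
        cc_a = cc_half(groups, md, seed=0)[0]
        cc_b = cc_half(groups, md, seed=1)[0]
        assert abs(cc_a - cc_b) < 0.02


class TestRMerge:
    def test_identical_replicates_zero(self):
        groups = {(1, 1, 1): [(50.0, 1.0)] * 4}
        assert r_merge_still(groups)[0] == 0.0

    def test_two_observation_arithmetic(self):
        groups = {(1, 1, 1): [(90.0, 1.0), (110.0, 1.0)]}
        assert r_merge_still(groups)[0] == pytest.approx(10.0)

    def test_matches_brute_force_on_random_observations(self):
        rng = np.random.default_rng(5)
        groups = {}
        for k in range(250):
            n = int(rng.integers(2, 7))
            groups[(1, k + 1, 2)] = [(float(rng.exponential(100)), 1.0) for _ in range(n)]
        got = r_merge_still(groups)[0]
        num = den = 0.0
        for vals in groups.values():
            ivals = [v[0] for v in vals]
            mean = sum(ivals) / len(ivals)
            num += sum(abs(i - mean) for i in ivals)
            den += sum(ivals)
        assert got == pytest.approx(100 * num / den, rel=1e-12)


class TestCompletenessMultiplicity:
    def test_full_unique_set_is_complete(self):
        unique = unique_reflections(SMALL, "P212121", 4.0)
        hkl = np.array(sorted(unique), dtype=int)
        merged = MergedDataset(hkl, np.ones(len(hkl)), np.ones(len(hkl)),
                               np.full(len(hkl), 3), SMALL, "P212121", 4.0)
        comp, mult = completeness_multiplicity(merged, unique)
        assert comp == 100.0 and mult == 3.0

    def test_brute_force_count_agreement(self):
        unique = unique_reflections(SMALL, "P212121", 4.0)
        subset = sorted(unique)[::2]
        hkl = np.array(subset, dtype=int)
        merged = MergedDataset(hkl, np.ones(len(hkl)), np.ones(len(hkl)),
                               np.ones(len(hkl), dtype=int), SMALL, "P212121", 4.0)
        comp, _ = completeness_multiplicity(merged, unique)
        assert comp == pytest.approx(100.0 * len(subset) / len(unique), rel=1e-12)

    def test_completeness_monotone_in_frames(self, standard_dataset):
        frames, _, _ = standard_dataset
        comp = []
        for n in (10, 30, 60):
            _, stats = merge_observations(frames[:n], d_min=2.5)
            comp.append(stats.completeness)
        assert comp[0] <= comp[1] <= comp[2]

    def test_empty_unique_set_rejected(self):
        merged = MergedDataset(np.array([[1, 1, 1]]), np.ones(1), np.ones(1),
                               np.ones(1, dtype=int), SMALL, "P212121", 4.0)
        with pytest.raises(ValueError):
            completeness_multiplicity(merged, set())


class TestResolutionCutoff:
    def test_all_shells_good_keeps_requested_limit(self):
        shells = equivolume_shells(math.inf, 2.0, 5)
        assert apply_resolution_cutoff([0.9] * 5, shells) == pytest.approx(2.0)

    def test_constructed_profile_cuts_after_third_shell(self):
        shells = equivolume_shells(math.inf, 2.0, 5)
        d = apply_resolution_cutoff([0.9, 0.8, 0.3, 0.2, 0.1], shells)
        assert d == pytest.approx(shells.d_limits(2)[1])

    def test_unusable_first_shell_is_an_error(self):
        shells = equivolume_shells(math.inf, 2.0, 5)
        with pytest.raises(ValueError):
            apply_resolution_cutoff([0.1, 0.05, 0.0, 0.0, 0.0], shells)

    def test_noise_coarsens_the_cutoff(self):
        """Resolution-dependent noise pushes the CC1/2 cutoff to coarser d."""
        rng = np.random.default_rng(9)
        shells = equivolume_shells(math.inf, 2.0, 8)
        centers = 0.5 * (shells.boundaries[:-1] + shells.boundaries[1:])

        def run(noise_scale):
            ccs = []
            for s in centers:
                truth = rng.exponential(100, 400)
                sd = noise_scale * 60 * (s / centers[-1]) ** 2
                h1 = truth + rng.normal(0, sd, 400)
                h2 = truth + rng.normal(0, sd, 400)
                ccs.append(float(np.corrcoef(h1, h2)[0, 1]))
            return apply_resolution_cutoff(ccs, shells)

        assert run(8.0) >= run(0.0)


class TestMergeStatsOracle:
    def test_all_statistics_match_naive_reimplementation(self):
        """Grouped fixture of ~500 observations: completeness, multiplicity,
        R_merge and CC1/2 all reproduce an independent naive recomputation."""
        cfg = SimConfig(cell=SMALL, d_min=3.5, n_frames=6, background_sd=60.0, seed=12)
        frames, _, fts = simulate_dataset(cfg)
        for f, ft in zip(frames, fts):
            f.g, f.b, f.orientation, f.cell = ft.g, ft.b, ft.orientation, ft.cell
        groups, n_obs = group_observations(frames, -3.0)
        assert 300 <= n_obs <= 1200
        shells = equivolume_shells(math.inf, 3.5, 4)
        merged, stats = merge_observations(frames, -3.0, shells, d_min=3.5, split_seed=7)

        # naive re-merge
        for h, i, sg, mu in zip(merged.hkl.tolist(), merged.intensity, merged.sigma,
                                merged.multiplicity):
            vals = groups[tuple(h)]
            w = np.array([1 / v[1] ** 2 for v in vals])
            iv = np.array([v[0] for v in vals])
            assert i == pytest.approx(float(np.sum(w * iv) / np.sum(w)), rel=1e-12)
            assert sg == pytest.approx(float(1 / np.sqrt(np.sum(w))), rel=1e-12)
            assert mu == len(vals)

        # naive completeness / multiplicity (same reference cell convention:
        # per-parameter median of the frames' cells)
        median_cell = UnitCell(*np.median([f.cell.parameters() for f in frames], axis=0))
        unique = unique_reflections(median_cell, "P212121", 3.5)
        present = {tuple(h) for h in merged.hkl.tolist()} & unique
        assert stats.completeness == pytest.approx(100 * len(present) / len(unique), rel=1e-12)
        assert stats.multiplicity == pytest.approx(float(np.mean(merged.multiplicity)), rel=1e-12)

        # naive R_merge
        num = den = 0.0
        for vals in groups.values():
            if len(vals) < 2:
                continue
            iv = [v[0] for v in vals]
            num += sum(abs(x - np.mean(iv)) for x in iv)
            den += sum(iv)
        assert stats.r_merge == pytest.approx(100 * num / den, rel=1e-9)

        # naive CC1/2 with the same seeded split protocol
        rng = np.random.default_rng(7)
        h1, h2 = [], []
        for rep in sorted(groups):
            vals = groups[rep]
            if len(vals) < 2:
                continue
            idx = rng.permutation(len(vals))
            cut = len(vals) // 2
            h1.append(np.mean([vals[i][0] for i in idx[:cut]]))
            h2.append(np.mean([vals[i][0] for i in idx[cut:]]))
        assert stats.cc_half == pytest.approx(float(np.corrcoef(h1, h2)[0, 1]), rel=1e-9)
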