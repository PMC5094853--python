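"""Merging of corrected still observations and data-quality statistics.

Still data are merged per symmetry-unique Miller index by inverse-variance
weighting of partiality-corrected intensities.  Quality is summarised with
the statistics conventional for serial crystallography: completeness and
multiplicity against the absence-filtered unique set, the half-dataset
correlation CC1/2, the still R_merge, and mean I/σ — overall and in
equal-reciprocal-volume resolution shells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cells import UnitCell
from .geometry import Frame, asu_indices, unique_reflections
from .partiality import observation_model

__all__ = [
    "ResolutionShells",
    "MergedDataset",
    "MergeStats",
    "equivolume_shells",
    "merge_observations",
    "group_observations",
    "cc_half",
    "r_merge_still",
    "completeness_multiplicity",
    "apply_resolution_cutoff",
]


@dataclass
class ResolutionShells:
    """Equal-reciprocal-volume resolution shells.

    Boundaries are stored as d* = 1/d values, ascending; shell k covers
    d* in [boundaries[k], boundaries[k+1]).
    """

    d_max: float
    d_min: float
    boundaries: np.ndarray  # d* values, length n_shells + 1

    @property
    def n_shells(self) -> int:
        return len(self.boundaries) - 1

    def assign(self, s: np.ndarray) -> np.ndarray:
        """Shell index for each d* value; −1 when outside the range."""
        idx = np.searchsorted(self.boundaries, s, side="right") - 1
        idx[(s < self.boundaries[0]) | (s > self.boundaries[-1] + 1e-12)] = -1
        return np.clip(idx, -1, self.n_shells - 1)

    def d_limits(self, k: int) -> tuple[float, float]:
        """(d_low, d_high) bounds of shell k in Å (d_low is the coarser)."""
        lo = self.boundaries[k]
        hi = self.boundaries[k + 1]
        return (math.inf if lo == 0 else 1.0 / lo, 1.0 / hi)


def equivolume_shells(d_max: float, d_min: float, n: int = 20) -> ResolutionShells:
    """Partition (d_min, d_max) into n shells of equal reciprocal volume:
    boundaries equally spaced in d*³.  ``d_max = inf`` starts at d* = 0."""
    if n < 2:
        raise ValueError("need at least 2 shells")
    if not (d_min > 0 and d_max > d_min):
        raise ValueError("require d_max > d_min > 0")
    smax3 = (1.0 / d_min) ** 3
    smin3 = 0.0 if math.isinf(d_max) else (1.0 / d_max) ** 3
    bounds = (smin3 + (smax3 - smin3) * np.arange(n + 1) / n) ** (1.0 / 3.0)
    return ResolutionShells(d_max, d_min, bounds)


@dataclass
class MergedDataset:
    """Merged unique intensities: parallel arrays indexed by unique hkl."""

    hkl: np.ndarray  # (M, 3) int unique representatives
    intensity: np.ndarray
    sigma: np.ndarray
    multiplicity: np.ndarray
    cell: UnitCell
    spacegroup: str = "P212121"
    d_min: float = 0.0

    def as_dict(self) -> dict[tuple[int, int, int], float]:
        return {tuple(h): float(i) for h, i in zip(self.hkl.tolist(), self.intensity)}

    def s_values(self) -> np.ndarray:
        from .geometry import reciprocal_basis

        return np.linalg.norm(self.hkl @ reciprocal_basis(self.cell).T, axis=1)


@dataclass
class MergeStats:
    completeness: float  # %
    multiplicity: float
    cc_half: float
    r_merge: float  # %
    i_over_sigma: float
    n_unique: int
    n_obs: int
    shells: ResolutionShells | None = None
    per_shell: list[dict] = field(default_factory=list)


def group_observations(
    frames: list[Frame],
    isigma_min: float = -3.0,
    spacegroup: str = "P212121",
) -> tuple[dict[tuple[int, int, int], list[tuple[float, float]]], int]:
    """Collect corrected observations per unique index.

    Applies each frame's current (G, B, γ, orientation, cell) model, the
    I/σ(I) ≥ isigma_min selection (the negative-intensity policy: the
    default −3.0 keeps moderately negative measurements), and the
    partiality floor.  Returns {unique hkl: [(I_corr, σ_corr), ...]} and
    the surviving observation count.
    """
    groups: dict[tuple[int, int, int], list[tuple[float, float]]] = {}
    n_obs = 0
    for frame in frames:
        if not frame.observations:
            continue
        m = observation_model(frame, predict=False)
        keep = m.usable & (m.i_raw / m.sigma_raw >= isigma_min)
        reps = asu_indices(m.hkl[keep], spacegroup)
        for rep, i, sig in zip(
            map(tuple, reps.tolist()), m.i_corr[keep], m.sigma_corr[keep]
        ):
            groups.setdefault(rep, []).append((float(i), float(sig)))
            n_obs += 1
    return groups, n_obs


def merge_observations(
    frames: list[Frame],
    isigma_min: float = -3.0,
    shells: ResolutionShells | None = None,
    spacegroup: str = "P212121",
    d_min: float | None = None,
    split_seed: int = 0,
    cell: UnitCell | None = None,
) -> tuple[MergedDataset, MergeStats]:
    """Merge frames into a unique dataset and compute its statistics.

    Merged I is the inverse-variance weighted mean of the corrected
    observations of each unique index; merged σ = sqrt(1/Σw).
    ``cell`` is the reference cell used for the unique set and shell
    assignment; it defaults to the per-parameter median of the frames'
    cells (individual frames carry slightly different refined cells, and
    picking one of them would bias the resolution boundary).
    """
    if not frames:
        raise ValueError("no frames to merge")
    if cell is None:
        params = np.median([f.cell.parameters() for f in frames], axis=0)
        cell = UnitCell(*params)
    groups, n_obs = group_observations(frames, isigma_min, spacegroup)
    if not groups:
        raise ValueError("no observations survive the selection")
    hkl = np.array(sorted(groups), dtype=int)
    merged_i = np.empty(len(hkl))
    merged_sig = np.empty(len(hkl))
    mult = np.empty(len(hkl), dtype=int)
    for j, rep in enumerate(map(tuple, hkl.tolist())):
        vals = np.array(groups[rep])
        w = 1.0 / vals[:, 1] ** 2
        merged_i[j] = np.sum(w * vals[:, 0]) / np.sum(w)
        merged_sig[j] = 1.0 / np.sqrt(np.sum(w))
        mult[j] = len(vals)
    if d_min is None:
        from .geometry import reciprocal_basis

        s = np.linalg.norm(hkl @ reciprocal_basis(cell).T, axis=1)
        d_min = float(1.0 / s.max())
    merged = MergedDataset(hkl, merged_i, merged_sig, mult, cell, spacegroup, d_min)
    if shells is None:
        shells = equivolume_shells(math.inf, d_min, 10)
    stats = compute_merge_stats(merged, groups, shells, split_seed=split_seed)
    return merged, stats


def compute_merge_stats(
    merged: MergedDataset,
    groups: dict[tuple[int, int, int], list[tuple[float, float]]],
    shells: ResolutionShells,
    split_seed: int = 0,
) -> MergeStats:
    s = merged.s_values()
    shell_idx = shells.assign(s)
    unique = unique_reflections(merged.cell, merged.spacegroup, merged.d_min)
    uniq_hkl = np.array(sorted(unique), dtype=int)
    from .geometry import reciprocal_basis

    s_uniq = np.linalg.norm(uniq_hkl @ reciprocal_basis(merged.cell).T, axis=1)
    uniq_shell = shells.assign(s_uniq)
    present = {tuple(h) for h in merged.hkl.tolist()}

    cc_all, cc_shell = cc_half(groups, merged, shells, seed=split_seed)
    rm_all, rm_shell = r_merge_still(groups, merged, shells)

    per_shell = []
    for k in range(shells.n_shells):
        in_shell = shell_idx == k
        n_uniq_k = int(np.sum(uniq_shell == k))
        pres_k = int(
            sum(1 for h, sk in zip(map(tuple, uniq_hkl.tolist()), uniq_shell) if sk == k and h in present)
        )
        d_lo, d_hi = shells.d_limits(k)
        per_shell.append(
            {
                "shell": k,
                "d_low": d_lo,
                "d_high": d_hi,
                "completeness": 100.0 * pres_k / n_uniq_k if n_uniq_k else math.nan,
                "multiplicity": float(np.mean(merged.multiplicity[in_shell])) if in_shell.any() else math.nan,
                "cc_half": cc_shell[k],
                "r_merge": rm_shell[k],
                "i_over_sigma": float(np.mean(merged.intensity[in_shell] / merged.sigma[in_shell]))
                if in_shell.any()
                else math.nan,
                "n_unique": n_uniq_k,
            }
        )
    completeness = 100.0 * len(present & unique) / len(unique)
    return MergeStats(
        completeness=completeness,
        multiplicity=float(np.mean(merged.multiplicity)),
        cc_half=cc_all,
        r_merge=rm_all,
        i_over_sigma=float(np.mean(merged.intensity / merged.sigma)),
        n_unique=len(merged.hkl),
        n_obs=int(np.sum(merged.multiplicity)),
        shells=shells,
        per_shell=per_shell,
    )


def cc_half(
    groups: dict[tuple[int, int, int], list[tuple[float, float]]],
    merged: MergedDataset,
    shells: ResolutionShells | None = None,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Half-dataset correlation CC1/2 by random splitting.

    The observations of every index with multiplicity ≥ 2 are split
    randomly (seeded) into two halves; CC1/2 is the Pearson correlation of
    the two half-merged intensity sets.  Returns (overall, per-shell);
    shells lacking enough multiplicity-≥2 indices report NaN.
    """
    rng = np.random.default_rng(seed)
    reps, half1, half2 = [], [], []
    for rep in sorted(groups):
        vals = groups[rep]
        if len(vals) < 2:
            continue
        idx = rng.permutation(len(vals))
        cut = len(vals) // 2
        a = [vals[i][0] for i in idx[:cut]]
        b = [vals[i][0] for i in idx[cut:]]
        reps.append(rep)
        half1.append(float(np.mean(a)))
        half2.append(float(np.mean(b)))
    half1 = np.array(half1)
    half2 = np.array(half2)

    def _cc(x, y):
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return math.nan
        return float(np.corrcoef(x, y)[0, 1])

    overall = _cc(half1, half2)
    per_shell: list[float] = []
    if shells is not None and reps:
        from .geometry import reciprocal_basis

        s = np.linalg.norm(np.array(reps) @ reciprocal_basis(merged.cell).T, axis=1)
        ks = shells.assign(s)
        for k in range(shells.n_shells):
            m = ks == k
            per_shell.append(_cc(half1[m], half2[m]))
    elif shells is not None:
        per_shell = [math.nan] * shells.n_shells
    return overall, per_shell


def r_merge_still(
    groups: dict[tuple[int, int, int], list[tuple[float, float]]],
    merged: MergedDataset | None = None,
    shells: ResolutionShells | None = None,
) -> tuple[float, list[float]]:
    """Still R_merge (%) = Σ_h Σ_i |I_i − ⟨I⟩_h| / Σ_h Σ_i I_i over indices
    with multiplicity ≥ 2; also per shell when shells are given."""
    reps = [r for r in sorted(groups) if len(groups[r]) >= 2]
    if not reps:
        raise ValueError("R_merge needs multiplicity >= 2 somewhere")
    num = np.empty(len(reps))
    den = np.empty(len(reps))
    for j, rep in enumerate(reps):
        ivals = np.array([v[0] for v in groups[rep]])
        num[j] = np.sum(np.abs(ivals - ivals.mean()))
        den[j] = np.sum(ivals)
    if den.sum() <= 0:
        raise ValueError("R_merge denominator is not positive")
    overall = 100.0 * num.sum() / den.sum()
    per_shell: list[float] = []
    if shells is not None and merged is not None:
        from .geometry import reciprocal_basis

        s = np.linalg.norm(np.array(reps) @ reciprocal_basis(merged.cell).T, axis=1)
        ks = shells.assign(s)
        for k in range(shells.n_shells):
            m = ks == k
            d = den[m].sum()
            per_shell.append(100.0 * num[m].sum() / d if m.any() and d > 0 else math.nan)
    return overall, per_shell


def completeness_multiplicity(
    merged: MergedDataset, unique: set[tuple[int, int, int]]
) -> tuple[float, float]:
    """Overall completeness (%) against a unique set and mean multiplicity."""
    if not unique:
        raise ValueError("empty unique reflection set")
    present = {tuple(h) for h in merged.hkl.tolist()}
    comp = 100.0 * len(present & unique) / len(unique)
    return comp, float(np.mean(merged.multiplicity))


def apply_resolution_cutoff(
    shell_cc: list[float], shells: ResolutionShells, threshold: float = 0.25
) -> float:
    """Resolution cutoff rule: d_min = inner boundary of the last shell
    (counting from low resolution) whose CC1/2 is still ≥ threshold; shells
    beyond the first failure are discarded."""
    last_good = -1
    for k, cc in enumerate(shell_cc):
        if not math.isnan(cc) and cc >= threshold:
            last_good = k
        else:
            break
    if last_good < 0:
        raise ValueError("first resolution shell already below the CC1/2 threshold")
    return shells.d_limits(last_good)[1]
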