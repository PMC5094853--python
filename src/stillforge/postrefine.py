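"""Per-frame post-refinement against an evolving merged reference.

Each still frame carries a model (linear scale G, temperature factor B,
reflecting-range parameters γ0/γe, orientation, unit cell) that determines
every observation's partiality and hence its full-intensity estimate.
Post-refinement minimises, per frame, the intensity target

    T_pr = (1/N) · Σ [ (I_ref − I_full_scaled) / σ_scaled ]²

against the current merged reference, with the spot-position target
T_xy = (1/N)·Σ‖x_obs − x_pred‖² (mm²) added as a weighted penalty when
geometric parameters move.  Refinement is staged — (G, B), then (γ0, γe),
then two orientation angles perpendicular to the beam, then the
symmetry-constrained cell edges — using bounded Nelder–Mead; a stage's
result is accepted only if it lowered the target.  After every cycle the
reference is rebuilt by re-merging all accepted frames, and frames whose
cell edges or ln G deviate more than 3 robust standard deviations from the
dataset medians are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .cells import UnitCell
from .geometry import Frame, Orientation, asu_indices, reciprocal_matrix, predict_positions
from .merging import MergedDataset, MergeStats, ResolutionShells, equivolume_shells, merge_observations
from .partiality import (
    P_FLOOR,
    PartialityParams,
    correct_intensities,
    partiality_fraction,
    reflecting_range,
)
from .scaling import ScatteringTable, pseudo_wilson_scale, wilson_plot

__all__ = [
    "PartialityParams",
    "reflecting_range",
    "partiality_fraction",
    "correct_observation",
    "RefinementResult",
    "PostRefinementConfig",
    "refine_frame",
    "reject_frames",
    "run_postrefinement",
]

# Parameter bounds enforced during refinement.
BOUNDS = {
    "g": (1e-3, 1e3),
    "b": (-10.0, 300.0),
    "gamma0": (1e-5, 0.01),
    "gamma_e": (0.0, 0.1),
    "rot_deg": 0.5,  # ± window for the two beam-perpendicular rotations
    "cell_frac": 0.02,  # ± fractional window for cell edges
}
MAX_EVALS_PER_STAGE = 200
MIN_MATCHED_OBSERVATIONS = 20


def correct_observation(obs, frame: Frame) -> tuple[float, float]:
    """Partiality-and-scale correction of a single observation under the
    frame's current model: (I_full_scaled, σ_scaled).  Negative intensities
    pass through with sign preserved; I/σ is invariant."""
    a_matrix = reciprocal_matrix(frame.cell, frame.orientation)
    h = np.asarray(obs.hkl, dtype=float)
    q = a_matrix @ h
    s = float(np.linalg.norm(q))
    delta = float(np.linalg.norm(q + frame.beam.s0) - 1.0 / frame.beam.wavelength)
    p = partiality_fraction(delta, reflecting_range(PartialityParams(frame.gamma0, frame.gamma_e), s))
    i, sig = correct_intensities(
        np.array([obs.i_raw]), np.array([obs.sigma_raw]), np.array([p]), frame.g, frame.b, np.array([s])
    )
    return float(i[0]), float(sig[0])


@dataclass
class RefinementResult:
    frame_id: str
    g: float
    b: float
    gamma0: float
    gamma_e: float
    orientation: Orientation
    cell: UnitCell
    t_pr_initial: float
    t_pr: float
    t_xy: float
    converged: bool
    n_matched: int
    n_rejected_obs: int
    flagged: bool = False
    message: str = ""


@dataclass
class PostRefinementConfig:
    """Controls for the iterative engine."""

    cycles: int = 10
    isigma_min: float = -3.0  # reflections used in refinement and merging
    d_min: float = 3.5
    n_shells: int = 10
    txy_weight: float = 10.0  # weight of T_xy in stages 3-4 (per mm²)
    spacegroup: str = "P212121"
    refine_geometry: bool = True  # stages 3-4 (orientation + cell)
    split_seed: int = 0  # CC1/2 half-split seed
    wilson_denominator: str = "f2"


class _FrameWorkspace:
    """Cached per-frame arrays for fast target evaluation."""

    def __init__(self, frame: Frame, reference: dict, config: PostRefinementConfig):
        self.frame = frame
        self.beam = frame.beam
        hkl = frame.hkl_array()
        reps = asu_indices(hkl, config.spacegroup)
        iref = np.array([reference.get(tuple(r), np.nan) for r in reps.tolist()])
        i_raw, sigma_raw = frame.intensity_arrays()
        matched = ~np.isnan(iref)
        matched &= (i_raw / sigma_raw) >= config.isigma_min
        self.hkl = hkl[matched].astype(float)
        self.iref = iref[matched]
        self.i_raw = i_raw[matched]
        self.sigma_raw = sigma_raw[matched]
        self.xy_obs = frame.position_array()[matched]
        self.n = int(np.sum(matched))
        self.config = config

    def targets(
        self,
        g: float,
        b: float,
        gamma0: float,
        gamma_e: float,
        a_matrix: np.ndarray,
    ) -> tuple[float, float]:
        q = self.hkl @ a_matrix.T
        s = np.linalg.norm(q, axis=1)
        delta = np.linalg.norm(q + self.beam.s0, axis=1) - 1.0 / self.beam.wavelength
        p = partiality_fraction(delta, reflecting_range(PartialityParams(gamma0, gamma_e), s))
        i_c, sig_c = correct_intensities(self.i_raw, self.sigma_raw, p, g, b, s)
        t_pr = float(np.mean(((self.iref - i_c) / sig_c) ** 2))
        rel = q + self.beam.s0
        nrm = np.linalg.norm(rel, axis=1, keepdims=True)
        s1 = rel / nrm / self.beam.wavelength
        scale = self.frame.detector.distance / s1[:, 2]
        xy = np.stack(
            [s1[:, 0] * scale + self.beam.center[0], s1[:, 1] * scale + self.beam.center[1]],
            axis=1,
        )
        t_xy = float(np.mean(np.sum((self.xy_obs - xy) ** 2, axis=1)))
        return t_pr, t_xy


def _minimize_stage(fun, x0, bounds, maxfev: int = MAX_EVALS_PER_STAGE) -> tuple[np.ndarray, float]:
    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxfev": maxfev, "xatol": 1e-8, "fatol": 1e-10},
    )
    return res.x, float(res.fun)


def refine_frame(
    frame: Frame,
    reference: dict | MergedDataset,
    config: PostRefinementConfig | None = None,
) -> RefinementResult:
    """Refine one frame's model against a merged reference (in place).

    Stage order: (G, B) → (γ0, γe) → orientation (two rotations
    perpendicular to the beam) → cell edges.  Every stage is accepted only
    if the target decreased, so the final T_pr never exceeds the initial.
    Frames with fewer than 20 matched reference reflections are flagged
    and left untouched.
    """
    config = config or PostRefinementConfig()
    if isinstance(reference, MergedDataset):
        reference = reference.as_dict()
    ws = _FrameWorkspace(frame, reference, config)
    base = RefinementResult(
        frame.id, frame.g, frame.b, frame.gamma0, frame.gamma_e,
        frame.orientation, frame.cell, math.nan, math.nan, math.nan,
        converged=False, n_matched=ws.n,
        n_rejected_obs=len(frame.observations) - ws.n,
    )
    if ws.n < MIN_MATCHED_OBSERVATIONS:
        base.flagged = True
        base.message = f"only {ws.n} matched observations"
        return base

    g, b = frame.g, frame.b
    gamma0, gamma_e = frame.gamma0, frame.gamma_e
    orientation, cell = frame.orientation, frame.cell
    a_matrix = reciprocal_matrix(cell, orientation)

    t_pr0, t_xy0 = ws.targets(g, b, gamma0, gamma_e, a_matrix)
    t_best = t_pr0

    # stage 1: G, B (log-scale G for conditioning)
    def f1(x):
        return ws.targets(math.exp(x[0]), x[1], gamma0, gamma_e, a_matrix)[0]

    x, t = _minimize_stage(
        f1,
        np.array([math.log(g), b]),
        [(math.log(BOUNDS["g"][0]), math.log(BOUNDS["g"][1])), BOUNDS["b"]],
    )
    if t < t_best:
        g, b, t_best = math.exp(x[0]), float(x[1]), t

    # stage 2: gamma0, gamma_e
    def f2(x):
        return ws.targets(g, b, x[0], x[1], a_matrix)[0]

    x, t = _minimize_stage(
        f2, np.array([gamma0, gamma_e]), [BOUNDS["gamma0"], BOUNDS["gamma_e"]]
    )
    if t < t_best:
        gamma0, gamma_e, t_best = float(x[0]), float(x[1]), t

    # joint polish of (G, B, γ0, γe): the scale and reflecting-range
    # parameters are strongly coupled through the partiality correction,
    # and alternating the two stages alone converges only slowly
    def f12(x):
        return ws.targets(math.exp(x[0]), x[1], x[2], x[3], a_matrix)[0]

    x, t = _minimize_stage(
        f12,
        np.array([math.log(g), b, gamma0, gamma_e]),
        [
            (math.log(BOUNDS["g"][0]), math.log(BOUNDS["g"][1])),
            BOUNDS["b"],
            BOUNDS["gamma0"],
            BOUNDS["gamma_e"],
        ],
        maxfev=3 * MAX_EVALS_PER_STAGE,
    )
    if t < t_best:
        g, b, gamma0, gamma_e = math.exp(x[0]), float(x[1]), float(x[2]), float(x[3])
        t_best = t

    if config.refine_geometry:
        w = config.txy_weight

        # stage 3: two rotations perpendicular to the beam
        u0 = orientation.matrix

        def f3(x):
            rot = Rotation.from_euler("xy", x, degrees=True).as_matrix()
            a_m = reciprocal_matrix(cell, Orientation(rot @ u0))
            t_pr, t_xy = ws.targets(g, b, gamma0, gamma_e, a_m)
            return t_pr + w * t_xy

        t_cur = f3([0.0, 0.0])
        lim = BOUNDS["rot_deg"]
        x, t = _minimize_stage(f3, np.array([0.0, 0.0]), [(-lim, lim), (-lim, lim)])
        if t < t_cur:
            rot = Rotation.from_euler("xy", x, degrees=True).as_matrix()
            orientation = Orientation(rot @ u0)
            a_matrix = reciprocal_matrix(cell, orientation)
            t_best = ws.targets(g, b, gamma0, gamma_e, a_matrix)[0]

        # stage 4: symmetry-constrained cell edges
        edges0 = np.array(cell.lengths)

        def f4(x):
            c = UnitCell(*(edges0 * x), *cell.angles)
            a_m = reciprocal_matrix(c, orientation)
            t_pr, t_xy = ws.targets(g, b, gamma0, gamma_e, a_m)
            return t_pr + w * t_xy

        t_cur = f4(np.ones(3))
        fr = BOUNDS["cell_frac"]
        x, t = _minimize_stage(f4, np.ones(3), [(1 - fr, 1 + fr)] * 3)
        if t < t_cur:
            cell = UnitCell(*(edges0 * x), *cell.angles)
            a_matrix = reciprocal_matrix(cell, orientation)
            t_best = ws.targets(g, b, gamma0, gamma_e, a_matrix)[0]

    t_pr_final, t_xy_final = ws.targets(g, b, gamma0, gamma_e, a_matrix)
    if t_pr_final > t_pr0:  # safety net: revert wholesale
        return replace(base, t_pr_initial=t_pr0, t_pr=t_pr0, t_xy=t_xy0, flagged=True,
                       message="refinement failed to reduce T_pr; reverted")
    frame.g, frame.b = g, b
    frame.gamma0, frame.gamma_e = gamma0, gamma_e
    frame.orientation, frame.cell = orientation, cell
    return RefinementResult(
        frame.id, g, b, gamma0, gamma_e, orientation, cell,
        t_pr0, t_pr_final, t_xy_final, converged=True, n_matched=ws.n,
        n_rejected_obs=len(frame.observations) - ws.n,
    )


def reject_frames(frames: list[Frame], results: list[RefinementResult] | None = None) -> list[bool]:
    """Keep/reject flags (True = keep) based on robust outlier tests.

    A frame is rejected when any refined cell edge deviates from the
    dataset median by more than 3 robust standard deviations
    (1.4826·MAD), or when |ln G − median ln G| exceeds the same bound.
    Needs at least 5 frames; deterministic.
    """
    n = len(frames)
    if n < 5:
        return [True] * n
    edges = np.array([f.cell.lengths for f in frames])
    ln_g = np.log(np.array([f.g for f in frames]))
    keep = np.ones(n, dtype=bool)
    for j in range(3):
        med = np.median(edges[:, j])
        sd = 1.4826 * np.median(np.abs(edges[:, j] - med))
        if sd > 0:
            keep &= np.abs(edges[:, j] - med) <= 3 * sd
        else:
            keep &= edges[:, j] == med
    med = np.median(ln_g)
    sd = 1.4826 * np.median(np.abs(ln_g - med))
    if sd > 0:
        keep &= np.abs(ln_g - med) <= 3 * sd
    else:
        keep &= ln_g == med
    if results is not None:
        for k, r in enumerate(results):
            if r is not None and r.flagged:
                keep[k] = False
    return keep.tolist()


def run_postrefinement(
    frames: list[Frame],
    table: ScatteringTable,
    config: PostRefinementConfig | None = None,
) -> tuple[MergedDataset, MergeStats, list[dict]]:
    """Iterative scaling / post-refinement / merging.

    Cycle 0 scales every frame by pseudo-Wilson fitting and merges the
    result into the initial reference.  Each subsequent cycle refines every
    frame against the current reference, rejects deviant frames and
    re-merges.  Returns the final merged dataset, its statistics, and a
    per-cycle history (CC1/2, overall Wilson B of the merged set, mean
    parameter shifts, frame counts).
    """
    config = config or PostRefinementConfig()
    if len(frames) < 2:
        raise ValueError("post-refinement needs at least 2 frames")
    shells = equivolume_shells(math.inf, config.d_min, config.n_shells)
    history: list[dict] = []

    active = list(frames)
    scaled: list[Frame] = []
    for frame in active:
        try:
            fit = pseudo_wilson_scale(frame, table, shells,
                                      denominator=config.wilson_denominator)
        except ValueError:
            continue
        frame.g, frame.b = fit.g0, max(fit.b0, BOUNDS["b"][0])
        scaled.append(frame)
    if len(scaled) < 2:
        raise ValueError("fewer than 2 scalable frames")
    active = scaled

    def _merge(frs):
        merged, stats = merge_observations(
            frs, isigma_min=config.isigma_min, shells=shells,
            spacegroup=config.spacegroup, d_min=config.d_min,
            split_seed=config.split_seed,
        )
        # re-anchor the reference to the ideal random-atom (Wilson) scale.
        # T_pr is exactly invariant under a common (scale, B-shift) applied
        # to every frame and the reference, so without an anchor both drift
        # freely from cycle to cycle; pinning the reference's Wilson
        # intercept to 1 and slope to 0 fixes the gauge the pseudo-Wilson
        # initial scaling defined.
        try:
            fit = wilson_plot(merged, table, shells,
                              denominator=config.wilson_denominator)
            if fit.g0 > 0:
                s2 = merged.s_values() ** 2
                corr = fit.g0 * np.exp(-fit.b0 * s2 / 2.0)
                merged.intensity /= corr
                merged.sigma /= corr
        except ValueError:
            pass
        return merged, stats

    merged, stats = _merge(active)

    def _overall_b(mgd):
        try:
            return wilson_plot(mgd, table, shells,
                               denominator=config.wilson_denominator).b0
        except ValueError:
            return math.nan

    history.append(
        {
            "cycle": 0,
            "n_frames": len(active),
            "cc_half": stats.cc_half,
            "r_merge": stats.r_merge,
            "completeness": stats.completeness,
            "overall_b": _overall_b(merged),
            "mean_t_pr": math.nan,
            "mean_t_xy": math.nan,
            "mean_shift_g": math.nan,
            "mean_shift_b": math.nan,
            "mean_shift_rot_deg": math.nan,
            "mean_shift_cell": math.nan,
        }
    )

    for cycle in range(1, config.cycles + 1):
        reference = merged.as_dict()
        results: list[RefinementResult] = []
        shifts = {"g": [], "b": [], "rot": [], "cell": []}
        for frame in active:
            g0, b0 = frame.g, frame.b
            u0 = frame.orientation.matrix
            c0 = np.array(frame.cell.lengths)
            res = refine_frame(frame, reference, config)
            results.append(res)
            if res.converged:
                shifts["g"].append(abs(frame.g - g0) / g0)
                shifts["b"].append(abs(frame.b - b0))
                cosang = (np.trace(u0.T @ frame.orientation.matrix) - 1.0) / 2.0
                shifts["rot"].append(math.degrees(math.acos(min(1.0, max(-1.0, cosang)))))
                shifts["cell"].append(float(np.max(np.abs(np.array(frame.cell.lengths) - c0))))
        keep = reject_frames(active, results)
        kept = [f for f, k in zip(active, keep) if k]
        if len(kept) >= 2:
            active = kept
        if not active:
            raise ValueError("all frames rejected")
        merged, stats = _merge(active)
        history.append(
            {
                "cycle": cycle,
                "n_frames": len(active),
                "cc_half": stats.cc_half,
                "r_merge": stats.r_merge,
                "completeness": stats.completeness,
                "overall_b": _overall_b(merged),
                "mean_t_pr": float(np.mean([r.t_pr for r in results if r.converged])) if any(r.converged for r in results) else math.nan,
                "mean_t_xy": float(np.mean([r.t_xy for r in results if r.converged])) if any(r.converged for r in results) else math.nan,
                "mean_shift_g": float(np.mean(shifts["g"])) if shifts["g"] else math.nan,
                "mean_shift_b": float(np.mean(shifts["b"])) if shifts["b"] else math.nan,
                "mean_shift_rot_deg": float(np.mean(shifts["rot"])) if shifts["rot"] else math.nan,
                "mean_shift_cell": float(np.mean(shifts["cell"])) if shifts["cell"] else math.nan,
            }
        )
    return merged, stats, history
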