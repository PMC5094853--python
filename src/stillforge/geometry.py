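"""Still-frame domain model and reciprocal-space geometry.

Lab convention (fixed throughout the package): the incident beam travels
along +z, the detector is a plane perpendicular to the beam at distance D
(mm), detector coordinates are physical mm with origin on the beam axis at
the detector centre, and the recorded beam centre is an (x, y) offset in mm.
Reciprocal-space vectors are in Å⁻¹.

On a still exposure each reciprocal lattice point sits a signed distance δ
(the Ewald offset) from the Ewald sphere; only points with small |δ| relative
to their reflecting range diffract, and then only partially.  This module
supplies the geometry those calculations need, plus the symmetry-aware index
bookkeeping for P1 and P2₁2₁2₁ — including the distinction between carrying
Miller indices through a change-of-basis operator exactly (robust) and
re-assigning them to the nearest node of the constrained lattice (fragile
when one cell axis is long and nodes crowd together).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .cells import UnitCell

__all__ = [
    "BeamModel",
    "DetectorModel",
    "Orientation",
    "Observation",
    "Frame",
    "cell_orthogonalization",
    "reciprocal_basis",
    "reciprocal_matrix",
    "ewald_offset",
    "ewald_offsets",
    "predict_position",
    "predict_positions",
    "unique_reflections",
    "asu_index",
    "asu_indices",
    "is_absent",
    "constrain_with_retained_indices",
    "nearest_node_reassign",
]

SUPPORTED_SPACEGROUPS = ("P1", "P212121")


@dataclass
class BeamModel:
    """Incident beam: wavelength (Å), unit direction (lab frame, default +z)
    and the recorded beam centre on the detector (mm)."""

    wavelength: float
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        d = np.asarray(self.direction, dtype=float)
        self.direction = tuple(d / np.linalg.norm(d))

    @property
    def s0(self) -> np.ndarray:
        """Incident wavevector s0 = direction / λ (Å⁻¹)."""
        return np.asarray(self.direction) / self.wavelength


@dataclass
class DetectorModel:
    """Flat detector perpendicular to the beam at distance D (mm)."""

    distance: float
    pixel_size: float = 0.1
    nx: int = 1024
    ny: int = 1024

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.pixel_size <= 0:
            raise ValueError("detector distance and pixel size must be positive")


class Orientation:
    """Proper rotation of the crystal, storable as three misset angles.

    The rotation matrix U satisfies UᵀU = I, det U = +1.  When constructed
    from misset angles (degrees, intrinsic x-y-z convention) the angles are
    retained so that serialization round-trips bit-exactly.
    """

    __slots__ = ("matrix", "_misset")

    def __init__(self, matrix: np.ndarray, misset: tuple[float, float, float] | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3):
            raise ValueError("orientation matrix must be 3x3")
        if not np.allclose(matrix @ matrix.T, np.eye(3), atol=1e-9) or np.linalg.det(matrix) < 0:
            raise ValueError("orientation must be a proper rotation")
        self.matrix = matrix
        self._misset = misset

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(np.eye(3), (0.0, 0.0, 0.0))

    @classmethod
    def from_misset(cls, phi1: float, phi2: float, phi3: float) -> "Orientation":
        m = Rotation.from_euler("xyz", [phi1, phi2, phi3], degrees=True).as_matrix()
        return cls(m, (float(phi1), float(phi2), float(phi3)))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "Orientation":
        return cls(Rotation.random(random_state=rng).as_matrix())

    def misset_angles(self) -> tuple[float, float, float]:
        if self._misset is not None:
            return self._misset
        ang = Rotation.from_matrix(self.matrix).as_euler("xyz", degrees=True)
        return (float(ang[0]), float(ang[1]), float(ang[2]))

    def rotated(self, rot: np.ndarray) -> "Orientation":
        return Orientation(rot @ self.matrix)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Orientation(misset={self.misset_angles()})"


@dataclass
class Observation:
    """One integrated Bragg spot on a still frame.

    ``s`` (= 2 sinθ/λ = 1/d), the Ewald offset ``delta`` and the partiality
    ``p`` are derived quantities, filled in from the current frame model by
    the processing code (None until computed).
    """

    hkl: tuple[int, int, int]
    i_raw: float
    sigma_raw: float
    x: float
    y: float
    s: float | None = None
    delta: float | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_raw <= 0:
            raise ValueError("sigma_raw must be positive")


@dataclass
class Frame:
    """One still exposure: metadata, the per-frame model parameters refined
    by post-refinement (G, B, γ0, γe, orientation, cell) and observations."""

    id: str
    beam: BeamModel
    detector: DetectorModel
    cell: UnitCell
    orientation: Orientation
    g: float = 1.0
    b: float = 0.0
    gamma0: float = 3e-4
    gamma_e: float = 3e-3
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("frame scale G must be positive")

    def hkl_array(self) -> np.ndarray:
        return np.array([o.hkl for o in self.observations], dtype=int).reshape(-1, 3)

    def intensity_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        i = np.array([o.i_raw for o in self.observations])
        s = np.array([o.sigma_raw for o in self.observations])
        return i, s

    def position_array(self) -> np.ndarray:
        return np.array([[o.x, o.y] for o in self.observations]).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Reciprocal-space geometry
# ---------------------------------------------------------------------------


def cell_orthogonalization(cell: UnitCell) -> np.ndarray:
    """Direct-space basis vectors as columns in a standard crystal frame:
    a along x, b in the x-y plane."""
    a, b, c = cell.lengths
    ca, cb, cg = np.cos(np.radians(cell.angles))
    sg = np.sin(np.radians(cell.gamma))
    v = cell.volume()
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, v / (a * b * sg)],
        ]
    )


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Reciprocal basis vectors a*, b*, c* as columns (crystal frame, Å⁻¹)."""
    return np.linalg.inv(cell_orthogonalization(cell)).T


def reciprocal_matrix(cell: UnitCell, orientation: Orientation) -> np.ndarray:
    """Lab-frame setting matrix A = U·B: A @ (h,k,l) is the reciprocal-space
    vector of reflection hkl.  |det A| = 1/V(cell)."""
    return orientation.matrix @ reciprocal_basis(cell)


def ewald_offsets(a_matrix: np.ndarray, hkl: np.ndarray, beam: BeamModel) -> np.ndarray:
    """Signed Ewald-sphere offsets δ (Å⁻¹) for an (N, 3) index array.

    The Ewald sphere has centre C = −s0 and radius 1/λ;
    δ = ‖A·hkl − C‖ − 1/λ, positive outside the sphere.
    """
    q = np.asarray(hkl, dtype=float) @ a_matrix.T
    center = -beam.s0
    return np.linalg.norm(q - center, axis=-1) - 1.0 / beam.wavelength


def ewald_offset(a_matrix: np.ndarray, hkl, beam: BeamModel) -> float:
    if not np.any(hkl):
        raise ValueError("Ewald offset undefined for (0,0,0)")
    return float(ewald_offsets(a_matrix, np.asarray(hkl)[None, :], beam)[0])


def predict_positions(
    a_matrix: np.ndarray, hkl: np.ndarray, beam: BeamModel, detector: DetectorModel
) -> np.ndarray:
    """Detector impact points (mm) for an (N, 3) index array.

    Each reciprocal vector q is projected radially onto the Ewald sphere
    (the still analogue of rotating it into diffracting condition); the
    diffracted ray s1 (|s1| = 1/λ) is then intersected with the detector
    plane at distance D and offset by the beam centre.
    """
    hkl = np.asarray(hkl, dtype=float)
    q = hkl @ a_matrix.T
    center = -beam.s0
    rel = q - center
    norm = np.linalg.norm(rel, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("cannot predict position for q at the Ewald centre")
    # s1 = s0 + q_proj with q_proj = C + (q-C)/|q-C|/λ and C = -s0, so
    # s1 is simply the unit vector along (q - C) scaled to the sphere radius.
    s1 = rel / norm / beam.wavelength  # |s1| = 1/λ
    sz = s1[..., 2]
    if np.any(sz <= 1e-12):
        raise ValueError("diffracted ray does not intersect the detector")
    scale = detector.distance / sz
    x = s1[..., 0] * scale + beam.center[0]
    y = s1[..., 1] * scale + beam.center[1]
    return np.stack([x, y], axis=-1)


def predict_position(a_matrix, hkl, beam, detector) -> tuple[float, float]:
    xy = predict_positions(a_matrix, np.asarray(hkl)[None, :], beam, detector)[0]
    return (float(xy[0]), float(xy[1]))


# ---------------------------------------------------------------------------
# Symmetry bookkeeping: P1 and P2(1)2(1)2(1)
# ---------------------------------------------------------------------------


def _check_spacegroup(spacegroup: str) -> str:
    sg = spacegroup.replace(" ", "")
    if sg not in SUPPORTED_SPACEGROUPS:
        raise ValueError(
            f"unsupported space group {spacegroup!r}; supported: {SUPPORTED_SPACEGROUPS}"
        )
    return sg


def is_absent(hkl, spacegroup: str = "P212121") -> bool:
    """Systematic absence test.  In P2₁2₁2₁ the three screw axes forbid
    odd-order axial reflections (h00 h odd, 0k0 k odd, 00l l odd)."""
    sg = _check_spacegroup(spacegroup)
    h, k, l = (int(v) for v in hkl)
    if sg == "P1":
        return False
    if k == 0 and l == 0:
        return h % 2 != 0
    if h == 0 and l == 0:
        return k % 2 != 0
    if h == 0 and k == 0:
        return l % 2 != 0
    return False


def asu_indices(hkl: np.ndarray, spacegroup: str = "P212121") -> np.ndarray:
    """Map an (N, 3) index array to symmetry-unique representatives.

    Friedel pairs are merged.  For P2₁2₁2₁ the Laue group is mmm, whose
    orbit of (h,k,l) is all sign combinations; the representative is
    (|h|,|k|,|l|).  For P1 (Laue -1) the representative is the
    lexicographically larger of (h,k,l) and (-h,-k,-l).
    """
    sg = _check_spacegroup(spacegroup)
    hkl = np.asarray(hkl, dtype=int)
    if sg == "P212121":
        return np.abs(hkl)
    flip = (hkl[:, 0] < 0) | (
        (hkl[:, 0] == 0) & ((hkl[:, 1] < 0) | ((hkl[:, 1] == 0) & (hkl[:, 2] < 0)))
    )
    out = hkl.copy()
    out[flip] *= -1
    return out


def asu_index(hkl, spacegroup: str = "P212121") -> tuple[int, int, int]:
    rep = asu_indices(np.asarray(hkl, dtype=int)[None, :], spacegroup)[0]
    return (int(rep[0]), int(rep[1]), int(rep[2]))


def all_reflections(cell: UnitCell, d_min: float) -> np.ndarray:
    """All nonzero integer triples with resolution d ≥ d_min (full sphere)."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    bstar = reciprocal_basis(cell)
    smax = 1.0 / d_min
    # conservative per-axis limits: |h_i| <= |a_i| * smax
    lengths = np.linalg.norm(np.linalg.inv(bstar.T), axis=0)  # direct axes lengths
    hmax = np.floor(smax * lengths).astype(int)
    grids = np.meshgrid(*(np.arange(-m, m + 1) for m in hmax), indexing="ij")
    hkl = np.stack([g.ravel() for g in grids], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = np.linalg.norm(hkl @ bstar.T, axis=1)
    return hkl[s <= smax + 1e-12]


def unique_reflections(
    cell: UnitCell, spacegroup: str = "P212121", d_min: float = 2.0
) -> set[tuple[int, int, int]]:
    """Symmetry-unique, absence-filtered reflection set to resolution d_min."""
    sg = _check_spacegroup(spacegroup)
    hkl = all_reflections(cell, d_min)
    reps = asu_indices(hkl, sg)
    uniq = set(map(tuple, reps.tolist()))
    return {h for h in uniq if not is_absent(h, sg)}


# ---------------------------------------------------------------------------
# Retained-index constraint vs. nearest-node re-assignment
# ---------------------------------------------------------------------------


def _cell_from_a_matrix(a_matrix: np.ndarray) -> tuple[UnitCell, Orientation]:
    """Split a lab setting matrix A into (cell, orientation)."""
    gstar = a_matrix.T @ a_matrix
    g = np.linalg.inv(gstar)
    cell = UnitCell.from_metric(g)
    u = a_matrix @ np.linalg.inv(reciprocal_basis(cell))
    # re-orthonormalize against rounding
    uu, _, vv = np.linalg.svd(u)
    return cell, Orientation(uu @ vv)


def constrain_with_retained_indices(frame: Frame, change_of_basis: np.ndarray) -> Frame:
    """Convert a frame to a constrained lattice setting by mapping every
    observation's Miller index exactly through the change-of-basis operator.

    ``change_of_basis`` is the integer matrix P with h_new = P @ h_old; no
    proximity-based re-assignment takes place, so index identities survive
    even when lattice nodes are closely spaced (long cell axes).  The cell
    and orientation are transformed consistently (A_new = A_old @ P⁻¹, so
    that A_new @ h_new = A_old @ h_old).
    """
    P = np.asarray(change_of_basis)
    if P.shape != (3, 3) or not np.allclose(P, np.round(P)):
        raise ValueError("change-of-basis operator must be an integer 3x3 matrix")
    P = np.round(P).astype(int)
    if round(abs(float(np.linalg.det(P)))) != 1:
        raise ValueError("change-of-basis operator must be unimodular (det ±1)")
    pinv = np.round(np.linalg.inv(P)).astype(int)
    a_old = reciprocal_matrix(frame.cell, frame.orientation)
    a_new = a_old @ pinv
    cell, orientation = _cell_from_a_matrix(a_new)
    new_obs = [
        replace(o, hkl=tuple(int(v) for v in (P @ np.asarray(o.hkl))))
        for o in frame.observations
    ]
    return replace(frame, cell=cell, orientation=orientation, observations=new_obs)


def nearest_node_reassign(frame: Frame) -> Frame:
    """Legacy behaviour: re-determine each observation's Miller index as the
    reciprocal lattice node nearest to its back-projected scattering vector.

    The scattering vector is reconstructed from the observed spot position
    (ray from the crystal through (x, y, D), normalized to the Ewald sphere)
    and converted to fractional indices with the frame's current lattice
    model; indices are rounded to the nearest integers.  With a long cell
    axis the node spacing along that axis can fall below the reconstruction
    error, corrupting indices — which is why the retained-index path exists.
    """
    if not frame.observations:
        return frame
    a_matrix = reciprocal_matrix(frame.cell, frame.orientation)
    a_inv = np.linalg.inv(a_matrix)
    xy = frame.position_array()
    bc = np.asarray(frame.beam.center)
    d = frame.detector.distance
    rays = np.column_stack([xy[:, 0] - bc[0], xy[:, 1] - bc[1], np.full(len(xy), d)])
    rays /= np.linalg.norm(rays, axis=1, keepdims=True)
    q_obs = rays / frame.beam.wavelength - frame.beam.s0
    frac = q_obs @ a_inv.T
    new_hkl = np.round(frac).astype(int)
    new_obs = [
        replace(o, hkl=(int(h[0]), int(h[1]), int(h[2])))
        for o, h in zip(frame.observations, new_hkl)
    ]
    return replace(frame, observations=new_obs)


def beam_s0(beam: BeamModel) -> np.ndarray:
    return beam.s0
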