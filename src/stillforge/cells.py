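"""Unit-cell algebra, Niggli reduction and crystal-form clustering.

Still-diffraction experiments on polymorphic crystals can mix two (or more)
lattices in one run — here, a "long" orthorhombic form and a related form with
a halved c axis.  Separating them requires a cell-to-cell distance that does
not depend on the arbitrary basis each indexing solution happened to pick, so
every cell is first brought to its Niggli-reduced canonical setting and the
distance is measured between reduced parameter vectors.  Single-linkage
hierarchical clustering on that distance then splits the forms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "UnitCell",
    "CellCluster",
    "niggli_reduce",
    "cell_distance",
    "cluster_cells",
    "read_cell_table",
    "write_cluster_report",
]

# Weight converting angle differences (degrees) to the Å scale of the edge
# differences when comparing reduced cells.
ANGLE_WEIGHT = 0.5


@dataclass(frozen=True)
class UnitCell:
    """Six lattice parameters: edge lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell edges must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180): {self}")
        if self.metric_tensor_determinant() <= 0:
            raise ValueError(f"degenerate cell (non-positive metric): {self}")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G with G_ij = a_i · a_j."""
        a, b, c = self.lengths
        ca, cb, cg = np.cos(np.radians(self.angles))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def metric_tensor_determinant(self) -> float:
        return float(np.linalg.det(self.metric_tensor()))

    def volume(self) -> float:
        """Cell volume in Å³ (sqrt of the metric determinant)."""
        return float(np.sqrt(max(self.metric_tensor_determinant(), 0.0)))

    def parameters(self) -> np.ndarray:
        return np.array([*self.lengths, *self.angles])

    @staticmethod
    def from_metric(g: np.ndarray) -> "UnitCell":
        a, b, c = np.sqrt(np.diag(g))
        alpha = np.degrees(np.arccos(np.clip(g[1, 2] / (b * c), -1, 1)))
        beta = np.degrees(np.arccos(np.clip(g[0, 2] / (a * c), -1, 1)))
        gamma = np.degrees(np.arccos(np.clip(g[0, 1] / (a * b), -1, 1)))
        return UnitCell(float(a), float(b), float(c), float(alpha), float(beta), float(gamma))


@dataclass
class CellCluster:
    """One cluster of unit cells: member indices into the input list, a
    per-parameter-median consensus cell, and a text label."""

    members: list[int]
    consensus: UnitCell
    label: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Niggli reduction (Krivy & Gruber algorithm on the metric tensor), tracking
# the integer change-of-basis matrix.  New basis vectors are columns of the
# old basis matrix times M: (a' b' c') = (a b c) · M, so G' = Mᵀ G M.
# ---------------------------------------------------------------------------


def _kg_state(cell: UnitCell) -> np.ndarray:
    g = cell.metric_tensor()
    return np.array(
        [g[0, 0], g[1, 1], g[2, 2], 2 * g[1, 2], 2 * g[0, 2], 2 * g[0, 1]]
    )


def niggli_reduce(cell: UnitCell, eps: float | None = None) -> tuple[UnitCell, np.ndarray]:
    """Return the Niggli-reduced cell and the integer change-of-basis matrix.

    The transform ``M`` (determinant ±1) maps the original basis to the
    reduced basis: metric_reduced = Mᵀ · metric_original · M.  Volume is
    preserved exactly; the reduced cell satisfies the Niggli main conditions
    a ≤ b ≤ c with the standard Krivy–Gruber angle conditions.
    """
    if eps is None:
        eps = 1e-5 * cell.volume() ** (2.0 / 3.0)
    A, B, C, xi, eta, zeta = _kg_state(cell)
    M = np.eye(3, dtype=int)

    def apply(T: np.ndarray) -> None:
        nonlocal A, B, C, xi, eta, zeta, M
        g = np.array(
            [
                [A, zeta / 2, eta / 2],
                [zeta / 2, B, xi / 2],
                [eta / 2, xi / 2, C],
            ]
        )
        g = T.T @ g @ T
        M = M @ T
        A, B, C = g[0, 0], g[1, 1], g[2, 2]
        xi, eta, zeta = 2 * g[1, 2], 2 * g[0, 2], 2 * g[0, 1]

    for _ in range(200):
        # A1: order A <= B
        if A > B + eps or (abs(A - B) <= eps and abs(xi) > abs(eta) + eps):
            apply(np.array([[0, -1, 0], [-1, 0, 0], [0, 0, -1]]))
        # A2: order B <= C
        if B > C + eps or (abs(B - C) <= eps and abs(eta) > abs(zeta) + eps):
            apply(np.array([[-1, 0, 0], [0, 0, -1], [0, -1, 0]]))
            continue
        # A3/A4: fix angle signs (all acute or all non-acute)
        if xi * eta * zeta > 0:
            i = -1 if xi < 0 else 1
            j = -1 if eta < 0 else 1
            k = -1 if zeta < 0 else 1
            apply(np.diag([i, j, k]))
        else:
            vals = [xi, eta, zeta]
            signs = [1 if v > eps else (-1 if v < -eps else 0) for v in vals]
            # choose ±1 per axis so that all three become <= 0
            i = -1 if signs[0] > 0 else 1
            j = -1 if signs[1] > 0 else 1
            k = -1 if signs[2] > 0 else 1
            if i * j * k < 0:
                # flip the sign attached to a zero component
                if signs[0] == 0:
                    i = -i
                elif signs[1] == 0:
                    j = -j
                else:
                    k = -k
            apply(np.diag([i, j, k]))
        # A5
        if abs(xi) > B + eps or (abs(xi - B) <= eps and 2 * eta < zeta - eps) or (
            abs(xi + B) <= eps and zeta < -eps
        ):
            s = 1 if xi > 0 else -1
            apply(np.array([[1, 0, 0], [0, 1, -s], [0, 0, 1]]))
            continue
        # A6
        if abs(eta) > A + eps or (abs(eta - A) <= eps and 2 * xi < zeta - eps) or (
            abs(eta + A) <= eps and zeta < -eps
        ):
            s = 1 if eta > 0 else -1
            apply(np.array([[1, 0, -s], [0, 1, 0], [0, 0, 1]]))
            continue
        # A7
        if abs(zeta) > A + eps or (abs(zeta - A) <= eps and 2 * xi < eta - eps) or (
            abs(zeta + A) <= eps and eta < -eps
        ):
            s = 1 if zeta > 0 else -1
            apply(np.array([[1, -s, 0], [0, 1, 0], [0, 0, 1]]))
            continue
        # A8
        if xi + eta + zeta + A + B < -eps or (
            abs(xi + eta + zeta + A + B) <= eps and 2 * (A + eta) + zeta > eps
        ):
            apply(np.array([[1, 0, 1], [0, 1, 1], [0, 0, 1]]))
            continue
        break
    else:  # pragma: no cover - safeguarded loop
        raise RuntimeError(f"Niggli reduction did not converge for {cell}")

    g = np.array(
        [[A, zeta / 2, eta / 2], [zeta / 2, B, xi / 2], [eta / 2, xi / 2, C]]
    )
    reduced = UnitCell.from_metric(g)
    if round(abs(float(np.linalg.det(M)))) != 1:
        raise RuntimeError("change-of-basis is not unimodular")
    return reduced, M


def _reduced_vector(cell: UnitCell) -> np.ndarray:
    """Weighted parameter vector of the Niggli-reduced cell used for
    distances.  Angles are folded to the [0°, 90°] equivalence class (the
    reduction leaves a ± ambiguity) and weighted by ANGLE_WEIGHT Å/degree."""
    red, _ = niggli_reduce(cell)
    ang = np.minimum(np.array(red.angles), 180.0 - np.array(red.angles))
    return np.concatenate([np.array(red.lengths), ANGLE_WEIGHT * ang])


def cell_distance(x: UnitCell, y: UnitCell) -> float:
    """Basis-independent distance between two unit cells (Å scale).

    Euclidean norm of (Δa, Δb, Δc, k·Δα, k·Δβ, k·Δγ) between Niggli-reduced
    parameter vectors, k = 0.5 Å/degree.  Symmetric; zero iff the reduced
    parameter vectors coincide.
    """
    return float(np.linalg.norm(_reduced_vector(x) - _reduced_vector(y)))


def cluster_cells(
    cells: list[UnitCell], cut_height: float = 5.0
) -> list[CellCluster]:
    """Single-linkage agglomerative clustering of unit cells.

    The dendrogram is cut at ``cut_height`` (Å); clusters come back ordered
    by size descending, each with a per-parameter median consensus cell
    (computed over the members' Niggli-reduced parameters).
    """
    if not cells:
        raise ValueError("cluster_cells requires at least one cell")
    vectors = np.array([_reduced_vector(c) for c in cells])
    if len(cells) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(vectors), method="single")
        labels = fcluster(z, t=cut_height, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = [int(i) for i in np.flatnonzero(labels == lab)]
        reduced = np.array(
            [niggli_reduce(cells[i])[0].parameters() for i in members]
        )
        med = np.median(reduced, axis=0)
        clusters.append(CellCluster(members, UnitCell(*med)))
    clusters.sort(key=lambda c: (-c.size, c.consensus.parameters().tolist()))
    for rank, cl in enumerate(clusters):
        cl.label = f"cluster{rank}"
    return clusters


def brute_force_reduce(cell: UnitCell, max_entry: int = 2) -> UnitCell:
    """Exhaustive reference reduction: search all integer change-of-basis
    matrices with |entries| ≤ max_entry and determinant ±1 for the basis
    minimizing a+b+c.  Exponential cost — testing oracle only."""
    g0 = cell.metric_tensor()
    best: UnitCell | None = None
    rng = range(-max_entry, max_entry + 1)
    cols = [
        np.array(v) for v in itertools.product(rng, rng, rng) if any(v)
    ]
    best_sum = np.inf
    for c1 in cols:
        for c2 in cols:
            for c3 in cols:
                T = np.column_stack([c1, c2, c3])
                if round(abs(float(np.linalg.det(T)))) != 1:
                    continue
                g = T.T @ g0 @ T
                s = float(np.sqrt(g[0, 0]) + np.sqrt(g[1, 1]) + np.sqrt(g[2, 2]))
                if s < best_sum - 1e-9:
                    best_sum = s
                    best = UnitCell.from_metric(g)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Text I/O: one cell per line "a b c alpha beta gamma [frame-id]"
# ---------------------------------------------------------------------------


def read_cell_table(path) -> tuple[list[UnitCell], list[str]]:
    cells: list[UnitCell] = []
    ids: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 cell parameters")
            try:
                params = [float(p) for p in parts[:6]]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric cell parameter") from exc
            cells.append(UnitCell(*params))
            ids.append(parts[6] if len(parts) > 6 else str(len(cells) - 1))
    return cells, ids


def write_cluster_report(clusters: list[CellCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tsize\ta\tb\tc\talpha\tbeta\tgamma\n")
        for cl in clusters:
            p = cl.consensus.parameters()
            fh.write(
                cl.label
                + f"\t{cl.size}\t"
                + "\t".join(f"{v:.4f}" for v in p)
                + "\n"
            )
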