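"""Triclinic periodic cells and minimum-image geometry.

Convention: lattice vectors are stored row-wise in a lower-triangular
3x3 matrix — the first vector lies along the laboratory x axis and the
second in the xy plane, as in common MD box encodings (GRO, TRR).
Lengths are nm throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from memtk.errors import DegenerateCellError

_HEX_ANGLE_TOL = 1e-9

# in-plane neighbor shifts used for 2D ghost replication
_NEIGHBOR_SHIFTS_2D = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)]


@dataclass(frozen=True)
class TriclinicCell:
    """Periodic simulation cell given by three row-wise lattice vectors (nm)."""

    vectors: np.ndarray = field()

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"cell vectors must be 3x3, got shape {v.shape}")
        if abs(v[0, 1]) > 1e-10 or abs(v[0, 2]) > 1e-10 or abs(v[1, 2]) > 1e-10:
            raise ValueError(
                "cell must be lower-triangular: first vector along x, second in xy plane"
            )
        if np.linalg.det(v) <= 0.0:
            raise DegenerateCellError(f"cell volume must be positive, got {np.linalg.det(v):g}")
        object.__setattr__(self, "vectors", v)

    # -- constructors -------------------------------------------------

    @classmethod
    def cubic(cls, length: float) -> "TriclinicCell":
        return cls(np.diag([length, length, length]).astype(float))

    @classmethod
    def rectangular(cls, lx: float, ly: float, lz: float) -> "TriclinicCell":
        return cls(np.diag([lx, ly, lz]).astype(float))

    @classmethod
    def hexagonal(cls, a: float, lz: float) -> "TriclinicCell":
        """Hexagonal prism: |v1| = |v2| = a with a 120 degree in-plane angle."""
        return cls(
            np.array(
                [
                    [a, 0.0, 0.0],
                    [-0.5 * a, 0.5 * np.sqrt(3.0) * a, 0.0],
                    [0.0, 0.0, lz],
                ]
            )
        )

    # -- basic properties ---------------------------------------------

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.vectors))

    @property
    def cross_area(self) -> float:
        """Area of the in-plane (xy) unit-cell parallelogram."""
        v = self.vectors
        return float(abs(v[0, 0] * v[1, 1] - v[0, 1] * v[1, 0]))

    @property
    def is_hexagonal(self) -> bool:
        v1, v2 = self.vectors[0], self.vectors[1]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if abs(n1 - n2) > _HEX_ANGLE_TOL * max(n1, n2):
            return False
        cosang = float(np.dot(v1, v2) / (n1 * n2))
        return abs(cosang + 0.5) <= _HEX_ANGLE_TOL

    # -- coordinate transforms ----------------------------------------

    def to_fractional(self, points: np.ndarray) -> np.ndarray:
        """Cartesian (nm) -> fractional coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ np.linalg.inv(self.vectors)

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.vectors

    def wrap(self, points: np.ndarray) -> np.ndarray:
        """Wrap points into the primary cell (fractional coordinates in [0, 1))."""
        frac = self.to_fractional(points)
        return self.to_cartesian(frac - np.floor(frac))

    # in-plane 2x2 lattice (rows v1_xy, v2_xy)
    @property
    def in_plane(self) -> np.ndarray:
        return self.vectors[:2, :2]


def minimum_image_displacement(p, q, cell: TriclinicCell) -> np.ndarray:
    """Displacement q - p shifted by the lattice translation of minimum norm.

    Accepts single 3-vectors or broadcastable (..., 3) arrays.  The
    fractional displacement is first wrapped to the central cell and the
    125 surrounding images (shifts of up to two cells per axis) are then
    searched, which is exact even for strongly skewed cells.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("coordinates must be finite")
    d = q - p
    single = d.ndim == 1
    d = np.atleast_2d(d)
    frac = d @ np.linalg.inv(cell.vectors)
    frac -= np.round(frac)
    shifts = np.array(list(itertools.product((-2.0, -1.0, 0.0, 1.0, 2.0), repeat=3)))
    # (n, 125, 3) candidate displacements
    cand = (frac[:, None, :] + shifts[None, :, :]) @ cell.vectors
    best = np.argmin(np.einsum("nkj,nkj->nk", cand, cand), axis=1)
    out = cand[np.arange(len(cand)), best]
    return out[0] if single else out


def minimum_image_distance(p, q, cell: TriclinicCell) -> np.ndarray:
    """Euclidean norm of the minimum-image displacement."""
    d = minimum_image_displacement(p, q, cell)
    return np.linalg.norm(d, axis=-1)


def replicate_ghosts_2d(
    points: np.ndarray, cell: TriclinicCell, margin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate in-plane points into the 8 neighboring lattice images.

    Parameters
    ----------
    points:
        (n, 2) or (n, 3) coordinates in the cell frame; only x and y are
        shifted, any z column is carried through unchanged.
    margin:
        Ghosts are retained when their fractional coordinates fall within
        a band of ``margin / |v_i|`` around the unit interval on each
        in-plane axis (inclusive).  ``margin >= max(|v1|, |v2|)`` keeps
        all 8 images.

    Returns
    -------
    (points_with_ghosts, parent_index):
        Originals first, ghosts appended; ``parent_index[i]`` is the row
        of the original point that ghost row ``i`` copies.
    """
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise ValueError("points must be (n, 2) or (n, 3)")
    n = len(pts)
    ip = cell.in_plane
    m1 = margin / np.linalg.norm(ip[0])
    m2 = margin / np.linalg.norm(ip[1])
    eps = 1e-12
    inv_ip = np.linalg.inv(ip)

    ghost_rows = []
    parents = []
    for i, j in _NEIGHBOR_SHIFTS_2D:
        shift_xy = i * ip[0] + j * ip[1]
        shifted = pts.copy()
        shifted[:, :2] += shift_xy
        frac = shifted[:, :2] @ inv_ip
        keep = (
            (frac[:, 0] >= -m1 - eps)
            & (frac[:, 0] <= 1.0 + m1 + eps)
            & (frac[:, 1] >= -m2 - eps)
            & (frac[:, 1] <= 1.0 + m2 + eps)
        )
        ghost_rows.append(shifted[keep])
        parents.append(np.nonzero(keep)[0])

    ghosts = np.concatenate(ghost_rows) if ghost_rows else pts[:0]
    parent_index = np.concatenate([np.arange(n)] + parents)
    return np.concatenate([pts, ghosts]), parent_index


def full_replication_2d(points: np.ndarray, cell: TriclinicCell) -> tuple[np.ndarray, np.ndarray]:
    """All 8 in-plane neighbor images retained (margin = infinity)."""
    ip = cell.in_plane
    margin = float(max(np.linalg.norm(ip[0]), np.linalg.norm(ip[1]))) * 2.0
    return replicate_ghosts_2d(points, cell, margin)
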