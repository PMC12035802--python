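"""Leaflet assignment robust to membrane curvature.

Lipids are grouped by connected components of a graph on their
phosphorus atoms with edges where the periodic distance is below a
cutoff; this follows the curved-leaflet grouping approach rather than a
z-threshold, so it stays correct when the two leaflets' z ranges
overlap around a deformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from memtk.core_model.cell import minimum_image_displacement
from memtk.core_model.model import Frame, LipidSelection
from memtk.errors import LeafletError

UPPER = "upper"
LOWER = "lower"

#: default P-P neighbour cutoff (nm); typical nearest-neighbour ceiling
DEFAULT_CUTOFF = 1.2


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels for one frame."""

    labels: np.ndarray  # dtype object, values "upper" / "lower"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def upper(self) -> np.ndarray:
        return np.nonzero(self.labels == UPPER)[0]

    @property
    def lower(self) -> np.ndarray:
        return np.nonzero(self.labels == LOWER)[0]

    def swapped(self) -> "LeafletAssignment":
        sw = np.where(self.labels == UPPER, LOWER, UPPER).astype(object)
        return LeafletAssignment(sw)


def _pairwise_periodic_distances(points: np.ndarray, cell) -> np.ndarray:
    n = len(points)
    ii, jj = np.triu_indices(n, k=1)
    d = minimum_image_displacement(points[ii], points[jj], cell)
    dist = np.zeros((n, n))
    dist[ii, jj] = dist[jj, ii] = np.linalg.norm(d, axis=1)
    return dist


def assign_leaflets(
    frame: Frame, selection: LipidSelection, cutoff: float = DEFAULT_CUTOFF
) -> LeafletAssignment:
    """Assign every lipid to the upper or lower leaflet.

    Builds the periodic P-P proximity graph at ``cutoff`` and reduces
    its connected components to two groups; if more than two components
    appear, the smallest are merged into the nearest component by
    periodic centroid distance (with a warning).  The group with the
    greater mean z is labelled upper.
    """
    if selection.n_lipids < 2:
        raise LeafletError("need at least 2 lipids to assign leaflets")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")

    pts = frame.positions[selection.phosphorus]
    dist = _pairwise_periodic_distances(pts, frame.cell)
    adj = csr_matrix((dist < cutoff) & (dist > 0))
    n_comp, comp = connected_components(adj, directed=False)

    if n_comp == 1:
        raise LeafletError(
            f"all lipids form one connected component at cutoff {cutoff} nm; "
            "use a smaller cutoff"
        )
    if n_comp > 2:
        warnings.warn(
            f"{n_comp} leaflet components at cutoff {cutoff} nm; merging smallest "
            "into nearest by centroid distance",
            stacklevel=2,
        )
        comp = _merge_to_two(pts, comp, frame.cell)

    mean_z = [pts[comp == g, 2].mean() for g in range(2)]
    upper_group = int(np.argmax(mean_z))
    labels = np.where(comp == upper_group, UPPER, LOWER).astype(object)
    return LeafletAssignment(labels)


def _merge_to_two(pts: np.ndarray, comp: np.ndarray, cell) -> np.ndarray:
    comp = comp.copy()
    while len(np.unique(comp)) > 2:
        groups = np.unique(comp)
        sizes = np.array([(comp == g).sum() for g in groups])
        small = groups[int(np.argmin(sizes))]
        c_small = pts[comp == small].mean(axis=0)
        best, best_d = None, np.inf
        for g in groups:
            if g == small:
                continue
            c_g = pts[comp == g].mean(axis=0)
            d = float(np.linalg.norm(minimum_image_displacement(c_small, c_g, cell)))
            if d < best_d:
                best, best_d = g, d
        comp[comp == small] = best
    # relabel to 0 / 1
    groups = np.unique(comp)
    out = np.zeros_like(comp)
    out[comp == groups[1]] = 1
    return out


def assign_leaflets_trajectory(
    frames,
    selection: LipidSelection,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "per-frame",
) -> list[LeafletAssignment]:
    """Assign leaflets for every frame.

    ``mode='per-frame'`` reassigns each frame independently and logs
    flip-flopping lipids; ``mode='first'`` computes the assignment once
    on the first frame and reuses it.
    """
    if mode not in ("per-frame", "first"):
        raise ValueError(f"mode must be 'per-frame' or 'first', got {mode!r}")
    frames = list(frames)
    if not frames:
        return []
    if mode == "first":
        first = assign_leaflets(frames[0], selection, cutoff)
        return [first] * len(frames)
    out = [assign_leaflets(fr, selection, cutoff) for fr in frames]
    flips = sum(
        int(np.any(a.labels != b.labels)) for a, b in zip(out[:-1], out[1:])
    )
    if flips:
        warnings.warn(f"leaflet labels changed between {flips} frame pairs", stacklevel=2)
    return out


def assignment_table(assignments, selection: LipidSelection):
    """Long-format table (frame, lipid resid, label) for CSV export."""
    import pandas as pd

    rows = [
        (k, int(selection.resids[i]), str(a.labels[i]))
        for k, a in enumerate(assignments)
        for i in range(selection.n_lipids)
    ]
    return pd.DataFrame(rows, columns=["frame", "lipid", "leaflet"])
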