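import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

from memtk.core_model.cell import TriclinicCell, full_replication_2d
from memtk.core_model.model import LipidSelection
from memtk.synthetic_data import make_flat_bilayer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["rectangular", "hexagonal"])
def cell_kind(request):
    return request.param


@pytest.fixture
def flat_bilayer():
    """Small exact flat bilayer (no jitter), hexagonal cell."""
    top, frames, gt = make_flat_bilayer(36, cell_kind="hexagonal", jitter=0.0, seed=7)
    sel = LipidSelection.from_topology(top)
    return top, frames, gt, sel


def enumerate_min_image(p, q, cell: TriclinicCell, reach: int = 2) -> float:
    """Brute-force minimum-image distance over (2*reach+1)^3 lattice shifts.

    Points are wrapped into the primary cell first so the enumeration
    covers the true minimum.
    """
    p = cell.wrap(np.asarray(p, dtype=float))
    q = cell.wrap(np.asarray(q, dtype=float))
    shifts = np.array(list(itertools.product(range(-reach, reach + 1), repeat=3)), dtype=float)
    cand = (q - p) + shifts @ cell.vectors
    return float(np.min(np.linalg.norm(cand, axis=1)))


def pixel_count_areas(sites_xy: np.ndarray, cell: TriclinicCell, grid: int) -> np.ndarray:
    """Voronoi areas by brute-force pixel counting on a grid^2 raster.

    Independent of the tessellation code path: every pixel of the
    fractional grid is assigned to the periodically nearest site and
    counted.
    """
    ghosts, parent = full_replication_2d(sites_xy, cell)
    tree = cKDTree(ghosts)
    counts = np.zeros(len(sites_xy))
    f = (np.arange(grid) + 0.5) / grid
    block = 512
    for start in range(0, grid, block):
        fx, fy = np.meshgrid(f[start : start + block], f, indexing="ij")
        frac = np.column_stack([fx.ravel(), fy.ravel(), np.zeros(fx.size)])
        xy = (frac @ cell.vectors)[:, :2]
        _, idx = tree.query(xy, workers=-1)
        counts += np.bincount(parent[idx], minlength=len(sites_xy))
    return counts * cell.cross_area / grid**2


def kmeans_1d_optimal(values: np.ndarray, k: int):
    """Exhaustive optimal 1-D k-means partition by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order; DP over split
    points minimises total within-cluster sum of squares.  Returns
    (labels, total_cost) with labels 0..k-1 in ascending value order.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    x = values[order]
    n = len(x)
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i, j):  # cost of cluster x[i:j]
        m = j - i
        s = pref[j] - pref[i]
        return (pref2[j] - pref2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                v = cost[c - 1, i] + sse(i, j)
                if v < cost[c, j]:
                    cost[c, j] = v
                    split[c, j] = i
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = split[c, j]
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, float(cost[k, n])
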