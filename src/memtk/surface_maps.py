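"""2D thickness and area-per-lipid maps over the periodic unit cell.

Per-lipid areas come from the Voronoi diagram (dual of the Delaunay
triangulation) of the phosphorus xy positions.  Periodicity — including
hexagonal cells — is handled by replicating every site into the 8
neighbouring in-plane lattice images before tessellating, so the cells
of the original sites tile the unit cell exactly and their areas sum to
the cell cross-section.

Raster maps use a nearest-site fill: each pixel of the (default
512 x 512) grid over fractional in-plane coordinates takes the value of
the periodically nearest phosphorus, then values are averaged over the
requested time window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import QhullError, Voronoi, cKDTree

from memtk.core_model.cell import TriclinicCell, full_replication_2d
from memtk.core_model.model import Frame, LipidSelection
from memtk.errors import MemtkError
from memtk.leaflets import LOWER, UPPER, LeafletAssignment

DEFAULT_GRID = 512
#: jitter applied once when Qhull rejects a degenerate configuration (nm)
DEGENERACY_EPS = 1e-9


@dataclass
class RasterMap:
    """Grid of values over fractional in-plane coordinates of the cell."""

    values: np.ndarray  # (grid, grid)
    counts: np.ndarray  # (grid, grid) frames contributing per pixel
    cell: TriclinicCell

    @property
    def grid(self) -> int:
        return self.values.shape[0]

    def pixel_centers(self) -> np.ndarray:
        """Cartesian xy of each pixel center, shape (grid, grid, 2)."""
        g = self.grid
        f = (np.arange(g) + 0.5) / g
        fx, fy = np.meshgrid(f, f, indexing="ij")
        frac = np.stack([fx, fy, np.zeros_like(fx)], axis=-1)
        return (frac.reshape(-1, 3) @ self.cell.vectors)[:, :2].reshape(g, g, 2)

    def spatial_mean(self) -> float:
        """Area-weighted mean (pixels have equal area in fractional space)."""
        return float(np.mean(self.values))

    def to_text(self, path: str) -> None:
        header = (
            "memtk raster map\n"
            f"grid {self.grid}\n"
            "cell_nm " + " ".join(f"{x:.9g}" for x in self.cell.vectors.ravel())
        )
        np.savetxt(path, self.values, header=header)

    def to_long_dataframe(self):
        import pandas as pd

        g = self.grid
        ix, iy = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        return pd.DataFrame(
            {
                "ix": ix.ravel(),
                "iy": iy.ravel(),
                "value": self.values.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass
class AreaRecord:
    """Per-lipid Voronoi areas (nm^2) for one frame, grouped by leaflet."""

    areas: np.ndarray  # (n_lipids,)
    labels: np.ndarray  # leaflet label per lipid
    cell: TriclinicCell

    def leaflet_areas(self, label: str) -> np.ndarray:
        return self.areas[self.labels == label]


def _pixel_fraction_grid(grid: int) -> np.ndarray:
    f = (np.arange(grid) + 0.5) / grid
    fx, fy = np.meshgrid(f, f, indexing="ij")
    return np.stack([fx.ravel(), fy.ravel()], axis=-1)


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _voronoi_areas_periodic(xy: np.ndarray, cell: TriclinicCell) -> np.ndarray:
    """Voronoi cell area of each site under full 8-image replication."""
    pts, _ = full_replication_2d(xy, cell)
    vor = Voronoi(pts)
    n = len(xy)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise MemtkError("unbounded Voronoi cell for an original site")
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


def voronoi_apl(frame: Frame, assignment: LeafletAssignment, selection: LipidSelection) -> AreaRecord:
    """Per-lipid Voronoi areas, computed per leaflet with periodic ghosts.

    Within each leaflet the per-lipid areas sum to the cell
    cross-section area.  Degenerate (e.g. collinear) site sets get one
    jitter-retry of amplitude ``DEGENERACY_EPS`` before failing.
    """
    cell = frame.cell
    xy_all = cell.wrap(frame.positions[selection.phosphorus])[:, :2]
    areas = np.full(selection.n_lipids, np.nan)
    for label in (UPPER, LOWER):
        idx = np.nonzero(assignment.labels == label)[0]
        if len(idx) < 4:
            raise MemtkError(f"leaflet {label!r} has {len(idx)} lipids; need >= 4 for Voronoi")
        xy = xy_all[idx]
        try:
            leaflet_areas = _voronoi_areas_periodic(xy, cell)
        except (QhullError, MemtkError):
            rng = np.random.default_rng(0)
            xy_j = xy + rng.normal(0.0, DEGENERACY_EPS, xy.shape)
            leaflet_areas = _voronoi_areas_periodic(xy_j, cell)
        areas[idx] = leaflet_areas
    return AreaRecord(areas, np.asarray(assignment.labels), cell)


def _nearest_site_pixels(
    xy_sites: np.ndarray, cell: TriclinicCell, frac_pixels: np.ndarray
) -> np.ndarray:
    """Index of the periodically nearest site for every pixel center."""
    ghosts, parent = full_replication_2d(xy_sites, cell)
    tree = cKDTree(ghosts)
    frac3 = np.concatenate([frac_pixels, np.zeros((len(frac_pixels), 1))], axis=1)
    centers = (frac3 @ cell.vectors)[:, :2]
    _, nearest = tree.query(centers, workers=-1)
    return parent[nearest]


def _select_window(frames, assignments, window):
    frames = list(frames)
    if window is None:
        return frames, list(assignments)
    t0, t1 = window
    picked = [(f, a) for f, a in zip(frames, assignments) if t0 < f.time <= t1]
    if not picked:
        raise MemtkError(f"no frames in window ({t0}, {t1}] ns")
    return [p[0] for p in picked], [p[1] for p in picked]


def apl_map(
    frames,
    assignments,
    selection: LipidSelection,
    window: tuple[float, float] | None = None,
    grid: int = DEFAULT_GRID,
) -> dict[str, RasterMap]:
    """Time-averaged area-per-lipid raster map, one per leaflet.

    Each pixel takes the Voronoi area of the lipid whose phosphorus is
    periodically nearest, then pixels are averaged over the window
    (half-open ``(t0, t1]`` in ns; ``None`` = all frames).
    """
    frames, assignments = _select_window(frames, assignments, window)
    frac = _pixel_fraction_grid(grid)
    acc = {lab: np.zeros(grid * grid) for lab in (UPPER, LOWER)}
    cnt = {lab: np.zeros(grid * grid) for lab in (UPPER, LOWER)}
    cell = frames[0].cell
    for fr, asg in zip(frames, assignments):
        record = voronoi_apl(fr, asg, selection)
        xy_all = fr.cell.wrap(fr.positions[selection.phosphorus])[:, :2]
        for lab in (UPPER, LOWER):
            idx = np.nonzero(asg.labels == lab)[0]
            near = _nearest_site_pixels(xy_all[idx], fr.cell, frac)
            acc[lab] += record.areas[idx][near]
            cnt[lab] += 1
    return {
        lab: RasterMap(
            (acc[lab] / cnt[lab]).reshape(grid, grid), cnt[lab].reshape(grid, grid), cell
        )
        for lab in (UPPER, LOWER)
    }


def _leaflet_z_pixels(fr, asg, selection, frac) -> dict[str, np.ndarray]:
    xy_all = fr.cell.wrap(fr.positions[selection.phosphorus])[:, :2]
    z_all = fr.positions[selection.phosphorus][:, 2]
    out = {}
    for lab in (UPPER, LOWER):
        idx = np.nonzero(asg.labels == lab)[0]
        if len(idx) == 0:
            raise MemtkError(f"leaflet {lab!r} has no lipids")
        near = _nearest_site_pixels(xy_all[idx], fr.cell, frac)
        out[lab] = z_all[idx][near]
    return out


def thickness_map(
    frames,
    assignments,
    selection: LipidSelection,
    window: tuple[float, float] | None = None,
    grid: int = DEFAULT_GRID,
) -> RasterMap:
    """Time-averaged membrane thickness map (upper z minus lower z, nm)."""
    frames, assignments = _select_window(frames, assignments, window)
    frac = _pixel_fraction_grid(grid)
    acc = np.zeros(grid * grid)
    n = 0
    cell = frames[0].cell
    for fr, asg in zip(frames, assignments):
        zpix = _leaflet_z_pixels(fr, asg, selection, frac)
        acc += zpix[UPPER] - zpix[LOWER]
        n += 1
    return RasterMap((acc / n).reshape(grid, grid), np.full((grid, grid), n, float), cell)


def mean_thickness(
    frames,
    assignments,
    selection: LipidSelection,
    window: tuple[float, float] | None = None,
    grid: int = DEFAULT_GRID,
) -> tuple[float, float]:
    """Pixel-weighted mean and sd of the per-frame thickness field (nm)."""
    frames, assignments = _select_window(frames, assignments, window)
    frac = _pixel_fraction_grid(grid)
    s = s2 = 0.0
    n = 0
    for fr, asg in zip(frames, assignments):
        zpix = _leaflet_z_pixels(fr, asg, selection, frac)
        th = zpix[UPPER] - zpix[LOWER]
        s += th.sum()
        s2 += (th**2).sum()
        n += th.size
    mean = s / n
    var = max(s2 / n - mean**2, 0.0)
    return float(mean), float(np.sqrt(var))


def project_outline(
    frame: Frame,
    group: np.ndarray,
    cell: TriclinicCell | None = None,
    grid: int = DEFAULT_GRID,
    dilation: float = 0.2,
) -> np.ndarray:
    """Boolean pixel mask covered by the xy projection of a group of atoms.

    Atoms are replicated into the neighbouring in-plane images, and a
    pixel is set when its center lies within ``dilation`` nm of any
    projected atom.
    """
    group = np.asarray(group, dtype=int)
    if len(group) == 0:
        raise ValueError("group is empty")
    cell = cell or frame.cell
    xy = cell.wrap(frame.positions[group])[:, :2]
    ghosts, _ = full_replication_2d(xy, cell)
    tree = cKDTree(ghosts)
    frac = _pixel_fraction_grid(grid)
    frac3 = np.concatenate([frac, np.zeros((len(frac), 1))], axis=1)
    centers = (frac3 @ cell.vectors)[:, :2]
    dist, _ = tree.query(centers, workers=-1)
    return (dist <= dilation).reshape(grid, grid)


def apl_summary(records: list[AreaRecord]) -> dict[str, tuple[float, float]]:
    """Mean and sd of per-lipid areas: upper, lower, and overall."""
    ups = np.concatenate([r.leaflet_areas(UPPER) for r in records])
    los = np.concatenate([r.leaflet_areas(LOWER) for r in records])
    allv = np.concatenate([ups, los])
    return {
        "upper": (float(ups.mean()), float(ups.std())),
        "lower": (float(los.mean()), float(los.std())),
        "overall": (float(allv.mean()), float(allv.std())),
    }
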