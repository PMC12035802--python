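"""Synthetic bilayer / nanoparticle / probe trajectory generators.

Every generator is a pure function of (parameters, seed) and returns a
``GroundTruth`` record holding the planted values, so each downstream
analysis stage can be tested against known answers.  The trajectories
are kinematic — no force field, no integrator.

Default parameters mirror the reference system: 356 lipids in a
hexagonal cell, area per lipid 0.64 nm^2, phosphorus-plane separation
3.93 nm, a nanoparticle of 14 forty-unit polystyrene chains, and 32
probe molecules.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from memtk.core_model.cell import TriclinicCell
from memtk.core_model.model import ATOMIC_MASSES, Frame, Topology

RELEASE_CLASSES = ("immobile", "released", "escaped")

_MASS_C = ATOMIC_MASSES["C"]
_MASS_H = ATOMIC_MASSES["H"]
_MASS_P = ATOMIC_MASSES["P"]

#: C8H8 styrene repeat unit, g/mol
STYRENE_UNIT_MASS = 8 * _MASS_C + 8 * _MASS_H


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic system (the recoverable answers)."""

    seed: int
    apl: float | None = None  # nm^2 per lipid
    thickness: float | None = None  # phosphorus-plane separation, nm
    leaflet_z: tuple[float, float] | None = None  # (lower, upper) plane z, nm
    bump_height: float | None = None  # nm
    bump_sigma: float | None = None  # nm
    bump_center: tuple[float, float] | None = None  # Cartesian xy, nm
    tilt_deg: float | None = None  # acyl chain axis tilt from z
    ch_angle_deg: float | None = None  # planted C-H angle to z
    jitter: float | None = None  # positional noise sigma, nm
    leaflet_labels: list[str] | None = None  # per lipid
    probe_classes: list[str] | None = None
    chain_molecules: list[int] | None = None  # molecule ids of polymer chains
    probe_molecules: list[int] | None = None
    com_z_series: list[float] | None = None  # planted blob COM z per frame
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probe_classes is not None:
            bad = set(self.probe_classes) - set(RELEASE_CLASSES)
            if bad:
                raise ValueError(f"unknown probe classes {sorted(bad)}")

    @property
    def expected_scd(self) -> float:
        """Order parameter implied by the planted C-H angle."""
        if self.ch_angle_deg is None:
            raise ValueError("no planted C-H angle")
        c = np.cos(np.deg2rad(self.ch_angle_deg))
        return 1.5 * c * c - 0.5

    def thickness_at(self, xy: np.ndarray, cell: TriclinicCell) -> np.ndarray:
        """Analytic phosphorus-plane separation at in-plane position(s)."""
        if self.thickness is None:
            raise ValueError("no planted thickness")
        base = self.thickness
        if not self.bump_height:
            return np.full(np.atleast_2d(xy).shape[0], base)
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        p = np.zeros((len(xy), 3))
        p[:, :2] = xy
        q = np.zeros(3)
        q[:2] = self.bump_center
        from memtk.core_model.cell import minimum_image_displacement

        d = minimum_image_displacement(p, np.broadcast_to(q, p.shape), cell)
        r2 = d[:, 0] ** 2 + d[:, 1] ** 2
        return base + 2.0 * self.bump_height * np.exp(-r2 / (2.0 * self.bump_sigma**2))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=lambda o: list(o), indent=1)


# -------------------------------------------------------------------------
# bilayers
# -------------------------------------------------------------------------


def _grid_shape(n: int) -> tuple[int, int]:
    """Near-square factorisation m1 * m2 = n (largest divisor <= sqrt(n))."""
    m1 = int(np.sqrt(n))
    while n % m1:
        m1 -= 1
    return m1, n // m1


def _lipid_atoms(n_carbons: int) -> tuple[list[str], list[str], list[float]]:
    """Atom names / elements / masses of one minimal lipid (P + 2 acyl chains)."""
    names, elements, masses = ["P"], ["P"], [_MASS_P]
    for chain in ("A", "B"):
        for k in range(1, n_carbons + 1):
            names += [f"C{k}{chain}", f"H{k}{chain}1", f"H{k}{chain}2"]
            elements += ["C", "H", "H"]
            masses += [_MASS_C, _MASS_H, _MASS_H]
    return names, elements, masses


def _lipid_geometry(
    p_pos: np.ndarray,
    leaflet_sign: float,
    n_carbons: int,
    tilt_deg: float,
    ch_angle_deg: float,
    phase: float,
) -> np.ndarray:
    """Coordinates of one lipid's atoms (P first), planted chain geometry.

    The chain axis is tilted ``tilt_deg`` from the membrane normal and
    points toward the midplane; every C-H bond makes exactly
    ``ch_angle_deg`` with the laboratory z axis so the order parameter
    is known in closed form.
    """
    tilt = np.deg2rad(tilt_deg)
    axis = np.array(
        [np.sin(tilt) * np.cos(phase), np.sin(tilt) * np.sin(phase), -leaflet_sign * np.cos(tilt)]
    )
    th = np.deg2rad(ch_angle_deg)
    bond = 0.127  # C-C projection along the chain axis, nm
    r_ch = 0.109  # C-H bond length, nm
    coords = [p_pos]
    for ci, chain_off in enumerate((np.array([0.15, 0.0, -0.1]), np.array([-0.15, 0.0, -0.1]))):
        base = p_pos + leaflet_sign * np.array([0, 0, -0.2]) + chain_off * [1, 1, leaflet_sign]
        for k in range(n_carbons):
            c = base + (k + 1) * bond * axis
            h1 = c + r_ch * np.array(
                [np.sin(th) * np.cos(phase), np.sin(th) * np.sin(phase), np.cos(th)]
            )
            h2 = c + r_ch * np.array(
                [
                    np.sin(th) * np.cos(phase + np.pi),
                    np.sin(th) * np.sin(phase + np.pi),
                    np.cos(th),
                ]
            )
            coords += [c, h1, h2]
    return np.asarray(coords)


def make_bump_bilayer(
    n_per_leaflet: int = 178,
    apl: float = 0.64,
    thickness: float = 3.93,
    cell_kind: str = "hexagonal",
    h: float = 0.0,
    sigma: float = 1.0,
    jitter: float = 0.0,
    seed: int = 0,
    n_frames: int = 1,
    dt: float = 1.0,
    n_carbons: int = 6,
    tilt_deg: float = 0.0,
    ch_angle_deg: float = 90.0,
) -> tuple[Topology, list[Frame], GroundTruth]:
    """Two-leaflet bilayer with a central Gaussian bump of height ``h``.

    Phosphorus atoms sit on a regular sub-lattice with exactly ``apl``
    nm^2 per site; each leaflet plane at +/- thickness/2 is displaced
    outward by ``h * exp(-r^2 / 2 sigma^2)`` from the cell center, so the
    planted thickness at the center is ``thickness + 2 h``.
    """
    if n_per_leaflet < 4:
        raise ValueError("need at least 4 lipids per leaflet (Voronoi undefined below)")
    if apl <= 0 or thickness <= 0:
        raise ValueError("apl and thickness must be positive")
    if h < 0:
        raise ValueError("bump height must be non-negative")
    if sigma <= 0:
        raise ValueError("bump sigma must be positive")
    if cell_kind not in ("rectangular", "hexagonal"):
        raise ValueError(f"cell_kind must be rectangular or hexagonal, got {cell_kind!r}")

    m1, m2 = _grid_shape(n_per_leaflet)
    lz = thickness + 2 * h + 6.0
    if cell_kind == "rectangular":
        a = np.sqrt(apl)
        cell = TriclinicCell.rectangular(m1 * a, m2 * a, lz)
    else:
        a_hex = np.sqrt(n_per_leaflet * apl / (np.sqrt(3.0) / 2.0))
        cell = TriclinicCell.hexagonal(a_hex, lz)

    mid_z = lz / 2.0
    frac = np.stack(
        np.meshgrid((np.arange(m1) + 0.5) / m1, (np.arange(m2) + 0.5) / m2, indexing="ij"),
        axis=-1,
    ).reshape(-1, 2)
    frac3 = np.concatenate([frac, np.zeros((len(frac), 1))], axis=1)
    xy = cell.to_cartesian(frac3)[:, :2]

    center_xy = cell.to_cartesian(np.array([0.5, 0.5, 0.0]))[:2]
    from memtk.core_model.cell import minimum_image_displacement

    p3 = np.zeros((len(xy), 3))
    p3[:, :2] = xy
    q3 = np.zeros(3)
    q3[:2] = center_xy
    d = minimum_image_displacement(p3, np.broadcast_to(q3, p3.shape), cell)
    r2 = d[:, 0] ** 2 + d[:, 1] ** 2
    bump = h * np.exp(-r2 / (2.0 * sigma**2))

    names_l, elements_l, masses_l = _lipid_atoms(n_carbons)
    n_atoms_lipid = len(names_l)
    names, elements, masses, resids, resnames, molecules = [], [], [], [], [], []
    base_positions = []
    leaflet_labels = []
    resid = 0
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=2 * len(xy))
    for li, (label, sign, zoff) in enumerate(
        (("upper", 1.0, thickness / 2.0), ("lower", -1.0, -thickness / 2.0))
    ):
        for i in range(len(xy)):
            resid += 1
            z = mid_z + zoff + sign * bump[i]
            p_pos = np.array([xy[i, 0], xy[i, 1], z])
            coords = _lipid_geometry(
                p_pos, sign, n_carbons, tilt_deg, ch_angle_deg, phases[li * len(xy) + i]
            )
            base_positions.append(coords)
            names += names_l
            elements += elements_l
            masses += masses_l
            resids += [resid] * n_atoms_lipid
            resnames += ["POPC"] * n_atoms_lipid
            start = (resid - 1) * n_atoms_lipid
            molecules.append(np.arange(start, start + n_atoms_lipid))
            leaflet_labels.append(label)

    base = np.concatenate(base_positions)
    topology = Topology(
        np.array(names, dtype=object),
        np.array(elements, dtype=object),
        np.array(masses),
        np.array(resids),
        np.array(resnames, dtype=object),
        molecules,
    )
    frames = []
    for k in range(n_frames):
        pos = base if jitter == 0 else base + rng.normal(0.0, jitter, size=base.shape)
        frames.append(Frame(k * dt, pos, cell))

    gt = GroundTruth(
        seed=seed,
        apl=apl,
        thickness=thickness,
        leaflet_z=(mid_z - thickness / 2.0, mid_z + thickness / 2.0),
        bump_height=h,
        bump_sigma=sigma,
        bump_center=(float(center_xy[0]), float(center_xy[1])),
        tilt_deg=tilt_deg,
        ch_angle_deg=ch_angle_deg,
        jitter=jitter,
        leaflet_labels=leaflet_labels,
        extras={"mid_z": mid_z, "cell_kind": cell_kind},
    )
    return topology, frames, gt


def make_flat_bilayer(
    n_per_leaflet: int = 178,
    apl: float = 0.64,
    thickness: float = 3.93,
    cell_kind: str = "hexagonal",
    jitter: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> tuple[Topology, list[Frame], GroundTruth]:
    """Flat bilayer: the ``h = 0`` special case of :func:`make_bump_bilayer`."""
    return make_bump_bilayer(
        n_per_leaflet=n_per_leaflet,
        apl=apl,
        thickness=thickness,
        cell_kind=cell_kind,
        h=0.0,
        sigma=1.0,
        jitter=jitter,
        seed=seed,
        **kwargs,
    )


# -------------------------------------------------------------------------
# polystyrene blob + probes
# -------------------------------------------------------------------------

#: atoms of one styrene repeat unit: backbone CH2-CH plus a C6H5 ring
_UNIT_NAMES = (
    ["C1", "H11", "H12", "C2", "H21"]
    + [f"C{k}" for k in range(3, 9)]
    + [f"H{k}1" for k in range(4, 9)]
)
_UNIT_ELEMENTS = ["C", "H", "H", "C", "H"] + ["C"] * 6 + ["H"] * 5


def chain_molecular_weight(units_per_chain: int) -> float:
    """Molecular weight (kDa) of a hydrogen-capped polystyrene chain."""
    if units_per_chain < 1:
        raise ValueError("need at least one repeat unit")
    return (units_per_chain * STYRENE_UNIT_MASS + 2 * _MASS_H) / 1000.0


def _styrene_unit_coords(anchor: np.ndarray, direction: np.ndarray, rng) -> np.ndarray:
    """Rough coordinates of one C8H8 unit near ``anchor`` (kinematic only)."""
    coords = np.empty((16, 3))
    coords[0] = anchor  # C1
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    nrm = np.linalg.norm(perp)
    perp = perp / nrm if nrm > 1e-8 else np.array([1.0, 0.0, 0.0])
    coords[1] = anchor + 0.109 * perp  # H11
    coords[2] = anchor - 0.109 * perp  # H12
    c2 = anchor + 0.153 * direction
    coords[3] = c2
    coords[4] = c2 + 0.109 * np.cross(direction, perp)  # H21
    ring_dir = perp + rng.normal(0, 0.1, 3)
    ring_dir /= np.linalg.norm(ring_dir)
    ring_center = c2 + 0.25 * ring_dir
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    u = ring_dir
    v = np.cross(u, direction)
    v /= max(np.linalg.norm(v), 1e-8)
    w = np.cross(u, v)
    for i, a in enumerate(ang):
        coords[5 + i] = ring_center + 0.14 * (np.cos(a) * v + np.sin(a) * w)
    for i in range(5):
        c = coords[6 + i]
        out = c - ring_center
        coords[11 + i] = c + 0.109 * out / max(np.linalg.norm(out), 1e-8)
    return coords


def _confined_walk(rng, n_steps: int, step: float, radius: float, start: np.ndarray) -> np.ndarray:
    """Random walk confined to a sphere of ``radius`` around the origin."""
    pts = np.empty((n_steps, 3))
    pos = start.copy()
    pts[0] = pos
    for k in range(1, n_steps):
        for _ in range(64):
            d = rng.normal(size=3)
            d *= step / np.linalg.norm(d)
            cand = pos + d
            if np.linalg.norm(cand) <= radius:
                pos = cand
                break
        else:  # fall back: pull toward center
            pos = pos * (radius / (np.linalg.norm(pos) + step))
        pts[k] = pos
    return pts


def make_ps_blob(
    n_chains: int = 14,
    units_per_chain: int = 40,
    probe_classes: Sequence[str] | None = None,
    seed: int = 0,
    n_frames: int = 1,
    dt: float = 1.0,
    density: float = 1.03,
    jitter: float = 0.0,
    com_z: float | tuple[float, float] | None = None,
    cell: TriclinicCell | None = None,
) -> tuple[Topology, list[Frame], GroundTruth]:
    """Compact blob of collapsed polystyrene chains, with optional probes.

    Chains are confined random walks packed inside a sphere whose radius
    follows from the chain mass and ``density`` (g/cm^3).  Probe
    molecules (styrene monomers, resname STYR) are placed in the core,
    at the periphery, or outside the blob according to their planted
    mobility class.  ``com_z`` translates the whole blob to a fixed z or
    drifts it linearly from ``com_z[0]`` to ``com_z[1]`` across frames.
    """
    if n_chains < 1 or units_per_chain < 1:
        raise ValueError("need n_chains >= 1 and units_per_chain >= 1")
    probe_classes = list(probe_classes or [])
    bad = set(probe_classes) - set(RELEASE_CLASSES)
    if bad:
        raise ValueError(f"unknown probe classes {sorted(bad)}")

    rng = np.random.default_rng(seed)
    total_mass = n_chains * chain_molecular_weight(units_per_chain) * 1000.0  # g/mol
    # radius from mass density: V[nm^3] = m[g] / rho / 1e-21
    vol_nm3 = (total_mass / 6.02214076e23) / density / 1e-21
    radius = (3.0 * vol_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0)

    if cell is None:
        box = max(4.0 * radius, 12.0)
        cell = TriclinicCell.rectangular(box, box, box)
    center = cell.to_cartesian(np.array([0.5, 0.5, 0.5]))

    names, elements, masses, resids, resnames, molecules = [], [], [], [], [], []
    coords_parts = []
    resid = 0
    chain_mol_ids, probe_mol_ids = [], []

    for _ in range(n_chains):
        resid += 1
        start = rng.normal(size=3)
        start *= rng.uniform(0, 0.7 * radius) / np.linalg.norm(start)
        backbone = _confined_walk(rng, units_per_chain, 0.25, radius, start)
        unit_coords = []
        for k in range(units_per_chain):
            direction = (
                backbone[min(k + 1, units_per_chain - 1)] - backbone[max(k - 1, 0)]
            )
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 1e-8 else np.array([0.0, 0.0, 1.0])
            unit_coords.append(_styrene_unit_coords(backbone[k], direction, rng))
        chain_xyz = np.concatenate(unit_coords)
        # hydrogen caps on the first and last backbone carbons
        caps = np.stack([backbone[0] + [0, 0, 0.109], backbone[-1] + [0, 0, -0.109]])
        chain_xyz = np.concatenate([chain_xyz, caps])
        coords_parts.append(chain_xyz)

        n_unit = len(_UNIT_NAMES)
        for _k in range(units_per_chain):
            names += list(_UNIT_NAMES)
            elements += list(_UNIT_ELEMENTS)
            masses += [ATOMIC_MASSES[e] for e in _UNIT_ELEMENTS]
        names += ["HC1", "HC2"]
        elements += ["H", "H"]
        masses += [_MASS_H, _MASS_H]
        n_chain_atoms = units_per_chain * n_unit + 2
        resids += [resid] * n_chain_atoms
        resnames += ["PS"] * n_chain_atoms
        start_idx = sum(len(m) for m in molecules)
        molecules.append(np.arange(start_idx, start_idx + n_chain_atoms))
        chain_mol_ids.append(len(molecules) - 1)

    # probes: radial placement by class
    radial = {"immobile": (0.0, 0.35), "released": (0.85, 1.05), "escaped": (1.6, 2.2)}
    for cls in probe_classes:
        resid += 1
        lo, hi = radial[cls]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        anchor = direction * rng.uniform(lo, hi) * radius
        xyz = _styrene_unit_coords(anchor, np.array([0.0, 0.0, 1.0]), rng)
        coords_parts.append(xyz)
        names += list(_UNIT_NAMES)
        elements += list(_UNIT_ELEMENTS)
        masses += [ATOMIC_MASSES[e] for e in _UNIT_ELEMENTS]
        resids += [resid] * len(_UNIT_NAMES)
        resnames += ["STYR"] * len(_UNIT_NAMES)
        start_idx = sum(len(m) for m in molecules)
        molecules.append(np.arange(start_idx, start_idx + len(_UNIT_NAMES)))
        probe_mol_ids.append(len(molecules) - 1)

    base = np.concatenate(coords_parts) + center
    topology = Topology(
        np.array(names, dtype=object),
        np.array(elements, dtype=object),
        np.array(masses),
        np.array(resids),
        np.array(resnames, dtype=object),
        molecules,
    )

    if com_z is None:
        com_targets = [None] * n_frames
    elif np.isscalar(com_z):
        com_targets = [float(com_z)] * n_frames
    else:
        z0, z1 = com_z
        com_targets = list(np.linspace(z0, z1, n_frames))

    blob_atoms = np.concatenate([molecules[i] for i in chain_mol_ids])
    w = topology.masses[blob_atoms]
    com0_z = float(np.average(base[blob_atoms, 2], weights=w))

    frames = []
    for k in range(n_frames):
        pos = base.copy()
        if com_targets[k] is not None:
            pos[:, 2] += com_targets[k] - com0_z
        if jitter > 0:
            pos += rng.normal(0.0, jitter, size=pos.shape)
        frames.append(Frame(k * dt, pos, cell))

    gt = GroundTruth(
        seed=seed,
        probe_classes=probe_classes or None,
        chain_molecules=chain_mol_ids,
        probe_molecules=probe_mol_ids,
        com_z_series=[t for t in com_targets] if com_z is not None else None,
        extras={"blob_radius": radius, "density": density},
    )
    return topology, frames, gt


def combine_systems(
    top_a: Topology, frames_a: Sequence[Frame], top_b: Topology, frames_b: Sequence[Frame]
) -> tuple[Topology, list[Frame]]:
    """Merge two systems atom-wise (cell and times taken from system A)."""
    if len(frames_a) != len(frames_b):
        raise ValueError("frame counts differ")
    off = top_a.n_atoms
    resid_off = int(top_a.resids.max()) if top_a.n_atoms else 0
    top = Topology(
        np.concatenate([top_a.names, top_b.names]),
        np.concatenate([top_a.elements, top_b.elements]),
        np.concatenate([top_a.masses, top_b.masses]),
        np.concatenate([top_a.resids, top_b.resids + resid_off]),
        np.concatenate([top_a.resnames, top_b.resnames]),
        list(top_a.molecules) + [m + off for m in top_b.molecules],
    )
    frames = [
        Frame(fa.time, np.concatenate([fa.positions, fb.positions]), fa.cell)
        for fa, fb in zip(frames_a, frames_b)
    ]
    return top, frames


# -------------------------------------------------------------------------
# release series
# -------------------------------------------------------------------------


def make_release_series(
    n_molecules: int = 32,
    class_fractions: Sequence[float] = (6 / 32, 18 / 32, 8 / 32),
    stds: Sequence[float] = (0.05, 0.6, 2.4),
    n_frames: int = 500,
    seed: int = 1,
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Per-molecule distance-vs-time series with planted mobility classes.

    immobile: constant baseline plus small white noise; released: a
    mean-reverting bounded walk of moderate dispersion; escaped: the
    same process with large excursions.  ``stds`` are the target
    stationary standard deviations and must increase strictly.

    Returns (times, series[n_molecules, n_frames], ground_truth).
    """
    if n_molecules < 3:
        raise ValueError("need at least 3 molecules for k = 3 clustering")
    fr = np.asarray(class_fractions, dtype=float)
    if len(fr) != 3 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("class_fractions must be 3 values summing to 1")
    stds = tuple(float(s) for s in stds)
    if not (stds[0] < stds[1] < stds[2]):
        raise ValueError("stds must increase strictly across classes")

    counts = np.floor(fr * n_molecules).astype(int)
    while counts.sum() < n_molecules:
        counts[int(np.argmax(fr * n_molecules - counts))] += 1

    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * dt
    series = np.empty((n_molecules, n_frames))
    labels: list[str] = []
    baselines = {"immobile": 1.0, "released": 3.0, "escaped": 6.0}
    phi = 0.85  # mean-reversion memory of the bounded walks
    row = 0
    for cls, cnt, sd in zip(RELEASE_CLASSES, counts, stds):
        for _ in range(cnt):
            mu = baselines[cls]
            if cls == "immobile":
                x = mu + rng.normal(0.0, sd, n_frames)
            else:
                x = np.empty(n_frames)
                x[0] = mu + rng.normal(0.0, sd)
                eps = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n_frames)
                for t in range(1, n_frames):
                    x[t] = mu + phi * (x[t - 1] - mu) + eps[t]
            series[row] = np.clip(x, 0.0, None)
            labels.append(cls)
            row += 1
    gt = GroundTruth(seed=seed, probe_classes=labels, extras={"stds": stds, "dt": dt})
    return times, series, gt
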