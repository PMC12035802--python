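"""Order parameters, density profiles, and polymer coil descriptors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from memtk.core_model.cell import minimum_image_displacement
from memtk.core_model.model import Frame, LipidSelection, Topology
from memtk.errors import SelectionError
from memtk.leaflets import LOWER, UPPER

AVOGADRO = 6.02214076e23
_NM3_TO_CM3 = 1e-21


@dataclass
class OrderProfile:
    """|S_CD| per acyl-carbon index, per chain, with sd across samples."""

    carbons: np.ndarray  # 1-based carbon indices along the chain
    values: dict[str, np.ndarray]  # chain name -> |S_CD| per carbon
    sd: dict[str, np.ndarray]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for ch, vals in self.values.items():
            for k, v, s in zip(self.carbons, vals, self.sd[ch]):
                rows.append((ch, int(k), float(v), float(s)))
        return pd.DataFrame(rows, columns=["chain", "carbon", "abs_scd", "sd"])


@dataclass
class DensityProfile:
    """Mass density (g/cm^3) vs distance from the bilayer midplane (nm)."""

    bin_centers: np.ndarray
    densities: dict[str, np.ndarray]
    bin_width: float

    def to_dataframe(self):
        import pandas as pd

        data = {"z_nm": self.bin_centers}
        data.update({g: d for g, d in self.densities.items()})
        return pd.DataFrame(data)


@dataclass
class CoilMetrics:
    """Time series of polymer descriptors."""

    times: np.ndarray
    rg: np.ndarray  # (n_frames,)
    d_ee: np.ndarray  # (n_chains, n_frames)
    com_z: np.ndarray | None = None  # relative to midplane

    def to_dataframe(self):
        import pandas as pd

        data = {"time_ns": self.times, "rg_nm": self.rg}
        for i in range(self.d_ee.shape[0]):
            data[f"d_ee_chain{i}_nm"] = self.d_ee[i]
        if self.com_z is not None:
            data["com_z_nm"] = self.com_z
        return pd.DataFrame(data)


# -------------------------------------------------------------------------
# order parameters
# -------------------------------------------------------------------------


def order_parameters(
    frames, selection: LipidSelection, normal=(0.0, 0.0, 1.0)
) -> OrderProfile:
    """Deuterium order parameter profile along the acyl chains.

    For every C-H bond, ``s = (3 cos^2 theta - 1) / 2`` with theta the
    angle to the membrane normal (laboratory z by default; the membrane
    is flat on average).  Values are averaged over hydrogens, lipids and
    frames per carbon index and reported as magnitudes.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)

    chain_names = selection.chain_names
    n_carbons = {ch: len(selection.acyl[0][ch]) for ch in chain_names}
    samples: dict[str, list[list[float]]] = {
        ch: [[] for _ in range(n_carbons[ch])] for ch in chain_names
    }
    for fr in frames:
        pos = fr.positions
        for lipid_i, acyl in enumerate(selection.acyl):
            for ch in chain_names:
                for k, (c_idx, h_idx) in enumerate(acyl[ch]):
                    if not h_idx:
                        raise SelectionError(
                            f"lipid {lipid_i}, carbon C{k + 1}{ch}: no bonded hydrogen"
                        )
                    d = pos[h_idx] - pos[c_idx]
                    cos = (d @ normal) / np.linalg.norm(d, axis=1)
                    samples[ch][k].extend(1.5 * cos**2 - 0.5)
    values = {
        ch: np.array([abs(np.mean(s)) for s in samples[ch]]) for ch in chain_names
    }
    sd = {ch: np.array([np.std(s) for s in samples[ch]]) for ch in chain_names}
    carbons = np.arange(1, max(n_carbons.values()) + 1)
    return OrderProfile(carbons, values, sd)


# -------------------------------------------------------------------------
# density profiles
# -------------------------------------------------------------------------


def _midplane_z(frame: Frame, selection: LipidSelection, assignment=None) -> float:
    z = frame.positions[selection.phosphorus][:, 2]
    if assignment is None:
        return float(z.mean())
    zu = z[assignment.labels == UPPER].mean()
    zl = z[assignment.labels == LOWER].mean()
    return float(0.5 * (zu + zl))


def mass_density_profile(
    frames,
    topology: Topology,
    groups: dict[str, np.ndarray],
    selection: LipidSelection,
    assignments=None,
    bin_width: float = 0.1,
    z_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Mass density of atom groups along the membrane normal.

    z is measured from the mean-phosphorus midplane per frame; per bin,
    atom masses are summed and divided by the bin volume
    (bin_width x cell cross-area), then frame-averaged.  Densities are
    in g/cm^3.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not groups:
        raise ValueError("no groups given")
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    if z_range is None:
        lz = frames[0].cell.vectors[2, 2]
        z_range = (-lz / 2.0, lz / 2.0)
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = {g: np.zeros(len(centers)) for g in groups}
    for k, fr in enumerate(frames):
        area = fr.cell.cross_area
        if area <= 0:
            raise ValueError("cell cross-area must be positive")
        mid = _midplane_z(fr, selection, assignments[k] if assignments else None)
        vol_cm3 = area * bin_width * _NM3_TO_CM3
        for g, idx in groups.items():
            idx = np.asarray(idx, dtype=int)
            z = fr.positions[idx, 2] - mid
            m = topology.masses[idx] / AVOGADRO  # grams
            hist, _ = np.histogram(z, bins=edges, weights=m)
            acc[g] += hist / vol_cm3
    densities = {g: acc[g] / len(frames) for g in groups}
    return DensityProfile(centers, densities, bin_width)


# -------------------------------------------------------------------------
# coil metrics
# -------------------------------------------------------------------------


def make_whole(positions: np.ndarray, group: np.ndarray, cell) -> np.ndarray:
    """Unwrap a compact group across periodic boundaries.

    Atoms are shifted by the lattice image closest to the group's first
    atom; valid while the unwrapped group fits within half the cell,
    which holds for the compact coils analysed here.
    """
    group = np.asarray(group, dtype=int)
    ref = positions[group[0]]
    d = minimum_image_displacement(
        np.broadcast_to(ref, (len(group), 3)), positions[group], cell
    )
    return ref + d


def center_of_mass(positions: np.ndarray, group: np.ndarray, masses: np.ndarray, cell) -> np.ndarray:
    whole = make_whole(positions, group, cell)
    w = masses[np.asarray(group, dtype=int)]
    if w.sum() <= 0:
        raise ValueError("group has zero total mass")
    return np.average(whole, axis=0, weights=w)


def radius_of_gyration(frames, topology: Topology, group: np.ndarray) -> np.ndarray:
    """Mass-weighted radius of gyration per frame (nm), group made whole first."""
    group = np.asarray(group, dtype=int)
    if len(group) == 0:
        raise ValueError("group is empty")
    w = topology.masses[group]
    if w.sum() <= 0:
        raise ValueError("group has zero total mass")
    out = []
    for fr in frames:
        whole = make_whole(fr.positions, group, fr.cell)
        com = np.average(whole, axis=0, weights=w)
        r2 = np.sum((whole - com) ** 2, axis=1)
        out.append(np.sqrt(np.average(r2, weights=w)))
    return np.asarray(out)


def end_to_end(frames, chains: list[tuple[int, int]]) -> np.ndarray:
    """Periodic-aware end-to-end distance per chain per frame (nm)."""
    if not chains:
        raise ValueError("no chains given")
    frames = list(frames)
    out = np.empty((len(chains), len(frames)))
    for k, fr in enumerate(frames):
        for c, (first, last) in enumerate(chains):
            d = minimum_image_displacement(fr.positions[first], fr.positions[last], fr.cell)
            out[c, k] = np.linalg.norm(d)
    return out


@dataclass
class ComTrajectory:
    """Group COM z relative to the bilayer midplane, plus leaflet levels."""

    times: np.ndarray
    com_z: np.ndarray  # relative to midplane, nm
    upper_z: np.ndarray  # leaflet mean-phosphorus z relative to midplane
    lower_z: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ns": self.times,
                "com_z_nm": self.com_z,
                "upper_p_z_nm": self.upper_z,
                "lower_p_z_nm": self.lower_z,
            }
        )


def com_trajectory(
    frames, topology: Topology, group: np.ndarray, selection: LipidSelection, assignments
) -> ComTrajectory:
    """COM z of a group relative to the mean-phosphorus midplane, per frame."""
    group = np.asarray(group, dtype=int)
    if len(group) == 0:
        raise ValueError("group is empty")
    frames = list(frames)
    times, com_z, up, lo = [], [], [], []
    for fr, asg in zip(frames, assignments):
        z = fr.positions[selection.phosphorus][:, 2]
        zu = float(z[asg.labels == UPPER].mean())
        zl = float(z[asg.labels == LOWER].mean())
        mid = 0.5 * (zu + zl)
        com = center_of_mass(fr.positions, group, topology.masses, fr.cell)
        times.append(fr.time)
        com_z.append(com[2] - mid)
        up.append(zu - mid)
        lo.append(zl - mid)
    return ComTrajectory(np.asarray(times), np.asarray(com_z), np.asarray(up), np.asarray(lo))


def coil_metrics(
    frames, topology: Topology, chain_molecules: list[np.ndarray], com_z: np.ndarray | None = None
) -> CoilMetrics:
    """Bundle R_g of the whole aggregate and per-chain end-to-end distances."""
    frames = list(frames)
    group = np.concatenate(chain_molecules)
    rg = radius_of_gyration(frames, topology, group)
    chains = [(int(m[0]), int(m[-1])) for m in chain_molecules]
    dee = end_to_end(frames, chains)
    times = np.asarray([fr.time for fr in frames])
    return CoilMetrics(times, rg, dee, com_z)
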