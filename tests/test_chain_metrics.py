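import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtk.chain_metrics import (
    com_trajectory,
    end_to_end,
    make_whole,
    mass_density_profile,
    order_parameters,
    radius_of_gyration,
)
from memtk.core_model.cell import TriclinicCell, minimum_image_displacement
from memtk.core_model.model import Frame, LipidSelection, Topology
from memtk.errors import SelectionError
from memtk.leaflets import assign_leaflets, assign_leaflets_trajectory
from memtk.synthetic_data import (
    combine_systems,
    make_flat_bilayer,
    make_ps_blob,
)


def _simple_topology(n, mass=12.011):
    return Topology(
        names=[f"C{i + 1}" for i in range(n)],
        elements=["C"] * n,
        masses=[mass] * n,
        resids=[1] * n,
        resnames=["X"] * n,
        molecules=[np.arange(n)],
    )


class TestOrderParameters:
    def test_perpendicular_ch_gives_half(self):
        top, frames, gt = make_flat_bilayer(16, ch_angle_deg=90.0)
        sel = LipidSelection.from_topology(top)
        prof = order_parameters(frames, sel)
        for ch in prof.values:
            assert np.allclose(prof.values[ch], 0.5, atol=1e-12)

    def test_magic_angle_vanishes(self):
        top, frames, gt = make_flat_bilayer(16, ch_angle_deg=np.degrees(np.arccos(1 / np.sqrt(3))))
        sel = LipidSelection.from_topology(top)
        prof = order_parameters(frames, sel)
        for ch in prof.values:
            assert np.all(prof.values[ch] <= 1e-6)

    @given(angle=st.floats(0.0, 180.0))
    @settings(max_examples=20, deadline=None)
    def test_matches_closed_form_and_bounds(self, angle):
        top, frames, gt = make_flat_bilayer(4, ch_angle_deg=angle)
        sel = LipidSelection.from_topology(top)
        prof = order_parameters(frames, sel)
        c = np.cos(np.radians(angle))
        expected = abs(1.5 * c * c - 0.5)
        for ch in prof.values:
            assert np.all(np.abs(prof.values[ch] - expected) < 1e-9)
            assert np.all(prof.values[ch] <= 1.0 + 1e-12)

    def test_planted_distribution_matches_direct_average(self, rng):
        # oracle: direct numeric average of (3 cos^2 - 1)/2 over the same bonds
        top, frames, gt = make_flat_bilayer(9, jitter=0.04, n_frames=5, seed=3)
        sel = LipidSelection.from_topology(top)
        prof = order_parameters(frames, sel)
        samples = {ch: [[] for _ in sel.acyl[0][ch]] for ch in sel.chain_names}
        for fr in frames:
            for acyl in sel.acyl:
                for ch, pairs in acyl.items():
                    for k, (c_idx, h_idx) in enumerate(pairs):
                        for h in h_idx:
                            d = fr.positions[h] - fr.positions[c_idx]
                            cos = d[2] / np.linalg.norm(d)
                            samples[ch][k].append(1.5 * cos**2 - 0.5)
        for ch in samples:
            direct = np.abs([np.mean(s) for s in samples[ch]])
            assert np.allclose(prof.values[ch], direct, atol=1e-12)

    def test_missing_hydrogen_error(self):
        top, frames, gt = make_flat_bilayer(4)
        sel = LipidSelection.from_topology(top)
        sel.acyl[0]["A"][0] = (sel.acyl[0]["A"][0][0], [])
        with pytest.raises(SelectionError, match="no bonded hydrogen"):
            order_parameters(frames, sel)


class TestMassDensity:
    def test_uniform_slab(self):
        ptop, pframes, gt = make_flat_bilayer(16, thickness=1.0, cell_kind="rectangular")
        cell = pframes[0].cell
        mid = gt.extras["mid_z"]
        n = 4000
        rng = np.random.default_rng(0)
        width = 4.0
        z = rng.uniform(mid - width / 2, mid + width / 2, n)
        xy = rng.uniform(0, cell.vectors[0, 0], (n, 2))
        pos = np.column_stack([xy, z])
        top = Topology([f"C{i}" for i in range(n)], ["C"] * n, [12.011] * n,
                       [1] * n, ["SLB"] * n, [np.arange(n)])
        sys_top, sys_frames = combine_systems(ptop, pframes, top, [Frame(0.0, pos, cell)])
        sel = LipidSelection.from_topology(sys_top)
        group = {"slab": np.arange(ptop.n_atoms, sys_top.n_atoms)}
        prof = mass_density_profile(sys_frames, sys_top, group, sel, bin_width=0.25)
        total_mass_g = n * 12.011 / 6.02214076e23
        area = cell.cross_area
        expected = total_mass_g / (area * width * 1e-21)
        # integral recovers the group mass regardless of shape
        integral = prof.densities["slab"].sum() * prof.bin_width * area * 1e-21
        assert integral == pytest.approx(total_mass_g, rel=1e-9)
        inner = prof.densities["slab"][np.abs(prof.bin_centers) < width / 2 - 0.3]
        assert np.all(np.abs(inner - expected) / expected < 0.15)

    def test_gaussian_group_matches_analytic(self, rng):
        top, frames, gt = make_flat_bilayer(16, cell_kind="rectangular")
        cell = frames[0].cell
        mid = gt.extras["mid_z"]
        n = 20000
        z = rng.normal(mid, 0.5, n)
        pos = np.column_stack([rng.uniform(0, 3, (n, 2)), z])
        gtop = Topology([f"C{i}" for i in range(n)], ["C"] * n, [12.011] * n,
                        [1] * n, ["GAU"] * n, [np.arange(n)])
        sys_top, sys_frames = combine_systems(top, frames, gtop, [Frame(0.0, pos, cell)])
        sel = LipidSelection.from_topology(sys_top)
        prof = mass_density_profile(
            sys_frames, sys_top, {"g": np.arange(top.n_atoms, sys_top.n_atoms)},
            sel, bin_width=0.2,
        )
        area = cell.cross_area
        m_atom = 12.011 / 6.02214076e23
        from scipy.stats import norm

        expected = (
            n * m_atom
            * (norm.cdf((prof.bin_centers + 0.1) / 0.5) - norm.cdf((prof.bin_centers - 0.1) / 0.5))
            / (area * 0.2 * 1e-21)
        )
        err = np.abs(prof.densities["g"] - expected).max() / expected.max()
        assert err < 0.05

    def test_bad_bin_width(self):
        top, frames, gt = make_flat_bilayer(16)
        sel = LipidSelection.from_topology(top)
        with pytest.raises(ValueError):
            mass_density_profile(frames, top, {"a": [0]}, sel, bin_width=0.0)
        with pytest.raises(ValueError):
            mass_density_profile(frames, top, {}, sel)


class TestRg:
    def test_two_equal_masses(self):
        cell = TriclinicCell.cubic(10.0)
        top = _simple_topology(2)
        d = 1.4
        frame = Frame(0.0, np.array([[5 - d / 2, 5, 5], [5 + d / 2, 5, 5]]), cell)
        rg = radius_of_gyration([frame], top, np.array([0, 1]))
        assert rg[0] == pytest.approx(d / 2, abs=1e-12)

    def test_single_atom_zero(self):
        cell = TriclinicCell.cubic(10.0)
        top = _simple_topology(1)
        rg = radius_of_gyration([Frame(0.0, np.array([[1.0, 2, 3]]), cell)], top, [0])
        assert rg[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        cell = TriclinicCell.cubic(50.0)  # big box: no wrapping effects
        n = 100
        masses = rng.uniform(1, 20, n)
        top = Topology([f"C{i}" for i in range(n)], ["C"] * n, masses,
                       [1] * n, ["X"] * n, [np.arange(n)])
        pos = 25 + rng.normal(0, 1.5, (n, 3))
        rg = radius_of_gyration([Frame(0.0, pos, cell)], top, np.arange(n))
        com = np.average(pos, axis=0, weights=masses)
        direct = np.sqrt(np.average(np.sum((pos - com) ** 2, axis=1), weights=masses))
        assert rg[0] == pytest.approx(direct, abs=1e-12)

    def test_invariant_under_lattice_translation(self, rng):
        cell = TriclinicCell.hexagonal(9.0, 9.0)
        n = 30
        top = _simple_topology(n)
        pos = cell.to_cartesian(np.array([0.5, 0.5, 0.5])) + rng.normal(0, 0.8, (n, 3))
        rg0 = radius_of_gyration([Frame(0.0, pos, cell)], top, np.arange(n))[0]
        shifted = pos.copy()
        shifted[::2] += cell.vectors[0] + 2 * cell.vectors[2]
        rg1 = radius_of_gyration([Frame(0.0, shifted, cell)], top, np.arange(n))[0]
        assert rg1 == pytest.approx(rg0, abs=1e-10)

    def test_zero_mass_error(self):
        cell = TriclinicCell.cubic(5.0)
        top = _simple_topology(2)
        frame = Frame(0.0, np.zeros((2, 3)), cell)
        with pytest.raises(ValueError):
            radius_of_gyration([frame], top, np.array([], dtype=int))


class TestEndToEnd:
    def test_straight_chain(self):
        cell = TriclinicCell.cubic(10.0)
        pos = np.array([[1, 1, 1], [1.15, 1, 1], [1.30, 1, 1]], dtype=float)
        dee = end_to_end([Frame(0.0, pos, cell)], [(0, 2)])
        assert dee[0, 0] == pytest.approx(0.30, abs=1e-12)

    def test_coincident_ends(self):
        cell = TriclinicCell.cubic(10.0)
        pos = np.array([[1, 1, 1], [2, 2, 2], [1, 1, 1]], dtype=float)
        dee = end_to_end([Frame(0.0, pos, cell)], [(0, 2)])
        assert dee[0, 0] == 0.0

    def test_matches_min_image(self, rng):
        cell = TriclinicCell.hexagonal(7.0, 6.0)
        pos = rng.uniform(-10, 10, (10, 3))
        dee = end_to_end([Frame(0.0, pos, cell)], [(2, 9)])
        expected = np.linalg.norm(minimum_image_displacement(pos[2], pos[9], cell))
        assert dee[0, 0] == pytest.approx(expected, abs=1e-12)


class TestComTrajectory:
    @staticmethod
    def _combined(n_frames=1, com_z=None, seed=0):
        topb, frb, gtb = make_flat_bilayer(36, n_frames=n_frames, seed=seed)
        mid = gtb.extras["mid_z"]
        topp, frp, gtp = make_ps_blob(
            n_chains=2, units_per_chain=6, n_frames=n_frames,
            com_z=(mid + com_z[0], mid + com_z[1]) if com_z else mid + 2.0,
            cell=frb[0].cell, seed=seed,
        )
        top, frames = combine_systems(topb, frb, topp, frp)
        sel = LipidSelection.from_topology(top)
        asgs = assign_leaflets_trajectory(frames, sel)
        return top, frames, sel, asgs

    def test_rigid_shift_equivariance(self):
        top, frames, sel, asgs = self._combined()
        group = top.select_resname("PS")
        ct = com_trajectory(frames, top, group, sel, asgs)
        pos = frames[0].positions.copy()
        pos[group, 2] += 1.0
        ct2 = com_trajectory([Frame(0.0, pos, frames[0].cell)], top, group, sel, asgs)
        assert ct2.com_z[0] == pytest.approx(ct.com_z[0] + 1.0, abs=1e-9)

    def test_leaflet_levels_symmetric(self):
        top, frames, sel, asgs = self._combined()
        ct = com_trajectory(frames, top, top.select_resname("PS"), sel, asgs)
        assert ct.upper_z[0] == pytest.approx(3.93 / 2, abs=1e-9)
        assert ct.lower_z[0] == pytest.approx(-3.93 / 2, abs=1e-9)

    def test_planted_drift_recovery(self):
        top, frames, sel, asgs = self._combined(n_frames=180, com_z=(4.0, 0.0))
        ct = com_trajectory(frames, top, top.select_resname("PS"), sel, asgs)
        slope = np.polyfit(ct.times, ct.com_z, 1)[0]
        expected = -4.0 / 179.0
        assert abs(slope - expected) / abs(expected) < 0.01
        assert ct.com_z[0] == pytest.approx(4.0, abs=1e-9)
        assert ct.com_z[-1] == pytest.approx(0.0, abs=1e-9)


class TestMakeWhole:
    def test_wrapped_group_restored(self, rng):
        cell = TriclinicCell.cubic(6.0)
        base = np.array([3.0, 3.0, 3.0]) + rng.normal(0, 0.4, (12, 3))
        wrapped = base.copy()
        wrapped[5] += cell.vectors[0]
        wrapped[8] -= cell.vectors[1] + cell.vectors[2]
        whole = make_whole(wrapped, np.arange(12), cell)
        assert np.allclose(whole, base, atol=1e-10)
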