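"""Structural observables against independent oracles and closed forms."""

import numpy as np
import pytest

import dacnc as D
from dacnc import structure_analysis as sa
from dacnc.ibeta import place_by_internal

from conftest import make_frame


def brute_force_interchain_rdf(frame, pair_class, r_max, bin_width):
    """O(N²) reference for the interchain pair histogram, normalised the
    same way as the implementation."""
    e1, e2 = pair_class.split("-")
    el = frame.elements.astype(str)
    i1 = np.where(el == e1)[0]
    i2 = np.where(el == e2)[0]
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(len(edges) - 1)
    for a in i1:
        for b in i2:
            if frame.chain_ids[a] == frame.chain_ids[b]:
                continue
            d = np.linalg.norm(frame.positions[a] - frame.positions[b])
            if d < edges[-1]:
                counts[np.searchsorted(edges, d, side="right") - 1] += 1
    rho2 = len(i2) / frame.bounding_volume()
    shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return counts / (len(i1) * rho2 * shell)


class TestInterchainRdf:
    @pytest.mark.parametrize("pair_class", sa.PAIR_CLASSES)
    def test_matches_brute_force(self, small_crystal, pair_class):
        frame = small_crystal.to_frame()
        prof = sa.interchain_rdf(frame, pair_class, r_max=1.5, bin_width=0.05)
        ref = brute_force_interchain_rdf(frame, pair_class, 1.5, 0.05)
        np.testing.assert_allclose(prof.g, ref, rtol=1e-10, atol=1e-12)

    def test_single_chain_excluded_entirely(self, single_chain):
        prof = sa.interchain_rdf(single_chain.to_frame(), "C-O")
        assert np.all(prof.g == 0)

    def test_two_atom_single_bin_closed_form(self):
        d = 0.525
        frame = make_frame(["C1", "O1"], [[0, 0, 0], [d, 0, 0]],
                           chain_ids=[0, 1], box=[4.0, 4.0, 4.0])
        bw = 0.05
        prof = sa.interchain_rdf(frame, "C-O", r_max=1.0, bin_width=bw)
        k = int(d / bw)
        rho = 1 / 64.0
        shell = 4 / 3 * np.pi * ((bw * (k + 1)) ** 3 - (bw * k) ** 3)
        expected = 1.0 / (1 * rho * shell)
        assert prof.g[k] == pytest.approx(expected, rel=1e-12)
        assert np.count_nonzero(prof.g) == 1

    def test_bad_inputs_rejected(self, small_crystal):
        frame = small_crystal.to_frame()
        with pytest.raises(ValueError, match="pair class"):
            sa.interchain_rdf(frame, "N-O")
        with pytest.raises(ValueError, match="bin_width"):
            sa.interchain_rdf(frame, "C-O", bin_width=0.0)


class TestStructureFactor:
    def test_ideal_gas_limit(self):
        r = np.arange(0.01, 2.0, 0.02)
        prof = sa.RDFProfile("C-O", r, np.ones_like(r), density=10.0,
                             n_reference=100, bin_width=0.02)
        sq = sa.structure_factor(prof, window="none")
        np.testing.assert_allclose(sq.s, 1.0, atol=1e-12)

    def test_two_atom_debye_closed_form(self):
        # dilute two-atom system: S(q) = 1 + sin(qd)/(qd)
        bw = 0.004
        d = bw * 75.5   # centre of bin 75
        frame = make_frame(["C1", "O1"], [[0, 0, 0], [d, 0, 0]],
                           chain_ids=[0, 1], box=[50.0, 50.0, 50.0])
        prof = sa.interchain_rdf(frame, "C-O", r_max=0.5, bin_width=bw)
        sq = sa.structure_factor(prof, window="none")
        expected = 1.0 + np.sin(sq.q * d) / (sq.q * d)
        np.testing.assert_allclose(sq.s, expected, atol=2e-3)

    def test_mismatched_grids_rejected(self):
        r1 = np.arange(0.01, 1.0, 0.02)
        r2 = np.arange(0.01, 1.2, 0.02)
        p1 = sa.RDFProfile("C-O", r1, np.ones_like(r1), 1.0, 10, 0.02)
        p2 = sa.RDFProfile("C-H", r2, np.ones_like(r2), 1.0, 10, 0.02)
        with pytest.raises(ValueError, match="same r grid"):
            sa.structure_factor([p1, p2])

    def test_peak_positions_insensitive_to_window(self, small_crystal):
        frame = small_crystal.to_frame()
        profs = [sa.interchain_rdf(frame, pc, r_max=1.5)
                 for pc in sa.PAIR_CLASSES]
        q_pairs = []
        for window in ("lorch", "none"):
            sq = sa.structure_factor(profs, window=window)
            peaks = sa.find_peaks(sq, 0.05, q_range=(12, 20))
            assert peaks
            q_pairs.append(peaks[0].q)
        assert abs(q_pairs[0] - q_pairs[1]) < 0.5

    def test_peak_positions_insensitive_to_class_weighting(self, small_crystal):
        # X-ray-style weights suppress the hydrogen classes; the reflection
        # positions must not depend on that choice
        frame = small_crystal.to_frame()
        profs = [sa.interchain_rdf(frame, pc, r_max=1.5)
                 for pc in sa.PAIR_CLASSES]
        f = {"C": 6.0, "O": 8.0, "H": 1.0}
        w = np.array([f[p.pair_class[0]] * f[p.pair_class[-1]] for p in profs])
        positions = []
        for weights in (None, tuple(w / w.sum())):
            sq = sa.structure_factor(profs, weights=weights)
            peaks = sa.find_peaks(sq, 0.05, q_range=(14, 20))
            assert peaks
            positions.append(peaks[0].q)
        assert abs(positions[0] - positions[1]) < 0.5


class TestFindPeaks:
    def test_two_gaussian_centres_recovered(self):
        q = np.arange(1.0, 30.0, 0.05)
        s = (1.0 + 0.8 * np.exp(-((q - 13.0) / 0.8) ** 2)
             + 1.2 * np.exp(-((q - 16.2) / 0.7) ** 2))
        prof = sa.StructureFactorProfile(q, s, "none", (1.0,))
        peaks = sa.find_peaks(prof, min_prominence=0.1)
        assert len(peaks) == 2
        assert peaks[0].q == pytest.approx(16.2, abs=0.05)
        assert peaks[1].q == pytest.approx(13.0, abs=0.05)

    def test_flat_profile_empty(self):
        q = np.arange(1.0, 10.0, 0.05)
        prof = sa.StructureFactorProfile(q, np.ones_like(q), "none", (1.0,))
        assert sa.find_peaks(prof, 0.01) == []


class TestHbonds:
    def _water(self, o, direction):
        """3-site water: O at ``o``, one H along ``direction``."""
        direction = np.asarray(direction, dtype=float)
        direction /= np.linalg.norm(direction)
        h1 = o + 0.09572 * direction
        # second H out of the O..A line
        perp = np.cross(direction, [0, 0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(direction, [0, 1.0, 0])
        perp /= np.linalg.norm(perp)
        h2 = o + 0.09572 * (np.cos(np.deg2rad(104.5)) * direction
                            + np.sin(np.deg2rad(104.5)) * perp)
        return [o, h1, h2]

    def _two_waters(self, separation):
        o1 = np.zeros(3)
        o2 = np.array([separation, 0.0, 0.0])
        pos = self._water(o1, [1, 0, 0]) + self._water(o2, [1, 0, 0])
        return make_frame(["OW", "HW1", "HW2"] * 2, pos,
                          chain_ids=[0, 0, 0, 1, 1, 1],
                          resids=[1, 1, 1, 2, 2, 2],
                          resnames=["SOL"] * 6)

    def test_aligned_pair_at_028_gives_one_bond(self):
        frame = self._two_waters(0.28)
        res = sa.detect_hbonds(frame, "water", "water")
        assert res.count == 1

    def test_beyond_cutoff_gives_zero(self):
        frame = self._two_waters(0.40)
        assert sa.detect_hbonds(frame, "water", "water").count == 0

    def test_group_without_hydrogens_rejected(self):
        frame = make_frame(["O1", "O2"], [[0, 0, 0], [0.3, 0, 0]],
                           chain_ids=[0, 1])
        with pytest.raises(ValueError, match="no O-H hydrogens"):
            sa.detect_hbonds(frame, np.array([True, True]),
                             np.array([True, True]))

    def test_crystal_count_per_glucose(self, small_crystal):
        res = sa.detect_hbonds(small_crystal.to_frame())
        # two intrachain bonds per interior linkage + interchain sheet bonds
        assert res.per_glucose == pytest.approx(2.2, abs=0.8)

    def test_same_residue_exclusion_toggle(self, small_crystal):
        frame = small_crystal.to_frame()
        strict = sa.detect_hbonds(frame, exclude_same_residue=True)
        loose = sa.detect_hbonds(frame, exclude_same_residue=False)
        assert loose.count >= strict.count


class TestTorsions:
    def test_trans_planar_linkage_is_180(self):
        # synthetic linkage: C4-O4 in residue 1, C1-O5 (+C5 on residue 1)
        pos = {
            "C5": [-0.1, 0.1, 0.0],
            "C4": [0.0, 0.0, 0.0],
            "O4": [0.14, 0.0, 0.0],
            "C1": [0.21, 0.12, 0.0],
            "O5": [0.35, 0.12, 0.0],
        }
        frame = make_frame(
            ["C5", "C4", "O4", "C1", "O5"],
            [pos[k] for k in ("C5", "C4", "O4", "C1", "O5")],
            resids=[1, 1, 1, 2, 2], resnames=["BGC"] * 5)
        tors = sa.glycosidic_torsions(frame)
        assert abs(tors.phi[0]) == pytest.approx(180.0, abs=1e-6)

    def test_programmed_dihedral_recovered(self):
        c5 = np.array([-0.1, 0.12, 0.03])
        c4 = np.array([0.0, 0.0, 0.0])
        o4 = np.array([0.143, 0.0, 0.0])
        c1 = place_by_internal(o4, c4, c5, 0.143, 116.0, -100.0)
        o5 = place_by_internal(c1, o4, c4, 0.143, 108.0, 60.0)
        frame = make_frame(["C5", "C4", "O4", "C1", "O5"],
                           [c5, c4, o4, c1, o5],
                           resids=[1, 1, 1, 2, 2], resnames=["BGC"] * 5)
        tors = sa.glycosidic_torsions(frame)
        assert tors.phi[0] == pytest.approx(60.0, abs=1e-6)
        assert tors.psi[0] == pytest.approx(-100.0, abs=1e-6)

    def test_built_crystal_torsions_unimodal_negative(self, small_crystal):
        tors = sa.glycosidic_torsions(small_crystal.to_frame())
        for vals in (tors.phi, tors.psi):
            assert np.all((-180.0 < vals) & (vals < 0.0))
            assert np.std(vals) < 5.0    # a single sharp mode
        centers, hist = tors.histogram("phi")
        assert hist.sum() * tors.bin_width == pytest.approx(1.0)

    def test_linkages_span_modified_units(self, single_chain):
        out = D.apply_dialcohol_modification(single_chain, [0],
                                             D.ModificationPattern.A, phase=0)
        tors = sa.glycosidic_torsions(out.to_frame())
        assert len(tors.phi) == 1


class TestWaterShellAndSasa:
    def test_no_water_warns_empty(self, single_chain):
        with pytest.warns(UserWarning, match="no water"):
            shell = sa.water_shell(single_chain.to_frame())
        assert shell.n_waters == 0

    def test_distance_threshold_selects_correct_molecule(self):
        names = ["C1", "OW", "HW1", "HW2", "OW", "HW1", "HW2"]
        pos = [[0, 0, 0],
               [0.5, 0, 0], [0.55, 0, 0.07], [0.55, 0, -0.07],
               [0.8, 0, 0], [0.85, 0, 0.07], [0.85, 0, -0.07]]
        frame = make_frame(names, pos, chain_ids=[0, 1, 1, 1, 1, 1, 1],
                           resids=[1, 1, 1, 1, 2, 2, 2],
                           resnames=["BGC"] + ["SOL"] * 6)
        shell = sa.water_shell(frame, cutoff=0.6)
        assert shell.n_waters == 1

    def test_shell_nesting_monotone(self, small_crystal):
        frame = D.place_water_shell(small_crystal, 0.6, 20.0, seed=1)
        n_small = sa.water_shell(frame, cutoff=0.3).n_waters
        n_large = sa.water_shell(frame, cutoff=0.6).n_waters
        assert n_large >= n_small

    def test_single_carbon_analytic_area(self):
        frame = make_frame(["C1"], [[0.0, 0.0, 0.0]])
        area = sa.sasa(frame, probe_radius=0.14)
        assert area == pytest.approx(4 * np.pi * 0.31**2, rel=1e-12)

    def test_overlapping_spheres_degenerate_to_one(self):
        frame = make_frame(["C1", "C2"], [[0, 0, 0], [0, 0, 0]])
        area = sa.sasa(frame)
        assert area == pytest.approx(4 * np.pi * 0.31**2, rel=0.01)

    def test_separated_spheres_sum(self):
        frame = make_frame(["C1", "O1"], [[0, 0, 0], [2.0, 0, 0]])
        expected = 4 * np.pi * (0.31**2 + (0.152 + 0.14) ** 2)
        assert sa.sasa(frame) == pytest.approx(expected, rel=1e-12)

    def test_unknown_element_rejected(self):
        frame = make_frame(["XX1"], [[0, 0, 0]])
        with pytest.raises(ValueError, match="radius"):
            sa.sasa(frame)

    def test_against_independent_shrake_rupley(self):
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(7)
        n = 30
        pos = rng.uniform(0, 1.0, (n, 3))
        names = ["C1" if i % 2 else "O1" for i in range(n)]
        frame = make_frame(names, pos)
        ours = sa.sasa(frame, n_sphere_points=960)
        top = mdtraj.Topology()
        ch = top.add_chain()
        res = top.add_residue("MOL", ch)
        for i, nm in enumerate(names):
            el = mdtraj.element.carbon if nm.startswith("C") else mdtraj.element.oxygen
            top.add_atom(f"{nm}{i}", el, res)
        traj = mdtraj.Trajectory(pos[None], top)
        ref = float(mdtraj.shrake_rupley(traj, probe_radius=0.14,
                                         n_sphere_points=960)[0].sum())
        assert ours == pytest.approx(ref, rel=0.02)


class TestRigidInvariance:
    def test_observables_invariant_under_rotation_translation(self, small_crystal):
        from scipy.spatial.transform import Rotation
        frame = small_crystal.to_frame()
        R = Rotation.from_euler("xyz", [1.0, 0.5, -0.8]).as_matrix()
        moved = frame.rotated(R).translated([2.0, -1.0, 4.0])
        moved.box = frame.box  # same nominal volume for identical RDF density

        hb0 = sa.detect_hbonds(frame).count
        hb1 = sa.detect_hbonds(moved).count
        assert hb0 == hb1

        t0 = sa.glycosidic_torsions(frame)
        t1 = sa.glycosidic_torsions(moved)
        np.testing.assert_allclose(t0.phi, t1.phi, atol=1e-8)

        a0 = sa.sasa(frame, n_sphere_points=960)
        a1 = sa.sasa(moved, n_sphere_points=960)
        assert a1 == pytest.approx(a0, rel=5e-3)   # quadrature reorientation

        p0 = sa.structure_factor([sa.interchain_rdf(frame, pc, r_max=1.2)
                                  for pc in sa.PAIR_CLASSES])
        p1 = sa.structure_factor([sa.interchain_rdf(moved, pc, r_max=1.2)
                                  for pc in sa.PAIR_CLASSES])
        np.testing.assert_allclose(p0.s, p1.s, atol=1e-8)
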