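import numpy as np
import pytest

from ansamer.core import Ensemble
from ansamer.ensemble_analysis import (
    amide_sasa,
    angle_distributions,
    backbone_dihedrals,
    classify_amide_exposure,
    classify_vt_slope,
    detect_hbonds,
    dihedral,
    filter_populations,
    hbond_cooccurrence,
    hbond_populations,
    rmsf,
    sasa,
)
from ansamer.errors import InputError
from ansamer.synth_fixtures import FixtureSpec, make_bridged_macrocycle, make_ensemble
from ansamer.topology import find_bridge, find_main_cycle, split_segments

from conftest import tiny_system


def _nho(o_position, with_h=True):
    coords = [[0, 0, 0], [1, 0, 0], list(o_position)]
    return tiny_system(
        coords, ["N", "H", "O"], names=["N", "H1", "O"], bonds=[(0, 1)]
    )


class TestDetectHbonds:
    def test_linear_geometry_detected(self):
        found = detect_hbonds(_nho([2.9, 0, 0]))
        assert found == {(0, 1, 2)}

    def test_far_acceptor_rejected(self):
        assert detect_hbonds(_nho([5.0, 0, 0])) == set()

    def test_bent_geometry_rejected(self):
        # D-H...A angle is 90 degrees by direct vector arithmetic
        system = _nho([1.0, 1.8, 0.0])
        v1 = np.array([0, 0, 0]) - np.array([1, 0, 0])
        v2 = np.array([1.0, 1.8, 0.0]) - np.array([1, 0, 0])
        angle = np.degrees(
            np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        assert angle == pytest.approx(90.0)
        assert detect_hbonds(system) == set()

    def test_implicit_amide_hydrogen_placement(self):
        # N bonded to two heavy atoms; implicit H points along the outward
        # bisector, toward an acceptor placed there.
        coords = [
            [0, 0, 0],      # N
            [-1.2, 0.9, 0],  # C' neighbor
            [-1.2, -0.9, 0],  # CA neighbor
            [2.9, 0, 0],    # O acceptor on the bisector
        ]
        system = tiny_system(
            coords, ["N", "C", "C", "O"], names=["N", "C", "CA", "O"],
            bonds=[(0, 1), (0, 2)],
        )
        found = detect_hbonds(system)
        assert found == {(0, -1, 3)}

    def test_no_donors_yields_empty_set(self):
        system = tiny_system([[0, 0, 0], [3, 0, 0]], ["C", "O"])
        assert detect_hbonds(system) == set()


def _engineered_ensemble():
    """Two isolated N-H/O pairs; pair 1 bonded in 11/100 frames, pair 2 in 10/100."""
    base = np.array(
        [
            [0, 0, 0], [1, 0, 0], [2.9, 0, 0],          # N1 H1 O1
            [50, 0, 0], [51, 0, 0], [52.9, 0, 0],       # N2 H2 O2
        ],
        float,
    )
    frames = np.repeat(base[None], 100, axis=0)
    frames[11:, 2, 0] = 20.0   # O1 far except in frames 0..10  -> pop 0.11
    frames[10:, 5, 0] = 70.0   # O2 far except in frames 0..9   -> pop 0.10
    system = tiny_system(
        frames,
        ["N", "H", "O", "N", "H", "O"],
        names=["N", "H1", "O", "N", "H1", "O"],
        resids=[1, 1, 1, 2, 2, 2],
        bonds=[(0, 1), (3, 4)],
    )
    return Ensemble(system=system)


class TestHbondPopulations:
    def test_strict_ten_percent_filter(self):
        records = hbond_populations(_engineered_ensemble())
        kept = {(r.donor, r.acceptor): r.population for r in records}
        assert kept == {(0, 2): pytest.approx(0.11)}

    def test_zero_threshold_keeps_everything(self):
        records = hbond_populations(_engineered_ensemble(), min_population=0.0)
        assert {(r.donor, r.acceptor) for r in records} == {(0, 2), (3, 5)}

    def test_filter_monotone_in_threshold(self):
        records = hbond_populations(_engineered_ensemble(), min_population=0.0)
        sizes = [
            len(filter_populations(records, t)) for t in (0.0, 0.05, 0.10, 0.11, 0.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_population_is_mean_presence(self):
        records = hbond_populations(_engineered_ensemble(), min_population=0.0)
        for r in records:
            assert r.population == pytest.approx(r.presence.mean())


class TestCooccurrence:
    def _records(self, bits_a, bits_b):
        from ansamer.ensemble_analysis import HBondRecord

        return [
            HBondRecord(0, 1, 2, np.array(bits_a, bool), float(np.mean(bits_a))),
            HBondRecord(3, 4, 5, np.array(bits_b, bool), float(np.mean(bits_b))),
        ]

    def test_identical_bits_correlate_plus_one(self):
        bits = [1, 0, 1, 1, 0, 0]
        matrix = hbond_cooccurrence(self._records(bits, bits))
        assert matrix[0, 1] == pytest.approx(1.0)

    def test_mutually_exclusive_bits_correlate_minus_one(self):
        a = [1, 0, 1, 0]
        b = [0, 1, 0, 1]
        matrix = hbond_cooccurrence(self._records(a, b))
        assert matrix[0, 1] == pytest.approx(-1.0)

    def test_independent_bits_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        matrix = hbond_cooccurrence(self._records(a, b))
        assert abs(matrix[0, 1]) < 0.1

    def test_zero_variance_bond_reported_missing(self):
        matrix = hbond_cooccurrence(self._records([1, 1, 1, 1], [1, 0, 1, 0]))
        assert np.isnan(matrix[0, 1]) and np.isnan(matrix[0, 0])
        assert matrix[1, 1] == pytest.approx(1.0)


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        area = sasa(np.zeros((1, 3)), ["C"])
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area[0] == pytest.approx(analytic, rel=0.02)

    def test_caged_atom_is_buried(self):
        center = np.zeros((1, 3))
        cage = 2.0 * np.concatenate([np.eye(3), -np.eye(3)])
        coords = np.concatenate([center, cage])
        areas = sasa(coords, ["C"] * 7)
        assert areas[0] == 0.0

    def test_two_sphere_overlap_matches_cap_formula(self):
        d = 2.0
        coords = np.array([[0, 0, 0], [d, 0, 0]], float)
        areas = sasa(coords, ["C", "C"])
        r = 1.7 + 1.4
        cap = 2 * np.pi * r * (r - d / 2)
        analytic = 2 * (4 * np.pi * r**2 - cap)
        assert areas.sum() == pytest.approx(analytic, rel=0.02)

    def test_convergence_in_sphere_points(self):
        coarse = sasa(np.zeros((1, 3)), ["C"], n_sphere_points=960)[0]
        fine = sasa(np.zeros((1, 3)), ["C"], n_sphere_points=1920)[0]
        assert abs(fine - coarse) / fine < 0.005

    def test_unknown_element_named(self):
        with pytest.raises(Exception, match="Xq"):
            sasa(np.zeros((1, 3)), ["Xq"])

    def test_amide_exposure_pipeline(self):
        ensemble = make_ensemble(
            FixtureSpec(n_residues=6, bridge_span=(2, 5)), n_frames=2, noise=0.0, seed=0
        )
        exposures = amide_sasa(ensemble, n_sphere_points=120)
        assert [e.residue for e in exposures] == [1, 2, 3, 4, 5, 6]
        assert all(e.exposure_class == "exposed" for e in exposures)  # bare ring N


class TestClassifiers:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.01, "shielded"), (0.03, "intermediate"), (0.05, "exposed")],
    )
    def test_sasa_classes(self, value, expected):
        assert classify_amide_exposure(value) == expected

    def test_negative_sasa_rejected(self):
        with pytest.raises(InputError):
            classify_amide_exposure(-0.01)

    @pytest.mark.parametrize(
        "slope,expected",
        [(-2.5, "H-bonded"), (-4.0, "weak"), (-5.0, "exposed")],
    )
    def test_vt_slope_classes(self, slope, expected):
        assert classify_vt_slope(slope) == expected

    def test_boundaries_are_strict(self):
        assert classify_amide_exposure(0.02) == "intermediate"
        assert classify_amide_exposure(0.04) == "intermediate"
        assert classify_vt_slope(-3.0) == "weak"
        assert classify_vt_slope(-4.6) == "weak"


class TestDihedrals:
    def test_trans_and_cis_reference_geometries(self):
        trans = dihedral([0, 1, 0], [0, 0, 0], [1.5, 0, 0], [1.5, -1, 0])
        cis = dihedral([0, 1, 0], [0, 0, 0], [1.5, 0, 0], [1.5, 1, 0])
        assert abs(trans) == pytest.approx(180.0)
        assert cis == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("target", [60.0, -60.0, 35.0, -145.0])
    def test_constructed_torsion_matches_mdanalysis(self, target):
        from MDAnalysis.lib.distances import calc_dihedrals

        chi = np.radians(target)
        p0 = np.array([-0.5, 1.0, 0.0])
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([1.5, 0.0, 0.0])
        p3 = p2 + np.array([0.5, np.cos(chi), np.sin(chi)])
        mine = dihedral(p0, p1, p2, p3)
        oracle = np.degrees(
            calc_dihedrals(
                p0[None].astype(np.float32),
                p1[None].astype(np.float32),
                p2[None].astype(np.float32),
                p3[None].astype(np.float32),
            )[0]
        )
        assert mine == pytest.approx(float(oracle), abs=1e-3)

    def test_cyclic_backbone_records_all_residues(self, octapeptide):
        records = backbone_dihedrals(octapeptide)
        assert [r.residue for r in records] == list(range(1, 9))
        for r in records:
            assert -180.0 < r.phi <= 180.0
            assert -180.0 < r.psi <= 180.0
            assert r.omega_class in ("cis", "trans")
            assert (abs(r.omega) <= 90.0) == (r.omega_class == "cis")


class TestAngleDistributions:
    def _parts(self, ensemble):
        cycle = find_main_cycle(ensemble.system)
        bridge = find_bridge(ensemble.system, cycle)
        seg_a, seg_b = split_segments(cycle, bridge)
        return seg_a, seg_b, bridge

    def test_identical_frames_concentrate_in_one_bin(self):
        ensemble = make_ensemble(FixtureSpec(), n_frames=4, noise=0.0, seed=0)
        seg_a, seg_b, bridge = self._parts(ensemble)
        dists, _ = angle_distributions(ensemble, seg_a, seg_b, bridge)
        ab = dists["theta_AB"]
        assert ab.frequencies[0] == pytest.approx(1.0)
        assert ab.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_noisy_ensemble_mean_near_noiseless_angles(self):
        spec = FixtureSpec()
        ensemble = make_ensemble(spec, n_frames=200, noise=0.05, seed=8)
        seg_a, seg_b, bridge = self._parts(ensemble)
        _, triples = angle_distributions(ensemble, seg_a, seg_b, bridge)
        from ansamer.geometry import angle_triple

        clean = angle_triple(
            make_bridged_macrocycle(spec).model(0), seg_a, seg_b, bridge
        )
        means = np.mean([t.as_tuple() for t in triples], axis=0)
        np.testing.assert_allclose(means, clean.as_tuple(), atol=2.0)

    def test_normalization_with_no_skipped_frames(self):
        ensemble = make_ensemble(FixtureSpec(), n_frames=30, noise=0.1, seed=2)
        seg_a, seg_b, bridge = self._parts(ensemble)
        dists, _ = angle_distributions(ensemble, seg_a, seg_b, bridge)
        for d in dists.values():
            assert d.n_frames_skipped == 0
            assert d.frequencies.sum() == pytest.approx(1.0, abs=1e-12)


class TestRmsf:
    def test_identical_frames_zero(self):
        ensemble = make_ensemble(
            FixtureSpec(), n_frames=5, noise=0.0, seed=0, rigid_motion=True
        )
        assert np.allclose(rmsf(ensemble), 0.0, atol=1e-9)

    def test_single_frame_rejected(self, amatoxin):
        with pytest.raises(InputError):
            rmsf(Ensemble(system=amatoxin))

    def test_single_jittered_atom_closed_form(self, amatoxin):
        d = 0.5
        frames = np.repeat(amatoxin.coords, 10, axis=0)
        frames[::2, 0, 0] += d
        frames[1::2, 0, 0] -= d
        ensemble = Ensemble(system=amatoxin.with_coords(frames))
        # no fitting: frames differ only in one atom, fit on static atoms
        values = rmsf(ensemble, fit_selection=np.arange(1, amatoxin.n_atoms))
        assert values[0] == pytest.approx(d, rel=1e-6)
        assert np.all(values[1:] < 1e-9)

    def test_gaussian_jitter_matches_sigma_sqrt3(self):
        sigma = 0.1
        ensemble = make_ensemble(
            FixtureSpec(n_residues=12, bridge_span=(4, 10)),
            n_frames=2000,
            noise=sigma,
            seed=17,
        )
        mean_rmsf = float(np.mean(rmsf(ensemble)))
        assert mean_rmsf == pytest.approx(sigma * np.sqrt(3.0), rel=0.05)
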