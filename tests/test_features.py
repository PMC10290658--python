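"""Feature stack: active geometry, hydration, strand statistics, contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hybridsheet.features import (
    FeatureError,
    active_geometry,
    assign_secondary_structure,
    beta3_fraction,
    count_catalytic_waters,
    extract_features,
    gap_width,
    s2_contacts,
    water_residence_times,
)
from hybridsheet.structio import AtomRecord, ResidueSelector, Structure, Trajectory
from hybridsheet.synthetic import (
    fixture_catalytic_spec,
    make_active_site_fixture,
    make_beta_sheet_fixture,
    make_helix_fixture,
)


class TestActiveGeometry:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [(2.0, 5.0, True), (2.6, 5.0, False), (2.0, 6.0, False), (2.5, 5.0, False)],
    )
    def test_strict_thresholds(self, spec, d1, d2, expected):
        frame = make_active_site_fixture(d1, d2)
        geo = active_geometry(frame, spec)
        assert geo.d1 == pytest.approx(d1, abs=0.01)
        assert geo.d2 == pytest.approx(d2, abs=0.01)
        assert geo.is_active is expected

    def test_monotone_in_both_distances(self, spec, rng):
        # shrinking either distance never deactivates an active geometry
        for _ in range(10):
            d1 = rng.uniform(1.2, 3.5)
            d2 = rng.uniform(max(d1, 4.0), 7.0)
            base = active_geometry(make_active_site_fixture(d1, d2), spec)
            tighter = active_geometry(
                make_active_site_fixture(max(d1 - 0.5, 1.1), max(d2 - 0.5, d1, 1.2)), spec
            )
            if base.is_active:
                assert tighter.is_active

    def test_heavy_atom_fallback_flagged(self, spec):
        frame = make_active_site_fixture(2.0, 5.0)
        frame = Structure(
            atoms=[a for a in frame.atoms if a.atom_name != "HD2"], title=frame.title
        )
        geo = active_geometry(frame, spec)
        assert geo.used_heavy_atom_fallback
        # fallback distance is carboxyl-O to carbonyl-O: d1 + the 0.98 Å O–H bond
        assert geo.d1 == pytest.approx(2.98, abs=0.01)

    def test_missing_cg_is_an_error(self, spec):
        frame = make_active_site_fixture(2.0, 5.0)
        frame = Structure(
            atoms=[
                a
                for a in frame.atoms
                if not (a.residue_number == 257 and a.atom_name == "CG")
            ]
        )
        with pytest.raises(FeatureError, match="Cγ"):
            active_geometry(frame, spec)


class TestWaters:
    def test_no_waters(self, spec):
        assert count_catalytic_waters(make_active_site_fixture(2.0, 5.0, 0), spec) == 0

    def test_planted_count(self, spec):
        assert count_catalytic_waters(make_active_site_fixture(3.0, 5.0, 5), spec) == 5

    def test_matches_brute_force_on_uniform_waters(self, spec, rng):
        frame = make_active_site_fixture(2.0, 5.0, 0)
        atoms = list(frame.atoms)
        centers = rng.uniform(-12, 12, (200, 3))
        for i, c in enumerate(centers):
            for name, off in (("O", [0, 0, 0]), ("H1", [0.96, 0, 0]), ("H2", [-0.24, 0.93, 0])):
                atoms.append(
                    AtomRecord(name, name[0], 2000 + i, "HOH", "W", c + off, hetatm=True)
                )
        frame = Structure(atoms=atoms)
        dyad = np.array(
            [a.position for a in frame.atoms
             if a.residue_name == "ASP" and a.residue_number in (257, 385)]
        )
        expected = 0
        for i in range(200):
            w = np.array([a.position for a in frame.atoms if a.residue_number == 2000 + i])
            if min(np.linalg.norm(p - q) for p in w for q in dyad) < 5.0:
                expected += 1
        assert count_catalytic_waters(frame, spec) == expected

    def test_rigid_motion_invariance(self, spec, rng):
        frame = make_active_site_fixture(2.0, 5.0, 4)
        n = count_catalytic_waters(frame, spec)
        rot = Rotation.random(random_state=7).as_matrix()
        shift = rng.uniform(-20, 20, 3)
        moved = frame.with_coordinates(frame.coordinates @ rot.T + shift)
        assert count_catalytic_waters(moved, spec) == n


class TestResidenceTimes:
    def _trajectory_from_pattern(self, pattern, timestep=1.0):
        """One water shuttled in/out of the shell following a 0/1 pattern."""
        base = make_active_site_fixture(2.0, 5.0, 1)
        xyz = base.coordinates
        w_idx = [i for i, a in enumerate(base.atoms) if a.residue_name == "HOH"]
        frames = []
        for inside in pattern:
            f = xyz.copy()
            if not inside:
                f[w_idx] += 100.0
            frames.append(f)
        return Trajectory(topology=base, frames=frames, timestep=timestep)

    def test_run_length_pattern(self, spec):
        traj = self._trajectory_from_pattern([0, 0, 1, 1, 1, 0])
        dwells = water_residence_times(traj, spec)
        assert list(dwells.values()) == [[3.0]]

    def test_never_inside(self, spec):
        traj = self._trajectory_from_pattern([0, 0, 0])
        assert list(water_residence_times(traj, spec).values()) == [[]]

    def test_matches_rle_oracle_and_duration_bound(self, spec, rng):
        pattern = rng.integers(0, 2, 40)
        traj = self._trajectory_from_pattern(pattern, timestep=0.5)
        dwells = list(water_residence_times(traj, spec).values())[0]
        # brute-force run-length encoding
        expected, run = [], 0
        for p in pattern:
            if p:
                run += 1
            elif run:
                expected.append(run * 0.5)
                run = 0
        if run:
            expected.append(run * 0.5)
        assert dwells == expected
        assert sum(dwells) <= traj.duration + 1e-12


class TestGapWidth:
    def test_explicit_distance(self, spec):
        atoms = []
        for resnum, pos in ((380, [0.0, 0.0, 0.0]), (432, [11.0, 0.0, 0.0])):
            atoms.append(AtomRecord("CA", "C", resnum, "LEU", "E", np.array(pos)))
        frame = Structure(atoms=atoms)
        assert gap_width(frame, spec) == pytest.approx(11.0)

    def test_matches_euclidean_formula(self, spec, rng):
        p, q = rng.uniform(-30, 30, 3), rng.uniform(-30, 30, 3)
        frame = Structure(
            atoms=[
                AtomRecord("CA", "C", 380, "LYS", "E", p),
                AtomRecord("CA", "C", 432, "LEU", "E", q),
            ]
        )
        assert gap_width(frame, spec) == pytest.approx(np.linalg.norm(p - q))

    def test_missing_ca_names_residue(self, spec):
        frame = Structure(atoms=[AtomRecord("CA", "C", 380, "LYS", "E", np.zeros(3)),
                                 AtomRecord("CB", "C", 432, "LEU", "E", np.ones(3))])
        with pytest.raises(FeatureError, match="432"):
            gap_width(frame, spec)


class TestSecondaryStructure:
    def test_sheet_interior_is_E(self):
        ss = assign_secondary_structure(make_beta_sheet_fixture(5))
        for chain in "AB":
            assert [ss[(chain, r)] for r in (2, 3, 4)] == ["E", "E", "E"]

    def test_single_strand_has_no_E(self):
        ss = assign_secondary_structure(make_beta_sheet_fixture(5, n_strands=1))
        assert "E" not in ss.values()

    def test_helix_is_H_not_E(self):
        ss = assign_secondary_structure(make_helix_fixture(12))
        labels = list(ss.values())
        assert labels.count("H") >= 8
        assert "E" not in labels

    @pytest.mark.parametrize("builder,kwargs", [
        (make_beta_sheet_fixture, dict(n_res_per_strand=5)),
        (make_beta_sheet_fixture, dict(n_res_per_strand=9)),
        (make_beta_sheet_fixture, dict(n_res_per_strand=7, twist=25.0)),
        (make_helix_fixture, dict(n_res=12)),
        (make_helix_fixture, dict(n_res=15)),
    ])
    def test_agrees_with_reference_dssp(self, builder, kwargs, tmp_path):
        md = pytest.importorskip("mdtraj")
        from hybridsheet.structio import write_structure

        s = builder(**kwargs)
        p = tmp_path / "f.pdb"
        p.write_text(write_structure(s))
        ref = list(md.compute_dssp(md.load(str(p)), simplified=True)[0])
        ours = list(assign_secondary_structure(s).values())
        agreement = np.mean([a == b for a, b in zip(ref, ours)])
        assert agreement >= 0.95


class TestBeta3:
    @pytest.mark.parametrize(
        "occ,expected",
        [
            ({"P2p": 1.0, "P3p": 1.0}, 1.0),
            ({"P2p": 0.6, "P3p": 0.2}, 0.4),
            ({"P2p": 0.7}, 0.7),  # substrate lacking P3' uses the single occupancy
        ],
    )
    def test_formula(self, occ, expected):
        assert beta3_fraction(occ) == pytest.approx(expected)

    def test_missing_p2_is_an_error(self):
        with pytest.raises(FeatureError):
            beta3_fraction({"P3p": 0.5})

    def test_range_validation(self):
        with pytest.raises(FeatureError):
            beta3_fraction({"P2p": 1.5})


class TestS2Contacts:
    def _frame_with_enzyme_residues(self, distances):
        spec = fixture_catalytic_spec()
        atoms = [AtomRecord("CA", "C", 51, "MET", "S", np.zeros(3))]
        for i, d in enumerate(distances):
            atoms.append(AtomRecord("CA", "C", 400 + i, "LEU", "E", np.array([d, 0.0, 0.0])))
        return Structure(atoms=atoms), spec

    def test_inside_and_outside(self):
        frame, spec = self._frame_with_enzyme_residues([4.0, 6.0])
        assert s2_contacts(frame, spec, "E") == [(400, "LEU")]

    def test_zero_radius_empty(self):
        frame, spec = self._frame_with_enzyme_residues([0.5])
        spec2 = fixture_catalytic_spec(contact_radius=1e-12)
        # contact_radius 0 semantics: nothing can be strictly closer than 0
        spec0 = fixture_catalytic_spec(contact_radius=0.0)
        assert s2_contacts(frame, spec0, "E") == []

    def test_matches_brute_force(self, rng):
        spec = fixture_catalytic_spec()
        p2_coords = rng.uniform(-3, 3, (4, 3))
        atoms = [
            AtomRecord(f"X{i}", "C", 51, "MET", "S", p) for i, p in enumerate(p2_coords)
        ]
        enzyme = {}
        for r in range(300, 320):
            coords = rng.uniform(-10, 10, (3, 3))
            enzyme[r] = coords
            for i, p in enumerate(coords):
                atoms.append(AtomRecord(f"Y{i}", "C", r, "ALA", "E", p))
        frame = Structure(atoms=atoms)
        expected = sorted(
            (r, "ALA")
            for r, coords in enzyme.items()
            if min(np.linalg.norm(p - q) for p in coords for q in p2_coords) < 5.0
        )
        assert s2_contacts(frame, spec, "E") == expected


class TestExtractFeatures:
    def test_series_length_matches_stride(self, planted, spec):
        traj, _ = planted
        fs = extract_features(traj, spec, stride=1.0)
        assert len(fs) == len(traj)
        fs2 = extract_features(traj, spec, stride=2.0)
        assert len(fs2) == len(traj) // 2

    def test_planted_truth_recovered_exactly(self, planted, spec):
        traj, truth = planted
        fs = extract_features(traj, spec)
        assert np.array_equal(fs.active_flags, truth.active_flags)
        assert np.array_equal(fs.beta3_series, truth.beta3_series)
        assert np.array_equal(fs.water_counts, truth.water_counts)
        assert np.allclose(fs.gap_widths, truth.gap_widths)
        assert np.allclose(fs.rc_values, truth.rc_values)

    def test_all_active_trajectory(self, spec):
        from hybridsheet.synthetic import make_dissociation_trajectory

        traj, _ = make_dissociation_trajectory(10, 9, seed=2, noise=0.0)
        fs = extract_features(traj, spec)
        assert fs.active_fraction == pytest.approx(0.9)

    def test_beta3_bounds_and_unity(self, planted, spec):
        traj, _ = planted
        fs = extract_features(traj, spec)
        assert 0.0 <= fs.beta3 <= 1.0
        pre = fs.beta3_series[: 10]
        assert np.all(pre == 1.0)  # both register residues E in every pre-event frame

    def test_oversized_stride_warns_and_collapses(self, planted, spec):
        traj, _ = planted
        with pytest.warns(UserWarning, match="stride"):
            fs = extract_features(traj, spec, stride=float(len(traj) + 5))
        assert len(fs) == 1

    def test_csv_columns(self, planted, spec, tmp_path):
        traj, _ = planted
        fs = extract_features(traj, spec)
        out = tmp_path / "features.csv"
        fs.to_csv(out)
        header = out.read_text().splitlines()[0].split(",")
        assert header == [
            "time_ns", "active", "beta_P2p", "beta_P3p", "beta3",
            "n_waters", "gap_width_A", "rc_A",
        ]
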