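"""Binned RC profiles, regimes, replicate stats, survey, decomposition."""

import numpy as np
import pandas as pd
import pytest

from hybridsheet.analysis import (
    DecompositionConfig,
    aggregate_replicates,
    bin_by_rc,
    classify_regime,
    correlate_features,
    estimate_changepoint,
    residue_decomposition,
    survey_gap_distance,
    _pair_energy_atoms,
)
from hybridsheet.features import FeatureSeries, extract_features
from hybridsheet.structio import AtomRecord, ResidueSelector, Structure
from hybridsheet.synthetic import make_dissociation_trajectory


def _series(rc, active=None, beta=None, water=None):
    n = len(rc)
    return FeatureSeries(
        times=np.arange(n, dtype=float),
        active_flags=np.array(active if active is not None else np.zeros(n), dtype=bool),
        beta_p2p=np.array(beta if beta is not None else np.zeros(n), dtype=float),
        beta_p3p=None,
        water_counts=np.array(water if water is not None else np.zeros(n), dtype=int),
        gap_widths=np.zeros(n),
        rc_values=np.asarray(rc, dtype=float),
    )


class TestBinByRc:
    def test_default_grid_has_11_bins(self, rng):
        fs = _series(rng.uniform(7, 18, 500))
        prof = bin_by_rc(fs)
        assert prof.n_bins == 11

    def test_half_open_convention(self):
        fs = _series([7.0, 17.999])
        prof = bin_by_rc(fs)
        assert prof.counts[0] == 1 and prof.counts[-1] == 1
        fs = _series([18.0, 10.0])
        assert bin_by_rc(fs).n_dropped == 1

    def test_means_match_group_by_oracle(self, rng):
        rc = rng.uniform(5, 20, 400)
        active = rng.integers(0, 2, 400)
        water = rng.integers(0, 8, 400)
        fs = _series(rc, active=active, water=water)
        prof = bin_by_rc(fs)
        for b in range(11):
            mask = (rc >= 7 + b) & (rc < 8 + b)
            if mask.sum() == 0:
                assert np.isnan(prof.means["active"].iloc[b])
                continue
            assert prof.means["active"].iloc[b] == pytest.approx(active[mask].mean())
            assert prof.means["n_waters"].iloc[b] == pytest.approx(water[mask].mean())

    def test_count_conservation(self, rng):
        rc = rng.uniform(0, 30, 300)
        prof = bin_by_rc(_series(rc))
        assert prof.counts.sum() + prof.n_dropped == 300

    def test_all_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_by_rc(_series([30.0, 40.0, 50.0]))


class TestRegimes:
    @pytest.mark.parametrize("rc,regime", [
        (16.5, "I"), (14.0, "II"), (9.0, "III"),
        (16.0, "II"), (12.0, "II"), (11.999, "III"), (16.001, "I"),
    ])
    def test_band_assignment(self, rc, regime):
        assert classify_regime(rc) == regime

    def test_partition_of_the_line(self, rng):
        for rc in rng.uniform(0, 30, 200):
            assert classify_regime(rc) in {"I", "II", "III"}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_regime(float("nan"))


class TestCorrelation:
    def test_self_and_negation(self, rng):
        x = rng.normal(size=50)
        assert correlate_features(x, x) == pytest.approx(1.0)
        assert correlate_features(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_features([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_planted_trajectory_correlations(self, planted_noisy, spec):
        traj, _ = planted_noisy
        fs = extract_features(traj, spec)
        assert correlate_features(fs.active_flags, fs.beta3_series) > 0.8
        assert correlate_features(fs.active_flags, fs.water_counts) < -0.8


class TestAggregate:
    @pytest.mark.parametrize("values,mean,sdm", [
        ([0.5, 0.5], 0.5, 0.0),
        ([0.0, 1.0], 0.5, 0.5),
        ([0.3, 0.3, 0.3, 0.3], 0.3, 0.0),
    ])
    def test_mean_and_sdm(self, values, mean, sdm):
        m, s = aggregate_replicates(values)
        assert m == pytest.approx(mean)
        assert s == pytest.approx(sdm)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])


class TestSurvey:
    def _structure(self, with_380=True):
        atoms = [AtomRecord("CA", "C", 432, "LEU", "A", np.array([10.0, 0.0, 0.0]))]
        if with_380:
            atoms.append(AtomRecord("CA", "C", 380, "LYS", "A", np.zeros(3)))
        return Structure(atoms=atoms)

    def test_resolved_matches_gap_width(self):
        table = survey_gap_distance(
            [("ok", self._structure())],
            ResidueSelector("A", 380),
            ResidueSelector("A", 432),
        )
        assert table.iloc[0]["status"] == "resolved"
        assert table.iloc[0]["distance_A"] == pytest.approx(10.0)

    def test_missing_residue_reported_unresolved(self):
        table = survey_gap_distance(
            [("ok", self._structure()), ("bad", self._structure(with_380=False))],
            ResidueSelector("A", 380),
            ResidueSelector("A", 432),
        )
        assert list(table["status"]) == ["resolved", "unresolved"]
        assert np.isnan(table.iloc[1]["distance_A"])


class TestDecomposition:
    def _atom(self, name, element, resnum, chain, pos):
        return AtomRecord(name, element, resnum, "ALA", chain, np.asarray(pos, float))

    def test_lj_minimum_value(self):
        cfg = DecompositionConfig(charges={"C": 0.0})
        sigma, eps = cfg.lj_params["C"]
        r = 2 ** (1 / 6) * sigma
        a = [self._atom("C1", "C", 1, "S", [0, 0, 0])]
        b = [self._atom("C2", "C", 2, "E", [r, 0, 0])]
        vdw, eel = _pair_energy_atoms(a, b, cfg)
        assert vdw == pytest.approx(-eps)
        assert eel == 0.0

    def test_coulomb_constant(self):
        cfg = DecompositionConfig(
            lj_params={"C": (3.4, 0.0)}, charges={"C": 1.0}, dielectric=1.0
        )
        a = [self._atom("C1", "C", 1, "S", [0, 0, 0])]
        b = [self._atom("C2", "C", 2, "E", [1.0, 0, 0])]
        vdw, eel = _pair_energy_atoms(a, b, cfg)
        assert eel == pytest.approx(332.0636)
        assert vdw == 0.0

    def test_missing_parameters_name_the_class(self):
        cfg = DecompositionConfig(lj_params={"C": (3.4, 0.1)}, charges={"C": 0.1})
        a = [self._atom("N1", "N", 1, "S", [0, 0, 0])]
        b = [self._atom("C2", "C", 2, "E", [2.0, 0, 0])]
        with pytest.raises(ValueError, match="'N'"):
            _pair_energy_atoms(a, b, cfg)

    def test_per_residue_terms_sum_to_total(self, rng):
        # whole-vs-parts conservation on random frames
        register = {
            "P1p": ResidueSelector("S", 50),
            "P2p": ResidueSelector("S", 51),
            "P3p": ResidueSelector("S", 52),
        }
        cfg = DecompositionConfig()

        def frame():
            atoms = []
            for r in (50, 51, 52):
                for i, el in enumerate("CNO"):
                    atoms.append(self._atom(f"{el}{i}", el, r, "S", rng.uniform(-5, 5, 3)))
            for r in (400, 401):
                for i, el in enumerate("CCO"):
                    atoms.append(
                        self._atom(f"{el}{i}x", el, r, "E", rng.uniform(6, 12, 3))
                    )
            return Structure(atoms=atoms)

        assoc = [frame() for _ in range(3)]
        ref = [frame() for _ in range(3)]
        table = residue_decomposition(assoc, ref, register, cfg)

        def total(frames):
            tot = 0.0
            for f in frames:
                sub = [a for a in f.atoms if a.chain_id == "S"]
                enz = [a for a in f.atoms if a.chain_id == "E"]
                vdw, eel = _pair_energy_atoms(sub, enz, cfg)
                tot += vdw + eel
            return tot / len(frames)

        expected = total(assoc) - total(ref)
        assert table.rows["total"].sum() == pytest.approx(expected, abs=1e-9)
        assert np.allclose(
            table.rows["total"], table.rows["vdw"] + table.rows["eel"]
        )


class TestChangepoint:
    def test_recovers_planted_event(self, planted_noisy, spec):
        traj, truth = planted_noisy
        fs = extract_features(traj, spec)
        est = estimate_changepoint(fs.gap_widths)
        assert abs(est - truth.dissociation_frame) <= 2

    def test_exact_on_clean_step(self):
        series = np.array([11.0] * 30 + [14.0] * 20)
        assert estimate_changepoint(series) == 30
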