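"""HDX-MS centroid masses, uptake, back-exchange and differential classes."""

import numpy as np
import pandas as pd
import pytest

from xldock.hdx import (
    DifferentialResult,
    IsotopeEnvelope,
    centroid_mass,
    differential,
    map_to_structure,
    n_exchangeable,
    normalize_backexchange,
    replicate_stats,
    residue_deltas,
    uptake,
)
from xldock.synthetic import simulate_hdx, simulate_labeling_envelopes, tile_peptides


class TestCentroid:
    def test_single_peak(self):
        env = IsotopeEnvelope("p", 1, [500.0], [1.0])
        assert centroid_mass(env) == pytest.approx(498.992724, abs=1e-9)

    def test_two_equal_peaks_midpoint(self):
        env = IsotopeEnvelope("p", 1, [500.0, 501.0], [1.0, 1.0])
        assert centroid_mass(env) == pytest.approx(499.492724, abs=1e-9)

    def test_five_peak_charge2_hand_computed(self):
        mz = np.array([600.0, 600.5, 601.0, 601.5, 602.0])
        inten = np.array([2.0, 5.0, 3.0, 1.0, 0.5])
        env = IsotopeEnvelope("p", 2, mz, inten)
        mz_bar = float((mz * inten).sum() / inten.sum())
        assert centroid_mass(env) == pytest.approx((mz_bar - 1.007276) * 2, abs=1e-9)

    def test_scale_invariance(self):
        mz = np.array([600.0, 600.5, 601.0])
        inten = np.array([1.0, 2.0, 1.0])
        a = centroid_mass(IsotopeEnvelope("p", 2, mz, inten))
        b = centroid_mass(IsotopeEnvelope("p", 2, mz, inten * 1e4))
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(mz=[500.0, 499.0], intensity=[1, 1]),  # not increasing
        dict(mz=[500.0], intensity=[0.0]),  # no positive peak
        dict(mz=[500.0], intensity=[-1.0]),  # negative intensity
    ])
    def test_invalid_envelopes_rejected(self, bad):
        with pytest.raises(ValueError):
            IsotopeEnvelope("p", 1, np.array(bad["mz"]), np.array(bad["intensity"]))


class TestNExchangeable:
    def test_standard_convention(self):
        # length - 1, minus prolines beyond the second residue
        assert n_exchangeable("ALANINE") == 6
        assert n_exchangeable("SAMPLER") == 5  # one internal proline
        assert n_exchangeable("SAPPLER") == 4  # two P at positions 3,4
        assert n_exchangeable("PPAAAA") == 5  # leading prolines don't count


def _centroid_frame(rows):
    return pd.DataFrame(rows, columns=["peptide", "state", "timepoint",
                                       "replicate", "centroid_mass"])


class TestUptake:
    def test_identity_state_zero(self):
        rows = [("p1", "undeuterated", 0.0, 0, 1000.0),
                ("p1", "apo", 10.0, 1, 1000.0)]
        out = uptake(_centroid_frame(rows))
        assert out["uptake"].iloc[0] == pytest.approx(0.0)

    def test_simple_subtraction(self):
        rows = [("p1", "undeuterated", 0.0, 0, 1000.0),
                ("p1", "apo", 10.0, 1, 1001.5)]
        out = uptake(_centroid_frame(rows))
        assert out["uptake"].iloc[0] == pytest.approx(1.5)

    def test_replicate_mean_and_sd(self):
        rows = [("p1", "undeuterated", 0.0, 0, 1000.0)]
        for i, u in enumerate([1.4, 1.5, 1.6], start=1):
            rows.append(("p1", "apo", 10.0, i, 1000.0 + u))
        stats = replicate_stats(uptake(_centroid_frame(rows)))
        assert stats["mean"].iloc[0] == pytest.approx(1.5)
        assert stats["sd"].iloc[0] == pytest.approx(0.1, abs=1e-12)
        assert stats["n"].iloc[0] == 3

    def test_missing_reference_flagged_and_excluded(self, caplog):
        rows = [("p1", "undeuterated", 0.0, 0, 1000.0),
                ("p1", "apo", 10.0, 1, 1001.0),
                ("p2", "apo", 10.0, 1, 900.0)]
        with caplog.at_level("WARNING"):
            out = uptake(_centroid_frame(rows))
        assert out[out["peptide"] == "p2"]["missing_reference"].all()
        stats = replicate_stats(out)
        assert set(stats["peptide"]) == {"p1"}


class TestBackExchange:
    def test_equal_to_control_is_one(self):
        frac, _ = normalize_backexchange(4.0, 4.0, 8)
        assert frac == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        frac, corrected = normalize_backexchange(2.0, 4.0, 8)
        assert frac == pytest.approx(0.5)
        assert corrected == pytest.approx(4.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            normalize_backexchange(1.0, 0.0, 8)

    def test_recovers_labeled_fraction_from_envelopes(self):
        """70 % labeling with 20 % back-exchange recovered within ±2 %."""
        seq = "ACDEFGHIKLMNQRSTVWY"
        envs = simulate_labeling_envelopes(seq, true_fraction=0.7,
                                           back_exchange=0.2, noise_sd=0.02,
                                           n_replicates=3, seed=5)
        undeut = np.mean([centroid_mass(e) for e in envs["undeuterated"]])
        labeled = np.mean([centroid_mass(e) for e in envs["labeled"]])
        control = np.mean([centroid_mass(e) for e in envs["fully_deuterated"]])
        frac, _ = normalize_backexchange(labeled - undeut, control - undeut,
                                         n_exchangeable(seq))
        assert frac == pytest.approx(0.70, abs=0.02)


def _uptake_frame(peptide, timepoint, values, start=1, end=10):
    return pd.DataFrame({
        "peptide": peptide, "timepoint": timepoint,
        "replicate": np.arange(1, len(values) + 1),
        "uptake": values, "start": start, "end": end,
    })


class TestDifferential:
    def test_identical_replicates_no_change(self):
        a = _uptake_frame("p1", 10.0, [1.0, 1.1, 0.9])
        res = differential(a, a.copy())
        assert res[0].classification == "no_change"
        assert res[0].delta_uptake == pytest.approx(0.0)

    def test_protection_detected(self):
        rng = np.random.default_rng(0)
        b = _uptake_frame("p1", 10.0, 3.0 + rng.normal(0, 0.1, 3))
        a = _uptake_frame("p1", 10.0, 1.5 + rng.normal(0, 0.1, 3))
        res = differential(a, b)
        assert res[0].classification == "protected"
        assert res[0].delta_uptake == pytest.approx(-1.5, abs=0.2)

    def test_large_delta_high_variance_is_no_change(self):
        a = _uptake_frame("p1", 10.0, [0.0, 3.0, -1.5])
        b = _uptake_frame("p1", 10.0, [2.0, 1.9, 2.1])
        res = differential(a, b)
        assert res[0].p_value > 0.05
        assert res[0].classification == "no_change"

    def test_missing_peptide_classified_missing(self):
        a = _uptake_frame("p1", 10.0, [1.0, 1.1])
        b = pd.concat([_uptake_frame("p1", 10.0, [1.0, 1.1]),
                       _uptake_frame("p2", 10.0, [2.0, 2.1])])
        res = differential(a, b)
        by_pep = {r.peptide: r for r in res}
        assert by_pep["p2"].classification == "missing"

    def test_antisymmetric_under_state_swap(self):
        rng = np.random.default_rng(3)
        a = _uptake_frame("p1", 10.0, 1.0 + rng.normal(0, 0.05, 3))
        b = _uptake_frame("p1", 10.0, 2.5 + rng.normal(0, 0.05, 3))
        fwd = differential(a, b)[0]
        rev = differential(b, a)[0]
        assert fwd.classification == "protected" and rev.classification == "deprotected"
        assert fwd.delta_uptake == pytest.approx(-rev.delta_uptake)


class TestRecoveryFromSimulation:
    def test_classification_accuracy(self):
        """Deltas in {-2, 0, +2} Da, σ = 0.15 Da, n = 3: ≥ 95 % accuracy."""
        pep_map = tile_peptides(120, seed=9)
        deltas = {}
        for i, p in enumerate(pep_map["peptide"]):
            deltas[p] = [-2.0, 0.0, 2.0][i % 3]
        table = simulate_hdx(pep_map, deltas, noise_sd=0.15, n_replicates=3, seed=9)
        upt = uptake(table)
        state = upt[upt["state"] == "variant"]
        ref = upt[upt["state"] == "apo"]
        res = differential(state, ref)
        expected = {-2.0: "protected", 0.0: "no_change", 2.0: "deprotected"}
        hits = [r.classification == expected[deltas[r.peptide]] for r in res]
        assert np.mean(hits) >= 0.95

    def test_type_i_rate_under_null(self):
        pep_map = tile_peptides(120, seed=4)
        table = simulate_hdx(pep_map, {}, noise_sd=0.1, n_replicates=3, seed=4)
        upt = uptake(table)
        res = differential(upt[upt["state"] == "variant"], upt[upt["state"] == "apo"])
        frac_no_change = np.mean([r.classification == "no_change" for r in res])
        assert frac_no_change >= 0.95

    def test_dropout_becomes_missing(self):
        pep_map = tile_peptides(36, seed=2)
        pep = pep_map["peptide"].iloc[1]
        table = simulate_hdx(pep_map, {}, noise_sd=0.1, n_replicates=3, seed=2,
                             dropout={(pep, 60.0)})
        upt = uptake(table)
        res = differential(upt[upt["state"] == "variant"], upt[upt["state"] == "apo"])
        flagged = [r for r in res if r.peptide == pep and r.timepoint == 60.0]
        assert flagged and flagged[0].classification == "missing"


class TestStructureMapping:
    def test_single_peptide_coverage(self, toy_truth, tmp_path):
        res = [DifferentialResult("p1", 10.0, -1.0, 0.01, "protected", 10, 20)]
        deltas = map_to_structure(res, toy_truth.system, "toy",
                                  tmp_path / "mapped.pdb")
        assert all(deltas[r] == pytest.approx(-1.0) for r in range(10, 21))
        assert 25 not in deltas
        text = (tmp_path / "mapped.pdb").read_text()
        assert "999.99" in text  # no-coverage sentinel present

    def test_overlapping_peptides_averaged(self, toy_truth):
        res = [DifferentialResult("p1", 10.0, -1.0, 0.01, "protected", 10, 20),
               DifferentialResult("p2", 10.0, -2.0, 0.01, "protected", 15, 25)]
        deltas = residue_deltas(res, "toy", toy_truth.system)
        assert deltas[17] == pytest.approx(-1.5)
        assert deltas[12] == pytest.approx(-1.0)
        assert deltas[23] == pytest.approx(-2.0)

    def test_full_map_matches_brute_force(self, toy_truth):
        rng = np.random.default_rng(6)
        res = []
        for i in range(12):
            s = int(rng.integers(1, 180))
            e = s + int(rng.integers(5, 15))
            res.append(DifferentialResult(f"p{i}", 10.0, float(rng.normal()), 0.01,
                                          "no_change", s, e))
        deltas = residue_deltas(res, "toy", toy_truth.system)
        # brute force per residue
        for r in list(deltas)[:50]:
            cover = [x.delta_uptake for x in res if x.start <= r <= x.end]
            assert deltas[r] == pytest.approx(float(np.mean(cover)))
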