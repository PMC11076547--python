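"""Ornament detection and the four ornamentation analyses."""

import dataclasses

import numpy as np
import pytest

from codakit.discretization import DiscreteType, RhythmModel
from codakit.model import ExchangeDataset, InsufficientDataError
from codakit.ornamentation import (
    chorus_change_test,
    detect_ornaments,
    final_ici_ks_test,
    final_ici_stat,
    ornament_centroid_test,
    ornament_fraction,
    positional_tests,
)
from codakit.pipeline import fit_type_system
from codakit.simulate import GeneratorConfig, generate_exchange, null_exchange

from conftest import TEMPO_BANDWIDTH_S, make_coda, make_exchange


def uniform_coda(cid, whale, onset, k, dur):
    return (cid, whale, onset, tuple(np.full(k - 1, dur / (k - 1))))


class TestDetectOrnaments:
    def test_six_click_among_five_click_flagged(self):
        rows = [uniform_coda("orn", "W1", 0.0, 6, 1.2)]
        rows += [uniform_coda(f"p{i}", "W1", 4.0 * (i + 1), 5, 1.0)
                 for i in range(4)]
        ds = make_exchange(rows)
        (rec,) = detect_ornaments(ds)
        assert rec.coda_id == "orn"
        assert rec.ornament_click_index == 5
        assert rec.comparison_coda_id == "p0"

    def test_uniform_click_counts_no_ornaments(self):
        ds = make_exchange([uniform_coda(f"c{i}", "W1", 4.0 * i, 5, 1.0)
                            for i in range(6)])
        assert detect_ornaments(ds) == []

    def test_outside_window_not_compared(self):
        ds = make_exchange([uniform_coda("a", "W1", 0.0, 6, 1.2),
                            uniform_coda("b", "W1", 20.0, 5, 1.0)])
        assert detect_ornaments(ds) == []

    def test_recall_precision_on_simulator(self):
        cfg = GeneratorConfig(recording_length_s=3600, ici_noise_sd=0.0,
                              response_jitter_sd=0.0)
        ds, truth = generate_exchange(cfg, seed=41)
        detected = {r.coda_id for r in detect_ornaments(ds)}
        true = truth.ornament_ids
        assert true, "generator should have produced ornaments"
        tp = len(detected & true)
        assert tp / len(true) >= 0.95        # recall
        assert tp / len(detected) >= 0.95    # precision

    def test_time_reversal_symmetry(self):
        rows = ([uniform_coda(f"c{i}", "W1", 4.0 * i, 5, 1.0) for i in range(5)]
                + [uniform_coda("orn", "W1", 20.0, 6, 1.0)]
                + [uniform_coda(f"d{i}", "W1", 24.0 + 4.0 * i, 5, 1.0)
                   for i in range(3)])
        ds = make_exchange(rows)
        flagged = {r.coda_id for r in detect_ornaments(ds)}
        total = max(c.termination for c in ds)
        reversed_rows = [(c.coda_id, c.whale_id, total - c.termination,
                          tuple(np.asarray(c.ici)[::-1])) for c in ds]
        flagged_rev = {r.coda_id
                       for r in detect_ornaments(make_exchange(reversed_rows))}
        assert flagged == flagged_rev == {"orn"}

    def test_fraction_near_configured_rate(self, exchange_1h):
        dataset, truth = exchange_1h
        recs = detect_ornaments(dataset)
        frac = ornament_fraction(dataset, recs)
        assert frac == pytest.approx(0.04, abs=0.02)


class TestFinalIciStat:
    def test_uniform_is_zero(self):
        assert final_ici_stat(make_coda("c", (0.2, 0.2, 0.2))) == 0.0

    def test_formula(self):
        assert final_ici_stat(make_coda("c", (0.2, 0.2, 0.3))) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ici = rng.uniform(0.05, 0.5, size=int(rng.integers(3, 9)))
            a = final_ici_stat(make_coda("a", ici))
            b = final_ici_stat(make_coda("b", 2.0 * ici))
            assert a == pytest.approx(b)

    def test_needs_three_icis(self):
        with pytest.raises(InsufficientDataError):
            final_ici_stat(make_coda("c", (0.2, 0.2)))


class TestFinalIciKs:
    def test_ornament_shift_detected(self, typed_exchange_1h):
        dataset, truth, system = typed_exchange_1h
        res = final_ici_ks_test(dataset, system.ornaments)
        assert res.observed > 0.3
        assert res.p_value < 1e-4
        n_orn, n_plain = res.n
        assert n_orn >= 15 and n_plain > 200


class TestCentroidTest:
    def test_perfect_match_after_removal_gives_zero(self):
        template = np.array([0.25, 0.25, 0.25, 0.25])
        rows = [uniform_coda(f"p{i}", "W1", 4.0 * i, 5, 1.0) for i in range(3)]
        orn_ici = tuple(template * 1.0) + (0.5,)
        rows.append(("orn", "W1", 12.0, orn_ici))
        rows += [uniform_coda(f"q{i}", "W1", 16.0 + 4 * i, 5, 1.0)
                 for i in range(2)]
        ds = make_exchange(rows)
        model = RhythmModel(centroids={
            "five": template.copy(),
            "six": np.append(template * 2, 1.0) / np.sum(np.append(template * 2, 1.0)),
        })
        types = {c.coda_id: DiscreteType("five", 0) for c in ds}
        types["orn"] = DiscreteType("six", 0)
        recs = detect_ornaments(ds)
        assert [r.coda_id for r in recs] == ["orn"]
        res = ornament_centroid_test(ds, model, types, recs,
                                     n_resamples=200, seed=1)
        assert res.observed == pytest.approx(0.0, abs=1e-12)  # B exactly 0

    def test_simulator_ornaments_match_neighbours(self, typed_exchange_1h):
        dataset, truth, system = typed_exchange_1h
        res = ornament_centroid_test(dataset, system.rhythm_model,
                                     system.types, system.ornaments,
                                     n_resamples=2000, seed=3)
        assert res.observed < res.null_value  # B (removed) < A (retained)
        assert res.p_value <= 0.01

    def test_no_usable_ornaments_raises(self):
        ds = make_exchange([uniform_coda("a", "W1", 0.0, 5, 1.0)])
        model = RhythmModel(centroids={"x": np.full(4, 0.25)})
        with pytest.raises(InsufficientDataError):
            ornament_centroid_test(ds, model, {"a": DiscreteType("x", 0)},
                                   [], n_resamples=200, seed=0)


class TestPositionalTests:
    def test_boundary_enrichment_detected(self):
        cfg = GeneratorConfig(recording_length_s=10_800, boundary_enrichment=4.0,
                              ornament_rate=0.06)
        ds, truth = generate_exchange(cfg, seed=51)
        recs = detect_ornaments(ds)
        initial, final = positional_tests(ds, recs)
        assert initial.observed > 1.0
        assert initial.p_value < 0.05

    def test_uniform_placement_or_near_one(self):
        cfg = GeneratorConfig(recording_length_s=10_800, ornament_rate=0.06)
        ds, truth = null_exchange(cfg, seed=52)
        recs = detect_ornaments(ds)
        initial, final = positional_tests(ds, recs)
        assert 0.4 < initial.observed < 2.5
        assert initial.p_value > 0.05

    def test_all_initial_ornaments_degenerate_table(self):
        rows = []
        for s in range(30):
            t0 = 40.0 * s
            rows.append(uniform_coda(f"o{s}", "W1", t0, 6, 1.2))
            rows += [uniform_coda(f"c{s}-{i}", "W1", t0 + 4.0 * (i + 1), 5, 1.0)
                     for i in range(3)]
        ds = make_exchange(rows)
        recs = detect_ornaments(ds)
        assert {r.coda_id for r in recs} == {f"o{s}" for s in range(30)}
        initial, _ = positional_tests(ds, recs)
        assert "haldane" in initial.method
        assert initial.observed > 50  # effectively infinite, flagged


class TestChorusChangeTest:
    def test_ornament_triggered_pauses_detected(self):
        # respond_prob 1 removes background pauses from missed responses,
        # isolating the ornament-triggered behaviour change
        cfg = GeneratorConfig(recording_length_s=10_800, ornament_rate=0.08,
                              follower_pause_prob_ornament=0.6,
                              follower_pause_prob_base=0.02,
                              respond_prob=1.0)
        ds, _ = generate_exchange(cfg, seed=61)
        recs = detect_ornaments(ds)
        res = chorus_change_test(ds, recs)
        assert res.observed > 1.0
        assert res.p_value <= 0.05

    def test_null_coupling_or_near_one(self):
        cfg = GeneratorConfig(recording_length_s=10_800, ornament_rate=0.08)
        ds, _ = null_exchange(cfg, seed=62)
        recs = detect_ornaments(ds)
        res = chorus_change_test(ds, recs)
        assert 0.4 < res.observed < 2.5

    def test_no_choruses_raises(self):
        ds = make_exchange([uniform_coda("a", "W1", 0.0, 5, 1.0)])
        with pytest.raises(InsufficientDataError):
            chorus_change_test(ds, [])
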