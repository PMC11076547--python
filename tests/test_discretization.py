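"""Tempo modes from KDE, rhythm centroids, discrete type assignment."""

import numpy as np
import pytest

from codakit.discretization import (
    RhythmModel,
    TempoModel,
    assign_rhythm,
    assign_tempo,
    assign_types,
    fit_rhythm_model,
    fit_tempo_model,
    load_rhythm_model,
    load_tempo_model,
    reference_rhythm_path,
    rhythm_distance,
    save_rhythm_model,
    save_tempo_model,
)
from codakit.model import ExchangeDataset, InsufficientDataError

from conftest import make_coda


class TestTempoModel:
    def test_two_gaussian_mixture_recovery(self):
        rng = np.random.default_rng(42)
        durations = np.concatenate([rng.normal(0.4, 0.05, 250),
                                    rng.normal(1.0, 0.05, 250)])
        model = fit_tempo_model(durations, bandwidth=0.05)
        assert model.n_types == 2
        assert model.mode_locations[0] == pytest.approx(0.4, abs=0.05)
        assert model.mode_locations[1] == pytest.approx(1.0, abs=0.05)
        assert len(model.boundaries) == 1
        assert 0.5 < model.boundaries[0] < 0.9

    def test_single_cluster_single_mode(self):
        rng = np.random.default_rng(0)
        model = fit_tempo_model(rng.normal(0.8, 0.03, 300))
        assert model.n_types == 1 and model.boundaries == ()

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_tempo_model(np.full(10, 0.5))

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            TempoModel(bandwidth=0.05, mode_locations=(0.4, 1.0), boundaries=())
        with pytest.raises(ValueError):
            TempoModel(bandwidth=0.05, mode_locations=(0.4, 1.0),
                       boundaries=(1.2,))  # mode not inside its interval


class TestAssignTempo:
    model = TempoModel(bandwidth=0.05, mode_locations=(0.4, 1.0, 1.6),
                       boundaries=(0.7, 1.3))

    def _coda(self, dur, k=5):
        return make_coda("c", np.full(k - 1, dur / (k - 1)))

    def test_mode_duration_maps_to_own_class(self):
        for i, m in enumerate(self.model.mode_locations):
            assert assign_tempo(self._coda(m), self.model) == i

    def test_boundary_goes_to_lower_class(self):
        assert assign_tempo(self._coda(0.7), self.model) == 0
        assert assign_tempo(self._coda(0.7 + 1e-9), self.model) == 1

    def test_matches_interval_scan_oracle(self):
        rng = np.random.default_rng(3)
        edges = (-np.inf,) + self.model.boundaries + (np.inf,)
        for dur in rng.uniform(0.05, 2.5, size=300):
            expected = next(i for i in range(3)
                            if edges[i] < dur <= edges[i + 1])
            assert assign_tempo(self._coda(dur), self.model) == expected


class TestRhythmModel:
    t_a = np.array([0.4, 0.3, 0.2, 0.1])
    t_b = np.array([0.1, 0.2, 0.3, 0.4])

    def _codas_from(self, template, n, seed, dur_range=(0.4, 1.2)):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            d = rng.uniform(*dur_range)
            ici = template * d + rng.normal(0, 0.002, template.size)
            out.append(make_coda(f"{seed}-{i}", np.clip(ici, 1e-3, None)))
        return out

    def test_two_template_kmeans_recovery(self):
        codas = (self._codas_from(self.t_a, 60, 1)
                 + self._codas_from(self.t_b, 60, 2))
        model = fit_rhythm_model(codas, {5: 2}, seed=0)
        assert model.n_types == 2
        fitted = sorted(model.centroids.values(), key=lambda c: c[0])
        np.testing.assert_allclose(fitted[0], self.t_b, atol=1e-2)
        np.testing.assert_allclose(fitted[1], self.t_a, atol=1e-2)

    def test_single_template_mean_centroid(self):
        codas = self._codas_from(self.t_a, 40, 3)
        model = fit_rhythm_model(codas, {5: 1})
        (centroid,) = model.centroids.values()
        stacked = np.stack([c.ici / c.duration for c in codas]).mean(axis=0)
        np.testing.assert_allclose(centroid, stacked / stacked.sum(), atol=1e-12)

    def test_reference_file_has_18_centroids(self):
        model = load_rhythm_model(reference_rhythm_path())
        assert model.n_types == 18
        for c in model.centroids.values():
            assert c.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unit_sum_enforced(self):
        with pytest.raises(ValueError):
            RhythmModel(centroids={"x": np.array([0.5, 0.6])})


class TestAssignRhythm:
    model = RhythmModel(centroids={
        "A": np.array([0.4, 0.3, 0.2, 0.1]),
        "B": np.array([0.1, 0.2, 0.3, 0.4]),
        "C": np.array([0.5, 0.5]),
    })

    def test_centroid_identity(self):
        coda = make_coda("c", self.model.centroids["A"] * 0.8)
        assert assign_rhythm(coda, self.model) == "A"
        assert rhythm_distance(coda, self.model.centroids["A"]) == pytest.approx(0.0)

    def test_scale_invariance(self):
        base = self.model.centroids["B"] * 0.6
        assert (assign_rhythm(make_coda("x", base), self.model)
                == assign_rhythm(make_coda("y", 2 * base), self.model) == "B")

    def test_unmatched_click_count_flagged(self):
        assert assign_rhythm(make_coda("c", np.full(7, 0.1)), self.model) is None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        for i in range(200):
            ici = rng.uniform(0.05, 0.5, size=4)
            coda = make_coda(f"c{i}", ici)
            v = ici / ici.sum()
            dists = {rid: np.mean((v - c) ** 2)
                     for rid, c in self.model.centroids.items() if c.size == 4}
            assert assign_rhythm(coda, self.model) == min(dists, key=dists.get)


class TestAssignTypes:
    def test_counts_reconcile_and_orthogonality(self, typed_exchange_1h):
        dataset, truth, system = typed_exchange_1h
        assigned = [t for t in system.types.values() if t is not None]
        unassigned = [t for t in system.types.values() if t is None]
        assert len(assigned) + len(unassigned) == len(dataset)
        # rhythm is scale-invariant, tempo is not: double one coda's speed
        coda = next(c for c in dataset
                    if system.types[c.coda_id] is not None
                    and c.coda_id not in system.ornament_ids
                    and system.types[c.coda_id].tempo_type == 0)
        slow = make_coda("slow", np.asarray(coda.ici) * 3.0)
        t_orig = system.types[coda.coda_id]
        assert assign_rhythm(slow, system.rhythm_model) == t_orig.rhythm_type
        assert (assign_tempo(slow, system.tempo_model) != t_orig.tempo_type)

    def test_tempo_refit_on_simulated_modes(self, typed_exchange_1h):
        """Re-simulating from fitted modes recovers count and locations."""
        _, _, system = typed_exchange_1h
        rng = np.random.default_rng(12)
        modes = system.tempo_model.mode_locations
        sim = np.concatenate([rng.normal(m, 0.04, 400) for m in modes])
        refit = fit_tempo_model(sim, bandwidth=system.tempo_model.bandwidth)
        assert refit.n_types == len(modes)
        for got, want in zip(refit.mode_locations, modes):
            assert got == pytest.approx(want, abs=system.tempo_model.bandwidth)


class TestModelFiles:
    def test_tempo_yaml_roundtrip(self, tmp_path):
        model = TempoModel(bandwidth=0.04, mode_locations=(0.4, 1.0),
                           boundaries=(0.7,))
        p = tmp_path / "tempo.yaml"
        save_tempo_model(model, p)
        back = load_tempo_model(p)
        assert back == model

    def test_rhythm_csv_roundtrip(self, tmp_path):
        model = RhythmModel(centroids={
            "5c1": np.array([0.4, 0.3, 0.2, 0.1]),
            "3c1": np.array([0.5, 0.5]),
        })
        p = tmp_path / "rhythm.csv"
        save_rhythm_model(model, p)
        back = load_rhythm_model(p)
        assert set(back.centroids) == set(model.centroids)
        for rid in model.centroids:
            np.testing.assert_allclose(back.centroids[rid],
                                       model.centroids[rid], atol=1e-12)
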