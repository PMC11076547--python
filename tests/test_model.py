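"""Core coda data model, ICI transforms, filtering and table I/O."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codakit.io import SchemaError, read_codas, write_codas
from codakit.model import (
    Coda,
    ExchangeDataset,
    InvalidCodaError,
    ParameterError,
    cumulative_ici,
    duration,
    filter_clicks,
    standardize_ici,
)

from _oracles import accumulate_sum
from conftest import make_coda, make_exchange

ici_vectors = st.lists(st.floats(1e-3, 2.0, allow_nan=False), min_size=1,
                       max_size=12)


class TestCoda:
    def test_duration_examples(self):
        assert duration(make_coda(ici=[0.25, 0.25, 0.25, 0.25])) == pytest.approx(1.0)
        assert duration(make_coda(ici=[0.2, 0.3])) == pytest.approx(0.5)

    def test_duration_matches_accumulation_oracle(self):
        rng = np.random.default_rng(0)
        ici = rng.uniform(0.05, 0.4, size=9)
        assert duration(make_coda(ici=ici)) == pytest.approx(accumulate_sum(ici))

    @pytest.mark.parametrize("bad", [[], [0.2, -0.1], [0.0, 0.2], [np.nan, 0.2]])
    def test_invalid_ici_rejected(self, bad):
        with pytest.raises(InvalidCodaError):
            make_coda(ici=bad)

    def test_click_times_strictly_increasing(self):
        c = make_coda(ici=[0.2, 0.3, 0.1], onset=5.0)
        times = c.click_times()
        assert times[0] == 5.0
        assert np.all(np.diff(times) > 0)
        assert c.termination == pytest.approx(times[-1])


class TestTransforms:
    def test_standardize_uniform(self):
        np.testing.assert_allclose(
            standardize_ici(make_coda(ici=[0.2, 0.2, 0.2, 0.2])),
            [0.25, 0.25, 0.25, 0.25])

    def test_standardize_scale_invariance(self):
        a = standardize_ici(make_coda(ici=[0.1, 0.3]))
        b = standardize_ici(make_coda(ici=[0.2, 0.6]))
        np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(a, [0.25, 0.75])

    @given(ici_vectors)
    @settings(max_examples=200, deadline=None)
    def test_standardize_unit_sum_and_roundtrip(self, ici):
        coda = make_coda(ici=ici)
        s = standardize_ici(coda)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(s * coda.duration, coda.ici, atol=1e-9)

    def test_cumulative_examples(self):
        c = make_coda(ici=[0.2, 0.3])
        np.testing.assert_allclose(cumulative_ici(c), [0.2, 0.5])
        np.testing.assert_allclose(cumulative_ici(c, standardized=True),
                                   [0.4, 1.0])

    @given(ici_vectors)
    @settings(max_examples=200, deadline=None)
    def test_cumulative_difference_inverse(self, ici):
        coda = make_coda(ici=ici)
        cum = cumulative_ici(coda)
        assert np.all(np.diff(cum) > 0) or cum.size == 1
        recovered = np.diff(np.concatenate(([0.0], cum)))
        np.testing.assert_allclose(recovered, coda.ici, atol=1e-9)
        std = cumulative_ici(coda, standardized=True)
        assert std[-1] == pytest.approx(1.0, abs=1e-12)


class TestFilterClicks:
    def test_threshold_boundary(self):
        ds = ExchangeDataset([
            make_coda("a", np.full(4, 0.2)),    # 5 clicks
            make_coda("b", np.full(10, 0.2)),   # 11 clicks
            make_coda("c", np.full(9, 0.2)),    # 10 clicks
        ])
        kept = filter_clicks(ds, max_clicks=10)
        assert [c.coda_id for c in kept] == ["a", "c"]

    def test_empty_and_idempotent(self):
        assert len(filter_clicks(ExchangeDataset([]))) == 0
        ds = ExchangeDataset([make_coda(str(i), np.full(i + 2, 0.1))
                              for i in range(12)])
        once = filter_clicks(ds, 10)
        twice = filter_clicks(once, 10)
        assert [c.coda_id for c in once] == [c.coda_id for c in twice]

    def test_bad_threshold(self):
        with pytest.raises(ParameterError):
            filter_clicks(ExchangeDataset([]), max_clicks=1)

    def test_injected_long_codas_removed_at_expected_rate(self, exchange_1h):
        dataset, _ = exchange_1h
        rng = np.random.default_rng(3)
        long = [make_coda(f"L{i}", rng.uniform(0.05, 0.2, size=11),
                          whale="W1", onset=10_000.0 + 5 * i)
                for i in range(int(0.05 * len(dataset) / 0.95))]
        mixed = ExchangeDataset(list(dataset.codas) + long, ordered=True)
        kept = filter_clicks(mixed)
        frac = len(kept) / len(mixed)
        assert frac == pytest.approx(0.95, abs=0.01)


class TestDatasetInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExchangeDataset([make_coda("x"), make_coda("x")])

    def test_ordered_requires_context(self):
        from codakit.model import UnorderedDatasetError
        with pytest.raises(UnorderedDatasetError):
            ExchangeDataset([make_coda("x")], ordered=True)

    def test_ordered_requires_sorted_onsets(self):
        from codakit.model import UnorderedDatasetError
        rows = [make_coda("a", (0.1, 0.1), whale="W1", onset=10.0),
                make_coda("b", (0.1, 0.1), whale="W1", onset=5.0)]
        with pytest.raises(UnorderedDatasetError):
            ExchangeDataset(rows, ordered=True)


class TestTableIO:
    def test_three_row_fixture_roundtrip(self, tmp_path):
        ds = make_exchange([
            ("c1", "W1", 0.0, (0.2, 0.3)),
            ("c2", "W2", 1.1, (0.15, 0.15, 0.2)),
            ("c3", "W1", 4.5, (0.4, 0.1, 0.1, 0.1)),
        ])
        path = tmp_path / "codas.csv"
        write_codas(ds, path)
        back = read_codas(path)
        assert len(back) == 3 and back.ordered
        for orig, rt in zip(ds, back):
            assert rt.coda_id == orig.coda_id
            assert rt.whale_id == orig.whale_id
            assert rt.onset_time == orig.onset_time
            np.testing.assert_array_equal(rt.ici, orig.ici)

    def test_write_read_write_byte_identical(self, tmp_path, exchange_1h):
        dataset, _ = exchange_1h
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_codas(dataset, p1)
        write_codas(read_codas(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_columns_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("foo,bar\n1,2\n")
        with pytest.raises(SchemaError):
            read_codas(p)

    def test_nonpositive_ici_row_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "codas.csv"
        p.write_text(
            "coda_id,recording_id,whale_id,onset_time_s,"
            "ici_1,ici_2,ici_3,ici_4,ici_5,ici_6,ici_7,ici_8,ici_9\n"
            "good,,,,0.2,0.3,,,,,,,\n"
            "bad,,,,-0.2,0.3,,,,,,,\n")
        with caplog.at_level(logging.WARNING, logger="codakit"):
            ds = read_codas(p)
        assert [c.coda_id for c in ds] == ["good"]
        assert ds.metadata["rows_rejected"] == 1
        assert any("rejected" in r.message for r in caplog.records)

    def test_deposited_dialect_adapter(self, tmp_path):
        p = tmp_path / "deposited.csv"
        p.write_text("Whale,TsTo,ICI1,ICI2,ICI3\n"
                     "5722,100.5,0.21,0.23,\n"
                     "5727,103.2,0.18,0.19,0.22\n")
        ds = read_codas(p, dialect="deposited")
        assert len(ds) == 2 and ds.ordered
        assert ds[0].whale_id == "5722"
        np.testing.assert_allclose(ds[0].ici, [0.21, 0.23])
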