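"""Shared fixtures: small hand-built datasets and one cached synthetic
exchange with its fitted type system (expensive, so session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from codakit.model import Coda, ExchangeDataset
from codakit.pipeline import fit_type_system
from codakit.simulate import GeneratorConfig, generate_exchange

#: Analysis bandwidth used throughout the suite for tempo-mode fitting on
#: synthetic durations (between the within-mode sd and the mode spacing).
TEMPO_BANDWIDTH_S = 0.05


def make_coda(coda_id="c", ici=(0.25, 0.25, 0.25, 0.25), whale=None, onset=None):
    return Coda(coda_id=coda_id, ici=np.asarray(ici, dtype=float),
                whale_id=whale, onset_time=onset)


def make_exchange(rows):
    """Dataset from (coda_id, whale, onset, ici) tuples, sorted by onset."""
    codas = [make_coda(cid, ici, whale, onset)
             for cid, whale, onset, ici in sorted(rows, key=lambda r: r[2])]
    return ExchangeDataset(codas, ordered=True)


@pytest.fixture(scope="session")
def exchange_1h():
    """One hour of the default two-whale exchange, with ground truth."""
    return generate_exchange(GeneratorConfig(recording_length_s=3600), seed=11)


@pytest.fixture(scope="session")
def typed_exchange_1h(exchange_1h):
    """The same exchange plus its fitted type system."""
    dataset, truth = exchange_1h
    system = fit_type_system(dataset, bandwidth=TEMPO_BANDWIDTH_S)
    return dataset, truth, system
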