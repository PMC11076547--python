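"""End-to-end typing pipeline: ornaments first, then tempo and rhythm.

Ornament clicks do not determine a coda's discrete type, so the fitting
order matters: ornaments are detected from raw click counts, the tempo
and rhythm models are fit on the de-ornamented codas, and every coda is
then typed on its de-ornamented form.  This keeps ornamented codas in
the cell of the pattern they decorate instead of contaminating the
next click-count class.
"""

from __future__ import annotations

from dataclasses import dataclass

from .discretization import (
    DiscreteType,
    RhythmModel,
    TempoModel,
    assign_types,
    fit_rhythm_model,
    fit_tempo_model,
)
from .model import Coda, ExchangeDataset
from .ornamentation import OrnamentRecord, detect_ornaments

__all__ = ["TypeSystem", "fit_type_system"]


@dataclass
class TypeSystem:
    """Fitted models plus per-coda assignments for one dataset."""

    tempo_model: TempoModel
    rhythm_model: RhythmModel
    types: dict[str, DiscreteType | None]
    ornaments: list[OrnamentRecord]

    @property
    def ornament_ids(self) -> set[str]:
        return {r.coda_id for r in self.ornaments}


def _deornamented(coda: Coda, ornament_ids: set[str]) -> Coda:
    if coda.coda_id in ornament_ids and coda.ici.size >= 2:
        return coda.drop_final_click()
    return coda


def fit_type_system(dataset: ExchangeDataset,
                    bandwidth: float | None = None,
                    k_per_click_count: dict[int, int] | None = None,
                    seed: int = 20240507,
                    ornament_window_s: float = 10.0) -> TypeSystem:
    """Fit tempo and rhythm models and type every coda.

    For ordered datasets ornaments are detected first and stripped
    before model fitting and type assignment; unordered (repertoire)
    datasets skip ornament detection.  ``k_per_click_count`` defaults to
    one rhythm type per click count.
    """
    ornaments = (detect_ornaments(dataset, window_s=ornament_window_s)
                 if dataset.ordered else [])
    orn_ids = {r.coda_id for r in ornaments}
    base = [_deornamented(c, orn_ids) for c in dataset]

    tempo_model = fit_tempo_model([c.duration for c in base],
                                  bandwidth=bandwidth)
    if k_per_click_count is None:
        k_per_click_count = {k: 1 for k in sorted({c.click_count for c in base})}
    rhythm_model = fit_rhythm_model(base, k_per_click_count, seed=seed)
    types = assign_types(dataset, rhythm_model, tempo_model,
                         ornament_ids=orn_ids)
    return TypeSystem(tempo_model=tempo_model, rhythm_model=rhythm_model,
                      types=types, ornaments=ornaments)
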