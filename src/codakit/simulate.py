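"""Synthetic multi-whale coda exchanges with recoverable ground truth.

The generator emulates the structure of an annotated exchange recording:

* one *leader* whale produces call sequences of codas, one coda roughly
  every 4 s (the average response period), with long pauses between
  sequences;
* each sequence uses one rhythm template (a unit-sum ICI vector) and one
  tempo mode; within a sequence the coda duration either stays i.i.d.
  around the mode or follows a damped stochastic oscillator (persistent
  drift velocity plus mean reversion), producing the smooth, sustained
  duration trends -- positively correlated consecutive drifts -- that
  define rubato while keeping durations clustered at the mode;
* *follower* whales respond to leader codas, either overlapping them or
  taking turns within two seconds; when imitation is enabled a
  follower's coda duration copies the leader's (plus noise) even though
  its rhythm template, and so its click count, may differ;
* ornaments (an extra final click, with a longer final ICI) are injected
  at a configurable rate, enriched at sequence boundaries;
* after an ornamented (or, at a lower rate, any) leader coda the
  follower can pause its responses, producing the "change in chorusing
  behaviour" events the ornamentation analysis looks for.

Every generated coda carries ground-truth labels (rhythm id, tempo id,
ornament flag, per-sequence rubato class, imitated coda), so every
pipeline stage can be scored against the truth.  :func:`null_exchange`
produces matched null worlds -- i.i.d. durations within type, no
imitation, uniform ornament placement, no behavioural coupling -- for
type-I-error calibration.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; a fixed seed reproduces the dataset bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import Coda, ExchangeDataset, ParameterError
from .rubato import DEFAULT_RUBATO_THRESHOLD_S

__all__ = ["GeneratorConfig", "GroundTruth", "generate_exchange",
           "null_exchange", "to_repertoire", "DEFAULT_TEMPLATES",
           "DEFAULT_TEMPO_MODES"]


def _template(ici: list[float]) -> np.ndarray:
    v = np.asarray(ici, dtype=float)
    v = v / v.sum()
    v.setflags(write=False)
    return v


#: Five synthetic rhythm templates over 4-8 clicks (one per click count,
#: so an appended ornament click is unambiguous in the ground truth).
DEFAULT_TEMPLATES: dict[str, np.ndarray] = {
    "r4": _template([1.0, 1.0, 1.0]),
    "r5": _template([1.0, 1.0, 1.0, 1.0]),
    "r6": _template([2.0, 2.0, 1.0, 1.0, 1.0]),
    "r7": _template([1.0, 1.2, 1.4, 1.6, 1.8, 2.0]),
    "r8": _template([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]),
}

#: Five tempo modes (mean, sd) in seconds; separations >= 5 sd so kernel
#: density estimation can resolve them.
DEFAULT_TEMPO_MODES: tuple[tuple[float, float], ...] = (
    (0.35, 0.04), (0.55, 0.04), (0.80, 0.04), (1.10, 0.05), (1.50, 0.05))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the exchange generator (times in seconds)."""

    n_whales: int = 2
    rhythm_templates: dict[str, np.ndarray] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))
    tempo_modes: tuple[tuple[float, float], ...] = DEFAULT_TEMPO_MODES
    rubato_step_sd: float = 0.03       # drift-step sd; 0 = i.i.d. durations
    rubato_persistence: float = 0.8    # AR(1) memory of the drift velocity
    rubato_reversion: float = 0.2      # pull of the drift back to the mode
    ici_noise_sd: float = 0.002        # per-ICI jitter on absolute ICIs
    ornament_rate: float = 0.04        # overall expected ornament fraction
    boundary_enrichment: float = 2.0   # relative rate at sequence ends
    ornament_ici_multiplier: float = 1.5
    response_period_s: float = 4.0
    response_jitter_sd: float = 0.3
    respond_prob: float = 0.9          # follower answers a leader coda
    imitation: bool = True
    imitation_sd: float = 0.01         # follower duration-copy noise
    overlap_prob: float = 0.4
    follower_pause_prob_base: float = 0.05
    follower_pause_prob_ornament: float = 0.15
    mean_sequence_length: float = 8.0
    pause_between_sequences_s: tuple[float, float] = (14.0, 30.0)
    recording_length_s: float = 1800.0
    rubato_threshold_s: float = DEFAULT_RUBATO_THRESHOLD_S

    def validate(self) -> None:
        rates = (self.ornament_rate, self.respond_prob, self.overlap_prob,
                 self.follower_pause_prob_base,
                 self.follower_pause_prob_ornament)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ParameterError("all rates must lie in [0, 1]")
        sds = (self.rubato_step_sd, self.ici_noise_sd, self.imitation_sd,
               self.response_jitter_sd)
        if any(s < 0 for s in sds):
            raise ParameterError("standard deviations must be >= 0")
        if not 0.0 <= self.rubato_persistence < 1.0:
            raise ParameterError("rubato_persistence must lie in [0, 1)")
        if not 0.0 <= self.rubato_reversion <= 1.0:
            raise ParameterError("rubato_reversion must lie in [0, 1]")
        if self.n_whales < 1:
            raise ParameterError("need at least one whale")
        for rid, t in self.rhythm_templates.items():
            if abs(float(np.sum(t)) - 1.0) > 1e-9:
                raise ParameterError(f"template {rid!r} is not unit-sum")
        if any(m <= 0 or s < 0 for m, s in self.tempo_modes):
            raise ParameterError("tempo modes need positive mean, sd >= 0")
        if self.mean_sequence_length < 2:
            raise ParameterError("mean_sequence_length must be >= 2")


@dataclass
class GroundTruth:
    """Per-coda truth labels emitted alongside a generated dataset.

    ``per_coda`` columns: coda_id, whale_id, rhythm_id, tempo_id,
    ornament (bool), rubato_class, imitates_coda_id ('' for none),
    sequence_id.
    """

    per_coda: pd.DataFrame

    def label(self, coda_id: str, column: str):
        row = self.per_coda.loc[self.per_coda["coda_id"] == coda_id]
        if row.empty:
            raise KeyError(coda_id)
        return row.iloc[0][column]

    @property
    def ornament_ids(self) -> set[str]:
        df = self.per_coda
        return set(df.loc[df["ornament"], "coda_id"])

    def discrete_types(self) -> dict:
        """True per-coda discrete types, in the analysis pipeline's form."""
        from .discretization import DiscreteType

        return {row["coda_id"]: DiscreteType(row["rhythm_id"],
                                             int(row["tempo_id"]))
                for _, row in self.per_coda.iterrows()}


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      rng: np.random.Generator) -> float:
    """Normal draw truncated to (lo, hi) by redraw (no edge point mass)."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _draw_coda_ici(template: np.ndarray, duration: float, ornament: bool,
                   cfg: GeneratorConfig, rng: np.random.Generator
                   ) -> np.ndarray:
    ici = template * duration
    if cfg.ici_noise_sd > 0:
        ici = ici + rng.normal(0.0, cfg.ici_noise_sd, size=ici.size)
        ici = np.clip(ici, 1e-3, None)
    if ornament:
        extra = cfg.ornament_ici_multiplier * template[-1] * duration
        ici = np.append(ici, max(extra, 1e-3))
    return ici


def _rubato_class(durations: list[float], threshold: float) -> str:
    net = durations[-1] - durations[0]
    if net > threshold:
        return "increasing"
    if net < -threshold:
        return "decreasing"
    return "constant"


def generate_exchange(config: GeneratorConfig,
                      seed: int | None = None
                      ) -> tuple[ExchangeDataset, GroundTruth]:
    """Generate one recording-length exchange plus its ground truth."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(seed)
    template_ids = sorted(cfg.rhythm_templates)
    modes = np.asarray([m for m, _ in cfg.tempo_modes])

    codas: list[Coda] = []
    truth_rows: list[dict] = []
    counters = {f"W{i + 1}": 0 for i in range(cfg.n_whales)}
    seq_counter = 0

    def emit(whale: str, onset: float, rid: str, duration: float,
             ornament: bool, imitates: str, seq_id: str) -> tuple[str, Coda]:
        counters[whale] += 1
        cid = f"{whale}-{counters[whale]:04d}"
        ici = _draw_coda_ici(cfg.rhythm_templates[rid], duration, ornament,
                             cfg, rng)
        coda = Coda(coda_id=cid, ici=ici, whale_id=whale, onset_time=onset)
        tempo_id = int(np.argmin(np.abs(modes - duration)))
        truth_rows.append({
            "coda_id": cid, "whale_id": whale, "rhythm_id": rid,
            "tempo_id": tempo_id, "ornament": ornament,
            "rubato_class": "",  # filled per sequence below
            "imitates_coda_id": imitates, "sequence_id": seq_id,
        })
        codas.append(coda)
        return cid, coda

    t = float(rng.uniform(0.0, 2.0))
    followers = [f"W{i + 2}" for i in range(cfg.n_whales - 1)]
    # follower pause state: number of upcoming responses to skip
    skip: dict[str, int] = {w: 0 for w in followers}

    while t < cfg.recording_length_s:
        seq_counter += 1
        seq_id = f"S{seq_counter:03d}"
        length = 2 + int(rng.poisson(max(cfg.mean_sequence_length - 2, 0.0)))
        leader_rid = template_ids[rng.integers(len(template_ids))]
        follower_rids = {w: template_ids[rng.integers(len(template_ids))]
                         for w in followers}
        mode_idx = int(rng.integers(len(cfg.tempo_modes)))
        mean, sd = cfg.tempo_modes[mode_idx]
        # class support is mean +- 2 sd: with mode separations >= 5 sd this
        # leaves a genuine density gap between tempo classes
        lo, hi = mean - 2.0 * sd, mean + 2.0 * sd

        # per-coda ornament probability, normalised so the expected overall
        # fraction equals ornament_rate despite boundary enrichment
        e = cfg.boundary_enrichment
        weight_sum = (length - 2) + 2 * e if length >= 2 else e * length
        base_p = cfg.ornament_rate * length / max(weight_sum, 1e-9)

        duration = _truncated_normal(mean, sd, lo, hi, rng)
        velocity = 0.0  # persistent drift velocity of the rubato process
        rho = cfg.rubato_persistence
        innov_sd = cfg.rubato_step_sd * np.sqrt(max(1.0 - rho ** 2, 0.0))
        seq_durations: dict[str, list[float]] = {w: [] for w in ["W1", *followers]}
        seq_row_idx: dict[str, list[int]] = {w: [] for w in ["W1", *followers]}
        for i in range(length):
            if t >= cfg.recording_length_s:
                break
            if i > 0:
                if cfg.rubato_step_sd > 0:
                    # damped stochastic oscillator around the mode: the
                    # momentum term sustains drift direction, the
                    # reversion term keeps durations clustered at the mode
                    velocity = (rho * velocity
                                - cfg.rubato_reversion * (duration - mean)
                                + rng.normal(0.0, innov_sd))
                    proposed = duration + velocity
                    duration = float(np.clip(proposed, lo, hi))
                    if duration != proposed:  # hit a class bound: kill momentum
                        velocity = 0.0
                else:
                    duration = _truncated_normal(mean, sd, lo, hi, rng)
            boundary = i == 0 or i == length - 1
            p_orn = min(base_p * (e if boundary else 1.0), 1.0)
            ornament = bool(rng.random() < p_orn)

            _, leader_coda = emit("W1", t, leader_rid, duration, ornament,
                                  "", seq_id)
            seq_durations["W1"].append(leader_coda.duration)
            seq_row_idx["W1"].append(len(truth_rows) - 1)

            for w in followers:
                # behavioural coupling: an ornament can silence the
                # follower starting with this very response
                p_pause = (cfg.follower_pause_prob_ornament if ornament
                           else cfg.follower_pause_prob_base)
                if rng.random() < p_pause:
                    skip[w] = 3
                if skip[w] > 0:
                    skip[w] -= 1
                elif rng.random() < cfg.respond_prob:
                    if cfg.imitation:
                        f_dur = max(leader_coda.duration
                                    + rng.normal(0.0, cfg.imitation_sd), 0.05)
                    else:
                        f_dur = _truncated_normal(mean, sd, lo, hi, rng)
                    if rng.random() < cfg.overlap_prob:
                        delay = rng.uniform(0.05, 0.9) * leader_coda.duration
                        f_onset = t + max(delay, 1e-2)
                    else:
                        f_onset = leader_coda.termination + rng.uniform(0.2, 1.8)
                    f_orn = bool(rng.random() < p_orn)
                    _, f_coda = emit(w, f_onset, follower_rids[w], f_dur,
                                     f_orn,
                                     leader_coda.coda_id if cfg.imitation
                                     else "", seq_id)
                    seq_durations[w].append(f_coda.duration)
                    seq_row_idx[w].append(len(truth_rows) - 1)
            t += cfg.response_period_s + rng.normal(0.0, cfg.response_jitter_sd)

        # label rubato per whale from that whale's own realised durations
        for w, durs in seq_durations.items():
            if not durs:
                continue
            label = _rubato_class(durs, cfg.rubato_threshold_s)
            for idx in seq_row_idx[w]:
                truth_rows[idx]["rubato_class"] = label
        t += rng.uniform(*cfg.pause_between_sequences_s)

    codas.sort(key=lambda c: (c.onset_time, c.coda_id))
    truth = pd.DataFrame(truth_rows, columns=[
        "coda_id", "whale_id", "rhythm_id", "tempo_id", "ornament",
        "rubato_class", "imitates_coda_id", "sequence_id"])
    dataset = ExchangeDataset(codas, ordered=True,
                              metadata={"generator": "codakit.simulate",
                                        "seed": seed})
    return dataset, GroundTruth(per_coda=truth)


def null_exchange(config: GeneratorConfig,
                  seed: int | None = None
                  ) -> tuple[ExchangeDataset, GroundTruth]:
    """A matched null world: i.i.d. durations within type, no imitation,
    uniform ornament placement, no ornament/behaviour coupling."""
    base = min(config.follower_pause_prob_base,
               config.follower_pause_prob_ornament)
    null_cfg = replace(config,
                       rubato_step_sd=0.0,
                       imitation=False,
                       boundary_enrichment=1.0,
                       follower_pause_prob_base=base,
                       follower_pause_prob_ornament=base)
    return generate_exchange(null_cfg, seed=seed)


def to_repertoire(dataset: ExchangeDataset) -> ExchangeDataset:
    """Strip temporal context: the Dataset-1 style view (ICIs only)."""
    codas = [Coda(coda_id=c.coda_id, ici=np.asarray(c.ici).copy())
             for c in dataset]
    return ExchangeDataset(codas, ordered=False,
                           metadata=dict(dataset.metadata))
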