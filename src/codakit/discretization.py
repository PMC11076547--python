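"""Discrete typing of codas: tempo and rhythm.

Coda durations cluster around a small set of modes.  A :class:`TempoModel`
is fit by Gaussian kernel density estimation on scalar durations: the
*tempo types* are the local maxima of the density on a fixed evaluation
grid, and the class boundaries are the interleaving local minima
(valleys).  A coda's tempo type is the boundary interval containing its
duration; a duration falling exactly on a boundary goes to the lower
class.

Standardised ICI vectors likewise cluster around a small set of *rhythm
types* (18 in the reference configuration for the Eastern Caribbean
clan).  A :class:`RhythmModel` holds one unit-sum centroid per rhythm
type; centroids are fit per click-count group by k-means with a fixed
seed, or loaded from a centroid table.  A coda is assigned the centroid
of matching click count that minimises the mean squared distance to its
standardised ICI vector, which makes rhythm assignment invariant to
uniform time-scaling of the coda (tempo assignment, by contrast, is not:
the two features are orthogonal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from .io import SchemaError
from .model import (
    Coda,
    ExchangeDataset,
    InsufficientDataError,
    ParameterError,
    standardize_ici,
    cumulative_ici,
)

__all__ = [
    "TempoModel",
    "RhythmModel",
    "DiscreteType",
    "fit_tempo_model",
    "assign_tempo",
    "fit_rhythm_model",
    "load_rhythm_model",
    "assign_rhythm",
    "assign_types",
    "reference_rhythm_path",
]

GRID_POINTS = 2048
MIN_TEMPO_POINTS = 50


@dataclass(frozen=True)
class TempoModel:
    """KDE-derived tempo classes over coda durations (seconds)."""

    bandwidth: float
    mode_locations: tuple[float, ...]
    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        modes, bounds = self.mode_locations, self.boundaries
        if len(bounds) != len(modes) - 1:
            raise ValueError("need exactly one boundary between consecutive modes")
        edges = (-np.inf,) + bounds + (np.inf,)
        for i, m in enumerate(modes):
            if not (edges[i] < m < edges[i + 1]):
                raise ValueError("each mode must lie inside its boundary interval")

    @property
    def n_types(self) -> int:
        return len(self.mode_locations)


@dataclass(frozen=True)
class RhythmModel:
    """Unit-sum rhythm centroids keyed by rhythm-type id."""

    centroids: dict[str, np.ndarray]
    distance: str = "absolute"  # or "cumulative"

    def __post_init__(self) -> None:
        for rid, c in self.centroids.items():
            c = np.asarray(c, dtype=float)
            if abs(c.sum() - 1.0) > 1e-9:
                raise ValueError(f"centroid {rid!r} is not unit-sum")
            c.setflags(write=False)
            self.centroids[rid] = c
        if self.distance not in ("absolute", "cumulative"):
            raise ParameterError(f"unknown distance {self.distance!r}")

    @property
    def n_types(self) -> int:
        return len(self.centroids)

    def click_counts(self) -> dict[str, int]:
        return {rid: c.size + 1 for rid, c in self.centroids.items()}

    def for_click_count(self, k: int) -> dict[str, np.ndarray]:
        return {rid: c for rid, c in self.centroids.items() if c.size + 1 == k}


@dataclass(frozen=True)
class DiscreteType:
    """A coda's cell address in the rhythm x tempo system."""

    rhythm_type: str
    tempo_type: int


# --------------------------------------------------------------------------
# tempo


def fit_tempo_model(durations, bandwidth: float | None = None,
                    min_density_frac: float = 0.05,
                    valley_ratio: float = 0.95) -> TempoModel:
    """Fit tempo classes by KDE mode finding on coda durations.

    The Gaussian-kernel density is evaluated on a 2048-point grid spanning
    ``[0, max(durations) + 3*bandwidth]``; modes are its local maxima and
    boundaries the interleaving local minima.  The bandwidth defaults to
    Silverman's rule (converted to an absolute width in seconds); pass an
    explicit value to override, and sweep it to check mode-count
    robustness.

    Two pruning rules suppress sampling artefacts: maxima whose density
    falls below ``min_density_frac`` of the global maximum are dropped
    (mass threshold), and a pair of maxima separated by a valley deeper
    than ``valley_ratio`` times the lower peak is merged into the taller
    peak (shallow-valley merge).  Set both to 1e9-safe extremes (0 and 1)
    to disable pruning.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < MIN_TEMPO_POINTS:
        raise InsufficientDataError(
            f"need >= {MIN_TEMPO_POINTS} durations to fit a tempo model, "
            f"got {d.size}")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("durations must be finite and positive")

    if bandwidth is None:
        kde = gaussian_kde(d, bw_method="silverman")
    else:
        if bandwidth <= 0:
            raise ParameterError("bandwidth must be positive")
        kde = gaussian_kde(d, bw_method=bandwidth / d.std(ddof=1))
    bw = float(kde.factor * d.std(ddof=1))

    grid = np.linspace(0.0, d.max() + 3.0 * bw, GRID_POINTS)
    dens = kde(grid)
    interior = np.arange(1, GRID_POINTS - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    mode_idx = list(interior[is_max])
    if not mode_idx:  # density monotone on the grid: single terminal mode
        mode_idx = [int(np.argmax(dens))]

    # mass threshold
    peak = dens.max()
    mode_idx = [i for i in mode_idx if dens[i] >= min_density_frac * peak]
    if not mode_idx:
        mode_idx = [int(np.argmax(dens))]

    # shallow-valley merge: absorb the lower of two peaks whose
    # separating valley is nearly as tall as it
    changed = True
    while changed and len(mode_idx) > 1:
        changed = False
        for a, b in zip(mode_idx[:-1], mode_idx[1:]):
            valley = dens[a:b + 1].min()
            lower = min(dens[a], dens[b])
            if valley > valley_ratio * lower:
                mode_idx.remove(a if dens[a] <= dens[b] else b)
                changed = True
                break

    boundaries = []
    for lo, hi in zip(mode_idx[:-1], mode_idx[1:]):
        seg = dens[lo:hi + 1]
        # centre of the low-density basin: when two modes are separated by
        # a near-empty gap the density is flat there and the raw argmin
        # wanders; the basin midpoint is a stabler cut point
        basin = np.flatnonzero(seg <= seg.min() * 1.05)
        valley = lo + int(round(basin.mean()))
        boundaries.append(float(grid[valley]))
    return TempoModel(bandwidth=bw,
                      mode_locations=tuple(float(grid[i]) for i in mode_idx),
                      boundaries=tuple(boundaries))


def assign_tempo(coda: Coda, model: TempoModel) -> int:
    """Index of the tempo class whose boundary interval holds the duration.

    Durations beyond the outermost boundaries map to the terminal classes;
    a duration exactly on a boundary goes to the lower class.
    """
    bounds = np.asarray(model.boundaries)
    return int(np.searchsorted(bounds, coda.duration, side="left"))


# --------------------------------------------------------------------------
# rhythm


def _rhythm_vector(coda: Coda, distance: str) -> np.ndarray:
    if distance == "absolute":
        return standardize_ici(coda)
    return cumulative_ici(coda, standardized=True)


def _centroid_vector(centroid: np.ndarray, distance: str) -> np.ndarray:
    if distance == "absolute":
        return centroid
    return np.cumsum(centroid)


def rhythm_distance(coda: Coda, centroid: np.ndarray,
                    distance: str = "absolute") -> float:
    """Mean squared distance between a coda's standardised ICI vector and a
    unit-sum centroid of the same click count."""
    v = _rhythm_vector(coda, distance)
    c = _centroid_vector(np.asarray(centroid, dtype=float), distance)
    if v.size != c.size:
        raise ValueError("click counts differ")
    return float(np.mean((v - c) ** 2))


def fit_rhythm_model(codas, k_per_click_count: dict[int, int],
                     seed: int = 20240507,
                     distance: str = "absolute") -> RhythmModel:
    """Fit rhythm centroids per click-count group by k-means.

    ``k_per_click_count`` maps a click count to the number of rhythm types
    to fit within that group; rhythm ids are ``"<clicks>c<index>"``.
    Centroids are computed on standardised absolute ICI vectors and
    re-normalised to unit sum.
    """
    groups: dict[int, list[Coda]] = {}
    for c in codas:
        groups.setdefault(c.click_count, []).append(c)

    centroids: dict[str, np.ndarray] = {}
    for clicks, k in sorted(k_per_click_count.items()):
        members = groups.get(clicks, [])
        if len(members) < k:
            raise InsufficientDataError(
                f"{len(members)} codas with {clicks} clicks cannot support "
                f"k={k} rhythm types")
        X = np.stack([standardize_ici(c) for c in members])
        if k == 1:
            fitted = X.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            km.fit(X)
            fitted = km.cluster_centers_
        # order types by their first ICI for a stable labelling
        fitted = fitted[np.argsort(fitted[:, 0])]
        for j, centre in enumerate(fitted, start=1):
            centroids[f"{clicks}c{j}"] = centre / centre.sum()
    return RhythmModel(centroids=centroids, distance=distance)


def assign_rhythm(coda: Coda, model: RhythmModel) -> str | None:
    """Id of the nearest same-click-count centroid, or None if the model
    has no centroid with this coda's click count (flagged upstream)."""
    candidates = model.for_click_count(coda.click_count)
    if not candidates:
        return None
    return min(candidates,
               key=lambda rid: rhythm_distance(coda, candidates[rid],
                                               model.distance))


def assign_types(dataset: ExchangeDataset, rhythm_model: RhythmModel,
                 tempo_model: TempoModel,
                 ornament_ids: set[str] | None = None,
                 ) -> dict[str, DiscreteType | None]:
    """Assign every coda a :class:`DiscreteType`, or None when its click
    count has no rhythm centroid.  Counts always reconcile:
    assigned + unassignable = len(dataset).

    Ornaments do not determine discrete type: codas listed in
    ``ornament_ids`` are typed on their de-ornamented form (final click
    removed), so an ornamented coda shares the cell of the pattern it
    decorates rather than leaking into the next click-count class.
    """
    ornament_ids = ornament_ids or set()
    out: dict[str, DiscreteType | None] = {}
    for coda in dataset:
        c = coda
        if coda.coda_id in ornament_ids and coda.ici.size >= 2:
            c = coda.drop_final_click()
        rid = assign_rhythm(c, rhythm_model)
        out[coda.coda_id] = (None if rid is None else
                             DiscreteType(rid, assign_tempo(c, tempo_model)))
    return out


# --------------------------------------------------------------------------
# model files


def save_tempo_model(model: TempoModel, path: str | Path) -> None:
    """Write a tempo model as YAML (bandwidth, modes, boundaries)."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({"bandwidth_s": model.bandwidth,
                        "mode_locations_s": list(model.mode_locations),
                        "boundaries_s": list(model.boundaries)}, fh)


def load_tempo_model(path: str | Path) -> TempoModel:
    """Load a tempo model written by :func:`save_tempo_model`."""
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        return TempoModel(bandwidth=float(d["bandwidth_s"]),
                          mode_locations=tuple(d["mode_locations_s"]),
                          boundaries=tuple(d["boundaries_s"]))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{Path(path).name}: malformed tempo model") from exc


def save_rhythm_model(model: RhythmModel, path: str | Path) -> None:
    """Write a centroid table: ``rhythm_id, click_count, s1..s9``."""
    n_s = max(9, max(c.size for c in model.centroids.values()))
    rows = []
    for rid, c in sorted(model.centroids.items()):
        row = {"rhythm_id": rid, "click_count": c.size + 1}
        for i in range(n_s):
            row[f"s{i + 1}"] = repr(float(c[i])) if i < c.size else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def load_rhythm_model(path: str | Path,
                      distance: str = "absolute") -> RhythmModel:
    """Load a centroid table written by :func:`save_rhythm_model`."""
    df = pd.read_csv(path)
    if "rhythm_id" not in df.columns or "click_count" not in df.columns:
        raise SchemaError(f"{Path(path).name}: need rhythm_id and click_count")
    s_cols = sorted((c for c in df.columns if c.startswith("s") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    if not s_cols:
        raise SchemaError(f"{Path(path).name}: no s1.. centroid columns")
    centroids: dict[str, np.ndarray] = {}
    for _, row in df.iterrows():
        vals = pd.to_numeric(row[s_cols], errors="coerce").to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size != int(row["click_count"]) - 1:
            raise SchemaError(
                f"centroid {row['rhythm_id']!r}: {vals.size} values for "
                f"click_count {row['click_count']}")
        centroids[str(row["rhythm_id"])] = vals / vals.sum()
    return RhythmModel(centroids=centroids, distance=distance)


def reference_rhythm_path() -> Path:
    """Path of the bundled synthetic 18-centroid reference table.

    These centroids are *synthetic* stand-ins with the reference
    configuration's cardinality (18 types over 3-10 clicks); substitute a
    table fitted on real data for empirical work.
    """
    return Path(__file__).parent / "data" / "reference_rhythms_synthetic.csv"
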