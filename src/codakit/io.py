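"""Reading and writing coda tables.

The canonical table is a UTF-8 CSV with a header row and columns::

    coda_id, recording_id, whale_id, onset_time_s, ici_1 .. ici_9

One row per coda; trailing ICI cells are left empty for codas shorter than
ten clicks (tables holding longer codas simply carry more ``ici_*``
columns).  ``whale_id`` and ``onset_time_s`` may be empty throughout
(repertoire-style tables); when both are filled for every row the dataset
is returned with ``ordered=True`` after sorting by onset.

A tolerant ``deposited`` dialect ingests wide annotation tables as they
circulate in the coda literature: any columns matching ``ICI<k>`` (case
insensitive, optional separator) are taken as the ICI vector, and
whale/onset columns are recognised under several common names.  Rows whose
ICI cells cannot form a valid coda are rejected and logged, never silently
dropped.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Coda,
    ExchangeDataset,
    InvalidCodaError,
    MIN_ANALYSIS_CLICKS,
    logger,
)

__all__ = ["read_codas", "write_codas", "SchemaError", "CANONICAL_COLUMNS"]

N_CANONICAL_ICI = 9

CANONICAL_COLUMNS = (
    ["coda_id", "recording_id", "whale_id", "onset_time_s"]
    + [f"ici_{i}" for i in range(1, N_CANONICAL_ICI + 1)]
)

_DEPOSITED_WHALE = ("whale", "whale_id", "speaker", "speaker_id", "id", "tag")
_DEPOSITED_ONSET = ("tsto", "onset", "onset_s", "onset_time", "time", "start")
_DEPOSITED_REC = ("rec", "recording", "recording_id", "file", "bout")


class SchemaError(ValueError):
    """Raised when a coda table lacks required columns."""


def _ici_columns(columns: list[str], dialect: str) -> list[str]:
    if dialect == "canonical":
        cols = [c for c in columns if re.fullmatch(r"ici_\d+", c)]
        return sorted(cols, key=lambda c: int(c.split("_")[1]))
    pat = re.compile(r"(?i)^ici[_ ]?(\d+)$")
    matches = [(int(m.group(1)), c) for c in columns if (m := pat.match(c.strip()))]
    return [c for _, c in sorted(matches)]


def _find_column(columns: list[str], names: tuple[str, ...]) -> str | None:
    lower = {c.strip().lower(): c for c in columns}
    for name in names:
        if name in lower:
            return lower[name]
    return None


def _parse_float(v) -> float:
    # exact round-trip parsing (pandas' fast float parser is lossy)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return np.nan
    s = str(v).strip()
    if not s:
        return np.nan
    try:
        return float(s)
    except ValueError:
        return np.nan


def _row_ici(row: pd.Series, ici_cols: list[str]) -> np.ndarray:
    vals = np.array([_parse_float(row[c]) for c in ici_cols], dtype=float)
    # ICIs fill the leading cells; the vector ends at the first empty cell.
    finite = np.isfinite(vals)
    n = int(np.argmax(~finite)) if not finite.all() else len(vals)
    if finite[n:].any():
        raise InvalidCodaError("ICI cells are not a contiguous leading block")
    return vals[:n]


def read_codas(path: str | Path, dialect: str = "canonical") -> ExchangeDataset:
    """Read a coda table into an :class:`ExchangeDataset`.

    Parameters
    ----------
    path
        CSV file to read.
    dialect
        ``"canonical"`` (fixed schema above) or ``"deposited"`` (tolerant
        wide-table adapter).

    Rows with non-positive or malformed ICIs are rejected with a warning.
    Codas with fewer than three clicks are kept but flagged with a warning,
    as they are below the analysis minimum.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    df.columns = [str(c) for c in df.columns]

    if dialect == "canonical":
        missing = [c for c in ("coda_id",) if c not in df.columns]
        if missing or not _ici_columns(list(df.columns), "canonical"):
            raise SchemaError(
                f"{path.name}: missing required canonical columns "
                f"(need coda_id and ici_1..): {missing or 'no ici_* columns'}"
            )
        id_col, whale_col, onset_col, rec_col = (
            "coda_id", "whale_id", "onset_time_s", "recording_id")
    elif dialect == "deposited":
        whale_col = _find_column(list(df.columns), _DEPOSITED_WHALE)
        onset_col = _find_column(list(df.columns), _DEPOSITED_ONSET)
        rec_col = _find_column(list(df.columns), _DEPOSITED_REC)
        id_col = _find_column(list(df.columns), ("coda_id", "coda", "index"))
        if not _ici_columns(list(df.columns), "deposited"):
            raise SchemaError(f"{path.name}: no ICI columns recognised")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    ici_cols = _ici_columns(list(df.columns), dialect)
    codas: list[Coda] = []
    n_rejected = n_short = 0
    for idx, row in df.iterrows():
        coda_id = (str(row[id_col]) if id_col and id_col in df.columns
                   and pd.notna(row[id_col]) else f"row{idx}")
        whale = (str(row[whale_col]) if whale_col and pd.notna(row[whale_col])
                 else None)
        onset = (float(row[onset_col]) if onset_col and pd.notna(row[onset_col])
                 else None)
        try:
            ici = _row_ici(row, ici_cols)
            coda = Coda(coda_id=coda_id, ici=ici, whale_id=whale, onset_time=onset)
        except InvalidCodaError as exc:
            n_rejected += 1
            logger.warning("%s row %s rejected: %s", path.name, idx, exc)
            continue
        if coda.click_count < MIN_ANALYSIS_CLICKS:
            n_short += 1
            logger.warning("%s row %s: %d-click coda below analysis minimum",
                           path.name, idx, coda.click_count)
        codas.append(coda)

    if n_rejected:
        logger.warning("%s: rejected %d of %d rows", path.name, n_rejected, len(df))

    ordered = bool(codas) and all(
        c.whale_id is not None and c.onset_time is not None for c in codas)
    if ordered:
        codas.sort(key=lambda c: c.onset_time)  # type: ignore[arg-type, return-value]
    metadata = {"source": str(path), "dialect": dialect,
                "rows_read": len(df), "rows_rejected": n_rejected}
    if rec_col and rec_col in df.columns and df[rec_col].nunique() == 1:
        metadata["recording_id"] = str(df[rec_col].iloc[0])
    return ExchangeDataset(codas, ordered=ordered, metadata=metadata)


def write_codas(dataset: ExchangeDataset, path: str | Path) -> None:
    """Write *dataset* as a canonical CSV (see module docstring).

    Reading the file back yields an equal dataset; writing that dataset
    again reproduces the file byte for byte.
    """
    path = Path(path)
    n_ici = max([N_CANONICAL_ICI] + [c.ici.size for c in dataset.codas])
    ici_cols = [f"ici_{i}" for i in range(1, n_ici + 1)]
    rec = dataset.metadata.get("recording_id", "")
    rows = []
    for c in dataset.codas:
        row: dict[str, str] = {
            "coda_id": c.coda_id,
            "recording_id": rec,
            "whale_id": c.whale_id if c.whale_id is not None else "",
            "onset_time_s": (repr(float(c.onset_time))
                             if c.onset_time is not None else ""),
        }
        for i, col in enumerate(ici_cols):
            row[col] = repr(float(c.ici[i])) if i < c.ici.size else ""
        rows.append(row)
    header = ["coda_id", "recording_id", "whale_id", "onset_time_s"] + ici_cols
    df = pd.DataFrame(rows, columns=header)
    df.to_csv(path, index=False, lineterminator="\n")
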