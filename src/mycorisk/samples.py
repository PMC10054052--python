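"""Sample records, CSV input/output and grouped summaries.

One record describes one fruiting body split into cap and stem, paired with
the mercury concentration of its underlying soil/substrate sample.  All
concentrations are on a dry-weight (DW) basis in mg kg⁻¹.

The CSV schema is fixed: ``locality, species, cap_hg_dw, stem_hg_dw,
soil_hg_dw`` — one row per fruiting body, because every downstream index
pairs a cap and a stem with exactly one substrate measurement.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, FormatError, ParseError

__all__ = [
    "DEFAULT_LOQ",
    "SampleRecord",
    "LocalitySummary",
    "read_samples",
    "write_samples",
    "summarize_by",
]

log = logging.getLogger(__name__)

#: Limit of quantification of the cold-vapour AAS mercury analyser
#: (mg kg-1 DW); values below it are unreliable and are rejected, never
#: silently zeroed.
DEFAULT_LOQ = 4.45e-6

REQUIRED_COLUMNS = ("locality", "species", "cap_hg_dw", "stem_hg_dw", "soil_hg_dw")
_CONC_COLUMNS = ("cap_hg_dw", "stem_hg_dw", "soil_hg_dw")


@dataclass(frozen=True)
class SampleRecord:
    """One fruiting body (cap + stem) and its underlying substrate."""

    locality: str
    species: str
    cap_hg_dw: float  # mg kg-1 DW
    stem_hg_dw: float  # mg kg-1 DW
    soil_hg_dw: float  # mg kg-1 DW

    def __post_init__(self) -> None:
        if not self.locality or not str(self.locality).strip():
            raise DomainError("locality must be a non-empty label")
        if not self.species or not str(self.species).strip():
            raise DomainError("species must be a non-empty label")
        for name in _CONC_COLUMNS:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise DomainError(
                    f"{name} must be finite and > 0, got {value!r} "
                    f"(locality={self.locality!r})"
                )


@dataclass(frozen=True)
class LocalitySummary:
    """Per-group mean/SD/min/max of soil, cap and stem concentrations."""

    locality: str
    n: int
    soil_mean: float
    soil_sd: float
    soil_min: float
    soil_max: float
    cap_mean: float
    cap_sd: float
    cap_min: float
    cap_max: float
    stem_mean: float
    stem_sd: float
    stem_min: float
    stem_max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("summary requires n >= 1")
        for part in ("soil", "cap", "stem"):
            lo = getattr(self, f"{part}_min")
            mu = getattr(self, f"{part}_mean")
            hi = getattr(self, f"{part}_max")
            sd = getattr(self, f"{part}_sd")
            if not (lo <= mu <= hi) or sd < 0:
                raise DomainError(f"inconsistent {part} summary for {self.locality}")


def read_samples(path: str | Path, loq: float = DEFAULT_LOQ) -> list[SampleRecord]:
    """Read validated sample records from a CSV file.

    Rows with any concentration below ``loq`` are excluded (and the count
    logged): a below-quantification value carries no usable information and
    must not be treated as zero.  Non-numeric concentration cells raise
    :class:`ParseError` with the offending 1-based data row number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        for column in REQUIRED_COLUMNS:
            if column not in header:
                raise FormatError(f"missing required column {column!r} in {path}")
        records: list[SampleRecord] = []
        n_below_loq = 0
        for row_number, row in enumerate(reader, start=1):
            values = {}
            for column in _CONC_COLUMNS:
                cell = (row[column] or "").strip()
                try:
                    values[column] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"row {row_number}: cannot parse {column}={cell!r} "
                        "as a decimal number",
                        row=row_number,
                    ) from None
                if not math.isfinite(values[column]):
                    raise ParseError(
                        f"row {row_number}: non-finite {column}={cell!r}",
                        row=row_number,
                    )
            if any(values[c] < loq for c in _CONC_COLUMNS):
                n_below_loq += 1
                continue
            records.append(
                SampleRecord(
                    locality=row["locality"].strip(),
                    species=row["species"].strip(),
                    **values,
                )
            )
    if n_below_loq:
        log.info("excluded %d record(s) below LOQ=%g from %s", n_below_loq, loq, path)
    if not records:
        raise EmptyInputError(f"no records above LOQ={loq} in {path}")
    return records


def write_samples(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Write records as CSV with full float precision (round-trip safe)."""
    records = list(records)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.locality,
                    r.species,
                    repr(float(r.cap_hg_dw)),
                    repr(float(r.stem_hg_dw)),
                    repr(float(r.soil_hg_dw)),
                ]
            )


def summarize_by(
    records: Sequence[SampleRecord], key: str = "locality"
) -> list[LocalitySummary]:
    """Summarise soil/cap/stem concentrations per group.

    ``key`` is ``"locality"`` or ``"species"``.  Uses the arithmetic mean and
    the sample standard deviation (n−1 denominator; 0 for a single record).
    Groups are returned sorted by label; the result is invariant to record
    order.
    """
    if key not in ("locality", "species"):
        raise DomainError(f"key must be 'locality' or 'species', got {key!r}")
    records = list(records)
    if not records:
        raise EmptyInputError("summarize_by received no records")
    frame = to_frame(records)
    summaries = []
    for label, group in sorted(frame.groupby(key)):
        row: dict[str, float | int | str] = {"locality": str(label), "n": len(group)}
        for part, column in (("soil", "soil_hg_dw"), ("cap", "cap_hg_dw"), ("stem", "stem_hg_dw")):
            x = group[column].to_numpy()
            row[f"{part}_mean"] = float(np.mean(x))
            row[f"{part}_sd"] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            row[f"{part}_min"] = float(np.min(x))
            row[f"{part}_max"] = float(np.max(x))
        summaries.append(LocalitySummary(**row))  # type: ignore[arg-type]
    return summaries


def to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a record collection."""
    return pd.DataFrame(
        {
            "locality": [r.locality for r in records],
            "species": [r.species for r in records],
            "cap_hg_dw": [r.cap_hg_dw for r in records],
            "stem_hg_dw": [r.stem_hg_dw for r in records],
            "soil_hg_dw": [r.soil_hg_dw for r in records],
        }
    )


def summaries_to_frame(summaries: Sequence[LocalitySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
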