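"""Plate-level CSV input/output.

Endpoint-fluorescence genotyping data is a per-well table: two normalized
reporter signals (allele-1 channel ``signal_x``, e.g. FAM Rn; allele-2 channel
``signal_y``, e.g. VIC Rn), sample / assay / platform identity and an NTC
(no-template control) flag.  This module fixes a plain CSV dialect for that
table, a matching dialect for genotype-call tables, and a tolerant
``instrument_export`` reader mode that skips instrument preamble lines and maps
vendor column headings onto the canonical names.

Signals are treated as opaque normalized fluorescence values: they may be
negative after instrument baselining, and the writer serializes them with
17 significant digits so that a write/read round-trip is lossless.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FluorescencePoint",
    "PlateFormatError",
    "PLATE_COLUMNS",
    "CALL_COLUMNS",
    "CALL_LABELS",
    "GENOTYPE_LABELS",
    "read_plate",
    "write_plate",
    "points_to_frame",
    "frame_to_points",
    "write_calls",
    "read_calls",
]

#: Canonical plate-table column order.
PLATE_COLUMNS = (
    "well_id",
    "sample_id",
    "assay_id",
    "platform_id",
    "signal_x",
    "signal_y",
    "is_ntc",
)

#: Canonical call-table column order.
CALL_COLUMNS = ("sample_id", "assay_id", "platform_id", "label", "quality")

#: Every label a call table may contain.
CALL_LABELS = ("A11", "A12", "A22", "INVALID", "FAILED", "NTC")

#: The three genotype classes (homozygote-1, heterozygote, homozygote-2).
GENOTYPE_LABELS = ("A11", "A12", "A22")

#: Header aliases accepted by the ``instrument_export`` dialect, mapping
#: vendor-style column headings onto canonical names.
DEFAULT_COLUMN_ALIASES: Mapping[str, str] = {
    "Well": "well_id",
    "Well Position": "well_id",
    "Sample": "sample_id",
    "Sample Name": "sample_id",
    "SNP Assay Name": "assay_id",
    "Assay": "assay_id",
    "Assay ID": "assay_id",
    "Platform": "platform_id",
    "Allele1 Rn": "signal_x",
    "Allele1 Delta Rn": "signal_x",
    "FAM Rn": "signal_x",
    "Allele2 Rn": "signal_y",
    "Allele2 Delta Rn": "signal_y",
    "VIC Rn": "signal_y",
    "NTC": "is_ntc",
    "Is NTC": "is_ntc",
}

_TRUE_STRINGS = {"true", "1", "yes", "ntc", "t"}
_FALSE_STRINGS = {"false", "0", "no", "f", ""}


class PlateFormatError(ValueError):
    """A plate or call CSV does not conform to the documented dialect."""


@dataclass(frozen=True)
class FluorescencePoint:
    """One well's endpoint fluorescence readout.

    ``signal_x`` is the allele-1 reporter (the FAM Rn role on TaqMan),
    ``signal_y`` the allele-2 reporter (the VIC Rn role).  NTC wells carry
    ``sample_id == "NTC"`` and ``is_ntc=True``; their mean signal anchors all
    downstream geometry.
    """

    well_id: str
    sample_id: str
    assay_id: str
    platform_id: str
    signal_x: float
    signal_y: float
    is_ntc: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.signal_x) and math.isfinite(self.signal_y)):
            raise PlateFormatError(
                f"non-finite signal in well {self.well_id!r}: "
                f"({self.signal_x}, {self.signal_y})"
            )


def _format_signal(value: float) -> str:
    return format(float(value), ".17g")


def _parse_bool(raw: str, well_id: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS:
        return False
    raise PlateFormatError(f"cannot parse is_ntc value {raw!r} in well {well_id!r}")


def _parse_signal(raw: str, column: str, well_id: str) -> float:
    try:
        value = float(raw)
    except ValueError as exc:
        raise PlateFormatError(
            f"non-numeric {column} value {raw!r} in well {well_id!r}"
        ) from exc
    if not math.isfinite(value):
        raise PlateFormatError(
            f"non-finite {column} value {raw!r} in well {well_id!r}"
        )
    return value


def read_plate(
    path: str | Path,
    dialect: str = "plain",
    column_aliases: Mapping[str, str] | None = None,
) -> list[FluorescencePoint]:
    """Read a plate CSV into a list of :class:`FluorescencePoint`.

    Parameters
    ----------
    path
        CSV file to read.
    dialect
        ``"plain"`` expects exactly the canonical header.  ``"instrument_export"``
        additionally skips leading metadata lines beginning with ``#`` or ``*``
        and maps vendor column headings through *column_aliases*.
    column_aliases
        Extra ``{vendor heading: canonical name}`` entries for the
        ``instrument_export`` dialect; merged over the built-in defaults.

    The reader preserves row order.
    """
    if dialect not in ("plain", "instrument_export"):
        raise ValueError(f"unknown dialect {dialect!r}")
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_aliases:
        aliases.update(column_aliases)

    path = Path(path)
    with path.open(newline="") as handle:
        lines: Iterable[str] = handle
        if dialect == "instrument_export":
            lines = (ln for ln in handle if not ln.lstrip().startswith(("#", "*")))
        reader = csv.reader(lines)
        try:
            header = next(reader)
        except StopIteration:
            raise PlateFormatError(f"{path}: empty file, no header") from None
        if dialect == "instrument_export":
            header = [aliases.get(name.strip(), name.strip()) for name in header]
        missing = [c for c in PLATE_COLUMNS if c not in header]
        if missing:
            raise PlateFormatError(
                f"{path}: missing required column {missing[0]!r}"
            )
        idx = {name: header.index(name) for name in PLATE_COLUMNS}

        points: list[FluorescencePoint] = []
        for row in reader:
            if not row or all(not cell.strip() for cell in row):
                continue
            well_id = row[idx["well_id"]]
            points.append(
                FluorescencePoint(
                    well_id=well_id,
                    sample_id=row[idx["sample_id"]],
                    assay_id=row[idx["assay_id"]],
                    platform_id=row[idx["platform_id"]],
                    signal_x=_parse_signal(row[idx["signal_x"]], "signal_x", well_id),
                    signal_y=_parse_signal(row[idx["signal_y"]], "signal_y", well_id),
                    is_ntc=_parse_bool(row[idx["is_ntc"]], well_id),
                )
            )
    return points


def write_plate(points: Sequence[FluorescencePoint], path: str | Path) -> None:
    """Write points to *path* in the canonical plate dialect (RFC-4180)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(PLATE_COLUMNS)
        for p in points:
            writer.writerow(
                [
                    p.well_id,
                    p.sample_id,
                    p.assay_id,
                    p.platform_id,
                    _format_signal(p.signal_x),
                    _format_signal(p.signal_y),
                    "true" if p.is_ntc else "false",
                ]
            )


def points_to_frame(points: Sequence[FluorescencePoint]) -> pd.DataFrame:
    """Tabular view of a point list (columns = :data:`PLATE_COLUMNS`)."""
    return pd.DataFrame(
        {
            "well_id": [p.well_id for p in points],
            "sample_id": [p.sample_id for p in points],
            "assay_id": [p.assay_id for p in points],
            "platform_id": [p.platform_id for p in points],
            "signal_x": [p.signal_x for p in points],
            "signal_y": [p.signal_y for p in points],
            "is_ntc": [p.is_ntc for p in points],
        }
    )


def frame_to_points(frame: pd.DataFrame) -> list[FluorescencePoint]:
    """Inverse of :func:`points_to_frame`."""
    return [
        FluorescencePoint(
            well_id=str(r.well_id),
            sample_id=str(r.sample_id),
            assay_id=str(r.assay_id),
            platform_id=str(r.platform_id),
            signal_x=float(r.signal_x),
            signal_y=float(r.signal_y),
            is_ntc=bool(r.is_ntc),
        )
        for r in frame.itertuples(index=False)
    ]


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check call-table invariants; returns the frame unchanged.

    Labels must be drawn from :data:`CALL_LABELS`; quality is in [0, 1] for
    genotype rows and missing (NaN) for every other label.
    """
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise PlateFormatError(f"call table missing required column {missing[0]!r}")
    bad = set(calls["label"].unique()) - set(CALL_LABELS)
    if bad:
        raise PlateFormatError(f"call table contains unknown labels {sorted(bad)}")
    genotyped = calls["label"].isin(GENOTYPE_LABELS)
    q = calls.loc[genotyped, "quality"]
    if q.isna().any() or ((q < 0) | (q > 1)).any():
        raise PlateFormatError("genotype rows must carry quality in [0, 1]")
    if calls.loc[~genotyped, "quality"].notna().any():
        raise PlateFormatError("non-genotype rows must have missing quality")
    return calls


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a call table; missing quality serializes as an empty field."""
    validate_calls(calls)
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(CALL_COLUMNS)
        for r in calls.itertuples(index=False):
            quality = "" if pd.isna(r.quality) else _format_signal(r.quality)
            writer.writerow([r.sample_id, r.assay_id, r.platform_id, r.label, quality])


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls`."""
    path = Path(path)
    frame = pd.read_csv(
        path,
        dtype={
            "sample_id": str,
            "assay_id": str,
            "platform_id": str,
            "label": str,
        },
        float_precision="round_trip",
    )
    missing = [c for c in CALL_COLUMNS if c not in frame.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing required column {missing[0]!r}")
    if frame.empty:
        frame = frame.astype({"quality": float})
    return validate_calls(frame[list(CALL_COLUMNS)])
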