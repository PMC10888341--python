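"""Raw sensor parsing, reading averaging, clear-channel normalization and
the dataset interchange CSV.

The acquisition protocol averages 10 raw readings per specimen and then
divides the averaged R, G, B counts by the averaged clear count C, yielding
the three dimensionless descriptors used by every model. Averaging precedes
normalization throughout this package.
"""

from __future__ import annotations

import io
from dataclasses import replace
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

from .core import (
    ColourFeature,
    Dataset,
    DegenerateReadingError,
    Illuminant,
    OilIdentity,
    OilSample,
    ParseError,
    RawReading,
    SchemaError,
    Task,
)

#: Column order of the dataset interchange CSV (one row per sample).
CSV_COLUMNS = [
    "sample_id",
    "oil",
    "fraction",
    "replicate",
    "illuminant",
    "R",
    "G",
    "B",
    "C",
    "r",
    "g",
    "b",
]


def parse_sensor_log(lines: Iterable[str] | IO[str], illum: Illuminant) -> list[RawReading]:
    """Parse a raw sensor log: one "R,G,B,C" integer quadruple per line.

    Blank lines are skipped; anything else that is not four comma-separated
    nonnegative integers raises :class:`ParseError` naming the line number
    (1-based).
    """
    readings: list[RawReading] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        fields = [f.strip() for f in stripped.split(",")]
        if len(fields) != 4:
            raise ParseError(
                f"line {lineno}: expected 4 comma-separated values, got {len(fields)}"
            )
        values: list[int] = []
        for f in fields:
            try:
                v = int(f)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer field {f!r}") from None
            if v < 0:
                raise ParseError(f"line {lineno}: negative channel value {v}")
            values.append(v)
        readings.append(RawReading(*values, illuminant=illum))
    return readings


def average_readings(readings: list[RawReading]) -> RawReading:
    """Channel-wise arithmetic mean of repeated acquisitions.

    The mean is kept real-valued; metadata (illuminant, integration time,
    gain) is propagated from the first reading.
    """
    if not readings:
        raise ValueError("cannot average an empty list of readings")
    illums = {r.illuminant for r in readings}
    if len(illums) != 1:
        raise ValueError("cannot average readings from mixed illuminants")
    arr = np.array([r.channels() for r in readings], dtype=float)
    mean = arr.mean(axis=0)
    return replace(readings[0], R=mean[0], G=mean[1], B=mean[2], C=mean[3])


def normalize(raw: RawReading) -> ColourFeature:
    """Clear-channel normalization: (r, g, b) = (R/C, G/C, B/C).

    Scale-invariant: multiplying all four channels by k > 0 leaves the
    features unchanged, which is what makes the descriptors robust to
    overall illumination intensity.
    """
    if raw.C <= 0:
        raise DegenerateReadingError("clear channel C must be positive to normalize")
    return ColourFeature(raw.R / raw.C, raw.G / raw.C, raw.B / raw.C)


def make_sample(
    sample_id: str,
    oil: OilIdentity,
    fraction: float,
    replicate: int,
    raw: RawReading,
) -> OilSample:
    """Assemble a labelled sample, deriving features from the raw reading."""
    return OilSample(
        sample_id=sample_id,
        oil=oil,
        fraction=fraction,
        replicate=replicate,
        illuminant=raw.illuminant,
        raw=raw,
        features=normalize(raw),
    )


def write_dataset(ds: Dataset, path) -> None:
    """Write a dataset to the interchange CSV at full float precision."""
    rows = []
    for s in ds.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "oil": s.oil.value,
                "fraction": repr(s.fraction),
                "replicate": s.replicate,
                "illuminant": s.illuminant.value,
                "R": repr(s.raw.R),
                "G": repr(s.raw.G),
                "B": repr(s.raw.B),
                "C": repr(s.raw.C),
                "r": repr(s.features.r),
                "g": repr(s.features.g),
                "b": repr(s.features.b),
            }
        )
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    with open(path, "w", newline="") as fh:
        if ds.provenance:
            fh.write(f"# task={ds.task.value} provenance={ds.provenance}\n")
        frame.to_csv(fh, index=False)


def read_dataset(path, task: Task | None = None) -> Dataset:
    """Read a dataset from the interchange CSV.

    Schema violations (missing columns, unknown oil or illuminant tokens,
    fractions outside [0, 0.5]) raise :class:`SchemaError` naming the row.
    The task defaults to multiclass for mixed-adulterant files and
    regression for single-adulterant files unless given explicitly.
    """
    provenance = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            provenance = first.lstrip("#").strip()
            frame = pd.read_csv(fh, dtype=str)
        else:
            frame = pd.read_csv(io.StringIO(first + fh.read()), dtype=str)

    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    samples: list[OilSample] = []
    for i, row in frame.iterrows():
        rowno = int(i) + 1
        try:
            oil = OilIdentity.parse(row["oil"])
            illum = Illuminant.parse(row["illuminant"])
        except Exception as exc:
            raise SchemaError(f"row {rowno}: {exc}") from None
        fraction = float(row["fraction"])
        if not (0.0 <= fraction <= 0.5):
            raise SchemaError(f"row {rowno}: fraction {fraction} outside [0, 0.5]")
        try:
            raw = RawReading(
                R=float(row["R"]),
                G=float(row["G"]),
                B=float(row["B"]),
                C=float(row["C"]),
                illuminant=illum,
            )
            sample = OilSample(
                sample_id=str(row["sample_id"]),
                oil=oil,
                fraction=fraction,
                replicate=int(row["replicate"]),
                illuminant=illum,
                raw=raw,
                features=ColourFeature(
                    float(row["r"]), float(row["g"]), float(row["b"])
                ),
            )
        except ValueError as exc:
            raise SchemaError(f"row {rowno}: {exc}") from None
        samples.append(sample)

    if task is None:
        adulterants = {s.oil for s in samples if not s.is_pure}
        task = Task.REGRESSION if len(adulterants) <= 1 else Task.MULTICLASS
    return Dataset(samples=samples, task=task, provenance=provenance)
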