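"""Data model and file I/O for landing-event tables, species sheets, sample
sheets and study reports.

A mass-photometry acquisition yields one signed ratiometric contrast value
per detected particle-landing event.  Events are exchanged as plain CSV
(comma separator, dot decimal, UTF-8, one row per event) with columns
``measurement_id, day_id, sample_id, contrast``.  Species sheets declare
calibrant identities (``name, material_class, size_value, size_unit``) and
sample sheets declare AAV samples with their expected genome length.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ContrastMeasurement",
    "SpeciesSpec",
    "AAVSampleSpec",
    "MATERIAL_CLASSES",
    "normalize_sign",
    "read_events_csv",
    "write_events_csv",
    "read_species_csv",
    "write_species_csv",
    "read_samples_csv",
    "write_report",
    "read_report",
]

MATERIAL_CLASSES = frozenset(
    {
        "protein",
        "aav_capsid",
        "dsDNA",
        "ssRNA",
        "ssDNA_circular",
        "ssDNA_linear",
        "hmw_standard",
    }
)

#: Unit expected for each material class.
_CLASS_UNIT = {
    "protein": "kDa",
    "aav_capsid": "kDa",
    "hmw_standard": "kDa",
    "dsDNA": "bp",
    "ssRNA": "bases",
    "ssDNA_circular": "bases",
    "ssDNA_linear": "bases",
}

_EVENT_COLUMNS = ["measurement_id", "day_id", "sample_id", "contrast"]
_SPECIES_COLUMNS = ["name", "material_class", "size_value", "size_unit"]


@dataclass
class ContrastMeasurement:
    """The event list of one 60-s mass-photometry acquisition.

    Parameters
    ----------
    measurement_id : str
        Unique identifier of the acquisition.
    events : array-like of float
        Signed ratiometric contrasts, one per landing event.  Canonical
        sign is negative (mass binding).
    day_id, sample_id : str
        Grouping metadata for study-level aggregation.
    duration_s : float
        Acquisition length in seconds (default 60).
    allow_empty : bool
        Permit an empty event list (e.g. a failed acquisition placeholder).
    """

    measurement_id: str
    events: np.ndarray
    day_id: str = ""
    sample_id: str = ""
    duration_s: float = 60.0
    metadata: dict = field(default_factory=dict)
    allow_empty: bool = False

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float)
        if ev.ndim != 1:
            raise ValidationError("events must be a 1-D sequence of contrasts")
        if ev.size == 0 and not self.allow_empty:
            raise ValidationError(
                f"measurement {self.measurement_id!r} has no events; "
                "pass allow_empty=True if this is intentional"
            )
        if ev.size and not np.all(np.isfinite(ev)):
            raise ValidationError(
                f"measurement {self.measurement_id!r} contains non-finite contrasts"
            )
        self.events = ev

    @property
    def n_events(self) -> int:
        return int(self.events.size)

    def shifted(self, offset: float) -> "ContrastMeasurement":
        """Return a copy with a constant contrast offset added to every event."""
        return ContrastMeasurement(
            measurement_id=self.measurement_id,
            events=self.events + offset,
            day_id=self.day_id,
            sample_id=self.sample_id,
            duration_s=self.duration_s,
            metadata=dict(self.metadata),
            allow_empty=self.allow_empty,
        )


@dataclass(frozen=True)
class SpeciesSpec:
    """A calibrant species with its known mass or chain length."""

    name: str
    material_class: str
    size_value: float
    size_unit: str

    def __post_init__(self) -> None:
        if self.material_class not in MATERIAL_CLASSES:
            raise ValidationError(
                f"unknown material_class {self.material_class!r}; "
                f"expected one of {sorted(MATERIAL_CLASSES)}"
            )
        expected = _CLASS_UNIT[self.material_class]
        if self.size_unit != expected:
            raise ValidationError(
                f"species {self.name!r}: class {self.material_class!r} requires "
                f"unit {expected!r}, got {self.size_unit!r}"
            )
        if not (self.size_value > 0) or not math.isfinite(self.size_value):
            raise ValidationError(
                f"species {self.name!r}: size_value must be a positive finite number"
            )


#: Sentinel for an AAV sample whose genome length is not known a priori.
UNKNOWN = "unknown"


@dataclass(frozen=True)
class AAVSampleSpec:
    """An AAV sample under study.

    ``expected_genome_length`` is in bases; 0 means a deliberately empty
    capsid, while an unknown payload is the explicit string ``"unknown"``
    (never 0, which is a meaningful value).
    """

    sample_id: str
    serotype: str = ""
    expected_genome_length: float | str = UNKNOWN
    spiked_reference: SpeciesSpec | None = None

    def __post_init__(self) -> None:
        exp = self.expected_genome_length
        if isinstance(exp, str):
            if exp != UNKNOWN:
                raise ValidationError(
                    f"sample {self.sample_id!r}: expected_genome_length must be a "
                    f"number of bases or {UNKNOWN!r}, got {exp!r}"
                )
        elif not (math.isfinite(float(exp)) and float(exp) >= 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: expected_genome_length must be >= 0"
            )

    @property
    def expected_known(self) -> bool:
        return not isinstance(self.expected_genome_length, str)


def normalize_sign(values: np.ndarray, policy: str = "auto") -> np.ndarray:
    """Normalize contrast signs to the canonical (negative) convention.

    ``as_is`` keeps the values; ``force_negative`` maps each value to
    ``-|value|``; ``auto`` negates the whole list when more than half of
    the values are positive (vendor exports differ in sign convention).
    Idempotent for every policy.
    """
    values = np.asarray(values, dtype=float)
    if policy == "as_is":
        return values
    if policy == "force_negative":
        return -np.abs(values)
    if policy == "auto":
        if values.size and np.count_nonzero(values > 0) > values.size / 2:
            return -values
        return values
    raise ValidationError(f"unknown sign_policy {policy!r}")


def _read_table(source, columns: Sequence[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{what} file has no header row") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what} file is missing required column(s): {', '.join(missing)}")
    return df


def read_events_csv(
    source: str | Path | IO[str],
    sign_policy: str = "auto",
) -> list[ContrastMeasurement]:
    """Read a landing-event table, grouping rows by ``measurement_id``.

    Row order within each measurement is preserved.  Sign normalization is
    applied per measurement according to ``sign_policy``.
    """
    df = _read_table(source, _EVENT_COLUMNS, "events")
    if df.empty:
        warnings.warn("events file contains a header but no rows", stacklevel=2)
        return []
    contrasts = pd.to_numeric(df["contrast"], errors="coerce")
    bad = contrasts.isna() | ~np.isfinite(contrasts.to_numpy(dtype=float))
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise FormatError(
            f"non-numeric or non-finite contrast value "
            f"{df.loc[df.index[bad][0], 'contrast']!r} at line {line}"
        )
    df = df.assign(contrast=contrasts.to_numpy(dtype=float))

    out: list[ContrastMeasurement] = []
    for mid, grp in df.groupby("measurement_id", sort=False):
        events = normalize_sign(grp["contrast"].to_numpy(), sign_policy)
        out.append(
            ContrastMeasurement(
                measurement_id=str(mid),
                events=events,
                day_id=str(grp["day_id"].iloc[0]),
                sample_id=str(grp["sample_id"].iloc[0]),
            )
        )
    return out


def write_events_csv(
    measurements: Iterable[ContrastMeasurement],
    dest: str | Path | IO[str],
) -> None:
    """Write measurements to the events CSV dialect (one row per event)."""
    frames = []
    for m in measurements:
        frames.append(
            pd.DataFrame(
                {
                    "measurement_id": m.measurement_id,
                    "day_id": m.day_id,
                    "sample_id": m.sample_id,
                    "contrast": m.events,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=_EVENT_COLUMNS)
    df.to_csv(dest, index=False)


def read_species_csv(source: str | Path | IO[str]) -> list[SpeciesSpec]:
    """Read a species sheet declaring calibrant identities."""
    df = _read_table(source, _SPECIES_COLUMNS, "species")
    specs = []
    for i, row in df.iterrows():
        try:
            size = float(row["size_value"])
        except (TypeError, ValueError):
            raise FormatError(
                f"non-numeric size_value {row['size_value']!r} at line {int(i) + 2}"
            ) from None
        specs.append(
            SpeciesSpec(
                name=str(row["name"]),
                material_class=str(row["material_class"]),
                size_value=size,
                size_unit=str(row["size_unit"]),
            )
        )
    return specs


def write_species_csv(species: Iterable[SpeciesSpec], dest) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "material_class": s.material_class,
                "size_value": s.size_value,
                "size_unit": s.size_unit,
            }
            for s in species
        ],
        columns=_SPECIES_COLUMNS,
    ).to_csv(dest, index=False)


def read_samples_csv(source: str | Path | IO[str]) -> list[AAVSampleSpec]:
    """Read a sample sheet: ``sample_id, serotype, expected_genome_length``.

    ``expected_genome_length`` is bases or the literal string ``unknown``.
    """
    df = _read_table(source, ["sample_id", "expected_genome_length"], "samples")
    out = []
    for i, row in df.iterrows():
        raw = str(row["expected_genome_length"]).strip()
        if raw.lower() == UNKNOWN:
            exp: float | str = UNKNOWN
        else:
            try:
                exp = float(raw)
            except ValueError:
                raise FormatError(
                    f"expected_genome_length must be bases or 'unknown', "
                    f"got {raw!r} at line {int(i) + 2}"
                ) from None
        serotype = str(row["serotype"]) if "serotype" in df.columns else ""
        out.append(
            AAVSampleSpec(
                sample_id=str(row["sample_id"]),
                serotype=serotype,
                expected_genome_length=exp,
            )
        )
    return out


def _check_finite(obj, path: str = "$") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{path}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}[{i}]")
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise ValidationError(f"non-finite number at {path} cannot be serialized")


def write_report(report, dest: str | Path | IO[str]) -> None:
    """Serialize a :class:`~mpsize.sizing.StudyReport` to JSON.

    Keys are emitted in deterministic (sorted) order and non-finite numbers
    are refused, so re-reading yields an equal report byte-for-byte.
    """
    payload = report.to_dict()
    _check_finite(payload)
    text = json.dumps(payload, indent=2, sort_keys=True)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text + "\n", encoding="utf-8")
    else:
        dest.write(text + "\n")


def read_report(source: str | Path | IO[str]):
    """Read a study report written by :func:`write_report`."""
    from .sizing import StudyReport  # deferred: sizing builds on this module

    if isinstance(source, (str, Path)):
        payload = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        payload = json.load(source)
    return StudyReport.from_dict(payload)
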