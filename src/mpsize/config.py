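"""Run configuration and the end-to-end pipeline.

A run is described by a small YAML file::

    events: events.csv          # landing-event table
    species: species.csv        # calibrant sheet (standard families)
    samples: samples.csv        # AAV sample sheet
    approach: a1                # a1 | a2_delta | a2_abs | a3
    calibration:
      family: protein_mass
      include_empty: false      # aav_abs_bases only
      reference_label: aav_empty
    regions:
      fragment_max: 0.030
      released: [0.030, 0.07]
      aav: [0.10, 0.20]
      aggregate_min: 0.5
    bandwidths:
      intact: [40.0, kDa]       # or [120.0, bases] / [120.0, bp]
      released: [50.0, bases]
    seed: 1
    out: report.json
    verbosity: 0

Unknown keys are rejected; omitted keys take the documented defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import constants
from .calibration import FAMILIES, fit_calibration_from_measurements
from .errors import ConfigError, ValidationError
from .events_io import read_events_csv, read_samples_csv, read_species_csv, write_report
from .peaks import RegionConfig
from .sizing import (
    StudyReport,
    aggregate_study,
    build_aav_abs_calibration,
    build_aav_delta_calibration,
    size_approach1,
    size_approach2_abs,
    size_approach2_delta,
    size_approach3,
)

__all__ = ["RunConfig", "parse_config", "serialize_config", "run_pipeline"]

log = logging.getLogger("mpsize")

_APPROACH_FAMILIES = {
    "a1": {"protein_mass", "dsDNA_bp", "RNA_bases", "ssDNA_plasmid_bases"},
    "a2_delta": {"aav_delta_bases"},
    "a2_abs": {"aav_abs_bases"},
    "a3": {"RNA_bases", "ssDNA_plasmid_bases"},
}

_TOP_KEYS = {
    "events",
    "species",
    "samples",
    "approach",
    "calibration",
    "regions",
    "bandwidths",
    "seed",
    "out",
    "verbosity",
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    events: str
    approach: str
    family: str
    species: str | None = None
    samples: str | None = None
    include_empty: bool = False
    reference_label: str = "aav_empty"
    regions: RegionConfig = field(default_factory=RegionConfig)
    bandwidth_intact: tuple[float, str] = (constants.BANDWIDTH_INTACT_KDA, "kDa")
    bandwidth_released: tuple[float, str] = (constants.BANDWIDTH_RELEASED_BASES, "bases")
    seed: int | None = None
    out: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.approach not in _APPROACH_FAMILIES:
            raise ConfigError(
                f"approach must be one of {sorted(_APPROACH_FAMILIES)}, got {self.approach!r}"
            )
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown calibration family {self.family!r}")
        if self.family not in _APPROACH_FAMILIES[self.approach]:
            raise ConfigError(
                f"approach {self.approach!r} is incompatible with calibration "
                f"family {self.family!r}"
            )
        for bw, unit in (self.bandwidth_intact, self.bandwidth_released):
            if bw <= 0:
                raise ConfigError("bandwidths must be > 0")
            if unit not in ("kDa", "bases", "bp", "contrast"):
                raise ConfigError(f"unknown bandwidth unit {unit!r}")


def parse_config(path: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    if isinstance(path, dict):
        raw = dict(path)
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "events" not in raw:
        raise ConfigError("config key 'events' (path to events CSV) is required")
    if "approach" not in raw:
        raise ConfigError("config key 'approach' is required")

    cal = raw.get("calibration") or {}
    unknown = set(cal) - {"family", "include_empty", "reference_label"}
    if unknown:
        raise ConfigError(f"unknown calibration key(s): {', '.join(sorted(unknown))}")
    if "family" not in cal:
        raise ConfigError("config key 'calibration.family' is required")

    reg = raw.get("regions") or {}
    unknown = set(reg) - {"fragment_max", "released", "aav", "aggregate_min"}
    if unknown:
        raise ConfigError(f"unknown regions key(s): {', '.join(sorted(unknown))}")
    try:
        regions = RegionConfig(
            fragment_max=float(reg.get("fragment_max", 0.030)),
            released=tuple(reg.get("released", (0.030, 0.07))),
            aav=tuple(reg.get("aav", (0.10, 0.20))),
            aggregate_min=float(reg.get("aggregate_min", 0.5)),
        )
    except ValidationError as exc:
        raise ConfigError(f"invalid regions: {exc}") from exc

    bws = raw.get("bandwidths") or {}
    unknown = set(bws) - {"intact", "released"}
    if unknown:
        raise ConfigError(f"unknown bandwidths key(s): {', '.join(sorted(unknown))}")

    def _bw(key, default):
        v = bws.get(key, default)
        if not (isinstance(v, (list, tuple)) and len(v) == 2):
            raise ConfigError(f"bandwidths.{key} must be [value, unit]")
        return (float(v[0]), str(v[1]))

    return RunConfig(
        events=str(raw["events"]),
        approach=str(raw["approach"]),
        family=str(cal["family"]),
        species=None if raw.get("species") is None else str(raw["species"]),
        samples=None if raw.get("samples") is None else str(raw["samples"]),
        include_empty=bool(cal.get("include_empty", False)),
        reference_label=str(cal.get("reference_label", "aav_empty")),
        regions=regions,
        bandwidth_intact=_bw("intact", (constants.BANDWIDTH_INTACT_KDA, "kDa")),
        bandwidth_released=_bw("released", (constants.BANDWIDTH_RELEASED_BASES, "bases")),
        seed=None if raw.get("seed") is None else int(raw["seed"]),
        out=None if raw.get("out") is None else str(raw["out"]),
        verbosity=int(raw.get("verbosity", 0)),
    )


def serialize_config(cfg: RunConfig) -> dict:
    """Inverse of :func:`parse_config`: a dict that reparses identically."""
    return {
        "events": cfg.events,
        "species": cfg.species,
        "samples": cfg.samples,
        "approach": cfg.approach,
        "calibration": {
            "family": cfg.family,
            "include_empty": cfg.include_empty,
            "reference_label": cfg.reference_label,
        },
        "regions": {
            "fragment_max": cfg.regions.fragment_max,
            "released": list(cfg.regions.released),
            "aav": list(cfg.regions.aav),
            "aggregate_min": cfg.regions.aggregate_min,
        },
        "bandwidths": {
            "intact": list(cfg.bandwidth_intact),
            "released": list(cfg.bandwidth_released),
        },
        "seed": cfg.seed,
        "out": cfg.out,
        "verbosity": cfg.verbosity,
    }


def _size_one(cfg: RunConfig, m, curve):
    if cfg.approach == "a1":
        return size_approach1(
            m, curve, regions=cfg.regions,
            bandwidth=cfg.bandwidth_intact[0], bandwidth_unit=cfg.bandwidth_intact[1],
        )
    if cfg.approach == "a2_delta":
        return size_approach2_delta(
            m, curve, reference_label=cfg.reference_label, regions=cfg.regions,
            bandwidth=cfg.bandwidth_intact[0], bandwidth_unit=cfg.bandwidth_intact[1],
        )
    if cfg.approach == "a2_abs":
        return size_approach2_abs(
            m, curve, regions=cfg.regions,
            bandwidth=cfg.bandwidth_intact[0], bandwidth_unit=cfg.bandwidth_intact[1],
        )
    return size_approach3(
        m, curve, regions=cfg.regions,
        bandwidth=cfg.bandwidth_released[0], bandwidth_unit=cfg.bandwidth_released[1],
    )


def run_pipeline(cfg: RunConfig) -> StudyReport:
    """Run the full study pipeline described by a configuration.

    Measurements whose ``sample_id`` matches a species-sheet name are
    calibrant acquisitions; the rest are analyte samples.  For the AAV
    calibration families, samples with a known expected genome length act
    as the calibration set and each of them is sized leave-one-out, so
    its own measurements never calibrate themselves.
    """
    measurements = read_events_csv(cfg.events)
    log.info("read %d measurements from %s", len(measurements), cfg.events)
    species = read_species_csv(cfg.species) if cfg.species else []
    samples = read_samples_csv(cfg.samples) if cfg.samples else []
    species_by_name = {s.name: s for s in species}
    expected = {
        s.sample_id: float(s.expected_genome_length) if s.expected_known else None
        for s in samples
    }

    calibrant_ms = [m for m in measurements if m.sample_id in species_by_name]
    sample_ms = [m for m in measurements if m.sample_id not in species_by_name]
    by_sample: dict[str, list] = {}
    for m in sample_ms:
        by_sample.setdefault(m.sample_id, []).append(m)

    report = StudyReport(provenance={"seed": cfg.seed, "approach": cfg.approach})

    def _aav_curve(exclude: str | None):
        items = [
            (m, expected[sid])
            for sid, ms in by_sample.items()
            if sid != exclude and expected.get(sid) is not None
            for m in ms
        ]
        if cfg.approach == "a2_delta":
            return build_aav_delta_calibration(
                items, reference_label=cfg.reference_label, regions=cfg.regions,
                bandwidth=cfg.bandwidth_intact[0], bandwidth_unit=cfg.bandwidth_intact[1],
            )
        return build_aav_abs_calibration(
            items, include_empty=cfg.include_empty, regions=cfg.regions,
            bandwidth=cfg.bandwidth_intact[0], bandwidth_unit=cfg.bandwidth_intact[1],
        )

    if cfg.approach in ("a1", "a3"):
        pairs = [(species_by_name[m.sample_id], m) for m in calibrant_ms]
        pairs = [(s, m) for s, m in pairs if _family_matches(cfg.family, s.material_class)]
        curve = fit_calibration_from_measurements(pairs, cfg.family)
        log.info(
            "calibration %s: slope=%.4g intercept=%.4g r2=%.6f (%d points)",
            cfg.family, curve.slope, curve.intercept, curve.r_squared, len(curve.points),
        )
        report.calibrations.append(curve)
        curves = {sid: curve for sid in by_sample}
    else:
        curves = {}
        for sid in by_sample:
            exclude = sid if expected.get(sid) is not None else None
            curves[sid] = _aav_curve(exclude)
        if by_sample:
            report.calibrations.append(_aav_curve(None))

    for sid, ms in sorted(by_sample.items()):
        per_measurement = []
        for m in ms:
            bases = _size_one(cfg, m, curves[sid])
            log.info("sized %s / %s: %.1f bases", sid, m.measurement_id, bases)
            per_measurement.append((m.measurement_id, m.day_id, bases))
        report.estimates.append(
            aggregate_study(
                per_measurement,
                expected=expected.get(sid),
                sample_id=sid,
                approach=cfg.approach,
                reference_label=cfg.reference_label if cfg.approach == "a2_delta" else "none",
            )
        )
    if cfg.out:
        write_report(report, cfg.out)
        log.info("report written to %s", cfg.out)
    return report


def _family_matches(family: str, material_class: str) -> bool:
    from .calibration import FAMILY_MATERIAL_CLASSES

    return material_class in FAMILY_MATERIAL_CLASSES.get(family, frozenset())
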