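"""Genome-length determination from fitted contrast peaks.

Three approaches are implemented:

1. **Approach 1** — the contrast difference between the filled and empty
   capsid populations of an intact AAV sample is converted to bases
   through a protein, dsDNA, RNA or ssDNA-plasmid calibration (the mass
   route applies 309 kDa = 1,000 bases; the bp route doubles).
2. **Approach 2** — AAVs of known genome length serve as calibrants,
   either through their filled-minus-reference contrast differences
   (``a2_delta``; reference = empty capsid or HMW standard) or through
   the absolute contrasts of the filled capsids (``a2_abs``).
3. **Approach 3** — the genome is released from the capsid (heat or
   heat + SDS) and the released-genome peak is sized directly on a
   single-stranded nucleic acid calibration.

Study-level aggregation follows the three-measurement-day design: events
are averaged within a day, and mean / SD / %CV are computed across day
means.  Accuracy is determined/expected x 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants
from .calibration import (
    CalibrationCurve,
    CalibrationPoint,
    build_linear_calibration,
    delta_contrast_to_bases,
    predict_response,
)
from .errors import (
    DegenerateCurveError,
    IncompleteDisassemblyError,
    MissingPeakError,
    NoRouteError,
    ValidationError,
)
from .events_io import ContrastMeasurement
from .peaks import PeakFit, RegionConfig, default_slope_hint, fit_measurement_peaks

__all__ = [
    "GenomeLengthEstimate",
    "StudyReport",
    "Availability",
    "Recommendation",
    "build_aav_delta_calibration",
    "build_aav_abs_calibration",
    "size_approach1",
    "size_approach2_delta",
    "size_approach2_abs",
    "size_approach3",
    "aggregate_study",
    "estimate_resolution_limit",
    "recommend_approach",
]

#: Separation criterion for two equal Gaussian peaks to appear bimodal:
#: the full width at half maximum, 2 sqrt(2 ln 2) sigma.
RESOLUTION_CRITERION_K = 2.355


def _intact_peaks(
    m: ContrastMeasurement,
    regions: RegionConfig | None,
    bandwidth: float,
    unit: str,
    slope_hint: float | None,
    single_aav_label: str = "aav_filled",
) -> dict[str, PeakFit]:
    if slope_hint is None and unit != "contrast":
        slope_hint = default_slope_hint(unit)
    fits = fit_measurement_peaks(
        m,
        bandwidth,
        unit=unit,
        slope_hint=slope_hint,
        regions=regions,
        single_aav_label=single_aav_label,
    )
    by_label: dict[str, PeakFit] = {}
    for p in fits:
        # keep the peak with the most events per label
        if p.label not in by_label or p.n_events > by_label[p.label].n_events:
            by_label[p.label] = p
    return by_label


def size_approach1(
    m: ContrastMeasurement,
    curve: CalibrationCurve,
    regions: RegionConfig | None = None,
    bandwidth: float = constants.BANDWIDTH_INTACT_KDA,
    bandwidth_unit: str = "kDa",
    slope_hint: float | None = None,
) -> float:
    """Size an intact AAV sample from its filled-minus-empty contrast difference."""
    if curve.family not in ("protein_mass", "dsDNA_bp", "RNA_bases", "ssDNA_plasmid_bases"):
        raise ValidationError(
            f"approach 1 needs a protein/dsDNA/RNA/ssDNA-plasmid calibration, "
            f"got {curve.family!r}"
        )
    peaks = _intact_peaks(m, regions, bandwidth, bandwidth_unit, slope_hint)
    if "aav_empty" not in peaks:
        raise MissingPeakError(
            f"measurement {m.measurement_id!r}: no empty-capsid reference peak; "
            "spike an empty AAV sample into the measurement"
        )
    if "aav_filled" not in peaks:
        raise MissingPeakError(
            f"measurement {m.measurement_id!r}: no filled-capsid peak detected"
        )
    delta_c = peaks["aav_filled"].mu - peaks["aav_empty"].mu
    return delta_contrast_to_bases(curve, delta_c)


def size_approach2_delta(
    m: ContrastMeasurement,
    curve: CalibrationCurve,
    reference_label: str = "aav_empty",
    regions: RegionConfig | None = None,
    bandwidth: float = constants.BANDWIDTH_INTACT_KDA,
    bandwidth_unit: str = "kDa",
    slope_hint: float | None = None,
) -> float:
    """Size an intact AAV sample on a Delta-contrast-vs-bases AAV calibration.

    The reference population (empty capsid or spiked HMW standard) is the
    lower-magnitude peak of the intact-AAV band; the curve must have been
    built against the same reference.
    """
    if curve.family != "aav_delta_bases":
        raise ValidationError(f"approach 2-delta needs family aav_delta_bases, got {curve.family!r}")
    if reference_label not in ("aav_empty", "hmw_standard"):
        raise ValidationError(f"unknown reference_label {reference_label!r}")
    if curve.reference_label != reference_label:
        raise ValidationError(
            f"curve was built against reference {curve.reference_label!r} but "
            f"{reference_label!r} was requested"
        )
    peaks = _intact_peaks(m, regions, bandwidth, bandwidth_unit, slope_hint)
    # with the HMW standard spiked instead of empty capsids, the reference is
    # still the lower-|mu| AAV-band peak, which classify labels aav_empty
    if "aav_empty" not in peaks:
        raise MissingPeakError(
            f"measurement {m.measurement_id!r}: no reference peak "
            f"({reference_label}) in the intact-AAV band"
        )
    if "aav_filled" not in peaks:
        raise MissingPeakError(f"measurement {m.measurement_id!r}: no filled-capsid peak")
    delta_c = peaks["aav_filled"].mu - peaks["aav_empty"].mu
    return delta_contrast_to_bases(curve, delta_c)


def size_approach2_abs(
    m: ContrastMeasurement,
    curve: CalibrationCurve,
    regions: RegionConfig | None = None,
    bandwidth: float = constants.BANDWIDTH_INTACT_KDA,
    bandwidth_unit: str = "kDa",
    slope_hint: float | None = None,
) -> float:
    """Size an intact AAV sample from the absolute contrast of its filled peak.

    Needs no reference population, at the price of full sensitivity to
    additive measurement drift (a contrast offset d shifts the estimate by
    d / slope bases).
    """
    if curve.family != "aav_abs_bases":
        raise ValidationError(f"approach 2-abs needs family aav_abs_bases, got {curve.family!r}")
    peaks = _intact_peaks(m, regions, bandwidth, bandwidth_unit, slope_hint)
    if "aav_filled" not in peaks:
        raise MissingPeakError(f"measurement {m.measurement_id!r}: no filled-capsid peak")
    return predict_response(curve, peaks["aav_filled"].mu)


def size_approach3(
    m: ContrastMeasurement,
    curve: CalibrationCurve,
    regions: RegionConfig | None = None,
    bandwidth: float = constants.BANDWIDTH_RELEASED_BASES,
    bandwidth_unit: str = "bases",
    slope_hint: float | None = None,
) -> float:
    """Size the released genome of a disassembled AAV sample.

    Refuses to size when any intact-AAV peak is present (incomplete
    disassembly); fragment and aggregate populations are excluded by the
    band classification and never enter the fit window.
    """
    if curve.family not in ("RNA_bases", "ssDNA_plasmid_bases"):
        raise ValidationError(
            f"approach 3 needs an RNA or ssDNA-plasmid calibration, got {curve.family!r}"
        )
    peaks = _intact_peaks(m, regions, bandwidth, bandwidth_unit, slope_hint)
    intact = [lbl for lbl in peaks if lbl in ("aav_empty", "aav_filled", "aav")]
    if intact:
        raise IncompleteDisassemblyError(
            f"measurement {m.measurement_id!r}: intact AAVs detected "
            f"(peak at {peaks[intact[0]].mu:.4f}); capsid disassembly incomplete"
        )
    if "released_genome" not in peaks:
        raise MissingPeakError(
            f"measurement {m.measurement_id!r}: no released-genome peak found"
        )
    return predict_response(curve, peaks["released_genome"].mu)


def build_aav_delta_calibration(
    calibrants: list[tuple[ContrastMeasurement, float]],
    reference_label: str = "aav_empty",
    regions: RegionConfig | None = None,
    bandwidth: float = constants.BANDWIDTH_INTACT_KDA,
    bandwidth_unit: str = "kDa",
) -> CalibrationCurve:
    """Build the Delta-contrast-vs-bases calibration from AAVs of known length.

    Each calibrant measurement must contain both a reference peak (empty
    capsid or HMW standard) and a filled peak; the regressed contrast is
    the filled-minus-reference difference.
    """
    points = []
    for m, genome_bases in calibrants:
        peaks = _intact_peaks(m, regions, bandwidth, bandwidth_unit, None)
        if "aav_empty" not in peaks or "aav_filled" not in peaks:
            raise MissingPeakError(
                f"calibrant measurement {m.measurement_id!r} lacks a "
                "reference or filled peak"
            )
        delta_c = peaks["aav_filled"].mu - peaks["aav_empty"].mu
        points.append(
            CalibrationPoint(name=m.sample_id or m.measurement_id, contrast=delta_c, response=genome_bases)
        )
    return build_linear_calibration(
        points, "aav_delta_bases", reference_label=reference_label
    )


def build_aav_abs_calibration(
    calibrants: list[tuple[ContrastMeasurement, float]],
    include_empty: bool = False,
    regions: RegionConfig | None = None,
    bandwidth: float = constants.BANDWIDTH_INTACT_KDA,
    bandwidth_unit: str = "kDa",
) -> CalibrationCurve:
    """Build the absolute-contrast-vs-bases calibration from filled AAVs.

    With ``include_empty`` the empty-capsid peak (first measurement that
    shows one) is added as a 0-base point; the paper-style comparison of
    the two variants exposes the empty point's leverage on the slope.
    """
    points = []
    empty_point = None
    for m, genome_bases in calibrants:
        peaks = _intact_peaks(m, regions, bandwidth, bandwidth_unit, None)
        if "aav_filled" not in peaks:
            raise MissingPeakError(
                f"calibrant measurement {m.measurement_id!r} lacks a filled peak"
            )
        points.append(
            CalibrationPoint(
                name=m.sample_id or m.measurement_id,
                contrast=peaks["aav_filled"].mu,
                response=genome_bases,
            )
        )
        if empty_point is None and "aav_empty" in peaks:
            empty_point = CalibrationPoint(
                name="empty", contrast=peaks["aav_empty"].mu, response=0.0
            )
    if include_empty:
        if empty_point is None:
            raise MissingPeakError(
                "include_empty=True but no calibrant measurement shows an "
                "empty-capsid peak"
            )
        points.append(empty_point)
    return build_linear_calibration(points, "aav_abs_bases", include_empty=include_empty)


@dataclass
class GenomeLengthEstimate:
    """Per-study sizing result for one sample and one approach."""

    sample_id: str
    approach: str
    per_measurement: list[tuple[str, str, float]]  # (measurement_id, day_id, bases)
    per_day_mean: dict[str, float]
    mean_bases: float
    sd_bases: float | None
    cv_percent: float | None
    accuracy_percent: float | None
    reference_label: str = "none"

    def display(self) -> dict:
        """Table-style rounding: integer bases/accuracy, one-decimal %CV."""
        return {
            "sample_id": self.sample_id,
            "approach": self.approach,
            "mean_bases": int(round(self.mean_bases)),
            "sd_bases": None if self.sd_bases is None else int(round(self.sd_bases)),
            "cv_percent": None if self.cv_percent is None else round(self.cv_percent, 1),
            "accuracy_percent": None
            if self.accuracy_percent is None
            else int(round(self.accuracy_percent)),
        }

    def to_dict(self) -> dict:
        per_day = [
            {
                "day_id": day,
                "mean_bases": mean,
                "n": sum(1 for _, d, _ in self.per_measurement if d == day),
            }
            for day, mean in sorted(self.per_day_mean.items())
        ]
        return {
            "sample_id": self.sample_id,
            "approach": self.approach,
            "per_day": per_day,
            "per_measurement": [
                {"measurement_id": mid, "day_id": day, "bases": b}
                for mid, day, b in self.per_measurement
            ],
            "mean_bases": self.mean_bases,
            "sd_bases": self.sd_bases,
            "cv_percent": self.cv_percent,
            "accuracy_percent": self.accuracy_percent,
            "reference_label": self.reference_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeLengthEstimate":
        return cls(
            sample_id=d["sample_id"],
            approach=d["approach"],
            per_measurement=[
                (e["measurement_id"], e["day_id"], e["bases"]) for e in d["per_measurement"]
            ],
            per_day_mean={e["day_id"]: e["mean_bases"] for e in d["per_day"]},
            mean_bases=d["mean_bases"],
            sd_bases=d["sd_bases"],
            cv_percent=d["cv_percent"],
            accuracy_percent=d["accuracy_percent"],
            reference_label=d.get("reference_label", "none"),
        )


@dataclass
class StudyReport:
    """All estimates of one study run plus the calibrations they used."""

    estimates: list[GenomeLengthEstimate] = field(default_factory=list)
    calibrations: list[CalibrationCurve] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "samples": [e.to_dict() for e in self.estimates],
            "calibrations": [c.to_dict() for c in self.calibrations],
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(
            estimates=[GenomeLengthEstimate.from_dict(e) for e in d["samples"]],
            calibrations=[CalibrationCurve.from_dict(c) for c in d["calibrations"]],
            provenance=dict(d.get("provenance", {})),
        )


def aggregate_study(
    per_measurement: list[tuple[str, str, float]],
    expected: float | None = None,
    sample_id: str = "",
    approach: str = "",
    reference_label: str = "none",
) -> GenomeLengthEstimate:
    """Aggregate per-measurement estimates into the study-level statistics.

    Measurements are averaged within each day; mean, SD (ddof=1) and
    %CV = 100 SD/mean are computed across the day means.  With a single
    day, SD and %CV are reported as not applicable (None), never as 0.
    Accuracy = 100 x mean/expected is reported only when ``expected`` > 0.
    """
    if not per_measurement:
        raise ValidationError("aggregate_study needs at least one measurement")
    days: dict[str, list[float]] = {}
    for _, day, bases in per_measurement:
        days.setdefault(day, []).append(bases)
    per_day_mean = {day: float(np.mean(v)) for day, v in days.items()}
    day_means = np.array(list(per_day_mean.values()), dtype=float)
    mean = float(day_means.mean())
    if day_means.size > 1:
        sd = float(day_means.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else None
    else:
        sd = None
        cv = None
    accuracy = 100.0 * mean / expected if expected is not None and expected > 0 else None
    return GenomeLengthEstimate(
        sample_id=sample_id,
        approach=approach,
        per_measurement=list(per_measurement),
        per_day_mean=per_day_mean,
        mean_bases=mean,
        sd_bases=sd,
        cv_percent=cv,
        accuracy_percent=accuracy,
        reference_label=reference_label,
    )


def estimate_resolution_limit(
    sigma_contrast: float,
    curve: CalibrationCurve,
    k: float = RESOLUTION_CRITERION_K,
) -> float:
    """Smallest genome-length difference resolvable within one sample.

    Two equally tall Gaussian peaks of width ``sigma_contrast`` remain
    bimodal only when separated by about the full width at half maximum,
    ``k = 2.355`` sigma; dividing by the calibration slope (expressed per
    base) converts that contrast separation into bases.
    """
    if sigma_contrast < 0:
        raise ValidationError("sigma_contrast must be >= 0")
    slope = curve.slope_per_base
    if slope == 0:
        raise DegenerateCurveError("calibration slope is zero")
    return k * sigma_contrast / slope


@dataclass(frozen=True)
class Availability:
    """Which reference and calibration materials are on hand."""

    has_empty_reference: bool = False
    has_hmw_standard: bool = False
    has_aav_calibration_set: bool = False
    has_protein_calibrants: bool = False
    has_ss_nucleic_calibrants: bool = False
    can_release_genome: bool = False


@dataclass(frozen=True)
class Recommendation:
    approach: str
    rationale: str


def recommend_approach(availability: Availability | dict) -> Recommendation:
    """Decision tree selecting the most suitable sizing approach.

    Priority: the Delta-contrast AAV calibration (most accurate) when an
    AAV calibration set and a spikable reference exist; the absolute-contrast
    AAV calibration when only the AAV set exists; the filled-minus-empty
    difference on protein or nucleic calibrants (fastest) when a reference
    can be spiked; genome release on single-stranded nucleic calibrants
    (needs no AAV calibration material) otherwise.
    """
    if isinstance(availability, dict):
        availability = Availability(**availability)
    a = availability
    has_reference = a.has_empty_reference or a.has_hmw_standard
    if a.has_aav_calibration_set and has_reference:
        ref = "empty-AAV" if a.has_empty_reference else "HMW-standard"
        return Recommendation(
            "a2_delta",
            f"AAV calibration set plus {ref} reference available: the "
            "Delta-contrast AAV calibration gives the most accurate and "
            "most precise genome lengths.",
        )
    if a.has_aav_calibration_set:
        return Recommendation(
            "a2_abs",
            "AAV calibration set available but no reference can be spiked: "
            "size the filled peak's absolute contrast directly (valuable for "
            "samples with only a small empty fraction).",
        )
    if has_reference and (a.has_protein_calibrants or a.has_ss_nucleic_calibrants):
        material = "protein" if a.has_protein_calibrants else "nucleic acid"
        return Recommendation(
            "a1",
            f"Reference population plus {material} calibrants available: "
            "converting the filled-minus-empty contrast difference is the "
            "fastest route (protein calibration is the most accurate of the "
            "non-AAV materials).",
        )
    if a.has_ss_nucleic_calibrants and a.can_release_genome:
        return Recommendation(
            "a3",
            "Only single-stranded nucleic calibrants available: release the "
            "genome from the capsid and size it directly; requires no AAV "
            "material for calibration.",
        )
    raise NoRouteError(
        "no sizing route available with the declared reference and "
        "calibration materials"
    )
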