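"""Contrast-to-size calibration families and conversion chains.

Six calibration families are supported, named after their material class
and response unit:

========================  ==========  =============================================
family                    unit        calibrants
========================  ==========  =============================================
``protein_mass``          kDa         urease (272/545), thyroglobulin (670),
                                      empty AAV capsid (3,700)
``dsDNA_bp``              bp          dsDNA ladder 100-2,000 bp
``RNA_bases``             bases       RNA ladder 200-6,000 bases
``ssDNA_plasmid_bases``   bases       PhiX174 (5,386), M13 mp18 (7,249) + (0, 0)
``aav_delta_bases``       bases       Delta-contrast of AAVs of known genome length
``aav_abs_bases``         bases       absolute contrasts of filled AAVs
                                      (optionally plus the empty AAV at 0 bases)
========================  ==========  =============================================

Each family fits contrast as a linear function of response (slope in
contrast per kDa/bp/base, negative under the canonical sign convention)
and inverts the line analytically for prediction.  Contrast *differences*
are converted through the slope only, so the intercept cancels; the mass
route additionally applies the 309 kDa = 1,000 bases conversion and the
bp route doubles (1 bp = 2 bases).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .constants import (
    BASES_PER_BP,
    DNMP_RESIDUE_MASS_DA,
    KDA_PER_1000_BASES,
)
from .errors import DegenerateCurveError, FamilyMisuseError, ValidationError
from .events_io import SpeciesSpec

__all__ = [
    "FAMILIES",
    "CalibrationPoint",
    "CalibrationCurve",
    "build_linear_calibration",
    "predict_response",
    "convert_mass_diff_to_bases",
    "convert_bp_to_bases",
    "delta_contrast_to_bases",
    "point_leverage",
    "theoretical_conversion_factor_kda",
    "zero_point",
    "save_calibration",
    "load_calibration",
    "calibration_points_from_fits",
]

#: material classes whose species can calibrate each standard family
FAMILY_MATERIAL_CLASSES: dict[str, frozenset[str]] = {
    "protein_mass": frozenset({"protein", "aav_capsid"}),
    "dsDNA_bp": frozenset({"dsDNA"}),
    "RNA_bases": frozenset({"ssRNA"}),
    "ssDNA_plasmid_bases": frozenset({"ssDNA_circular"}),
}

#: family -> (response unit, minimum number of points)
FAMILIES: dict[str, tuple[str, int]] = {
    "protein_mass": ("kDa", 3),
    "dsDNA_bp": ("bp", 3),
    "RNA_bases": ("bases", 3),
    "ssDNA_plasmid_bases": ("bases", 3),
    "aav_delta_bases": ("bases", 2),
    "aav_abs_bases": ("bases", 2),
}


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibrant: a fitted peak contrast paired with its known response."""

    name: str
    contrast: float
    response: float
    species: SpeciesSpec | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.contrast) or not np.isfinite(self.response):
            raise ValidationError(f"point {self.name!r}: non-finite values")
        if self.contrast > 0:
            raise ValidationError(
                f"point {self.name!r}: contrast must be <= 0 (canonical sign)"
            )
        if self.response < 0:
            raise ValidationError(f"point {self.name!r}: response must be >= 0")


def zero_point() -> CalibrationPoint:
    """The (0 contrast, 0 bases) datum of the ssDNA-plasmid calibration."""
    return CalibrationPoint(name="zero", contrast=0.0, response=0.0)


@dataclass
class CalibrationCurve:
    """A fitted linear contrast-vs-response calibration."""

    family: str
    slope: float
    intercept: float
    response_unit: str
    points: list[CalibrationPoint]
    r_squared: float
    include_empty: bool | None = None
    reference_label: str = "none"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown calibration family {self.family!r}")

    @property
    def slope_per_base(self) -> float:
        """Slope magnitude expressed as contrast per base of ssDNA genome."""
        s = abs(self.slope)
        if self.response_unit == "bases":
            return s
        if self.response_unit == "bp":
            return s / BASES_PER_BP
        if self.response_unit == "kDa":
            return s * KDA_PER_1000_BASES / 1000.0
        raise ValidationError(f"unknown response unit {self.response_unit!r}")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "slope": self.slope,
            "intercept": self.intercept,
            "response_unit": self.response_unit,
            "r_squared": self.r_squared,
            "include_empty": self.include_empty,
            "reference_label": self.reference_label,
            "points": [
                {"name": p.name, "contrast": p.contrast, "response": p.response}
                for p in self.points
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            family=d["family"],
            slope=d["slope"],
            intercept=d["intercept"],
            response_unit=d["response_unit"],
            r_squared=d["r_squared"],
            include_empty=d.get("include_empty"),
            reference_label=d.get("reference_label", "none"),
            points=[
                CalibrationPoint(name=p["name"], contrast=p["contrast"], response=p["response"])
                for p in d["points"]
            ],
        )


def build_linear_calibration(
    points: list[CalibrationPoint],
    family: str,
    include_empty: bool | None = None,
    reference_label: str = "none",
) -> CalibrationCurve:
    """Ordinary-least-squares fit of contrast = slope x response + intercept.

    The intercept is always estimated (the ssDNA zero point enters as an
    ordinary datum, not a constraint).  For ``ssDNA_plasmid_bases`` the
    (0, 0) zero point is appended automatically when absent.  For
    ``aav_abs_bases``, ``include_empty`` controls whether the 0-base empty
    capsid point participates in the fit.
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown calibration family {family!r}")
    unit, min_points = FAMILIES[family]
    pts = list(points)

    if family == "ssDNA_plasmid_bases" and not any(p.response == 0 for p in pts):
        pts.append(zero_point())
    if family == "aav_abs_bases":
        if include_empty is None:
            include_empty = any(p.response == 0 for p in pts)
        if not include_empty:
            pts = [p for p in pts if p.response != 0]
        elif not any(p.response == 0 for p in pts):
            raise ValidationError(
                "aav_abs_bases with include_empty=True needs an empty-capsid "
                "point at 0 bases"
            )

    if len(pts) < min_points:
        raise ValidationError(
            f"family {family!r} needs at least {min_points} points, got {len(pts)}"
        )
    resp = np.array([p.response for p in pts], dtype=float)
    cont = np.array([p.contrast for p in pts], dtype=float)
    if np.ptp(resp) == 0:
        raise DegenerateCurveError("all calibration responses are identical")
    for r in np.unique(resp):
        c = cont[resp == r]
        if c.size > 1 and np.ptp(c) > 0:
            warnings.warn(
                f"duplicate response {r} with conflicting contrasts; both kept",
                stacklevel=2,
            )
    fit = stats.linregress(resp, cont)
    return CalibrationCurve(
        family=family,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        response_unit=unit,
        points=pts,
        r_squared=float(fit.rvalue**2),
        include_empty=include_empty if family == "aav_abs_bases" else None,
        reference_label=reference_label,
    )


def predict_response(curve: CalibrationCurve, contrast: float) -> float:
    """Invert the calibration line: response = (contrast - intercept)/slope.

    No clipping is applied; a negative prediction triggers a warning so the
    caller can decide how to treat it.
    """
    if curve.slope == 0:
        raise DegenerateCurveError("calibration slope is zero; cannot invert")
    response = (contrast - curve.intercept) / curve.slope
    if response < 0:
        warnings.warn(
            f"negative predicted response {response:.4g} {curve.response_unit}",
            stacklevel=2,
        )
    return float(response)


def convert_mass_diff_to_bases(delta_mass_kda: float) -> float:
    """Convert a mass difference (kDa) to bases via 309 kDa = 1,000 bases."""
    return float(delta_mass_kda) * 1000.0 / KDA_PER_1000_BASES


def convert_bp_to_bases(delta_bp: float) -> float:
    """Convert a base-pair difference to bases (1 bp = 2 bases)."""
    return float(delta_bp) * BASES_PER_BP


def delta_contrast_to_bases(curve: CalibrationCurve, delta_contrast: float) -> float:
    """Convert a contrast *difference* (filled minus reference) to bases.

    For the mass/bp/bases families only the slope is used, so the intercept
    cancels on differences; the ``aav_delta_bases`` family applies its full
    line (slope and intercept) because the regressed quantity is itself a
    contrast difference.
    """
    if curve.family == "aav_abs_bases":
        raise FamilyMisuseError(
            "aav_abs_bases sizes absolute contrasts; use predict_response"
        )
    if curve.slope == 0:
        raise DegenerateCurveError("calibration slope is zero; cannot invert")
    if curve.family == "aav_delta_bases":
        return float((delta_contrast - curve.intercept) / curve.slope)
    delta_response = delta_contrast / curve.slope
    if curve.family == "protein_mass":
        return convert_mass_diff_to_bases(delta_response)
    if curve.family == "dsDNA_bp":
        return convert_bp_to_bases(delta_response)
    return float(delta_response)  # RNA_bases / ssDNA_plasmid_bases


def point_leverage(curve: CalibrationCurve) -> np.ndarray:
    """Hat-matrix diagonal of each calibration point.

    For simple linear regression ``h_i = 1/n + (x_i - xbar)^2 / Sxx`` with
    x the response values.  Leverages sum to 2 (the number of regression
    parameters) and each lies in [1/n, 1].
    """
    x = np.array([p.response for p in curve.points], dtype=float)
    if x.size < 3:
        raise ValidationError("leverage diagnostics need at least 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateCurveError("all responses identical; leverage undefined")
    return 1.0 / x.size + (x - x.mean()) ** 2 / sxx


def theoretical_conversion_factor_kda(n_bases: float = 1000.0) -> float:
    """Mean dNMP chain-residue mass scaled to ``n_bases`` bases, in kDa.

    The average of the four deoxynucleotide-monophosphate residue masses is
    ~308.95 Da, which for 1,000 bases gives the ~309 kDa conversion factor
    used by :func:`convert_mass_diff_to_bases`.
    """
    mean_da = float(np.mean(list(DNMP_RESIDUE_MASS_DA.values())))
    return mean_da * n_bases / 1000.0  # Da -> kDa


def calibration_points_from_fits(
    species_and_mu: list[tuple[SpeciesSpec, float]],
) -> list[CalibrationPoint]:
    """Pair fitted peak contrasts with their species' known responses."""
    return [
        CalibrationPoint(name=s.name, contrast=mu, response=s.size_value, species=s)
        for s, mu in species_and_mu
    ]


#: Declared smoothing bandwidth used when fitting each family's calibrants:
#: 40 kDa for the mass route, 120 bp / 120 bases for nucleic ladders.
_FAMILY_BANDWIDTH = {
    "protein_mass": (40.0, "kDa"),
    "dsDNA_bp": (120.0, "bp"),
    "RNA_bases": (120.0, "bases"),
    "ssDNA_plasmid_bases": (120.0, "bases"),
}


def fit_calibration_from_measurements(
    calibrants,
    family: str,
    bandwidth: tuple[float, str] | None = None,
    slope_hint: float | None = None,
    reference_label: str = "none",
) -> CalibrationCurve:
    """Fit each calibrant measurement's dominant peak and build the curve.

    ``calibrants`` is a sequence of ``(SpeciesSpec, ContrastMeasurement)``
    pairs, one acquisition per calibrant species.
    """
    from .peaks import default_slope_hint, fit_single_peak  # deferred import

    if bandwidth is None:
        bandwidth = _FAMILY_BANDWIDTH.get(family)
    if bandwidth is None:
        raise ValidationError(
            f"family {family!r} has no default bandwidth; pass one explicitly"
        )
    bw, unit = bandwidth
    if slope_hint is None and unit != "contrast":
        slope_hint = default_slope_hint(unit)
    allowed = FAMILY_MATERIAL_CLASSES.get(family)
    pairs = []
    for spec, m in calibrants:
        if allowed is not None and spec.material_class not in allowed:
            raise ValidationError(
                f"species {spec.name!r} (class {spec.material_class!r}) cannot "
                f"calibrate family {family!r}"
            )
        fit = fit_single_peak(m, bw, unit=unit, slope_hint=slope_hint)
        pairs.append((spec, fit.mu))
    return build_linear_calibration(
        calibration_points_from_fits(pairs), family, reference_label=reference_label
    )


def save_calibration(curve: CalibrationCurve, dest: str | Path) -> None:
    """Write a calibration to JSON (floats survive the round trip exactly)."""
    Path(dest).write_text(
        json.dumps(curve.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_calibration(source: str | Path) -> CalibrationCurve:
    return CalibrationCurve.from_dict(json.loads(Path(source).read_text(encoding="utf-8")))
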