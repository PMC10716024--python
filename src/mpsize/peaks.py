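"""Peak analysis of landing-event contrast distributions.

The event list of one acquisition is smoothed with a Gaussian kernel whose
bandwidth is declared in calibrated units (e.g. "40 kDa" or "120 bases")
and converted to contrast units through a provisional contrast-per-unit
slope.  Local maxima of the smoothed density are expanded into fit windows
and each window is fitted with a single Gaussian; fitted peaks are then
classified into fragment / released-genome / intact-AAV / aggregate bands
by the magnitude of their mean contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from . import constants
from .errors import AmbiguousPeaksError, PeakFitError, ValidationError
from .events_io import ContrastMeasurement

__all__ = [
    "RegionConfig",
    "SmoothedDistribution",
    "PeakFit",
    "default_slope_hint",
    "smooth_events",
    "detect_peaks",
    "fit_gaussian_peak",
    "classify_peaks",
    "fit_measurement_peaks",
    "fit_single_peak",
]


def default_slope_hint(unit: str) -> float:
    """Provisional contrast-per-unit magnitude for declared bandwidths.

    Used to convert a bandwidth stated in calibrated units (kDa, bases,
    bp) into contrast units before any calibration exists; once a
    calibration is available its ``slope_per_base`` supersedes this guess.
    """
    if unit == "kDa":
        return constants.ALPHA_CAPSID
    if unit == "bases":
        return constants.ALPHA_FREE_SS
    if unit == "bp":
        return constants.BASES_PER_BP * constants.ALPHA_FREE_SS
    raise ValidationError(f"no default slope hint for unit {unit!r}")

#: Events below this count give a low-confidence (but still returned) fit.
MIN_EVENTS_DEFAULT = 50
#: Sigma floor used when a window contains zero-variance events.
SIGMA_FLOOR = 1e-6
GRID_POINTS_DEFAULT = 2048


@dataclass(frozen=True)
class RegionConfig:
    """Contrast-magnitude bands used for peak classification.

    All bounds are magnitudes (positive numbers); events/peaks are signed
    negative.  Defaults: fragments below 0.030, released genomes in
    0.030-0.07, intact AAVs in 0.10-0.20, aggregates above 0.5.
    """

    fragment_max: float = 0.030
    released: tuple[float, float] = (0.030, 0.07)
    aav: tuple[float, float] = (0.10, 0.20)
    aggregate_min: float = 0.5

    def __post_init__(self) -> None:
        bounds = (
            self.fragment_max,
            *self.released,
            *self.aav,
            self.aggregate_min,
        )
        if any(b < 0 for b in bounds):
            raise ValidationError("region bounds are magnitudes and must be >= 0")
        if not (self.released[0] < self.released[1] <= self.aav[0] < self.aav[1] <= self.aggregate_min):
            raise ValidationError("region bands must be ordered and non-overlapping")


@dataclass
class SmoothedDistribution:
    """Gaussian-kernel density estimate of one event list on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth_contrast: float
    bandwidth_declared: tuple[float, str] | None
    slope_used: float | None
    n_events: int

    def __post_init__(self) -> None:
        if self.bandwidth_contrast <= 0:
            raise ValidationError("bandwidth_contrast must be > 0")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValidationError("density must be nonnegative")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass
class PeakFit:
    """A fitted Gaussian population in contrast space."""

    mu: float
    sigma: float
    amplitude: float
    n_events: int
    window: tuple[float, float]
    rms_residual: float
    label: str = "unlabeled"
    low_confidence: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo <= self.mu <= hi):
            raise ValidationError(f"fitted mu {self.mu} outside window [{lo}, {hi}]")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


def _bandwidth_to_contrast(
    bandwidth: float, unit: str, slope_hint: float | None
) -> tuple[float, tuple[float, str] | None, float | None]:
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    if unit == "contrast":
        return float(bandwidth), None, None
    if unit not in ("kDa", "bases", "bp"):
        raise ValidationError(f"unknown bandwidth unit {unit!r}")
    if slope_hint is None or slope_hint <= 0:
        raise ValidationError(
            "a positive slope_hint (contrast per unit) is required when the "
            "bandwidth is declared in calibrated units"
        )
    return float(bandwidth * slope_hint), (float(bandwidth), unit), float(slope_hint)


def smooth_events(
    m: ContrastMeasurement,
    bandwidth: float,
    unit: str = "contrast",
    slope_hint: float | None = None,
    grid_points: int = GRID_POINTS_DEFAULT,
) -> SmoothedDistribution:
    """Gaussian-kernel density estimate of an event list.

    Parameters
    ----------
    bandwidth, unit
        Kernel bandwidth.  When ``unit`` is ``kDa``/``bases``/``bp`` the
        declared value is converted to contrast units by multiplying with
        ``slope_hint`` (a positive contrast-per-unit magnitude); when
        ``unit`` is ``"contrast"`` it is used directly.
    grid_points
        Number of grid nodes spanning ``[min - 3 bw, max + 3 bw]``.
    """
    if m.n_events == 0:
        raise ValidationError("cannot smooth an empty measurement")
    bw, declared, slope = _bandwidth_to_contrast(bandwidth, unit, slope_hint)
    ev = m.events
    lo, hi = float(ev.min() - 3 * bw), float(ev.max() + 3 * bw)
    # keep >= 8 grid nodes per bandwidth so narrow kernels stay resolved
    # even when stray aggregate events stretch the event range
    grid_points = min(max(grid_points, int(np.ceil(8 * (hi - lo) / bw))), 65536)
    grid = np.linspace(lo, hi, grid_points)
    # direct evaluation keeps the declared-bandwidth convention exact even
    # for zero-variance event lists
    z = (grid[:, None] - ev[None, :]) / bw
    density = np.exp(-0.5 * z * z).sum(axis=1) / (ev.size * bw * np.sqrt(2 * np.pi))
    return SmoothedDistribution(
        grid=grid,
        density=density,
        bandwidth_contrast=bw,
        bandwidth_declared=declared,
        slope_used=slope,
        n_events=ev.size,
    )


def detect_peaks(
    dist: SmoothedDistribution,
    min_events: int = 0,
    min_prominence_frac: float = 0.10,
) -> list[tuple[float, float]]:
    """Find candidate peak windows in a smoothed distribution.

    Local maxima with prominence >= ``min_prominence_frac`` x max density
    are expanded to windows of +-2 bandwidths, truncated at the density
    minimum between neighbouring maxima.  When ``min_events`` > 0,
    windows whose estimated event count (density integral x n) falls below
    it are dropped.  Candidates are sorted by \\|contrast\\| ascending.
    """
    dens = dist.density
    if dens.size < 3:
        return []
    idx, _ = find_peaks(dens, prominence=min_prominence_frac * dens.max())
    if idx.size == 0:
        return []
    idx = np.sort(idx)
    bw = dist.bandwidth_contrast
    step = dist.step
    windows: list[tuple[float, float]] = []
    for k, i in enumerate(idx):
        lo = dist.grid[i] - 2 * bw
        hi = dist.grid[i] + 2 * bw
        if k > 0:  # truncate at the density minimum towards the left neighbour
            j0, j1 = idx[k - 1], i
            jmin = j0 + int(np.argmin(dens[j0 : j1 + 1]))
            lo = max(lo, dist.grid[jmin])
        if k < idx.size - 1:
            j0, j1 = i, idx[k + 1]
            jmin = j0 + int(np.argmin(dens[j0 : j1 + 1]))
            hi = min(hi, dist.grid[jmin])
        if min_events > 0:
            sel = (dist.grid >= lo) & (dist.grid <= hi)
            est = float(np.trapezoid(dens[sel], dist.grid[sel])) * dist.n_events
            if est < min_events:
                continue
        windows.append((float(lo), float(hi)))
    windows.sort(key=lambda w: abs((w[0] + w[1]) / 2))
    return windows


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_window(
    dist: SmoothedDistribution, ev: np.ndarray, window: tuple[float, float]
) -> tuple[float, float, float, float]:
    lo, hi = window
    sel = (dist.grid >= lo) & (dist.grid <= hi)
    if sel.sum() < 5:
        raise PeakFitError(f"window [{lo:.4g}, {hi:.4g}] covers fewer than 5 grid nodes")
    x, y = dist.grid[sel], dist.density[sel]
    inw = ev[(ev >= lo) & (ev <= hi)]
    mu0 = float(x[np.argmax(y)])
    sd0 = float(inw.std()) if inw.size > 1 else 0.0
    sigma0 = max(sd0, dist.bandwidth_contrast)
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=(float(y.max()), mu0, sigma0),
            bounds=([0.0, lo, SIGMA_FLOOR], [np.inf, hi, 10 * (hi - lo) + 10 * sigma0]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise PeakFitError(f"Gaussian fit did not converge in window [{lo:.4g}, {hi:.4g}]") from exc
    a, mu, sigma = map(float, popt)
    rms = float(np.sqrt(np.mean((y - _gauss(x, a, mu, sigma)) ** 2)))
    return a, mu, sigma, rms


def fit_gaussian_peak(
    m: ContrastMeasurement,
    window: tuple[float, float],
    dist: SmoothedDistribution | None = None,
    min_events: int = MIN_EVENTS_DEFAULT,
) -> PeakFit:
    """Least-squares Gaussian fit of the smoothed density inside a window.

    The fit is initialized at the windowed mode with the sample SD of the
    windowed events, then refitted once on a window recentered to
    ``mu +- 2.5 sigma``.  ``n_events`` counts raw events inside the final
    window; fewer than ``min_events`` flags the fit low-confidence rather
    than raising.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValidationError("window must satisfy lo < hi")
    ev = m.events
    inw = ev[(ev >= lo) & (ev <= hi)]
    if inw.size == 0:
        raise PeakFitError(f"no events inside window [{lo:.4g}, {hi:.4g}]")
    if float(np.ptp(inw)) == 0.0:
        # all events identical: delta population, sigma pinned at the floor
        mu = float(inw[0])
        return PeakFit(
            mu=mu,
            sigma=SIGMA_FLOOR,
            amplitude=float("nan"),
            n_events=int(inw.size),
            window=(lo, hi),
            rms_residual=0.0,
            low_confidence=inw.size < min_events,
            degenerate=True,
        )
    if dist is None:
        dist = smooth_events(m, bandwidth=max(float(inw.std()), SIGMA_FLOOR))

    a, mu, sigma, rms = _fit_window(dist, ev, (lo, hi))
    # one refit pass on the recentered window
    lo2 = max(float(dist.grid[0]), mu - 2.5 * sigma)
    hi2 = min(float(dist.grid[-1]), mu + 2.5 * sigma)
    if hi2 > lo2:
        try:
            a, mu, sigma, rms = _fit_window(dist, ev, (lo2, hi2))
            lo, hi = lo2, hi2
        except PeakFitError:
            pass  # keep the first-pass fit and window
    n_final = int(np.count_nonzero((ev >= lo) & (ev <= hi)))
    return PeakFit(
        mu=mu,
        sigma=sigma,
        amplitude=a,
        n_events=n_final,
        window=(lo, hi),
        rms_residual=rms,
        low_confidence=n_final < min_events,
    )


def classify_peaks(
    peaks: list[PeakFit],
    regions: RegionConfig | None = None,
    single_aav_label: str = "aav_filled",
) -> list[PeakFit]:
    """Assign band labels to fitted peaks by \\|mu\\|.

    Fragments below ``fragment_max``; released genomes inside the released
    band; intact AAVs inside the AAV band (with the lower-magnitude peak
    labelled empty and the higher filled when two are present — a single
    AAV-band peak gets ``single_aav_label``, which the caller resolves from
    the sample sheet); aggregates above ``aggregate_min``.  Three or more
    peaks in the AAV band raise :class:`AmbiguousPeaksError`.
    """
    regions = regions or RegionConfig()
    out = []
    aav_band: list[int] = []
    for i, p in enumerate(peaks):
        mag = abs(p.mu)
        if mag < regions.fragment_max:
            label = "fragment"
        elif regions.released[0] <= mag < regions.released[1]:
            label = "released_genome"
        elif regions.aav[0] <= mag <= regions.aav[1]:
            label = "aav"
            aav_band.append(i)
        elif mag > regions.aggregate_min:
            label = "aggregate"
        else:
            label = "unlabeled"
        out.append(replace(p, label=label))
    if len(aav_band) >= 3:
        raise AmbiguousPeaksError(
            f"{len(aav_band)} candidate peaks in the intact-AAV band; "
            "resolve with the sample sheet",
            candidates=[out[i] for i in aav_band],
        )
    if len(aav_band) == 2:
        i, j = sorted(aav_band, key=lambda k: abs(out[k].mu))
        out[i] = replace(out[i], label="aav_empty")
        out[j] = replace(out[j], label="aav_filled")
    elif len(aav_band) == 1:
        out[aav_band[0]] = replace(out[aav_band[0]], label=single_aav_label)
    return out


def fit_measurement_peaks(
    m: ContrastMeasurement,
    bandwidth: float,
    unit: str = "contrast",
    slope_hint: float | None = None,
    regions: RegionConfig | None = None,
    min_events: int = MIN_EVENTS_DEFAULT,
    min_prominence_frac: float = 0.10,
    single_aav_label: str = "aav_filled",
) -> list[PeakFit]:
    """Smooth, detect, fit and classify all peaks of one measurement."""
    dist = smooth_events(m, bandwidth, unit=unit, slope_hint=slope_hint)
    windows = detect_peaks(dist, min_events=0, min_prominence_frac=min_prominence_frac)
    fits = []
    for w in windows:
        try:
            fits.append(fit_gaussian_peak(m, w, dist=dist, min_events=min_events))
        except PeakFitError:
            warnings.warn(f"skipping unfittable window {w}", stacklevel=2)
    return classify_peaks(fits, regions=regions, single_aav_label=single_aav_label)


def fit_single_peak(
    m: ContrastMeasurement,
    bandwidth: float,
    unit: str = "contrast",
    slope_hint: float | None = None,
) -> PeakFit:
    """Fit the dominant peak of a (single-population) measurement."""
    dist = smooth_events(m, bandwidth, unit=unit, slope_hint=slope_hint)
    windows = detect_peaks(dist, min_prominence_frac=0.10)
    if not windows:
        raise PeakFitError(f"no peak found in measurement {m.measurement_id!r}")
    # dominant = window with most raw events
    best = max(
        windows,
        key=lambda w: np.count_nonzero((m.events >= w[0]) & (m.events <= w[1])),
    )
    return fit_gaussian_peak(m, best, dist=dist)
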