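"""Fluorescence chromatogram reading, calibration and peak quantification.

Implements the HILIC-UHPLC quantification chain used for released plasma
N-glycans: traces arrive as two-column delimited text (retention time in
minutes, fluorescence intensity in arbitrary units), are optionally
retention-time calibrated against reference features, and each feature is
quantified by least-squares Gaussian fitting with sigma-edge integration
(area of the background-subtracted signal between ``mu +/- k * sigma`` of
the fitted Gaussian, ``k = 2`` by default).  Analytes are gated on
Gaussian peak quality (GPQ, the squared Pearson correlation between the
observed and fitted peak, threshold 0.8) and signal-to-noise (fitted
height over the flanking-baseline noise SD, threshold 9).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Chromatogram",
    "Feature",
    "PeakQuantification",
    "CalibrationError",
    "read_chromatogram",
    "detect_features",
    "RetentionTimeCalibrator",
    "calibrate_rt",
    "quantify_peak",
    "quantify_chromatogram",
    "compute_gpq",
    "gate_analytes",
    "quantifications_to_frame",
    "read_feature_list",
    "gaussian_model_area",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class Chromatogram:
    """A sampled fluorescence trace on a retention-time axis (minutes)."""

    time: np.ndarray
    intensity: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must be 1-D and equal length")
        if self.time.size < 2:
            raise ValueError("chromatogram needs at least 2 points")
        if np.isnan(self.time).any() or np.isnan(self.intensity).any():
            raise ValueError("chromatogram contains missing values")
        bad = np.nonzero(np.diff(self.time) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"time axis not strictly increasing at row {bad[0] + 2}"
            )

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class Feature:
    """A quantification target: expected apex position and window half-width."""

    label: str
    expected_rt: float  # minutes
    width: float        # minutes, window half-width
    is_calibrant: bool = False

    def __post_init__(self) -> None:
        if self.expected_rt <= 0:
            raise ValueError("expected_rt must be > 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")


@dataclass
class PeakQuantification:
    """Fitted parameters and quality metrics for one feature."""

    label: str
    apex_rt: float = math.nan
    fitted_mu: float = math.nan
    fitted_sigma: float = math.nan
    fitted_height: float = math.nan
    background: float = math.nan
    noise: float = math.nan
    area: float = 0.0            # sigma-edge, background-subtracted, a.u.*min
    model_area: float = math.nan  # diagnostic: analytic area of the fitted model
    sn: float = math.nan
    gpq: float = 0.0
    fit_ok: bool = False
    passed_qc: bool = False
    message: str = ""


class CalibrationError(RuntimeError):
    """Raised when retention-time calibration cannot proceed."""


# ---------------------------------------------------------------------------
# Reading


def read_chromatogram(source) -> Chromatogram:
    """Read a two-column delimited text trace (minutes, intensity).

    The delimiter is auto-detected among tab, comma, semicolon and
    whitespace; a header line and other unparseable rows are skipped with
    a warning reporting their positions.  Requires at least two valid rows
    and a strictly increasing time axis.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        # a path unless it is multi-line literal trace data
        text = source if "\n" in source else Path(source).read_text()
    else:  # file-like
        text = source.read()

    times: list[float] = []
    values: list[float] = []
    bad_rows: list[int] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        for delim in ("\t", ",", ";", None):
            parts = line.split(delim)
            parts = [p for p in parts if p != ""]
            if len(parts) < 2:
                continue
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                continue
            times.append(t)
            values.append(v)
            break
        else:
            bad_rows.append(lineno)
    if bad_rows:
        warnings.warn(
            f"skipped {len(bad_rows)} unparseable row(s) at line(s) "
            f"{bad_rows[:10]}", stacklevel=2,
        )
    if len(times) < 2:
        raise ValueError("fewer than 2 valid data rows in chromatogram")
    return Chromatogram(np.array(times), np.array(values))


def read_feature_list(path) -> list[Feature]:
    """Read a feature list CSV: label, expected_rt, width[, is_calibrant]."""
    df = pd.read_csv(path)
    required = {"label", "expected_rt", "width"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature list missing column(s): {sorted(missing)}")
    feats = []
    for _, row in df.iterrows():
        feats.append(
            Feature(
                label=str(row["label"]),
                expected_rt=float(row["expected_rt"]),
                width=float(row["width"]),
                is_calibrant=bool(row.get("is_calibrant", False)),
            )
        )
    return feats


# ---------------------------------------------------------------------------
# Detection


def detect_features(
    chrom: Chromatogram,
    min_intensity: float = 0.001,
    smoothing_window: int = 5,
) -> list[Feature]:
    """Automated peak detection on the smoothed, baseline-subtracted trace.

    Local maxima above ``min_intensity`` times the global maximum of the
    smoothed, minimum-subtracted trace are reported as features, with the
    apex time and a width estimated as the half-height width divided by
    2.355 (the Gaussian FWHM-to-sigma factor).  A flat plateau of equal
    samples is assigned to its earliest time point.
    """
    if not 0.0 < min_intensity < 1.0:
        raise ValueError("min_intensity must be in (0, 1)")
    y = uniform_filter1d(chrom.intensity, size=max(1, smoothing_window),
                         mode="nearest")
    y = y - y.min()
    top = y.max()
    if top <= 0:
        warnings.warn("flat trace: no features detected", stacklevel=2)
        return []
    peaks, props = find_peaks(y, height=min_intensity * top,
                              plateau_size=(1, None))
    apexes = props["left_edges"]  # tie-break toward the earlier time
    if apexes.size == 0:
        warnings.warn("no features above the intensity threshold", stacklevel=2)
        return []
    fwhm = peak_widths(y, peaks, rel_height=0.5)[0] * chrom.sampling_interval
    dt = chrom.sampling_interval
    return [
        Feature(
            label=f"f{i + 1}",
            expected_rt=_refine_apex(chrom.time, y, int(a)),
            width=float(max(w / _FWHM_TO_SIGMA, dt)),
        )
        for i, (a, w) in enumerate(zip(apexes, fwhm))
    ]


def _refine_apex(t: np.ndarray, y: np.ndarray, a: int) -> float:
    """Sub-sample apex position by a parabola through the apex triplet.

    Plateau apexes (equal neighbours) are left at their grid point so the
    earlier-time tie-break is preserved.
    """
    if a <= 0 or a >= y.size - 1 or not (y[a - 1] < y[a] > y[a + 1]):
        return float(t[a])
    coef = np.polyfit(t[a - 1:a + 2], y[a - 1:a + 2], 2)
    if coef[0] >= 0:  # degenerate curvature
        return float(t[a])
    vertex = -coef[1] / (2.0 * coef[0])
    lo, hi = float(t[a - 1]), float(t[a + 1])
    return float(min(max(vertex, lo), hi))


# ---------------------------------------------------------------------------
# Retention-time calibration


class RetentionTimeCalibrator(BaseEstimator, TransformerMixin):
    """Least-squares polynomial retention-time calibration.

    Matches each calibrant feature to the nearest detected apex within its
    window, fits a polynomial mapping observed apex times to expected
    retention times (degree 2 when at least 3 calibrants are matched,
    degree 1 otherwise), and remaps the time axis with it.

    Parameters
    ----------
    calibrants
        Reference features; non-calibrant entries are ignored unless none
        is flagged, in which case all are used.
    min_intensity, smoothing_window
        Passed to :func:`detect_features` for apex detection.

    Attributes
    ----------
    coef_ : numpy.ndarray
        Ascending-power coefficients of the fitted time map.
    matched_ : list[tuple[str, float, float]]
        (label, observed apex, expected rt) for each matched calibrant.
    """

    def __init__(self, calibrants: Sequence[Feature] = (),
                 min_intensity: float = 0.001, smoothing_window: int = 5):
        self.calibrants = calibrants
        self.min_intensity = min_intensity
        self.smoothing_window = smoothing_window

    def fit(self, X: Chromatogram, y=None) -> "RetentionTimeCalibrator":
        cals = [f for f in self.calibrants if f.is_calibrant] or list(self.calibrants)
        if len(cals) < 2:
            raise CalibrationError("need at least 2 calibrant features")
        detected = detect_features(X, self.min_intensity, self.smoothing_window)
        if not detected:
            raise CalibrationError("no peaks detected for calibration")
        apexes = np.array([f.expected_rt for f in detected])
        matched = []
        for cal in cals:
            d = np.abs(apexes - cal.expected_rt)
            j = int(np.argmin(d))
            if d[j] <= cal.width:
                matched.append((cal.label, float(apexes[j]), cal.expected_rt))
        if len(matched) < 2:
            raise CalibrationError(
                f"only {len(matched)} calibrant(s) matched; calibration refused"
            )
        degree = 2 if len(matched) >= 3 else 1
        obs = np.array([m[1] for m in matched])
        exp = np.array([m[2] for m in matched])
        poly = np.polynomial.Polynomial.fit(obs, exp, deg=degree)
        self.coef_ = poly.convert().coef
        self.matched_ = matched
        return self

    def transform(self, X: Chromatogram) -> Chromatogram:
        if not hasattr(self, "coef_"):
            raise CalibrationError("calibrator is not fitted")
        new_time = np.polynomial.polynomial.polyval(X.time, self.coef_)
        if np.any(np.diff(new_time) <= 0):
            raise CalibrationError("calibration map is not monotone on this axis")
        return Chromatogram(new_time, X.intensity.copy(), calibrated=True)


def calibrate_rt(chrom: Chromatogram, calibrants: Sequence[Feature],
                 **detect_kwargs) -> Chromatogram:
    """Functional wrapper: fit a :class:`RetentionTimeCalibrator` and apply it."""
    return RetentionTimeCalibrator(calibrants, **detect_kwargs).fit(chrom).transform(chrom)


# ---------------------------------------------------------------------------
# Quantification


def _gauss(t, height, mu, sigma):
    return height * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def gaussian_model_area(height: float, sigma: float, sigma_edge: float) -> float:
    """Analytic area of a fitted Gaussian between ``mu +/- sigma_edge * sigma``."""
    return height * sigma * math.sqrt(2 * math.pi) * math.erf(sigma_edge / math.sqrt(2))


def _lowest_run(values: np.ndarray) -> np.ndarray:
    """The contiguous run of ~half the points with the lowest mean."""
    n = values.size
    run = max(3, n // 2)
    if n <= run:
        return values
    csum = np.cumsum(np.concatenate(([0.0], values)))
    means = (csum[run:] - csum[:-run]) / run
    start = int(np.argmin(means))
    return values[start:start + run]


def _flank_points(chrom: Chromatogram, feature: Feature,
                  exclude: Sequence[tuple[float, float]] = ()) -> np.ndarray:
    lo = feature.expected_rt - feature.width
    hi = feature.expected_rt + feature.width
    t = chrom.time
    mask = ((t >= lo - feature.width) & (t < lo)) | ((t > hi) & (t <= hi + feature.width))
    for a, b in exclude:
        mask &= ~((t >= a) & (t <= b))
    return chrom.intensity[mask]


def _integrate(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of sampled (t, y) over [lo, hi] with interpolated ends."""
    lo = max(lo, float(t[0]))
    hi = min(hi, float(t[-1]))
    if hi <= lo:
        return 0.0
    inner = (t > lo) & (t < hi)
    xx = np.concatenate(([lo], t[inner], [hi]))
    yy = np.concatenate(([np.interp(lo, t, y)], y[inner], [np.interp(hi, t, y)]))
    return float(np.trapezoid(yy, xx))


def compute_gpq(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Gaussian peak quality: squared Pearson correlation, clamped to [0, 1].

    Quantifies how well the fitted Gaussian reproduces the observed,
    background-subtracted signal in the feature window.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.size != fitted.size:
        raise ValueError("observed and fitted must have equal length")
    if observed.size < 5:
        raise ValueError("GPQ needs at least 5 points")
    so = observed.std()
    sf = fitted.std()
    if so == 0.0 or sf == 0.0:
        return 0.0
    r = float(np.corrcoef(observed, fitted)[0, 1])
    return float(np.clip(r * r, 0.0, 1.0))


def quantify_peak(
    chrom: Chromatogram,
    feature: Feature,
    sigma_edge: float = 2.0,
    exclude_windows: Sequence[tuple[float, float]] = (),
) -> PeakQuantification:
    """Quantify one feature by Gaussian fitting with sigma-edge integration.

    Background and noise come from flanking windows (one feature-width on
    each side of the window, minus any ``exclude_windows`` belonging to
    neighbouring features): background is the mean of the lowest contiguous
    half of the flank points and noise their standard deviation.  A
    Gaussian is least-squares fitted to the background-subtracted window;
    the reported area is the trapezoidal integral of the background-
    subtracted raw signal over ``mu +/- sigma_edge * sigma`` (negative
    integrals are clamped to zero and fail QC).  Fit failures are flagged
    on the result, never raised.
    """
    lo = feature.expected_rt - feature.width
    hi = feature.expected_rt + feature.width
    if lo < chrom.time[0] or hi > chrom.time[-1]:
        raise ValueError(
            f"feature window [{lo:.3f}, {hi:.3f}] outside the time axis"
        )
    q = PeakQuantification(label=feature.label)
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    t = chrom.time[mask]
    raw = chrom.intensity[mask]
    if t.size < 5:
        q.message = "fewer than 5 points in window"
        return q

    flank = _flank_points(chrom, feature, exclude_windows)
    if flank.size >= 4:
        run = _lowest_run(flank)
    else:  # no usable flanks: fall back to the window's own lowest half
        run = _lowest_run(raw)
    q.background = float(run.mean())
    q.noise = float(run.std(ddof=1)) if run.size > 1 else 0.0

    y = raw - q.background
    q.apex_rt = float(t[int(np.argmax(raw))])
    height0 = float(y.max())
    if height0 <= 0:
        q.message = "no signal above background"
        return q
    half = y >= height0 / 2.0
    sigma0 = max((t[half][-1] - t[half][0]) / _FWHM_TO_SIGMA,
                 chrom.sampling_interval)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss, t, y,
                p0=(height0, q.apex_rt, sigma0),
                bounds=((0.0, lo, chrom.sampling_interval / 10.0),
                        (np.inf, hi, 4.0 * feature.width)),
                maxfev=5000,
            )
    except (RuntimeError, ValueError) as exc:
        q.message = f"fit failed: {exc}"
        return q
    height, mu, sigma = map(float, popt)
    if not all(map(math.isfinite, (height, mu, sigma))) or sigma > 2.0 * feature.width:
        q.message = "fit diverged"
        return q
    q.fitted_height, q.fitted_mu, q.fitted_sigma = height, mu, sigma
    q.model_area = gaussian_model_area(height, sigma, sigma_edge)
    q.area = _integrate(t, y, mu - sigma_edge * sigma, mu + sigma_edge * sigma)
    q.gpq = compute_gpq(y, _gauss(t, *popt))
    q.sn = height / q.noise if q.noise > 0 else math.inf
    q.fit_ok = True
    if q.area < 0:
        q.area = 0.0
        q.passed_qc = False
        q.message = "negative integral clamped to 0"
    else:
        q.passed_qc = q.area > 0
    return q


def quantify_chromatogram(
    chrom: Chromatogram,
    features: Sequence[Feature],
    sigma_edge: float = 2.0,
    gpq_min: float = 0.8,
    sn_min: float = 9.0,
) -> list[PeakQuantification]:
    """Quantify every feature of a trace and gate the analytes.

    Each feature's flanking background windows exclude the windows of the
    other features.  Precondition violations (window outside the axis)
    are recorded as failed quantifications so one bad feature cannot abort
    a batch.
    """
    windows = [(f.expected_rt - f.width, f.expected_rt + f.width) for f in features]
    quants = []
    for i, feat in enumerate(features):
        others = windows[:i] + windows[i + 1:]
        try:
            q = quantify_peak(chrom, feat, sigma_edge, exclude_windows=others)
        except ValueError as exc:
            q = PeakQuantification(label=feat.label, message=str(exc))
        quants.append(q)
    return gate_analytes(quants, gpq_min=gpq_min, sn_min=sn_min)


def gate_analytes(
    quants: Iterable[PeakQuantification],
    gpq_min: float = 0.8,
    sn_min: float = 9.0,
) -> list[PeakQuantification]:
    """Apply the analyte QC gate: GPQ >= gpq_min and SN >= sn_min (inclusive).

    Nothing is removed — results are returned in order with ``passed_qc``
    set to whether the fit succeeded and both thresholds are met.
    """
    out = []
    for q in quants:
        passed = bool(q.fit_ok and q.gpq >= gpq_min and q.sn >= sn_min)
        out.append(replace(q, passed_qc=passed))
    return out


def quantifications_to_frame(quants: Sequence[PeakQuantification],
                             sample_id: str | None = None) -> pd.DataFrame:
    """One row per quantified peak, with all fitted fields."""
    df = pd.DataFrame([vars(q) for q in quants])
    if sample_id is not None:
        df.insert(0, "sample_id", sample_id)
    return df
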