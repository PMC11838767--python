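"""Detection, asymmetric-Gaussian modelling and characterisation of the
Abeta1-42 envelope in ROI spectra.

In linear-TOF mode (R ~ 1000) the isotopologue envelope is a single broad
peak; its intensity-weighted centroid tracks mean 15N incorporation. In
reflector mode (R ~ 15000) individual isotopologues resolve and the
4th/3rd peak-area ratio is an alternative label score. The stages are:

1. TIC normalisation of the ROI spectrum;
2. main-peak detection in a configured m/z search window;
3. symmetric fit-range selection around the apex;
4. linear baseline correction with zero clipping;
5. bounded nonlinear least-squares fit of a split (asymmetric) Gaussian,
   gated on R^2;
6. centroid of the baseline-subtracted trace between the baseline
   intersections flanking the apex;
7. (reflector) per-isotopologue peak areas between local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .spectra import Spectrum

log = logging.getLogger(__name__)

_HWHM = np.sqrt(2.0 * np.log(2.0))  # half-width-at-half-max per unit sigma


@dataclass
class FitConfig:
    """Tunables of the spectral pipeline.

    ``search_window`` defaults to 4460-4580 m/z, wide enough to hold the
    natural through fully 15N-labeled Abeta1-42 envelopes. ``noise_fraction``
    is the apex fraction below which the fit range stops extending;
    ``fwhm_cap_mult`` caps the half-range at that many provisional FWHMs.
    """

    search_window: tuple[float, float] = (4460.0, 4580.0)
    noise_fraction: float = 0.02
    fwhm_cap_mult: float = 5.0
    baseline_flank_fraction: float = 0.10
    r2_threshold: float = 0.95
    amp_bound_mult: float = 2.0
    centroid_mode: str = "discrete"  # "discrete" (measured trace) or "fitted"

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.search_window[1] <= self.search_window[0]:
            raise ValueError("search window must have positive width")


@dataclass
class PeakFitResult:
    """Fitted split-Gaussian description of one ROI's main peak."""

    amplitude: float
    center: float
    width_left: float
    width_right: float
    baseline_slope: float
    baseline_intercept: float
    fwhm: float
    r_squared: float
    centroid: float
    fit_range: tuple[float, float]
    accepted: bool
    diagnostic: str = ""
    meta: dict = field(default_factory=dict)


@dataclass
class IsotopologueAreas:
    """Integrated isotopologue peak areas, indexed 1-based from the first
    detected (monoisotopic) peak; ``ratio43`` = area(4th) / area(3rd)."""

    ladder_indices: np.ndarray  # positions along the expected m/z ladder
    areas: np.ndarray
    ratio43: float | None
    flagged: bool
    note: str = ""


def tic_normalize(spectrum: Spectrum) -> Spectrum:
    """Divide intensities by the total ion current (their sum)."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise ValueError("cannot TIC-normalize a spectrum with no positive signal")
    return spectrum.copy_with(spectrum.intensity / total)


def detect_main_peak(spectrum: Spectrum, config: FitConfig) -> int:
    """Index of the highest interior local maximum inside the search window.

    Ties are broken toward lower m/z (first occurrence in the ascending axis).
    """
    lo, hi = config.search_window
    sel = np.nonzero((spectrum.mz >= lo) & (spectrum.mz <= hi))[0]
    if sel.size < 3:
        raise ValueError("search window contains fewer than 3 samples")
    y = spectrum.intensity[sel]
    # interior local maxima; plateaus count once, at their left edge
    peaks = []
    i = 1
    while i < len(y) - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < len(y) - 1 and y[j + 1] == y[j]:
                j += 1
            if j < len(y) - 1 and y[j + 1] < y[j]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    if not peaks:
        raise ValueError("no local maximum in the search window")
    peaks = np.asarray(peaks)
    best = peaks[np.argmax(y[peaks])]  # argmax -> first = lowest m/z on ties
    return int(sel[best])


def _half_max_crossings(mz: np.ndarray, y: np.ndarray, apex: int) -> tuple[float, float]:
    """Interpolated m/z distances from apex to half-maximum on each flank."""
    half = y[apex] / 2.0
    left = right = None
    for i in range(apex, 0, -1):
        if y[i - 1] <= half:
            t = (y[i] - half) / max(y[i] - y[i - 1], 1e-300)
            left = mz[apex] - (mz[i] - t * (mz[i] - mz[i - 1]))
            break
    for i in range(apex, len(y) - 1):
        if y[i + 1] <= half:
            t = (y[i] - half) / max(y[i] - y[i + 1], 1e-300)
            right = (mz[i] + t * (mz[i + 1] - mz[i])) - mz[apex]
            break
    step = float(np.median(np.diff(mz)))
    return (left if left is not None else step, right if right is not None else step)


def select_fit_range(spectrum: Spectrum, peak: int, config: FitConfig) -> tuple[int, int]:
    """Symmetric index bounds (inclusive) around the apex.

    Extends until intensity falls below ``noise_fraction`` of the apex on both
    flanks, or the half-range reaches ``fwhm_cap_mult`` provisional FWHMs,
    whichever happens first; bounds clamp to the spectrum edges (logged).
    The stop test runs on a 5-sample moving average so single noise
    excursions below the threshold do not truncate the range mid-peak.
    """
    mz, y = spectrum.mz, spectrum.intensity
    ys = np.convolve(y, np.ones(5) / 5.0, mode="same") if len(y) >= 5 else y
    apex_val = y[peak]
    if apex_val <= 0:
        raise ValueError("apex intensity must be positive")
    dl, dr = _half_max_crossings(mz, y, peak)
    provisional_fwhm = dl + dr
    cap = config.fwhm_cap_mult * provisional_fwhm
    thr = config.noise_fraction * apex_val
    w = 1
    while True:
        lo, hi = peak - w, peak + w
        clamped = lo <= 0 or hi >= len(y) - 1
        lo, hi = max(lo, 0), min(hi, len(y) - 1)
        below = ys[lo] < thr and ys[hi] < thr
        over_cap = (mz[hi] - mz[peak] >= cap) or (mz[peak] - mz[lo] >= cap)
        if below or over_cap or clamped:
            if clamped and not (below or over_cap):
                log.warning("fit range clamped at spectrum edge (apex m/z %.2f)", mz[peak])
            break
        w += 1
    if hi - lo + 1 < 5:
        raise ValueError("fit range collapsed to fewer than 5 points")
    return lo, hi


def correct_baseline(
    mz: np.ndarray, intensity: np.ndarray, flank_fraction: float = 0.10
) -> tuple[np.ndarray, float, float]:
    """Subtract a straight line fitted through the outer flanks of the window.

    The line goes through the outer ``flank_fraction`` of points on each side
    (at least 2 per side); negatives after subtraction are clipped to zero.
    Returns (corrected, slope, intercept).
    """
    n = len(intensity)
    if n < 5:
        raise ValueError("baseline correction needs at least 5 points")
    k = max(2, int(round(flank_fraction * n)))
    idx = np.r_[0:k, n - k:n]
    slope, intercept = np.polyfit(mz[idx], intensity[idx], 1)
    corrected = intensity - (slope * mz + intercept)
    return np.clip(corrected, 0.0, None), float(slope), float(intercept)


def _split_gaussian(x: np.ndarray, a: float, c: float, wl: float, wr: float) -> np.ndarray:
    w = np.where(x < c, wl, wr)
    return a * np.exp(-0.5 * ((x - c) / w) ** 2)


def fit_asym_gaussian(
    mz: np.ndarray, corrected: np.ndarray, config: FitConfig
) -> PeakFitResult:
    """Bounded least-squares fit of a split Gaussian to a corrected window.

    The model has independent left/right flank widths; FWHM is
    sqrt(2 ln 2) * (wL + wR). Non-convergence yields a rejected result with a
    diagnostic, never an exception.
    """
    apex = int(np.argmax(corrected))
    apex_val = float(corrected[apex])
    step = float(np.median(np.diff(mz)))
    width = float(mz[-1] - mz[0])
    dl, dr = _half_max_crossings(mz, corrected, apex)
    p0 = [apex_val, float(mz[apex]), max(dl / _HWHM, step), max(dr / _HWHM, step)]
    bounds = (
        [0.0, mz[0], step, step],
        [config.amp_bound_mult * max(apex_val, 1e-300), mz[-1], width, width],
    )
    p0 = [min(max(p, lo), hi) for p, lo, hi in zip(p0, *bounds)]
    try:
        popt, _ = curve_fit(
            _split_gaussian, mz, corrected, p0=p0, bounds=bounds, maxfev=2000
        )
        a, c, wl, wr = (float(v) for v in popt)
        converged = True
        note = ""
    except (RuntimeError, ValueError) as exc:
        a, c, wl, wr = p0
        converged = False
        note = f"fit did not converge: {exc}"
    model = _split_gaussian(mz, a, c, wl, wr)
    ss_res = float(np.sum((corrected - model) ** 2))
    ss_tot = float(np.sum((corrected - corrected.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    fwhm = _HWHM * (wl + wr)
    accepted = converged and r2 > config.r2_threshold
    return PeakFitResult(
        amplitude=a,
        center=c,
        width_left=wl,
        width_right=wr,
        baseline_slope=np.nan,
        baseline_intercept=np.nan,
        fwhm=fwhm,
        r_squared=r2,
        centroid=np.nan,
        fit_range=(float(mz[0]), float(mz[-1])),
        accepted=accepted,
        diagnostic=note,
    )


def centroid(
    mz: np.ndarray,
    corrected: np.ndarray,
    fit: PeakFitResult | None = None,
    mode: str = "discrete",
    bound_fraction: float = 0.02,
) -> float:
    """Intensity-weighted mean m/z between the baseline intersections
    flanking the apex.

    The integration bounds are where the fitted curve meets the baseline:
    since the model only reaches the baseline asymptotically, the
    intersection is taken where it falls below ``bound_fraction`` of the
    fitted amplitude. This keeps the window deterministic under noise.
    Without a converged fit, the bounds fall back to the nearest zero
    samples of the zero-clipped corrected trace on each side of the apex.
    ``mode`` selects the weights: the measured corrected trace
    ("discrete", default) or the fitted curve ("fitted").
    """
    apex = int(np.argmax(corrected))
    lo, hi = None, None
    if fit is not None and np.isfinite(fit.center) and fit.amplitude > 0:
        k = np.sqrt(2.0 * np.log(1.0 / bound_fraction))
        left = fit.center - fit.width_left * k
        right = fit.center + fit.width_right * k
        sel = np.nonzero((mz >= left) & (mz <= right))[0]
        if sel.size >= 3:
            lo, hi = int(sel[0]), int(sel[-1])
    if lo is None:
        lo = 0
        for i in range(apex, -1, -1):
            if corrected[i] <= 0:
                lo = i
                break
        hi = len(corrected) - 1
        for i in range(apex, len(corrected)):
            if corrected[i] <= 0:
                hi = i
                break
    if mode == "fitted":
        if fit is None:
            raise ValueError("fitted-mode centroid needs a PeakFitResult")
        weights = _split_gaussian(
            mz[lo : hi + 1], fit.amplitude, fit.center, fit.width_left, fit.width_right
        )
    elif mode == "discrete":
        weights = corrected[lo : hi + 1]
    else:
        raise ValueError(f"unknown centroid mode {mode!r}")
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("zero total area between baseline intersections")
    return float(np.sum(mz[lo : hi + 1] * weights) / total)


def fit_roi_spectrum(spectrum: Spectrum, config: FitConfig | None = None) -> PeakFitResult:
    """Run the full linear-mode chain on one ROI spectrum.

    TIC-normalises, detects the main peak, selects the fit range, corrects
    the baseline, fits the split Gaussian and computes the centroid. The
    centroid is invariant to the TIC step (it is a weighted mean).
    """
    config = config or FitConfig()
    spec = tic_normalize(spectrum)
    peak = detect_main_peak(spec, config)
    lo, hi = select_fit_range(spec, peak, config)
    wmz = spec.mz[lo : hi + 1]
    corrected, slope, intercept = correct_baseline(
        wmz, spec.intensity[lo : hi + 1], config.baseline_flank_fraction
    )
    result = fit_asym_gaussian(wmz, corrected, config)
    result.baseline_slope = slope
    result.baseline_intercept = intercept
    try:
        result.centroid = centroid(wmz, corrected, result, config.centroid_mode)
    except ValueError as exc:
        result.accepted = False
        result.diagnostic = (result.diagnostic + f"; centroid failed: {exc}").strip("; ")
    result.meta = dict(spectrum.meta)
    return result


def isotopologue_areas(
    spectrum: Spectrum,
    expected_mz_ladder: np.ndarray,
    tolerance: float = 0.3,
    min_rel_height: float = 0.05,
) -> IsotopologueAreas:
    """Integrate resolved isotopologue peaks of a reflector-mode spectrum.

    Each ladder position is matched to a detected local maximum within
    ``tolerance`` Da; each matched peak is integrated between the local
    minima separating it from its neighbours. Indexing is 1-based from the
    first detected ladder peak; ``ratio43`` is undefined (and flagged) if the
    3rd or 4th peak is missing or the 3rd has zero area.

    The peak list is kept above the noise floor by a joint height and
    prominence cut at max(``min_rel_height`` x spectrum maximum, 6 x the
    MAD-estimated noise sd); spurious noise spikes would otherwise
    masquerade as neighbouring peaks and corrupt the integration bounds.
    """
    from scipy.signal import find_peaks

    ladder = np.asarray(expected_mz_ladder, dtype=float)
    mz, y = spectrum.mz, spectrum.intensity
    noise_sd = 1.4826 * float(np.median(np.abs(y - np.median(y))))
    floor = max(min_rel_height * float(y.max(initial=0.0)), 6.0 * noise_sd)
    peaks, _ = find_peaks(y, height=floor, prominence=floor / 2.0)
    if peaks.size == 0:
        return IsotopologueAreas(
            np.array([], int), np.array([]), None, True, "no peaks detected"
        )
    matched: list[tuple[int, int]] = []  # (ladder position, peak index)
    for j, m in enumerate(ladder):
        d = np.abs(mz[peaks] - m)
        k = int(np.argmin(d))
        if d[k] <= tolerance:
            matched.append((j, int(peaks[k])))
    if not matched:
        return IsotopologueAreas(
            np.array([], int), np.array([]), None, True, "no ladder peaks matched"
        )
    areas = []
    indices = []
    peak_sorted = np.sort(peaks)
    for j, p in matched:
        pos = np.searchsorted(peak_sorted, p)
        left_peak = peak_sorted[pos - 1] if pos > 0 else 0
        right_peak = peak_sorted[pos + 1] if pos + 1 < len(peak_sorted) else len(y) - 1
        lo = left_peak + int(np.argmin(y[left_peak:p + 1])) if left_peak < p else p
        hi = p + int(np.argmin(y[p:right_peak + 1])) if right_peak > p else p
        if hi <= lo:
            area = 0.0
        else:
            area = float(np.trapezoid(y[lo : hi + 1], mz[lo : hi + 1]))
        indices.append(j)
        areas.append(area)
    indices = np.asarray(indices)
    areas = np.asarray(areas)
    first = indices[0]
    want3, want4 = first + 2, first + 3  # 3rd and 4th, 1-based from first
    have = {int(i): float(a) for i, a in zip(indices, areas)}
    if want3 in have and want4 in have and have[want3] > 0:
        ratio43: float | None = have[want4] / have[want3]
        flagged = False
        note = ""
    else:
        ratio43 = None
        flagged = True
        note = "3rd or 4th isotopologue undetected or zero-area"
    return IsotopologueAreas(indices, areas, ratio43, flagged, note)
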