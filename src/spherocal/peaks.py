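"""Calcium transient detection and multiparametric peak features.

A well (or ROI) trace is scanned for positive-going transients with a
moving-average detector: the trace is smoothed with a centered window of
``search_vector_length`` frames, a baseline is taken as the 10th
percentile of the smoothed trace, and candidate apexes must clear both a
trigger level 10% above the baseline and a dynamic threshold of
``dynamic_threshold_k`` robust noise SDs above it.  Each detected
transient is then measured for amplitude, kinetics (rise/decay times and
10-90% slopes), transient durations at 50% and 90% of amplitude
(cardiac CTD convention: CTD90 is measured near the baseline and is the
wider of the two), and secondary decay-phase humps (EAD-like events).

The per-trace summary is a fixed catalogue of peak statistics
(:data:`FEATURE_NAMES`): mean/SD pairs over the per-peak measurements
plus count, rate, and spacing statistics.  Traces with fewer than two
peaks report SDs as missing (NaN), and traces with no peaks report every
statistic except the count as missing, so that population summaries are
never biased by silent wells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

#: Canonical order of the per-trace peak statistics (seven mean/SD pairs
#: plus count, CTD50, CTD90, and the EAD-like event count).
FEATURE_NAMES: tuple[str, ...] = (
    "mean_peak_amplitude",
    "peak_amplitude_sd",
    "peak_count",
    "mean_peak_rate",
    "peak_rate_sd",
    "peak_spacing",
    "peak_spacing_sd",
    "ead_like_per_well",
    "ctd50",
    "ctd90",
    "rise_slope",
    "rise_slope_sd",
    "mean_peak_rise_time",
    "peak_rise_time_sd",
    "decay_slope",
    "decay_slope_sd",
    "mean_peak_decay_time",
    "peak_decay_time_sd",
)


class TraceError(ValueError):
    """Raised for structurally invalid traces or detector inputs."""


@dataclass(frozen=True)
class Trace:
    """A single fluorescence time series sampled at a uniform frame rate.

    Parameters
    ----------
    values:
        Fluorescence in arbitrary units (raw counts for plate-reader
        wells, F/F0 units for normalized ROI traces).
    frame_rate_hz:
        Acquisition rate in frames per second.
    id:
        Label carried through feature tables (well id or ROI id).
    """

    values: np.ndarray
    frame_rate_hz: float
    id: str = "trace"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise TraceError(f"trace {self.id!r}: need a 1-D series of >= 2 frames")
        if not np.all(np.isfinite(v)):
            raise TraceError(f"trace {self.id!r}: non-finite values")
        if not self.frame_rate_hz > 0:
            raise TraceError(f"trace {self.id!r}: frame rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Recording length in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class DetectorParams:
    """Detector settings for :func:`detect_peaks`.

    ``search_vector_length`` is the centered smoothing window in frames
    (always 11 for plate-reader analyses here), ``trigger_fraction``
    places the trigger level 10% above the baseline by default, and the
    dynamic threshold adds ``dynamic_threshold_k`` robust noise SDs on
    top of the baseline; a candidate apex must clear both.
    """

    search_vector_length: int = 11
    trigger_fraction: float = 0.10
    positive_polarity: bool = True
    dynamic_threshold_k: float = 3.0
    min_peak_separation_s: float | None = None  # default: window / frame rate
    ead_prominence_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.search_vector_length < 3 or self.search_vector_length % 2 == 0:
            raise ValueError("search_vector_length must be odd and >= 3")
        if not self.trigger_fraction > 0:
            raise ValueError("trigger_fraction must be > 0")
        if self.dynamic_threshold_k < 0:
            raise ValueError("dynamic_threshold_k must be >= 0")
        if not self.positive_polarity:
            raise ValueError("only positive event polarity is supported")


@dataclass(frozen=True)
class Peak:
    """One measured calcium transient."""

    apex_index: int
    apex_time_s: float
    amplitude: float
    start_index: int
    end_index: int
    rise_time_s: float
    decay_time_s: float
    ctd50_s: float
    ctd90_s: float
    rise_slope: float
    decay_slope: float
    n_ead: int


@dataclass(frozen=True)
class PeakFeatureSet:
    """The per-trace peak statistic panel, keyed by :data:`FEATURE_NAMES`."""

    trace_id: str
    mean_peak_amplitude: float
    peak_amplitude_sd: float
    peak_count: int
    mean_peak_rate: float
    peak_rate_sd: float
    peak_spacing: float
    peak_spacing_sd: float
    ead_like_per_well: float
    ctd50: float
    ctd90: float
    rise_slope: float
    rise_slope_sd: float
    mean_peak_rise_time: float
    peak_rise_time_sd: float
    decay_slope: float
    decay_slope_sd: float
    mean_peak_decay_time: float
    peak_decay_time_sd: float

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge replication (length preserving)."""
    if window <= 1:
        return values.astype(float)
    pad = window // 2
    padded = np.pad(values.astype(float), pad, mode="edge")
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def estimate_baseline(
    trace: Trace, params: DetectorParams | None = None
) -> tuple[float, float]:
    """Estimate the resting fluorescence level and noise SD of a trace.

    The baseline is the 10th percentile of the smoothed trace; the noise
    is a MAD-scaled SD of the frame-to-frame difference (divided by
    sqrt(2)), restricted to sub-trigger frames.  Difference detrending
    makes the estimate insensitive to the smooth transient waveform
    itself, so dense oscillations do not inflate it.  A constant trace
    returns (that constant, 0).
    """
    p = params or DetectorParams()
    v = trace.values
    window = min(p.search_vector_length, v.size if v.size % 2 == 1 else v.size - 1)
    s = _smooth(v, window)
    baseline = float(np.percentile(s, 10))
    trigger = baseline * (1.0 + p.trigger_fraction)
    resid = np.diff(v)
    mask = (s[:-1] < trigger) & (s[1:] < trigger)
    r = resid[mask] if mask.any() else resid
    noise_sd = float(1.4826 * np.median(np.abs(r - np.median(r))) / np.sqrt(2.0))
    # The 10th percentile of a flat noisy stretch sits z_{0.9} smoothed-noise
    # SDs below the resting level; undo that known bias so a pure-noise
    # trace is estimated at its true mean.
    baseline += 1.2816 * noise_sd / np.sqrt(window)
    return baseline, noise_sd


def trigger_level(baseline: float, params: DetectorParams | None = None) -> float:
    """Trigger level: ``trigger_fraction`` above the baseline (10% default)."""
    p = params or DetectorParams()
    return baseline * (1.0 + p.trigger_fraction)


def _cross_time_rising(
    v: np.ndarray, lo: int, hi: int, level: float, fs: float
) -> float:
    """Interpolated time at which v rises through `level`, scanning back from hi."""
    i = hi
    while i > lo and v[i - 1] >= level:
        i -= 1
    if i == lo and v[lo] >= level:
        return lo / fs  # clipped at window edge
    denom = v[i] - v[i - 1]
    frac = (level - v[i - 1]) / denom if denom != 0 else 0.0
    return (i - 1 + frac) / fs


def _cross_time_falling(
    v: np.ndarray, lo: int, hi: int, level: float, fs: float
) -> float:
    """Interpolated time at which v falls through `level`, scanning from lo."""
    i = lo
    while i < hi and v[i + 1] >= level:
        i += 1
    if i == hi and v[hi] >= level:
        return hi / fs
    denom = v[i] - v[i + 1]
    frac = (v[i] - level) / denom if denom != 0 else 0.0
    return (i + frac) / fs


def measure_peak(
    trace: Trace,
    baseline: float,
    start: int,
    apex: int,
    end: int,
    other_apexes: Sequence[int] = (),
    params: DetectorParams | None = None,
) -> Peak | None:
    """Measure one transient bracketed by trigger crossings.

    Returns None (and logs) for degenerate windows where the apex sits
    on the window boundary or the amplitude is non-positive.
    """
    p = params or DetectorParams()
    v = trace.values
    fs = trace.frame_rate_hz
    if not (start < apex < end):
        logger.warning(
            "trace %s: degenerate peak window (%d, %d, %d) discarded",
            trace.id, start, apex, end,
        )
        return None
    amplitude = float(v[apex] - baseline)
    if amplitude <= 0:
        logger.warning("trace %s: non-positive amplitude at frame %d", trace.id, apex)
        return None

    rise_time = (apex - start) / fs
    decay_time = (end - apex) / fs

    def level(frac: float) -> float:
        return baseline + frac * amplitude

    # Widths at 50% and 10% of amplitude (CTD50 / CTD90, cardiac convention).
    ctd50 = _cross_time_falling(v, apex, end, level(0.5), fs) - _cross_time_rising(
        v, start, apex, level(0.5), fs
    )
    ctd90 = _cross_time_falling(v, apex, end, level(0.1), fs) - _cross_time_rising(
        v, start, apex, level(0.1), fs
    )

    # Slopes between the 10% and 90% amplitude crossings on each limb.
    t10r = _cross_time_rising(v, start, apex, level(0.1), fs)
    t90r = _cross_time_rising(v, start, apex, level(0.9), fs)
    if t90r > t10r:
        rise_slope = 0.8 * amplitude / (t90r - t10r)
    else:
        rise_slope = amplitude / max(rise_time, 1.0 / fs)
    t90f = _cross_time_falling(v, apex, end, level(0.9), fs)
    t10f = _cross_time_falling(v, apex, end, level(0.1), fs)
    if t10f > t90f:
        decay_slope = -0.8 * amplitude / (t10f - t90f)
    else:
        decay_slope = -amplitude / max(decay_time, 1.0 / fs)

    # EAD-like events: interior local maxima on the decay limb with
    # prominence >= 10% of amplitude that are not stand-alone peaks.
    n_ead = 0
    if end - apex >= 3:
        seg = v[apex + 1 : end]
        sub, _ = _signal.find_peaks(seg, prominence=p.ead_prominence_fraction * amplitude)
        excluded = set(int(a) for a in other_apexes)
        n_ead = sum(1 for k in sub if (apex + 1 + int(k)) not in excluded)

    return Peak(
        apex_index=int(apex),
        apex_time_s=apex / fs,
        amplitude=amplitude,
        start_index=int(start),
        end_index=int(end),
        rise_time_s=rise_time,
        decay_time_s=decay_time,
        ctd50_s=float(ctd50),
        ctd90_s=float(ctd90),
        rise_slope=float(rise_slope),
        decay_slope=float(decay_slope),
        n_ead=int(n_ead),
    )


def detect_peaks(
    trace: Trace, params: DetectorParams | None = None
) -> list[Peak]:
    """Detect and measure all positive-going transients in a trace.

    The smoothed trace is searched for local maxima clearing
    max(trigger level, baseline + k * noise SD); apexes closer than the
    minimum separation are merged keeping the larger, the apex is then
    refined to the raw-trace maximum within half a smoothing window, and
    each peak is bracketed by the trigger crossings around its apex.
    Deterministic: identical inputs give identical output.
    """
    p = params or DetectorParams()
    v = trace.values
    n = v.size
    fs = trace.frame_rate_hz
    if n < p.search_vector_length:
        raise TraceError(
            f"trace {trace.id!r}: {n} frames < search vector length "
            f"{p.search_vector_length}"
        )
    s = _smooth(v, p.search_vector_length)
    baseline, noise_sd = estimate_baseline(trace, p)
    trigger = trigger_level(baseline, p)
    threshold = max(trigger, baseline + p.dynamic_threshold_k * noise_sd)

    min_sep = (
        p.min_peak_separation_s
        if p.min_peak_separation_s is not None
        else p.search_vector_length / fs
    )
    distance = max(1, int(round(min_sep * fs)))
    candidates, _ = _signal.find_peaks(s, height=trigger, distance=distance)

    # Refine each apex to the raw-trace maximum within half a window;
    # the height requirement (trigger AND dynamic threshold) is applied
    # to the raw apex, which smoothing has not attenuated.
    half = p.search_vector_length // 2
    refined: list[int] = []
    for i in candidates:
        lo = max(0, int(i) - half)
        hi = min(n, int(i) + half + 1)
        j = lo + int(np.argmax(v[lo:hi]))
        if v[j] >= threshold:
            refined.append(j)
    # Minimum separation was enforced on the smoothed candidates; after
    # refinement only collisions within half a window can occur (two
    # candidates sliding onto the same raw maximum) — merge those,
    # keeping the larger.
    refined = sorted(set(refined))
    apexes: list[int] = []
    for j in refined:
        if apexes and j - apexes[-1] <= half:
            if v[j] > v[apexes[-1]]:
                apexes[-1] = j
        else:
            apexes.append(j)

    peaks: list[Peak] = []
    for j in apexes:
        a = j
        while a > 0 and s[a - 1] >= trigger:
            a -= 1
        start = a - 1 if a > 0 else 0
        b = j
        while b < n - 1 and s[b + 1] >= trigger:
            b += 1
        end = b + 1 if b < n - 1 else n - 1
        peak = measure_peak(trace, baseline, start, j, end, other_apexes=apexes, params=p)
        if peak is not None:
            peaks.append(peak)
    return peaks


def _sd(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return math.nan
    return float(np.std(arr, ddof=1))


def _mean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return math.nan
    return float(np.mean(arr))


def extract_features(trace: Trace, peaks: Sequence[Peak]) -> PeakFeatureSet:
    """Summarize detected peaks into the multiparametric feature panel.

    Rates are per minute; the mean rate is count / duration while the
    rate SD is taken over per-interval instantaneous rates (60 s divided
    by each inter-apex interval).  Spacing is the mean inter-apex
    interval in seconds.  With no peaks every statistic except the count
    is missing; SDs additionally require at least two peaks.
    """
    count = len(peaks)
    duration_min = trace.duration_s / 60.0
    nan = math.nan
    if count == 0:
        return PeakFeatureSet(trace_id=trace.id, peak_count=0, **{
            name: nan for name in FEATURE_NAMES if name != "peak_count"
        })

    apex_times = np.array([pk.apex_time_s for pk in peaks])
    intervals = np.diff(apex_times)
    inst_rates = 60.0 / intervals if intervals.size else np.array([])

    amplitudes = [pk.amplitude for pk in peaks]
    rises = [pk.rise_time_s for pk in peaks]
    decays = [pk.decay_time_s for pk in peaks]
    rslopes = [pk.rise_slope for pk in peaks]
    dslopes = [pk.decay_slope for pk in peaks]

    return PeakFeatureSet(
        trace_id=trace.id,
        mean_peak_amplitude=_mean(amplitudes),
        peak_amplitude_sd=_sd(amplitudes),
        peak_count=count,
        mean_peak_rate=count / duration_min,
        peak_rate_sd=_sd(inst_rates) if intervals.size else nan,
        peak_spacing=_mean(intervals) if intervals.size else nan,
        peak_spacing_sd=_sd(intervals),
        ead_like_per_well=float(sum(pk.n_ead for pk in peaks)),
        ctd50=_mean([pk.ctd50_s for pk in peaks]),
        ctd90=_mean([pk.ctd90_s for pk in peaks]),
        rise_slope=_mean(rslopes),
        rise_slope_sd=_sd(rslopes),
        mean_peak_rise_time=_mean(rises),
        peak_rise_time_sd=_sd(rises),
        decay_slope=_mean(dslopes),
        decay_slope_sd=_sd(dslopes),
        mean_peak_decay_time=_mean(decays),
        peak_decay_time_sd=_sd(decays),
    )


def analyze_trace(
    trace: Trace, params: DetectorParams | None = None
) -> PeakFeatureSet:
    """Convenience: detect peaks and extract the full feature panel."""
    return extract_features(trace, detect_peaks(trace, params))
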