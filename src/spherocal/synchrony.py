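"""Single-cell (ROI) stage: F/F0 normalization, SNR filtering, pairwise
R-squared correlation matrices, the network synchrony score, and the
correlation-constrained 12-ROI subsample used for per-ROI peak analysis.

Synchrony is scored as the mean squared Pearson correlation (R²) over
all distinct ROI pairs of one spheroid.  R² is sign-blind — a perfectly
anti-correlated pair scores 1 — so the signed correlation matrix is
kept alongside for audit.  The score excludes the unit diagonal by
default (including it inflates small-n scores); pass
``include_diagonal=True`` to average the whole matrix instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import peaks as _peaks
from .peaks import DetectorParams, Trace

logger = logging.getLogger(__name__)


class RoiError(ValueError):
    """Raised for invalid ROI sets or undefined synchrony operations."""


@dataclass(frozen=True)
class ROITraceSet:
    """A frames x ROIs fluorescence matrix for one spheroid."""

    data: np.ndarray
    frame_rate_hz: float
    roi_ids: list[str]
    spheroid_id: str = "spheroid"
    normalized: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        # Zero columns are tolerated so an emptied-out filter result can be
        # represented; every downstream operation refuses to consume it.
        if d.ndim != 2 or d.shape[0] < 2:
            raise RoiError("ROI matrix must be frames x ROIs with >= 2 frames")
        if not np.all(np.isfinite(d)):
            raise RoiError("ROI matrix contains non-finite values")
        if not self.frame_rate_hz > 0:
            raise RoiError("frame rate must be positive")
        if len(self.roi_ids) != d.shape[1]:
            raise RoiError("roi_ids length must match the number of columns")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "roi_ids", list(self.roi_ids))

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_rois(self) -> int:
        return int(self.data.shape[1])

    def column(self, i: int) -> Trace:
        return Trace(self.data[:, i], self.frame_rate_hz, id=self.roi_ids[i])

    def select(self, indices: list[int]) -> "ROITraceSet":
        return ROITraceSet(
            data=self.data[:, indices],
            frame_rate_hz=self.frame_rate_hz,
            roi_ids=[self.roi_ids[i] for i in indices],
            spheroid_id=self.spheroid_id,
            normalized=self.normalized,
        )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise squared Pearson correlations (with the signed r kept)."""

    r2: np.ndarray
    r: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.r2, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise RoiError("correlation matrix must be square")

    @property
    def n_rois(self) -> int:
        return int(self.r2.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.roi_ids, columns=self.roi_ids)


@dataclass(frozen=True)
class SynchronyResult:
    score: float
    n_rois: int
    include_diagonal: bool = False


@dataclass(frozen=True)
class SubsampleResult:
    roi_set: ROITraceSet
    indices: list[int]
    score: float
    population_score: float
    attempts: int


def normalize_f_over_f0(roi_set: ROITraceSet) -> ROITraceSet:
    """Normalize each ROI to F/F0 and shift so its minimum equals exactly 1.

    Each column is divided by its own baseline estimate (10th percentile
    of the smoothed trace) and then shifted so the column minimum is
    1.0, matching the convention for reported confocal values.  The
    result is invariant to positive rescaling of the raw column.
    """
    data = roi_set.data
    out = np.empty_like(data)
    for i in range(roi_set.n_rois):
        col = data[:, i]
        if np.min(col) <= 0:
            raise RoiError(
                f"ROI {roi_set.roi_ids[i]!r}: non-positive fluorescence; "
                "F/F0 normalization needs strictly positive input"
            )
        baseline, _ = _peaks.estimate_baseline(
            Trace(col, roi_set.frame_rate_hz, id=roi_set.roi_ids[i])
        )
        f = col / baseline
        out[:, i] = f - f.min() + 1.0
    return ROITraceSet(
        data=out,
        frame_rate_hz=roi_set.frame_rate_hz,
        roi_ids=roi_set.roi_ids,
        spheroid_id=roi_set.spheroid_id,
        normalized=True,
    )


def filter_active_rois(
    roi_set: ROITraceSet, snr_threshold: float = 3.0
) -> tuple[ROITraceSet, pd.DataFrame]:
    """Keep ROIs whose signal-to-noise ratio clears the threshold.

    SNR is (smoothed max - baseline) / noise_sd per ROI: smoothing
    suppresses the extreme-value excursions of pure noise (whose raw
    maximum alone would sit ~3 SDs above baseline) while a real
    transient survives it.  A noiseless ROI with any signal above
    baseline has infinite SNR and is always retained.  Returns the
    retained subset and a per-ROI report (roi, snr, retained); warns
    if nothing survives.
    """
    records = []
    keep: list[int] = []
    window = DetectorParams().search_vector_length
    for i in range(roi_set.n_rois):
        col = roi_set.data[:, i]
        baseline, noise_sd = _peaks.estimate_baseline(
            Trace(col, roi_set.frame_rate_hz, id=roi_set.roi_ids[i])
        )
        smoothed = _peaks._smooth(col, window)
        signal = float(smoothed.max() - baseline)
        snr = np.inf if noise_sd == 0 and signal > 0 else (
            signal / noise_sd if noise_sd > 0 else 0.0
        )
        retained = bool(snr >= snr_threshold)
        if retained:
            keep.append(i)
        records.append({"roi": roi_set.roi_ids[i], "snr": snr, "retained": retained})
    report = pd.DataFrame(records)
    if not keep:
        warnings.warn(
            f"spheroid {roi_set.spheroid_id!r}: no ROI passed SNR >= {snr_threshold}",
            stacklevel=2,
        )
    return roi_set.select(keep), report


def correlation_matrix(roi_set: ROITraceSet) -> CorrelationMatrix:
    """Pairwise squared Pearson correlation over all frames.

    Zero-variance ROIs have undefined correlations and are excluded
    with a warning rather than assigned a value.
    """
    if roi_set.n_rois < 2:
        raise RoiError("correlation matrix needs >= 2 ROIs")
    variances = roi_set.data.var(axis=0)
    good = [i for i in range(roi_set.n_rois) if variances[i] > 0]
    dropped = [roi_set.roi_ids[i] for i in range(roi_set.n_rois) if variances[i] == 0]
    if dropped:
        warnings.warn(
            f"excluding zero-variance ROIs from correlation: {dropped}", stacklevel=2
        )
    if len(good) < 2:
        raise RoiError("fewer than 2 ROIs with nonzero variance")
    sub = roi_set.select(good)
    r = np.corrcoef(sub.data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r2 = np.clip(r**2, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return CorrelationMatrix(r2=r2, r=r, roi_ids=sub.roi_ids)


def synchrony_score(
    cm: CorrelationMatrix, include_diagonal: bool = False
) -> SynchronyResult:
    """Mean pairwise R² — the spheroid's network synchrony in [0, 1].

    By default the unit diagonal is excluded (strict upper triangle);
    ``include_diagonal=True`` averages the full matrix instead.
    """
    n = cm.n_rois
    if n < 2:
        raise RoiError("synchrony score is undefined for a single ROI")
    if include_diagonal:
        score = float(np.mean(cm.r2))
    else:
        iu = np.triu_indices(n, k=1)
        score = float(np.mean(cm.r2[iu]))
    return SynchronyResult(score=score, n_rois=n, include_diagonal=include_diagonal)


def _subset_score(cm: CorrelationMatrix, idx: np.ndarray) -> float:
    block = cm.r2[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.mean(block[iu]))


def subsample_rois(
    roi_set: ROITraceSet,
    cm: CorrelationMatrix | None = None,
    k: int = 12,
    tolerance: float = 0.05,
    seed: int = 0,
    max_attempts: int = 10000,
) -> SubsampleResult:
    """Draw a random k-ROI subset representative of population synchrony.

    Uniform k-subsets are drawn (rejection sampling, deterministic under
    ``seed``) until the subset's synchrony score is within ``tolerance``
    relative of the population score.  If the set has at most k ROIs it
    is returned whole with zero attempts.
    """
    if cm is None:
        cm = correlation_matrix(roi_set)
    if cm.n_rois != roi_set.n_rois or cm.roi_ids != roi_set.roi_ids:
        # Correlation may have dropped zero-variance ROIs; restrict to them.
        keep = [roi_set.roi_ids.index(rid) for rid in cm.roi_ids]
        roi_set = roi_set.select(keep)
    n = roi_set.n_rois
    if n <= k:
        pop = synchrony_score(cm).score if n >= 2 else float("nan")
        return SubsampleResult(
            roi_set=roi_set, indices=list(range(n)), score=pop,
            population_score=pop, attempts=0,
        )
    pop = synchrony_score(cm).score
    rng = np.random.default_rng(seed)
    best_dev = np.inf
    for attempt in range(1, max_attempts + 1):
        idx = np.sort(rng.choice(n, size=k, replace=False))
        score = _subset_score(cm, idx)
        dev = abs(score - pop) if pop == 0 else abs(score - pop) / pop
        if dev <= tolerance:
            return SubsampleResult(
                roi_set=roi_set.select(list(idx)),
                indices=[int(i) for i in idx],
                score=score,
                population_score=pop,
                attempts=attempt,
            )
        best_dev = min(best_dev, dev)
    raise RoiError(
        f"no {k}-ROI subset within {tolerance:.0%} of the population score "
        f"after {max_attempts} attempts (best relative deviation {best_dev:.3f})"
    )


def roi_feature_table(
    subset: ROITraceSet,
    score: SynchronyResult | None = None,
    params: DetectorParams | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-ROI peak features plus the spheroid-level summary.

    Each ROI trace goes through the standard peak detector; the summary
    reports the mean peak count, amplitude and width (CTD50) over the
    subset — the three statistics reported for confocal recordings —
    plus the synchrony score when one is supplied.
    """
    if subset.n_rois == 0:
        raise RoiError("empty ROI subset")
    rows = []
    for i in range(subset.n_rois):
        feats = _peaks.analyze_trace(subset.column(i), params)
        rows.append({"roi": subset.roi_ids[i], **feats.to_dict()})
    table = pd.DataFrame(rows).set_index("roi")
    summary = {
        "mean_peak_count": float(table["peak_count"].mean()),
        "mean_peak_amplitude": float(table["mean_peak_amplitude"].mean()),
        "mean_peak_width": float(table["ctd50"].mean()),
    }
    if score is not None:
        summary["synchrony_score"] = score.score
    return table, summary


def mean_trace_with_ci(roi_set: ROITraceSet) -> pd.DataFrame:
    """Per-frame population mean with a 95% confidence band (1.96 x SEM)."""
    mean = roi_set.data.mean(axis=1)
    sem = roi_set.data.std(axis=1, ddof=1) / np.sqrt(roi_set.n_rois) if roi_set.n_rois > 1 else np.zeros_like(mean)
    t = np.arange(roi_set.n_frames) / roi_set.frame_rate_hz
    return pd.DataFrame({
        "time_s": t,
        "mean": mean,
        "ci_low": mean - 1.96 * sem,
        "ci_high": mean + 1.96 * sem,
    })
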