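"""Plate-level quality control and normalization.

Three stages gate a feature table before classification:

* a reproducibility screen that computes the percent coefficient of
  variation (%CV = 100 * SD / mean) of each peak parameter within each
  plate and retains only parameters under a cutoff (30% by default) on
  every plate;
* percent-of-control normalization, in which every value is expressed
  as a percentage of the mean of that plate's vehicle-control wells, so
  the control group averages exactly 100 per plate and parameter;
* iterated Grubbs outlier removal at alpha = 0.05.

%CV is computed over vehicle-control wells by default, since the screen
measures assay reproducibility rather than biology; pass
``controls_only=False`` to use all wells of the plate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class QCError(ValueError):
    """Raised for undefined QC quantities (e.g. %CV with mean <= 0)."""


def _plate_values(
    features: pd.DataFrame,
    plate_map: pd.DataFrame,
    parameter: str,
    plate: str,
    controls_only: bool,
) -> np.ndarray:
    pm = plate_map[plate_map["plate"] == plate]
    if controls_only:
        pm = pm[pm["is_control"]]
    wells = [w for w in pm["well"] if w in features.index]
    vals = features.loc[wells, parameter].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def percent_cv(
    features: pd.DataFrame,
    plate_map: pd.DataFrame,
    parameter: str,
    plate: str,
    controls_only: bool = True,
) -> float:
    """%CV = 100 * SD / mean of a parameter within one plate.

    Undefined (raises) when fewer than two non-missing values exist or
    the mean is non-positive; the CV screen treats either as a failure.
    """
    vals = _plate_values(features, plate_map, parameter, plate, controls_only)
    if vals.size < 2:
        raise QCError(
            f"%CV of {parameter!r} on plate {plate!r}: need >= 2 non-missing values"
        )
    mean = float(np.mean(vals))
    if mean <= 0:
        raise QCError(f"%CV of {parameter!r} on plate {plate!r}: non-positive mean")
    return 100.0 * float(np.std(vals, ddof=1)) / mean


def cv_filter(
    features: pd.DataFrame,
    plate_map: pd.DataFrame,
    threshold: float = 30.0,
    controls_only: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Retain parameters whose %CV is under the threshold on every plate.

    Returns the retained parameter list (in table column order) and a
    per-plate %CV report covering all parameters; parameters whose %CV
    is undefined on any plate (too few values, non-positive mean)
    auto-fail the screen and carry NaN in the report.
    """
    plates = list(dict.fromkeys(plate_map["plate"]))
    records = []
    retained: list[str] = []
    for param in features.columns:
        ok = True
        for plate in plates:
            try:
                cv = percent_cv(features, plate_map, param, plate, controls_only)
            except QCError:
                cv = float("nan")
                ok = False
            records.append({"plate": plate, "parameter": param, "percent_cv": cv})
            if not (np.isfinite(cv) and cv < threshold):
                ok = False
        if ok:
            retained.append(param)
    return retained, pd.DataFrame(records)


def normalize_to_control(
    features: pd.DataFrame, plate_map: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Express every value as a percentage of its plate's control mean.

    After normalization the control-well mean is exactly 100 for every
    plate and parameter.  A control mean of zero (or all-missing
    controls) leaves that plate/parameter missing with a warning.
    Missing inputs stay missing.  Applying the operation twice returns
    the once-normalized table unchanged (the control mean is already
    100).
    """
    pm = plate_map.set_index("well")
    out = features.copy().astype(float)
    control_rows = []
    for plate in dict.fromkeys(plate_map["plate"]):
        plate_wells = [w for w in pm.index[pm["plate"] == plate] if w in features.index]
        ctrl_wells = [w for w in plate_wells if pm.loc[w, "is_control"]]
        if not ctrl_wells:
            raise QCError(f"plate {plate!r} has no control wells")
        for param in features.columns:
            ctrl_mean = features.loc[ctrl_wells, param].mean(skipna=True)
            control_rows.append(
                {"plate": plate, "parameter": param, "control_mean": ctrl_mean}
            )
            if not np.isfinite(ctrl_mean) or ctrl_mean == 0:
                warnings.warn(
                    f"plate {plate!r}, parameter {param!r}: control mean "
                    f"{ctrl_mean!r}; values set missing",
                    stacklevel=2,
                )
                out.loc[plate_wells, param] = np.nan
            else:
                out.loc[plate_wells, param] = (
                    100.0 * features.loc[plate_wells, param] / ctrl_mean
                )
    return out, pd.DataFrame(control_rows)


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t-distribution closed form."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outliers(
    values: np.ndarray | list[float],
    alpha: float = 0.05,
    max_removals: int | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Iterated one-at-a-time two-sided Grubbs test.

    The most extreme value is removed whenever G = max|x - mean| / SD
    exceeds the critical value at ``alpha``, and the test repeats on
    the remainder.  Returns the retained values and the indices (into
    the original array) of removed points.  Fewer than three values, or
    zero SD, is a no-op.  At most floor(n/2) values are ever removed
    (logged if the cap is hit).
    """
    x = np.asarray(values, dtype=float)
    if max_removals is None:
        max_removals = x.size // 2
    if x.size < 3:
        warnings.warn("Grubbs test needs >= 3 values; nothing removed", stacklevel=2)
        return x.copy(), []
    idx = np.arange(x.size)
    removed: list[int] = []
    current = x.copy()
    while current.size >= 3 and len(removed) < max_removals:
        mean = current.mean()
        sd = current.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(current - mean)
        j = int(np.argmax(dev))
        g = dev[j] / sd
        if g <= grubbs_critical_value(current.size, alpha):
            break
        removed.append(int(idx[j]))
        keep = np.ones(current.size, dtype=bool)
        keep[j] = False
        current = current[keep]
        idx = idx[keep]
    if len(removed) >= max_removals:
        logger.warning("Grubbs removal cap (%d of %d) reached", max_removals, x.size)
    return current, removed
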