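"""Seeded generators for synthetic calcium recordings.

Every downstream stage of the pipeline is exercised against traces from
this module, which emulates two acquisition modes:

* plate-reader wells — one population trace per well of a 384-well
  plate, 1.67 fps for 1000 frames (a 10-minute recording) by default;
* confocal ROI sets — a frames x ROIs matrix per spheroid, 1.6 fps for
  480 frames (5 minutes) by default, in which every ROI shares one
  population event train with a per-ROI participation probability that
  controls network synchrony.

A trace is baseline (with optional linear drift) plus a sum of
transient kernels plus Gaussian noise.  The kernel is a peak-normalized
difference of exponentials ``A * (exp(-t/tau_d) - exp(-t/tau_r))``, the
simplest form with separate rise and decay time constants.  Event times
come from a Gamma renewal process (mean interval from the event rate,
CV from the jitter parameter) because real spheroid recordings
oscillate quasi-regularly rather than as a Poisson process.  With
probability ``ead_prob`` an event carries a secondary decay-phase hump
(an EAD-like event) at 40% of its parent's amplitude, launched when the
parent kernel has decayed to 50%.

Each generator records the inserted events in a ground-truth sidecar so
the detector can be validated against exactly what was simulated.
Identical configs (including seeds) give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .peaks import Trace
from .synchrony import ROITraceSet

#: Fraction of the parent amplitude carried by an EAD-like hump.
EAD_AMPLITUDE_FRACTION = 0.40
#: The hump is launched when the parent kernel has decayed to this level.
EAD_LAUNCH_FRACTION = 0.50


class ConfigError(ValueError):
    """Raised for invalid simulation configs or plate specs."""


class PresetError(KeyError):
    """Raised for unknown phenotype preset names."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one well trace.

    Rates are per minute, time constants in seconds, fluorescence in
    arbitrary units.  ``event_jitter_cv`` is the coefficient of
    variation of inter-event intervals (0 = perfectly regular train).
    """

    frame_rate_hz: float = 1.67
    n_frames: int = 1000
    baseline_f0: float = 1000.0
    baseline_drift_per_min: float = 0.0
    event_rate_per_min: float = 6.0
    event_jitter_cv: float = 0.2
    amplitude_mean: float = 1000.0
    amplitude_cv: float = 0.10
    rise_tau_s: float = 1.0
    decay_tau_s: float = 4.0
    noise_sd: float = 100.0
    ead_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ConfigError("frame_rate_hz must be > 0")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if not self.baseline_f0 > 0:
            raise ConfigError("baseline_f0 must be > 0")
        if not self.amplitude_mean > 0:
            raise ConfigError("amplitude_mean must be > 0")
        for name in ("event_rate_per_min", "event_jitter_cv", "amplitude_cv",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.rise_tau_s < self.decay_tau_s:
            raise ConfigError("need 0 < rise_tau_s < decay_tau_s")
        if not 0 <= self.ead_prob <= 1:
            raise ConfigError("ead_prob must be in [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass(frozen=True)
class RoiSimConfig:
    """Generative parameters for a confocal-style multi-ROI recording.

    ``participation_p`` is the probability that a given ROI expresses a
    given population event; it is the generator's synchrony dial.
    ``independent_rate_per_min`` adds per-ROI private events, and
    ``roi_amplitude_cv`` sets between-ROI amplitude heterogeneity.
    """

    base: SimConfig
    n_rois: int = 30
    participation_p: float = 0.9
    independent_rate_per_min: float = 1.0
    roi_amplitude_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ConfigError("n_rois must be >= 1")
        if not 0 <= self.participation_p <= 1:
            raise ConfigError("participation_p must be in [0, 1]")
        if self.independent_rate_per_min < 0 or self.roi_amplitude_cv < 0:
            raise ConfigError("rates and CVs must be >= 0")


@dataclass(frozen=True)
class SimEvent:
    """Ground truth for one inserted transient (pre-noise, on-grid)."""

    onset_s: float
    apex_index: int
    apex_time_s: float
    amplitude: float
    ead: bool


@dataclass(frozen=True)
class GroundTruth:
    """Sidecar record of what the generator inserted into one trace."""

    events: tuple[SimEvent, ...]

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events])

    @property
    def apex_times_s(self) -> np.ndarray:
        return np.array([e.apex_time_s for e in self.events])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([e.amplitude for e in self.events])

    @property
    def n_ead(self) -> int:
        return sum(1 for e in self.events if e.ead)


@dataclass(frozen=True)
class SimulatedTrace:
    trace: Trace
    truth: GroundTruth


@dataclass(frozen=True)
class RoiGroundTruth:
    """Population onsets plus, per ROI, the kept/private event splits."""

    population_onsets_s: tuple[float, ...]
    kept: tuple[tuple[int, ...], ...]        # indices of population events per ROI
    private_onsets_s: tuple[tuple[float, ...], ...]


@dataclass(frozen=True)
class SimulatedRoiSet:
    roi_set: ROITraceSet
    truth: RoiGroundTruth


@lru_cache(maxsize=64)
def _kernel_constants(rise_tau: float, decay_tau: float) -> tuple[float, float, float]:
    """(time to peak, normalization, time after onset of 50% decay)."""
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    norm = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)

    def k(t: float) -> float:
        return (math.exp(-t / decay_tau) - math.exp(-t / rise_tau)) / norm

    t_half = brentq(lambda t: k(t) - EAD_LAUNCH_FRACTION, t_peak, t_peak + 20 * decay_tau)
    return t_peak, norm, float(t_half)


def transient_kernel(t: np.ndarray, rise_tau_s: float, decay_tau_s: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel, zero for t < 0."""
    _, norm, _ = _kernel_constants(rise_tau_s, decay_tau_s)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = (np.exp(-tp / decay_tau_s) - np.exp(-tp / rise_tau_s)) / norm
    return out


def kernel_time_to_peak(rise_tau_s: float, decay_tau_s: float) -> float:
    return _kernel_constants(rise_tau_s, decay_tau_s)[0]


#: Frames required after an event's apex for it to be resolvable (half an
#: 11-frame smoothing window plus two frames); events whose apex would land
#: closer to the end of the recording are not inserted.
_APEX_MARGIN_FRAMES = 7.0

#: Fraction of the mean inter-event interval treated as refractory.
REFRACTORY_FRACTION = 0.7


def _draw_onsets(
    rng: np.random.Generator, rate_per_min: float, cv: float, t_max: float
) -> list[float]:
    """Renewal-process event onsets in [0, t_max); regular train at cv=0.

    Intervals are a refractory floor (70% of the mean interval — a
    transient cannot re-fire while the previous one is still rising)
    plus a Gamma-distributed remainder chosen so the interval mean is
    60/rate and the interval SD is cv * mean exactly.  The first event
    sits a quarter interval in (the recording phase is arbitrary), so
    a jitter-free train of rate r over duration T contains
    round(r * T / 60) events with every apex resolvable.
    """
    if rate_per_min <= 0:
        return []
    mean_iv = 60.0 / rate_per_min

    def draw() -> float:
        if cv == 0:
            return mean_iv
        floor = REFRACTORY_FRACTION * mean_iv
        rem_mean = mean_iv - floor
        sd = cv * mean_iv
        shape = (rem_mean / sd) ** 2
        return floor + float(rng.gamma(shape, sd**2 / rem_mean))

    onsets: list[float] = []
    t = 0.25 * draw()
    while t < t_max:
        onsets.append(t)
        t += draw()
    return onsets


def _draw_amplitude(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def simulate_well_trace(config: SimConfig, trace_id: str = "well") -> SimulatedTrace:
    """Simulate one well trace with its ground-truth sidecar.

    Events whose kernel apex would fall within two frames of the end of
    the recording are not inserted, so every recorded event has a
    resolvable apex.  The sidecar stores the on-grid (pre-noise) apex of
    each event's own kernel, which is exactly what a detector can
    recover in a noise-free, non-overlapping regime.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.frame_rate_hz
    times = np.arange(config.n_frames) / fs
    duration = config.duration_s
    t_peak, _, t_half = _kernel_constants(config.rise_tau_s, config.decay_tau_s)
    tail = t_peak + _APEX_MARGIN_FRAMES / fs

    clean = config.baseline_f0 * (1.0 + config.baseline_drift_per_min * times / 60.0)
    events: list[SimEvent] = []
    for onset in _draw_onsets(rng, config.event_rate_per_min, config.event_jitter_cv, duration):
        has_ead = bool(config.ead_prob > 0 and rng.random() < config.ead_prob)
        if onset + tail >= duration:
            continue
        amp = _draw_amplitude(rng, config.amplitude_mean, config.amplitude_cv)
        kern = amp * transient_kernel(times - onset, config.rise_tau_s, config.decay_tau_s)
        clean += kern
        apex_idx = int(np.argmax(kern))
        if has_ead and onset + t_half + tail < duration:
            ead_amp = EAD_AMPLITUDE_FRACTION * amp
            clean += ead_amp * transient_kernel(
                times - (onset + t_half), config.rise_tau_s, config.decay_tau_s
            )
        else:
            has_ead = False
        events.append(SimEvent(
            onset_s=float(onset),
            apex_index=apex_idx,
            apex_time_s=apex_idx / fs,
            amplitude=float(kern[apex_idx]),
            ead=has_ead,
        ))

    values = clean
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=config.n_frames)
    trace = Trace(values=values, frame_rate_hz=fs, id=trace_id)
    return SimulatedTrace(trace=trace, truth=GroundTruth(events=tuple(events)))


def simulate_roi_set(config: RoiSimConfig, spheroid_id: str = "spheroid") -> SimulatedRoiSet:
    """Simulate a frames x ROIs matrix with a shared population oscillator.

    One event train is drawn from the base config; each ROI keeps each
    population event with probability ``participation_p`` and replaces
    every non-kept event with one at an independent uniform-random
    time, so participation moves phase alignment with the population
    without changing how active a cell is.  Additional private events
    arrive at ``independent_rate_per_min``, and each ROI is scaled by
    an amplitude factor (mean 1, CV ``roi_amplitude_cv``) before
    Gaussian noise is added.
    """
    base = config.base
    rng = np.random.default_rng(base.seed)
    fs = base.frame_rate_hz
    times = np.arange(base.n_frames) / fs
    duration = base.duration_s
    t_peak, _, _ = _kernel_constants(base.rise_tau_s, base.decay_tau_s)
    tail = t_peak + _APEX_MARGIN_FRAMES / fs

    pop_onsets = [
        t for t in _draw_onsets(rng, base.event_rate_per_min, base.event_jitter_cv, duration)
        if t + tail < duration
    ]
    pop_amps = [_draw_amplitude(rng, base.amplitude_mean, base.amplitude_cv) for _ in pop_onsets]

    drift = base.baseline_f0 * (1.0 + base.baseline_drift_per_min * times / 60.0)
    columns = np.empty((base.n_frames, config.n_rois))
    kept_all: list[tuple[int, ...]] = []
    private_all: list[tuple[float, ...]] = []
    for r in range(config.n_rois):
        gain = _draw_amplitude(rng, 1.0, config.roi_amplitude_cv)
        col = drift.copy()
        kept = tuple(
            i for i in range(len(pop_onsets))
            if config.participation_p == 1.0 or rng.random() < config.participation_p
        )
        replaced = tuple(
            float(rng.uniform(0.0, duration - tail))
            for i in range(len(pop_onsets)) if i not in kept
        )
        for i in kept:
            col += gain * pop_amps[i] * transient_kernel(
                times - pop_onsets[i], base.rise_tau_s, base.decay_tau_s
            )
        private = replaced + tuple(
            t for t in _draw_onsets(rng, config.independent_rate_per_min, 1.0, duration)
            if t + tail < duration
        )
        for t in private:
            amp = _draw_amplitude(rng, base.amplitude_mean, base.amplitude_cv)
            col += gain * amp * transient_kernel(times - t, base.rise_tau_s, base.decay_tau_s)
        if base.noise_sd > 0:
            col = col + rng.normal(0.0, base.noise_sd, size=base.n_frames)
        columns[:, r] = col
        kept_all.append(kept)
        private_all.append(private)

    roi_ids = [f"ROI_{r + 1:03d}" for r in range(config.n_rois)]
    roi_set = ROITraceSet(
        data=columns, frame_rate_hz=fs, roi_ids=roi_ids, spheroid_id=spheroid_id
    )
    truth = RoiGroundTruth(
        population_onsets_s=tuple(float(t) for t in pop_onsets),
        kept=tuple(kept_all),
        private_onsets_s=tuple(private_all),
    )
    return SimulatedRoiSet(roi_set=roi_set, truth=truth)


# ---------------------------------------------------------------------------
# Phenotype presets
# ---------------------------------------------------------------------------

#: Reference well config all presets are deltas against.
_REFERENCE_WELL = SimConfig()

#: Reference confocal base config (1.6 fps, 480 frames, F in a.u.).
_REFERENCE_ROI_BASE = SimConfig(
    frame_rate_hz=1.6,
    n_frames=480,
    baseline_f0=100.0,
    event_rate_per_min=6.0,
    amplitude_mean=50.0,
    noise_sd=5.0,
)

# Each preset: overrides for the well-level SimConfig and for the
# ROI-level (participation/private-rate) parameters.  Directions encode
# the reported contrasts: the APOE4 genotype halves the event rate,
# widens transients and desynchronizes the network; chronic mu-opioid
# agonist treatment of cortical spheroids lowers count and widens peaks;
# opioid withdrawal in VTA-like spheroids raises count, lowers amplitude
# and disrupts synchrony; GABAergic-only spheroids have low-amplitude,
# poorly synchronized activity while dopaminergic ones have broad, slow
# transients.  Magnitudes are simulator choices.
_PRESETS: dict[str, tuple[dict, dict]] = {
    "PFC_wt": ({}, {"participation_p": 0.90}),
    "PFC_APOE4": (
        {"event_rate_per_min": 3.0, "decay_tau_s": 6.0},
        {"participation_p": 0.55},
    ),
    "PFC_DAMGO_chronic": (
        {"event_rate_per_min": 3.5, "decay_tau_s": 5.5},
        {"participation_p": 0.85},
    ),
    "VTA_wt": (
        {"event_rate_per_min": 4.0, "decay_tau_s": 5.0, "amplitude_mean": 930.0},
        {"participation_p": 0.85},
    ),
    "VTA_DAMGO_withdrawal": (
        {"event_rate_per_min": 6.0, "decay_tau_s": 5.0, "amplitude_mean": 630.0},
        {"participation_p": 0.55},
    ),
    "SNS_dopa": (
        {"event_rate_per_min": 4.0, "decay_tau_s": 6.0},
        {"participation_p": 0.90},
    ),
    "SNS_gluta": (
        {"event_rate_per_min": 7.0, "decay_tau_s": 3.0, "amplitude_mean": 1070.0},
        {"participation_p": 0.85},
    ),
    "SNS_gaba": (
        {"event_rate_per_min": 2.0, "decay_tau_s": 3.5, "amplitude_mean": 400.0},
        {"participation_p": 0.15, "independent_rate_per_min": 2.0},
    ),
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)


def phenotype_preset(
    name: str, kind: str = "well", seed: int | None = None
) -> SimConfig | RoiSimConfig:
    """Resolve a named phenotype preset into a full simulation config.

    ``kind`` selects the acquisition mode: ``"well"`` returns a
    :class:`SimConfig` for plate-reader traces, ``"roi"`` a
    :class:`RoiSimConfig` for confocal ROI sets.
    """
    try:
        well_over, roi_over = _PRESETS[name]
    except KeyError:
        raise PresetError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    if kind == "well":
        cfg = replace(_REFERENCE_WELL, **well_over)
        return replace(cfg, seed=seed) if seed is not None else cfg
    if kind == "roi":
        base = replace(_REFERENCE_ROI_BASE, **well_over)
        # Confocal amplitudes live on a different scale than plate-reader
        # counts; map the well-level mean onto the ROI reference scale.
        if "amplitude_mean" in well_over:
            base = replace(
                base,
                amplitude_mean=well_over["amplitude_mean"]
                * _REFERENCE_ROI_BASE.amplitude_mean
                / _REFERENCE_WELL.amplitude_mean,
            )
        if seed is not None:
            base = replace(base, seed=seed)
        return RoiSimConfig(base=base, **roi_over)
    raise ValueError(f"kind must be 'well' or 'roi', got {kind!r}")


# ---------------------------------------------------------------------------
# Whole-plate simulation
# ---------------------------------------------------------------------------

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"


def _well_sort_key(well: str) -> tuple[int, int]:
    return (_ROW_LETTERS.index(well[0]), int(well[1:]))


@dataclass(frozen=True)
class PlateSimSpec:
    """Layout for a simulated plate: well id -> (preset name, control flag)."""

    layout: dict[str, tuple[str, bool]]
    n_rows: int = 16
    n_cols: int = 24
    seed: int = 0
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        if not self.layout:
            raise ConfigError("plate layout is empty")
        seen = set()
        for well, (preset, _flag) in self.layout.items():
            if well in seen:
                raise ConfigError(f"duplicate well id {well!r}")
            seen.add(well)
            if (
                len(well) < 2
                or well[0] not in _ROW_LETTERS[: self.n_rows]
                or not well[1:].isdigit()
                or not 1 <= int(well[1:]) <= self.n_cols
            ):
                raise ConfigError(
                    f"well id {well!r} outside a {self.n_rows}x{self.n_cols} plate"
                )
            if preset not in _PRESETS:
                raise PresetError(
                    f"unknown preset {preset!r} for well {well}; "
                    f"valid presets: {', '.join(PRESET_NAMES)}"
                )
        if not any(flag for _p, flag in self.layout.values()):
            raise ConfigError("plate needs at least one control well")


def layout_from_lists(
    assignments: list[tuple[str, str, bool]]
) -> dict[str, tuple[str, bool]]:
    """Build a layout mapping from (well, preset, is_control) rows."""
    layout: dict[str, tuple[str, bool]] = {}
    for well, preset, flag in assignments:
        if well in layout:
            raise ConfigError(f"duplicate well id {well!r}")
        layout[well] = (preset, bool(flag))
    return layout


def simulate_plate(
    spec: PlateSimSpec,
) -> tuple[list[SimulatedTrace], pd.DataFrame]:
    """Simulate every mapped well of a plate.

    Per-well seeds are drawn deterministically from the plate seed in
    well-sorted order, so the same spec always produces the same traces.
    Returns the simulated traces and a plate map with columns
    (well, group, is_control, plate).
    """
    rng = np.random.default_rng(spec.seed)
    wells = sorted(spec.layout, key=_well_sort_key)
    traces: list[SimulatedTrace] = []
    rows = []
    for well in wells:
        preset, is_control = spec.layout[well]
        well_seed = int(rng.integers(0, 2**31 - 1))
        cfg = phenotype_preset(preset, kind="well", seed=well_seed)
        traces.append(simulate_well_trace(cfg, trace_id=well))
        rows.append({
            "well": well,
            "group": preset,
            "is_control": bool(is_control),
            "plate": spec.plate_id,
        })
    plate_map = pd.DataFrame(rows)
    return traces, plate_map
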