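"""Shared fixtures: all test data is generated, nothing is stored."""

import numpy as np
import pandas as pd
import pytest

import spherocal as sc
from spherocal import simulate as sim

ROWS = "ABCDEFGHIJKLMNOP"


@pytest.fixture(scope="session")
def clean_train():
    """Noise-free, non-overlapping transient train with ground truth."""
    cfg = sc.SimConfig(
        event_rate_per_min=2.0, event_jitter_cv=0.2, noise_sd=0.0,
        decay_tau_s=3.0, ead_prob=0.0, seed=7,
    )
    return sim.simulate_well_trace(cfg)


@pytest.fixture(scope="session")
def regular_train():
    """Perfectly regular noise-free train, period 12 s, over 10 minutes.

    The 2 Hz frame rate makes the period an exact number of frames, so
    apex spacing carries no grid-quantization jitter.
    """
    cfg = sc.SimConfig(
        frame_rate_hz=2.0, n_frames=1200,
        event_rate_per_min=5.0, event_jitter_cv=0.0, noise_sd=0.0,
        amplitude_cv=0.0, decay_tau_s=3.0, seed=1,
    )
    return sim.simulate_well_trace(cfg)


def make_triangle(baseline=100.0, amplitude=10000.0, base_width=8.0,
                  fs=50.0, total_s=40.0):
    """Symmetric triangular test peak on a flat baseline."""
    n = int(total_s * fs)
    t = np.arange(n) / fs
    v = np.full(n, baseline)
    apex_t = total_s / 2
    half = base_width / 2
    rising = (t >= apex_t - half) & (t <= apex_t)
    falling = (t > apex_t) & (t <= apex_t + half)
    v[rising] += amplitude * (t[rising] - (apex_t - half)) / half
    v[falling] += amplitude * ((apex_t + half) - t[falling]) / half
    return sc.Trace(v, fs, id="triangle")


def make_roi_set(seed=0, n_rois=30, participation_p=0.8, noise_sd=5.0,
                 independent_rate=1.0, roi_amplitude_cv=0.3, n_frames=480):
    base = sc.SimConfig(
        frame_rate_hz=1.6, n_frames=n_frames, baseline_f0=100.0,
        amplitude_mean=50.0, noise_sd=noise_sd, seed=seed,
    )
    cfg = sc.RoiSimConfig(
        base=base, n_rois=n_rois, participation_p=participation_p,
        independent_rate_per_min=independent_rate,
        roi_amplitude_cv=roi_amplitude_cv,
    )
    return sim.simulate_roi_set(cfg)


def two_group_layout(preset_a, preset_b, n_per_group, control=None):
    control = control or preset_a
    assignments = []
    i = 0
    for preset in (preset_a, preset_b):
        for _ in range(n_per_group):
            well = f"{ROWS[i // 24]}{i % 24 + 1}"
            assignments.append((well, preset, preset == control))
            i += 1
    return sim.layout_from_lists(assignments)


def extract_plate_features(traces):
    rows = [
        {"well": s.trace.id, **sc.analyze_trace(s.trace).to_dict()}
        for s in traces
    ]
    return pd.DataFrame(rows).set_index("well")


@pytest.fixture(scope="session")
def small_two_group_plate():
    """16 + 16 wells of the wild-type/APOE4 contrast, with features."""
    spec = sim.PlateSimSpec(
        layout=two_group_layout("PFC_wt", "PFC_APOE4", 16), seed=11
    )
    traces, plate_map = sim.simulate_plate(spec)
    features = extract_plate_features(traces)
    return traces, plate_map, features
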