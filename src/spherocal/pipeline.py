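"""End-to-end orchestration: simulate -> extract -> qc -> classify -> radar.

A :class:`RunConfig` (usually loaded from YAML) names the stages to run
and carries every stage parameter plus a global seed.  Each run writes
its artifacts into one output directory together with a provenance
record (resolved config, its hash, and the seed), and a re-run with the
same config overwrites the artifacts identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import io as _io
from . import plateqc as _qc
from . import simulate as _sim
from . import synchrony as _syn
from .peaks import DetectorParams, analyze_trace

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "qc", "classify", "radar", "synchrony")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its input."""


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    stages: list[str] = field(default_factory=lambda: ["simulate", "extract", "qc", "classify", "radar"])
    out_dir: str = "spherocal_run"
    seed: int = 0
    # simulate
    plate_layout: list = field(default_factory=list)   # [well, preset, is_control]
    # extract
    traces_path: str | None = None
    search_vector_length: int = 11
    trigger_fraction: float = 0.10
    dynamic_threshold_k: float = 3.0
    # qc
    cv_threshold: float = 30.0
    grubbs_alpha: float = 0.05
    map_path: str | None = None
    # classify
    variance_target: float = 0.85
    train_frac: float = 0.80
    balance_alpha: float = 0.05
    n_estimators: int = 500
    # synchrony
    roi_path: str | None = None
    snr_threshold: float = 3.0
    subsample_k: int = 12
    subsample_tolerance: float = 0.05

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in STAGES:
                raise PipelineError(f"unknown stage {stage!r}; valid: {STAGES}")
        if "simulate" in self.stages and not self.plate_layout:
            raise PipelineError("stage 'simulate': plate_layout is empty")
        if "extract" in self.stages and "simulate" not in self.stages and not self.traces_path:
            raise PipelineError("stage 'extract': traces_path required when not simulating")
        if ("qc" in self.stages or "classify" in self.stages or "radar" in self.stages) \
                and "simulate" not in self.stages and not self.map_path:
            raise PipelineError("stages qc/classify/radar need map_path when not simulating")
        if "synchrony" in self.stages and not self.roi_path:
            raise PipelineError("stage 'synchrony': roi_path required")
        if not 0 < self.train_frac < 1:
            raise PipelineError("train_frac must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the selected stages in order and return artifact paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    detector = DetectorParams(
        search_vector_length=config.search_vector_length,
        trigger_fraction=config.trigger_fraction,
        dynamic_threshold_k=config.dynamic_threshold_k,
    )

    traces = None
    plate_map = None
    features = None
    normalized = None
    retained = None

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                layout = _sim.layout_from_lists(
                    [(w, p, bool(c)) for w, p, c in config.plate_layout]
                )
                spec = _sim.PlateSimSpec(layout=layout, seed=config.seed)
                sim_traces, plate_map = _sim.simulate_plate(spec)
                paths = _io.write_simulated_plate(out, sim_traces, plate_map)
                artifacts.update(paths)
                traces = [s.trace for s in sim_traces]

            elif stage == "extract":
                if traces is None:
                    traces = _io.read_traces(config.traces_path)
                rows = []
                for tr in traces:
                    feats = analyze_trace(tr, detector)
                    rows.append({"well": tr.id, **feats.to_dict()})
                features = pd.DataFrame(rows).set_index("well")
                path = out / "features_raw.csv"
                _io.write_features(path, features)
                artifacts["features_raw"] = path

            elif stage == "qc":
                if plate_map is None:
                    plate_map = _io.read_plate_map(config.map_path)
                if features is None:
                    raise PipelineError("stage 'qc': no feature table (run extract first)")
                retained, cv_report = _qc.cv_filter(
                    features, plate_map, threshold=config.cv_threshold
                )
                normalized, control_means = _qc.normalize_to_control(
                    features[retained], plate_map
                )
                cv_path = out / "qc_cv_report.csv"
                cv_report.to_csv(cv_path, index=False)
                norm_path = out / "features_normalized.csv"
                _io.write_features(norm_path, normalized)
                (out / "qc_retained.json").write_text(json.dumps(retained, indent=1))
                artifacts["cv_report"] = cv_path
                artifacts["features_normalized"] = norm_path

            elif stage == "classify":
                if plate_map is None:
                    plate_map = _io.read_plate_map(config.map_path)
                table = normalized if normalized is not None else features
                if table is None:
                    raise PipelineError("stage 'classify': no feature table")
                pca = _classify.run_pca(table, config.variance_target)
                labels = plate_map.set_index("well").loc[pca.scores.index, "group"]
                split = _classify.balanced_split(
                    pca.scores, labels,
                    train_frac=config.train_frac,
                    alpha=config.balance_alpha,
                    seed=config.seed,
                )
                report = _classify.train_and_classify(
                    pca.scores, labels, split,
                    n_estimators=config.n_estimators, seed=config.seed,
                )
                scores_path = out / "pca_scores.csv"
                pca.scores.to_csv(scores_path, float_format="%.17g")
                conf_path = out / "confusion_matrix_pct.csv"
                report.confusion_pct.round(1).to_csv(conf_path)
                summary = {
                    "n_components": pca.n_components,
                    "explained_variance": [float(v) for v in pca.explained_variance_ratio],
                    "split_attempts": split.attempts,
                    "feature_pvalues": split.feature_pvalues,
                    "class_pvalues": split.class_pvalues,
                    "overall_accuracy": report.overall_accuracy,
                    "per_class_accuracy": report.per_class_accuracy,
                }
                (out / "classification_report.json").write_text(
                    json.dumps(summary, indent=1)
                )
                artifacts["pca_scores"] = scores_path
                artifacts["confusion_matrix"] = conf_path

            elif stage == "radar":
                if normalized is None:
                    raise PipelineError("stage 'radar': needs the qc stage output")
                radar = _classify.radar_summary(normalized, plate_map)
                path = out / "radar_summary.csv"
                radar.to_csv(path, index_label="group", float_format="%.17g")
                artifacts["radar_summary"] = path

            elif stage == "synchrony":
                roi_set = _io.read_roi_set(config.roi_path)
                norm = _syn.normalize_f_over_f0(roi_set)
                active, snr_report = _syn.filter_active_rois(norm, config.snr_threshold)
                cm = _syn.correlation_matrix(active)
                score = _syn.synchrony_score(cm)
                sub = _syn.subsample_rois(
                    active, cm, k=config.subsample_k,
                    tolerance=config.subsample_tolerance, seed=config.seed,
                )
                table, summary = _syn.roi_feature_table(sub.roi_set, score, detector)
                cm_path = out / "correlation_matrix.csv"
                _io.write_correlation_matrix(cm_path, cm)
                table_path = out / "roi_features.csv"
                table.to_csv(table_path, float_format="%.17g")
                trace_path = out / "mean_trace_ci.csv"
                _syn.mean_trace_with_ci(active).to_csv(
                    trace_path, index=False, float_format="%.17g"
                )
                snr_report.to_csv(out / "roi_snr_report.csv", index=False)
                (out / "synchrony_report.json").write_text(json.dumps({
                    "score": score.score,
                    "n_rois": score.n_rois,
                    "subsample_attempts": sub.attempts,
                    "subsample_score": sub.score,
                    "summary": summary,
                }, indent=1))
                artifacts["correlation_matrix"] = cm_path
                artifacts["roi_features"] = table_path

        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover - structured failure path
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": list(config.stages),
    }
    (out / "run_config.yaml").write_text(config.to_yaml())
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return artifacts
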