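"""End-to-end pipeline: generate → preprocess → analyze → classify → report.

A :class:`PipelineConfig` (YAML-serializable) fully determines one run;
every stochastic stage is seeded from the master seed, so two runs with the
same config produce byte-identical report files and an identical manifest
hash.  Stages communicate through files inside the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import spectral, workload
from .classify import cca_accuracy, cnn_crossval_accuracy, sweep_segment_length
from .cnn import CompactCNNSpec
from .preprocess import apply_filter_chain, average_trials
from .synth_eeg import ResponseModel, SessionLayout, generate_session

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on."""

    master_seed: int = 7
    out_dir: str = "ssmvep_out"
    # scaled-down session defaults: full study structure is 10 subjects x
    # 3 brightness levels x 20 trials and takes far longer to synthesize
    n_subjects: int = 2
    trials_per_run: int = 6
    brightness_levels: tuple = ("medium",)
    paradigms: tuple = ("bimodal", "single_motion", "single_color")
    stages: tuple = ("spectral", "workload", "classify")
    classifier_methods: tuple = ("cca",)
    segment_lengths_s: tuple = (0.5, 1.0, 2.0)
    n_folds: int = 3
    decimate: int = 4
    n_harmonics: int = 4
    band_drift_slopes: dict = field(default_factory=lambda: {
        "theta": 0.1, "alpha": 0.0, "beta": 0.0})

    def layout(self) -> SessionLayout:
        return SessionLayout(n_subjects=self.n_subjects,
                             trials_per_run=self.trials_per_run,
                             brightness_levels=tuple(self.brightness_levels))

    def model(self) -> ResponseModel:
        return ResponseModel(band_drift_slopes=dict(self.band_drift_slopes))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("brightness_levels", "paradigms", "stages",
                    "classifier_methods", "segment_lengths_s"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dict.

    Emits per-stage CSV/JSON reports plus ``manifest.json`` holding the
    config hash, package versions and a content hash of every output file.
    Any stage failure aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = config.layout()
    model = config.model()
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(
                f"stage '{name}' failed (config {config.content_hash()}): {exc}"
            ) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", name, timings[name])

    state: dict = {}

    def _generate():
        state["session"] = generate_session(layout, model, config.master_seed,
                                            paradigms=config.paradigms)

    _run_stage("generate", _generate)
    session = state["session"]

    if "spectral" in config.stages:
        def _spectral():
            filtered = apply_filter_chain(session, "fft_2_40")
            rows = []
            for paradigm in config.paradigms:
                sub = filtered.select(paradigm=paradigm)
                for f in layout.frequencies_hz:
                    sel = sub.select(frequency_hz=f)
                    avg = average_trials(sel)
                    spec = spectral.fft_amplitude_spectrum(avg, layout.sampling_rate_hz)
                    peak_f, peak_amp = spectral.find_peak(spec, f)
                    psd = spectral.welch_psd(sel.data, layout.sampling_rate_hz)
                    snr = spectral.compute_snr(
                        spectral.SpectrumResult(psd.freqs_hz,
                                                np.asarray(psd.values).mean(axis=(0, 1)),
                                                "welch_psd"),
                        f, n_harmonics=config.n_harmonics)
                    rows.append({"paradigm": paradigm, "frequency_hz": f,
                                 "peak_hz": peak_f, "peak_amplitude_uV": peak_amp,
                                 "snr_db": snr.snr_db})
            pd.DataFrame(rows).to_csv(out / "spectral_summary.csv", index=False)
            outputs["spectral_summary.csv"] = ""

        _run_stage("spectral", _spectral)

    if "workload" in config.stages:
        def _workload():
            filtered = apply_filter_chain(session, "avg_1_30")
            series = workload.bandpowers(filtered)
            report = workload.fatigue_report(series)
            series.to_csv(out / "bandpowers.csv", index=False)
            report["trends"].to_csv(out / "fatigue_trends.csv", index=False)
            report["paradigm_means"].to_csv(out / "fatigue_paradigm_means.csv",
                                            index=False)
            outputs.update({"bandpowers.csv": "", "fatigue_trends.csv": "",
                            "fatigue_paradigm_means.csv": ""})

        _run_stage("workload", _workload)

    if "classify" in config.stages:
        def _classify():
            rows = []
            for paradigm in config.paradigms:
                sub = session.select(paradigm=paradigm)
                for method in config.classifier_methods:
                    sweep = sweep_segment_length(
                        sub, config.segment_lengths_s, method=method,
                        seed=config.master_seed, n_folds=config.n_folds,
                        decimate=config.decimate)
                    for _, row in sweep.iterrows():
                        rows.append({"paradigm": paradigm, "method": method,
                                     "length_s": row["length_s"],
                                     "accuracy": row["accuracy"], "sd": row["sd"]})
            pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)
            outputs["classification.csv"] = ""

        _run_stage("classify", _classify)

    for name in outputs:
        outputs[name] = _file_hash(out / name)
    manifest = {
        "config_hash": config.content_hash(),
        "config": dataclasses.asdict(config),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=2)
    return manifest
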