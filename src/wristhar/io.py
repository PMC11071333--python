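"""CSV and configuration I/O.

Recordings travel as plain CSV with columns ``t, ax, ay, az, gx, gy, gz,
label`` (one row per sample, header mandatory; acceleration in g, angular
velocity in deg/s; ``label`` in {0,1,2,3} and omitted for unlabelled
data). Generator and pipeline settings are read from a YAML or JSON
mapping validated against a flat schema; unknown keys are rejected with a
field-level message so typos fail loudly instead of silently falling back
to defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bpnn import TrainConfig
from .pipeline import DecodedSequence, PipelineConfig
from .preprocess import CHANNEL_NAMES, ImuRecording, WindowSpec
from .simulate import Activity, ActivityModel, GeneratorConfig, default_activity_models

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_decoded_csv",
    "load_run_config",
    "RunConfig",
]

_CSV_COLUMNS = ("t", *CHANNEL_NAMES, "label")


def write_recording_csv(recording: ImuRecording, path: str | Path) -> None:
    """Write one recording as CSV (`t, ax..gz[, label]`)."""
    data = {"t": recording.times}
    for i, name in enumerate(CHANNEL_NAMES):
        data[name] = recording.samples[:, i]
    if recording.labels is not None:
        data["label"] = recording.labels
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")


def read_recording_csv(path: str | Path, sample_rate_hz: float | None = None) -> ImuRecording:
    """Read a recording CSV; the sample rate is inferred from the ``t``
    column unless given explicitly."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in ("t", *CHANNEL_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("t", *CHANNEL_NAMES):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[["t", *CHANNEL_NAMES]].isna().any().any():
        col = df[["t", *CHANNEL_NAMES]].isna().any().idxmax()
        raise ValueError(f"{path}: missing value in column {col!r}")
    if sample_rate_hz is None:
        t = df["t"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer sample rate from one sample")
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise ValueError(f"{path}: non-increasing timestamps")
        sample_rate_hz = 1.0 / dt
    labels = None
    if "label" in df.columns:
        lab = pd.to_numeric(df["label"], errors="coerce")
        if lab.isna().any():
            line = int(lab.isna().idxmax()) + 2
            raise ValueError(f"{path}: non-integer label at line {line}")
        labels = lab.to_numpy(dtype=int)
    return ImuRecording(
        float(sample_rate_hz),
        df[list(CHANNEL_NAMES)].to_numpy(dtype=float),
        labels,
        subject_id=path.stem,
    )


def write_decoded_csv(decoded: DecodedSequence, path: str | Path) -> None:
    """Export a decoded sequence (`window_start, raw_label, smoothed_label[, truth]`)."""
    data = {
        "window_start": decoded.window_starts,
        "raw_label": decoded.raw_labels,
        "smoothed_label": decoded.smoothed_labels,
    }
    if decoded.truth_labels is not None:
        data["truth"] = decoded.truth_labels
    pd.DataFrame(data).to_csv(path, index=False)


# --- configuration -----------------------------------------------------

_GENERATOR_KEYS = {
    "sample_rate_hz": float,
    "n_sequences": int,
    "sequence_length_s": float,
    "dwell_range_s": list,
    "switch_matrix": list,
    "seed": int,
    "noise_scale": float,
}
_PIPELINE_KEYS = {
    "window_length": int,
    "window_step": int,
    "filter_width": int,
    "smoothing_mode": str,
    "pseudocount": float,
    "min_run": int,
    "learning_rate": float,
    "epochs": int,
    "batch_size": int,
    "hidden_sizes": list,
    "init_scale": float,
}


class RunConfig:
    """Validated generator + pipeline settings for one CLI run."""

    def __init__(self, generator: GeneratorConfig, pipeline: PipelineConfig):
        self.generator = generator
        self.pipeline = pipeline


def _check_section(name: str, section: dict, schema: dict) -> None:
    unknown = set(section) - set(schema)
    if unknown:
        raise ValueError(
            f"config section {name!r}: unknown key(s) {sorted(unknown)}; "
            f"allowed: {sorted(schema)}"
        )
    for key, val in section.items():
        want = schema[key]
        if want in (int, float) and isinstance(val, bool):
            raise ValueError(f"config {name}.{key}: expected a number, got a boolean")
        if want is float and isinstance(val, int):
            continue
        if not isinstance(val, want):
            raise ValueError(
                f"config {name}.{key}: expected {want.__name__}, got "
                f"{type(val).__name__}"
            )


def load_run_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    The file holds two optional mappings, ``generator`` and ``pipeline``;
    missing keys take the packaged defaults. ``generator.seed`` is
    mandatory unless overridden by the ``seed`` argument (reproducible
    benchmarks need an explicit seed).
    """
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"{path}: invalid YAML{where}: {exc}") from exc
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"generator", "pipeline"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    gen_raw = dict(raw.get("generator") or {})
    pipe_raw = dict(raw.get("pipeline") or {})
    _check_section("generator", gen_raw, _GENERATOR_KEYS)
    _check_section("pipeline", pipe_raw, _PIPELINE_KEYS)

    if seed is not None:
        gen_raw["seed"] = seed
    if "seed" not in gen_raw:
        raise ValueError(
            f"{path}: generator.seed is required (or pass --seed) so runs "
            f"are reproducible"
        )
    noise_scale = gen_raw.pop("noise_scale", None)
    if "dwell_range_s" in gen_raw:
        gen_raw["dwell_range_s"] = tuple(gen_raw["dwell_range_s"])
    if "switch_matrix" in gen_raw:
        gen_raw["switch_matrix"] = np.asarray(gen_raw["switch_matrix"], dtype=float)
    if noise_scale is not None:
        from dataclasses import replace as _replace

        models = {
            act: _replace(m, noise_sd=tuple(noise_scale * s for s in m.noise_sd))
            for act, m in default_activity_models().items()
        }
        gen_raw["activity_models"] = models
    generator = GeneratorConfig(**gen_raw)

    window = WindowSpec(
        pipe_raw.pop("window_length", 50), pipe_raw.pop("window_step", 10)
    )
    train_kwargs = {}
    for key, dest in (
        ("learning_rate", "learning_rate"),
        ("epochs", "epochs"),
        ("batch_size", "batch_size"),
        ("init_scale", "init_scale"),
    ):
        if key in pipe_raw:
            train_kwargs[dest] = pipe_raw.pop(key)
    if "hidden_sizes" in pipe_raw:
        train_kwargs["hidden_sizes"] = tuple(pipe_raw.pop("hidden_sizes"))
    defaults = PipelineConfig()
    base = defaults.train
    train = TrainConfig(
        learning_rate=train_kwargs.get("learning_rate", base.learning_rate),
        epochs=train_kwargs.get("epochs", base.epochs),
        batch_size=train_kwargs.get("batch_size", base.batch_size),
        seed=generator.seed,
        init_scale=train_kwargs.get("init_scale", base.init_scale),
        hidden_sizes=train_kwargs.get("hidden_sizes", base.hidden_sizes),
    )
    pipeline = PipelineConfig(
        window=window,
        filter_width=pipe_raw.pop("filter_width", defaults.filter_width),
        train=train,
        smoothing_mode=pipe_raw.pop("smoothing_mode", defaults.smoothing_mode),
        pseudocount=pipe_raw.pop("pseudocount", defaults.pseudocount),
        min_run=pipe_raw.pop("min_run", defaults.min_run),
    )
    return RunConfig(generator, pipeline)
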