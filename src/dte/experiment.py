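"""Experiment orchestration: the full compare-and-calibrate workflow.

One experiment generates (or loads) a subject-disjoint train/validation/
test dataset, trains the window-size ensemble, and evaluates four method
variants on identical test windows framed at the largest window size w1:

* ``baseline`` — the single learner trained at w1 (the ensemble's first
  member, which by the reduction law equals a separately trained learner
  with the same seed);
* ``baseline_ts`` — the baseline after temperature scaling fitted on the
  validation split;
* ``standard_ensemble`` — same-window ensemble with seed-only diversity;
* ``dte`` — the window-size ensemble with nested sub-window averaging;
* ``dte_ts`` — DTE after temperature scaling on surrogate log-probability
  scores.

Each variant is scored with accuracy, macro F1, weighted F1 and ECE;
repeated runs (different master seeds) are summarised as mean +/- sd.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import (
    LOG_EPS,
    apply_temperature,
    fit_temperature,
    temperature_for_ensemble,
)
from .ensemble import DeepTimeEnsemble, EnsembleResults, StandardEnsemble
from .errors import ConfigError
from .learners import LearnerConfig
from .metrics import evaluate_predictions
from .series import MultichannelSeries, read_series_csv, write_series_csv
from .synthgen import (
    ProtocolTemplate,
    default_activity_specs,
    default_class_weights,
    generate_dataset,
)
from .windowing import WindowSizeSet, build_window_set, extract_all

__all__ = [
    "ExperimentConfig",
    "load_config",
    "simulate_dataset",
    "run_repeat",
    "run_experiment",
    "summarize_runs",
]

VARIANTS = ("baseline", "baseline_ts", "standard_ensemble", "dte", "dte_ts")
METRIC_NAMES = ("accuracy", "f1_macro", "f1_weighted", "ece")


@dataclass
class ExperimentConfig:
    """Resolved settings for one experiment.

    Defaults are the package's reference synthetic study: 10 subjects,
    six activity classes of heterogeneous periodicity with imbalanced
    frequencies, a five-size window set built by uniform 0.5 s stepping
    around a 3 s centre, and the small convolutional learner.
    """

    # data source: synthetic unless explicit split files are given
    train_file: str | None = None
    val_file: str | None = None
    test_file: str | None = None
    n_subjects: int = 10
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_segments: int = 24
    segment_seconds: float = 10.0
    sampling_rate: float = 20.0
    n_channels: int = 3
    class_weights: tuple[float, ...] | None = None

    # window-size set: explicit list wins over (center, count, step)
    window_sizes: tuple[float, ...] | None = None
    window_center: float = 3.0
    window_count: int = 5
    window_step: float = 0.5

    # extraction steps
    train_step_seconds: float = 1.0
    test_step_seconds: float = 0.5

    learner: LearnerConfig = field(default_factory=LearnerConfig)
    n_bins: int = 10
    repeats: int = 1
    seed: int = 0
    output_dir: str = "results"

    def window_set(self) -> WindowSizeSet:
        if self.window_sizes is not None:
            return WindowSizeSet(tuple(self.window_sizes))
        return build_window_set(
            self.window_center, self.window_count, self.window_step
        )

    def validate(self) -> None:
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")
        sizes = self.window_set()
        session = self.n_segments * self.segment_seconds
        if sizes.largest > session:
            raise ConfigError(
                f"largest window ({sizes.largest} s) exceeds the session "
                f"length ({session} s)"
            )
        files = [self.train_file, self.val_file, self.test_file]
        if any(files) and not all(files):
            raise ConfigError(
                "either all of train/val/test files or none must be given"
            )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["learner"] = dataclasses.asdict(self.learner)
        out["resolved_window_sizes"] = list(self.window_set())
        return out


def load_config(path) -> ExperimentConfig:
    """Build a config from a YAML mapping; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    learner_raw = raw.pop("learner", {})
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        learner = LearnerConfig(**learner_raw)
        for key in ("split", "class_weights", "window_sizes"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        config = ExperimentConfig(learner=learner, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    config.validate()
    return config


def _synthetic_splits(config: ExperimentConfig, seed: int):
    specs = default_activity_specs()
    weights = (
        np.asarray(config.class_weights)
        if config.class_weights is not None
        else default_class_weights()
    )
    template = ProtocolTemplate(
        n_segments=config.n_segments,
        segment_seconds=config.segment_seconds,
        sampling_rate=config.sampling_rate,
        n_channels=config.n_channels,
    )
    return generate_dataset(
        n_subjects=config.n_subjects,
        specs=specs,
        protocol_template=template,
        class_weights=weights,
        split=config.split,
        seed=seed,
    )


def get_splits(config: ExperimentConfig, seed: int):
    """Load the three splits from files, or synthesize them."""
    if config.train_file:
        return (
            read_series_csv(config.train_file),
            read_series_csv(config.val_file),
            read_series_csv(config.test_file),
        )
    return _synthetic_splits(config, seed)


def simulate_dataset(config: ExperimentConfig, out_dir) -> dict:
    """Generate and persist train/val/test series files plus a manifest."""
    if config.split[1] <= 0:
        raise ConfigError(
            "validation fraction must be > 0 (temperature scaling needs "
            "validation data)"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, val, test = _synthetic_splits(config, config.seed)
    paths = {}
    for name, series in (("train", train), ("val", val), ("test", test)):
        path = out / f"{name}.csv"
        write_series_csv(series, path)
        paths[name] = str(path)
    manifest = {
        "config": config.to_dict(),
        "files": paths,
        "subjects": {
            name: [s.subject_id for s in series]
            for name, series in (("train", train), ("val", val), ("test", test))
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _single_member_view(fitted: EnsembleResults, index: int) -> EnsembleResults:
    """A one-member ensemble sharing a fitted member's learner."""
    member = fitted.members[index]
    return EnsembleResults(
        [(member.window_seconds, member.learner)],
        sampling_rate=fitted.sampling_rate,
    )


def run_repeat(
    train: list[MultichannelSeries],
    val: list[MultichannelSeries],
    test: list[MultichannelSeries],
    config: ExperimentConfig,
    seed: int,
    include_standard_ensemble: bool = True,
) -> dict:
    """Train and evaluate all method variants for one master seed.

    Returns a dict with per-variant metric dicts and calibration reports,
    per-member test metrics, the fitted temperatures, and the per-example
    predictions needed for persistence.
    """
    window_set = config.window_set()
    step_rule = ("seconds", config.train_step_seconds)
    test_step = ("seconds", config.test_step_seconds)
    n_classes = len(default_activity_specs()) if not config.train_file else None
    if config.train_file:
        # infer K from the labels present across all splits
        all_labels = np.concatenate(
            [s.labels for coll in (train, val, test) for s in coll]
        )
        n_classes = int(all_labels.max()) + 1

    dte_model = DeepTimeEnsemble(
        train,
        window_set,
        config.learner,
        step_rule=step_rule,
        n_classes=n_classes,
    )
    fitted = dte_model.fit(seed=seed)

    test_result, test_labels = fitted.predict_series(test, test_step)
    val_result, val_labels = fitted.predict_series(val, test_step)

    out: dict = {
        "seed": seed,
        "metrics": {},
        "reports": {},
        "predictions": {},
        "labels": test_labels,
        "temperatures": {},
        "members": [],
    }

    def record(name: str, probs: np.ndarray) -> None:
        metrics, report = evaluate_predictions(
            probs, test_labels, n_bins=config.n_bins
        )
        out["metrics"][name] = metrics
        out["reports"][name] = report
        out["predictions"][name] = probs

    # DTE and its per-member diagnostics
    record("dte", test_result.probabilities)
    for j in range(fitted.n_members):
        member_metrics, _ = evaluate_predictions(
            test_result.per_member_probabilities[j],
            test_labels,
            n_bins=config.n_bins,
        )
        member_metrics["window_seconds"] = fitted.members[j].window_seconds
        out["members"].append(member_metrics)

    # baseline: the single learner at w1 (identical windows and labels)
    record("baseline", test_result.per_member_probabilities[0])

    # temperature scaling on the baseline, fitted on validation windows
    w1 = fitted.members[0].window_seconds
    val_table = extract_all(val, WindowSizeSet((w1,)), test_step)
    val_scores = fitted.members[0].learner.predict_scores(val_table[w1].values)
    temp_base = fit_temperature(val_scores, val_table[w1].labels)
    test_scores = fitted.members[0].learner.predict_scores(
        extract_all(test, WindowSizeSet((w1,)), test_step)[w1].values
    )
    record("baseline_ts", apply_temperature(test_scores, temp_base.temperature))
    out["temperatures"]["baseline"] = temp_base

    # temperature scaling on DTE via surrogate log-probability scores
    temp_dte = temperature_for_ensemble(val_result.probabilities, val_labels)
    record(
        "dte_ts",
        apply_temperature(
            np.log(test_result.probabilities + LOG_EPS), temp_dte.temperature
        ),
    )
    out["temperatures"]["dte"] = temp_dte

    if include_standard_ensemble:
        std_model = StandardEnsemble(
            train,
            fixed_window_seconds=w1,
            n_members=fitted.n_members,
            learner_config=config.learner,
            step_rule=step_rule,
            n_classes=n_classes,
        )
        std = std_model.fit(seed=seed)
        std_result, std_labels = std.predict_series(test, test_step)
        assert np.array_equal(std_labels, test_labels)
        record("standard_ensemble", std_result.probabilities)

    return out


def summarize_runs(runs: list[dict]) -> dict:
    """Mean and standard deviation of every metric across repeated runs."""
    summary: dict = {"n_runs": len(runs), "variants": {}}
    variant_names = runs[0]["metrics"].keys()
    for name in variant_names:
        summary["variants"][name] = {}
        for metric in METRIC_NAMES:
            values = np.array([r["metrics"][name][metric] for r in runs])
            summary["variants"][name][metric] = {
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            }
    member_count = len(runs[0]["members"])
    summary["members"] = []
    for j in range(member_count):
        entry = {"window_seconds": runs[0]["members"][j]["window_seconds"]}
        for metric in METRIC_NAMES:
            values = np.array([r["members"][j][metric] for r in runs])
            entry[metric] = {
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            }
        summary["members"].append(entry)
    summary["temperatures"] = {
        key: {
            "mean": float(
                np.mean([r["temperatures"][key].temperature for r in runs])
            )
        }
        for key in runs[0]["temperatures"]
    }
    return summary


def run_experiment(config: ExperimentConfig, progress=None) -> dict:
    """Run all repeats, persist per-run and summary artifacts, return summary.

    Output layout under ``config.output_dir``::

        manifest.json              resolved config echo
        run_<r>/metrics.json       per-variant metrics for repeat r
        run_<r>/<variant>.csv      per-example predictions
        run_<r>/<variant>_calibration.json
        summary.json               mean +/- sd over repeats
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs = []
    for r in range(config.repeats):
        seed = config.seed + 1000 * r
        if progress:
            progress(f"repeat {r + 1}/{config.repeats} (seed {seed})")
        train, val, test = get_splits(config, seed)
        result = run_repeat(train, val, test, config, seed)
        runs.append(result)

        run_dir = out / f"run_{r}"
        run_dir.mkdir(exist_ok=True)
        with open(run_dir / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": seed,
                    "metrics": result["metrics"],
                    "members": result["members"],
                    "temperatures": {
                        k: v.temperature
                        for k, v in result["temperatures"].items()
                    },
                },
                fh,
                indent=2,
            )
        for name, probs in result["predictions"].items():
            from .ensemble import PredictionResult

            pred = PredictionResult(
                probabilities=probs,
                predicted_labels=np.argmax(probs, axis=1),
            )
            pred.to_frame(result["labels"]).to_csv(
                run_dir / f"{name}.csv", index=False
            )
            result["reports"][name].to_json(
                run_dir / f"{name}_calibration.json"
            )

    summary = summarize_runs(runs)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"config": config.to_dict()}, fh, indent=2)
    return summary
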