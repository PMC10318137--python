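"""Configuration, file IO and the end-to-end pipeline runner.

The pipeline composes simulate -> featurize (full and first-minute) ->
synthesize -> split -> train -> evaluate, with one top-level seed from which
every stage's seed is derived by hashing (top seed, stage name), so adding a
stage never perturbs an earlier stage's randomness.  All tables are RFC-4180
CSV with a header row; the run report is JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, Cohort, simulate_cohort
from .features import featurize_cohort, featurize
from .synthesis import SynthesisConfig, synthesize_table, validate_synthesis, split_half
from .ensemble import SuperLearner, encode_labels
from .evaluation import (
    confusion_metrics,
    exact_binomial_test,
    bootstrap_compare,
    kfold_overfit_check,
    logistic_baseline,
    effect_stats,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_tables", "stage_seed"]

TRACE_COLUMNS = ["participant_id", "song_id", "t_sec", "immersion"]
SONG_COLUMNS = ["song_id", "label"]
SURVEY_COLUMNS = ["participant_id", "song_id", "familiar"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the top seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    folds: int = 5
    tune: bool = False  # grid-tune learners; False uses the selected settings
    tune_subsample: int | None = 1200
    min_participants: int = 2
    first_minute: bool = True  # also run the 60-second truncation variant
    base_rate: float | None = None  # None: observed hit fraction of the evaluated set
    bootstrap_iterations: int = 0  # 0 disables the bootstrap comparison
    bootstrap_train_n: int = 800
    bootstrap_test_n: int = 800
    kfold_k: int = 0  # 0 disables the overfitting check
    kfold_subsample: int = 1000
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.synthesis.validate()
        if self.folds < 2:
            raise ValueError("folds must be at least 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        synth_raw = raw.pop("synthesis", {})
        if "visit_order" in synth_raw:
            synth_raw["visit_order"] = tuple(synth_raw["visit_order"])
        synthesis = SynthesisConfig(**synth_raw)
        return cls(cohort=cohort, synthesis=synthesis, **raw)


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing column(s) {missing}")


def read_tables(paths: dict[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read and validate the cohort CSVs.

    ``paths`` maps table names ("traces", "songs", "surveys", optionally
    "participants") to files.  Trace second indices must be contiguous from 0
    per (participant, song); labels are normalized to lower-case hit/flop.
    """
    tables = {name: pd.read_csv(Path(p)) for name, p in paths.items()}
    if "traces" in tables:
        tr = tables["traces"]
        _require_columns(tr, TRACE_COLUMNS, "traces")
        for (pid, sid), grp in tr.groupby(["participant_id", "song_id"], sort=False):
            t = np.sort(grp["t_sec"].to_numpy())
            expected = np.arange(len(t))
            if not np.array_equal(t, expected):
                gap = int(expected[t != expected][0]) if (t != expected).any() else len(t)
                raise ValueError(
                    f"trace ({pid}, {sid}) has non-contiguous seconds: "
                    f"expected t={gap} (seconds must run 0..T-1 with no gaps)"
                )
    if "songs" in tables:
        so = tables["songs"]
        _require_columns(so, SONG_COLUMNS, "songs")
        labels = so["label"].astype(str).str.lower()
        bad = sorted(set(labels) - {"hit", "flop"})
        if bad:
            raise ValueError(f"songs has unknown label(s) {bad}; expected hit/flop")
        so["label"] = labels
    if "surveys" in tables:
        _require_columns(tables["surveys"], SURVEY_COLUMNS, "surveys")
    return tables


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sl_factory(seed_base: int, folds: int):
    def factory(X, y, seed):
        model = SuperLearner(X, y, folds=folds, tune=False, seed=seed % (2**31))
        return model.fit()
    return factory


def _logit_factory():
    from sklearn.linear_model import LogisticRegression

    def factory(X, y, seed):
        return LogisticRegression(max_iter=1000).fit(X, y)

    return factory


def _evaluate_variant(
    features: pd.DataFrame, config: PipelineConfig, variant: str
) -> dict:
    """Synthesize, split, train and evaluate one feature-window variant."""
    seed = stage_seed(config.seed, f"synthesize:{variant}")
    synth_cfg = replace(config.synthesis, seed=seed)
    synthetic = synthesize_table(features, synth_cfg)
    fidelity = validate_synthesis(features, synthetic.table)
    train, test = split_half(synthetic.table, seed=stage_seed(config.seed, f"split:{variant}"))

    model = SuperLearner.from_dataframe(
        train,
        folds=config.folds,
        tune=config.tune,
        tune_subsample=config.tune_subsample,
        seed=stage_seed(config.seed, f"train:{variant}"),
    )
    results = model.fit()

    y_test = encode_labels(test["label"])
    pred_test = results.predict_frame(test)
    conf_test = confusion_metrics(y_test, pred_test)
    base_rate = (
        config.base_rate if config.base_rate is not None else float(np.mean(y_test))
    )
    binom_test_res = exact_binomial_test(
        int(conf_test.tp + conf_test.tn), len(y_test), base_rate
    )

    y_obs = encode_labels(features["label"])
    pred_obs = results.predict_frame(features)
    conf_obs = confusion_metrics(y_obs, pred_obs)
    obs_base = (
        config.base_rate if config.base_rate is not None else float(np.mean(y_obs))
    )
    binom_obs = exact_binomial_test(int(conf_obs.tp + conf_obs.tn), len(y_obs), obs_base)

    logit1 = logistic_baseline(features, "model1")
    logit2 = logistic_baseline(features, "model2")
    logit_synth = logistic_baseline(test, "model2")

    report = {
        "synthesis": {
            "provenance": synthetic.provenance,
            "fidelity_passed": fidelity.passed,
            "fidelity_failures": fidelity.failures,
        },
        "ensemble": results.to_dict(),
        "synthetic_test": {
            "confusion": conf_test.to_dict(),
            "binomial": asdict(binom_test_res),
        },
        "observed": {
            "confusion": conf_obs.to_dict(),
            "binomial": asdict(binom_obs),
        },
        "logistic": {
            "model1": logit1.to_dict(),
            "model2": logit2.to_dict(),
            "model2_synthetic_test": logit_synth.to_dict(),
        },
        "effects": {
            "avg_immersion": effect_stats(features, "avg_immersion").to_dict(),
            "retreat": effect_stats(features, "retreat").to_dict(),
            "peak_immersion": effect_stats(features, "peak_immersion").to_dict(),
        },
    }

    if config.bootstrap_iterations >= 2:
        comp = bootstrap_compare(
            _logit_factory(),
            _sl_factory(config.seed, config.folds),
            synthetic.table,
            iterations=config.bootstrap_iterations,
            train_n=config.bootstrap_train_n,
            test_n=config.bootstrap_test_n,
            seed=stage_seed(config.seed, f"bootstrap:{variant}"),
        )
        report["bootstrap"] = comp.to_dict()

    if config.kfold_k >= 2:
        sub = train
        if config.kfold_subsample and len(train) > config.kfold_subsample:
            sub = train.sample(
                config.kfold_subsample,
                random_state=stage_seed(config.seed, f"kfold_sub:{variant}"),
            ).reset_index(drop=True)
        check = kfold_overfit_check(
            _sl_factory(config.seed, config.folds),
            sub,
            features,
            k=config.kfold_k,
            seed=stage_seed(config.seed, f"kfold:{variant}"),
        )
        report["kfold"] = check.to_dict()

    return report, synthetic, train, test, results


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    cohort: Cohort | None = None,
) -> dict:
    """Run the full analysis; returns the run report (JSON-serializable).

    When ``out_dir`` is given, writes the cohort CSVs, the feature tables,
    the synthetic tables and ``report.json`` there.  ``cohort`` may supply a
    pre-loaded cohort (e.g. from disk) instead of simulating one.
    """
    config = config if config is not None else PipelineConfig()
    config.validate()
    report: dict = {"config": _config_echo(config), "stages": {}}
    timings: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - abort with the stage named
            raise StageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return out

    if cohort is None:
        cohort = run_stage(
            "synthetic_cohort",
            lambda: simulate_cohort(config.cohort, seed=stage_seed(config.seed, "cohort")),
        )

    features_full = run_stage(
        "features",
        lambda: featurize_cohort(cohort, window="full", min_participants=config.min_participants),
    )
    variants = {"full": features_full}
    if config.first_minute:
        variants["first_minute"] = run_stage(
            "features_first_minute",
            lambda: featurize_cohort(
                cohort, window="first_minute", min_participants=config.min_participants
            ),
        )

    artifacts = {}
    for variant, feats in variants.items():
        section, synthetic, train, test, results = run_stage(
            f"evaluate:{variant}", lambda f=feats, v=variant: _evaluate_variant(f, config, v)
        )
        report["stages"][variant] = section
        artifacts[variant] = (feats, synthetic, train, test, results)

    report["timings_sec"] = timings

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.write(out)
        for variant, (feats, synthetic, _, _, results) in artifacts.items():
            feats.to_csv(out / f"features_{variant}.csv", index=False)
            synthetic.table.to_csv(out / f"synthetic_{variant}.csv", index=False)
            (out / f"model_{variant}.json").write_text(
                json.dumps(results.to_dict(), indent=2)
            )
        (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    echo["synthesis"]["visit_order"] = list(config.synthesis.visit_order)
    return echo
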