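"""End-to-end pipeline: simulate -> match -> profile -> classify ->
temporal -> sentiment, with TSV tables and a markdown report.

Every stage derives its seed from the master seed by a fixed offset, so
a run is idempotent given (config, seed); each output table carries the
config hash in a header comment line.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort_builder import MatchedCohort, build_cohort, temporal_subset
from .corpus_io import read_annotations, read_users, write_annotations, write_users
from .lexical_specificity import lemmatize_and_count, rank_terms
from .sentiment_regression import (
    LexiconSentimentScorer,
    band_percentages,
    fit_multinomial,
    fit_sentimentality_logistic,
    make_observations,
)
from .synthetic_data import GeneratorConfig, generate_cohort, write_truth
from .temporal_classify import build_windowed_dataset, crossval, naive_baseline_f1

__all__ = ["PipelineConfig", "run_pipeline", "subsample_controls"]

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the master seed
_STAGE_SEED = {"simulate": 11, "match": 23, "classify": 37, "temporal": 53,
               "sentiment": 71}


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    k_values: Sequence[int] = (1, 3, 5, 10)
    temporal_k_values: Sequence[int] = (1, 3)
    window_weeks: Sequence[int] = (4, 8, 12, 16, 20, 24)
    repeats: int = 3
    folds: int = 5
    tolerance: float = 0.15
    feature_modes: Sequence[str] = ("tfidf", "embedding", "both")
    top_terms: int = 10
    activity_window_weeks: int = 2
    #: overrides forwarded to GeneratorConfig (e.g. n_cases, lexicon_mixing)
    generator: dict[str, Any] = field(default_factory=dict)
    stages: Sequence[str] = (
        "simulate", "build-cohort", "specificity", "classify", "temporal",
        "sentiment",
    )

    def __post_init__(self) -> None:
        if not self.k_values or not self.window_weeks:
            raise ValueError("k_values and window_weeks must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Digest of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def subsample_controls(
    cohort: MatchedCohort, k: int, seed: int = 0
) -> MatchedCohort:
    """Seeded reduction of each case's control set to its first k of a
    random permutation (used to derive the 1:1 / 1:3 / 1:5 designs from
    the 1:10 matching)."""
    import numpy as np

    if k > cohort.k:
        raise ValueError(f"cannot take {k} controls from a 1:{cohort.k} cohort")
    if k == cohort.k:
        return cohort
    rng = np.random.default_rng(seed)
    out = MatchedCohort(cases=list(cohort.cases), controls={}, k=k,
                        tolerance=cohort.tolerance,
                        exclusion_ledger=dict(cohort.exclusion_ledger))
    for user, _ in cohort.cases:
        ctrls = cohort.controls[user.user_id]
        keep = rng.choice(len(ctrls), size=k, replace=False)
        out.controls[user.user_id] = [ctrls[i] for i in sorted(keep)]
    return out


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the enabled stages; returns a name -> path map of outputs.

    Any stage failure aborts with the stage name; completed stages are
    listed in the raised error and in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    outputs: dict[str, Path] = {}
    done: list[str] = []
    t_start = time.time()

    def _stage(name: str) -> bool:
        return name in config.stages

    try:
        users = annotations = truth = None
        if _stage("simulate"):
            t0 = time.time()
            gen = GeneratorConfig(seed=config.seed + _STAGE_SEED["simulate"],
                                  **config.generator)
            users, annotations, truth = generate_cohort(gen)
            write_users(users, out / "users.jsonl")
            write_annotations(annotations, out / "annotations.jsonl")
            write_truth(truth, out / "truth.jsonl")
            outputs["users"] = out / "users.jsonl"
            outputs["annotations"] = out / "annotations.jsonl"
            outputs["truth"] = out / "truth.jsonl"
            logger.info("simulate: %d users in %.1fs", len(users),
                        time.time() - t0)
            done.append("simulate")
        else:
            users = read_users(out / "users.jsonl")
            annotations = read_annotations(out / "annotations.jsonl")

        cohort = None
        if _stage("build-cohort"):
            t0 = time.time()
            k_max = max(max(config.k_values), max(config.temporal_k_values))
            cohort = build_cohort(users, annotations, k=k_max,
                                  tolerance=config.tolerance,
                                  seed=config.seed + _STAGE_SEED["match"])
            cohort.to_json(out / "cohort.json")
            outputs["cohort"] = out / "cohort.json"
            logger.info("build-cohort: %d users (%d cases) in %.1fs",
                        cohort.n_users, len(cohort.cases), time.time() - t0)
            done.append("build-cohort")
        elif (out / "cohort.json").exists():
            cohort = MatchedCohort.from_json(out / "cohort.json", users)

        if _stage("specificity"):
            t0 = time.time()
            ranked = rank_terms(lemmatize_and_count(users), config.top_terms)
            rows = [
                {"class": cls, "term": s.term, "score": round(s.score, 2),
                 "f": s.f}
                for cls, scores in ranked.items() for s in scores
            ]
            _write_tsv(pd.DataFrame(rows), out / "specificity.tsv", cfg_hash)
            outputs["specificity"] = out / "specificity.tsv"
            logger.info("specificity in %.1fs", time.time() - t0)
            done.append("specificity")

        if _stage("classify"):
            t0 = time.time()
            rows = []
            for k in config.k_values:
                sub = subsample_controls(cohort, k,
                                         config.seed + _STAGE_SEED["classify"] + k)
                ds = build_windowed_dataset(sub)
                for mode in config.feature_modes:
                    m = crossval(ds, feature_mode=mode, folds=config.folds,
                                 repeats=config.repeats,
                                 seed=config.seed + _STAGE_SEED["classify"])
                    rows.append({"k": k, "n_users": sub.n_users,
                                 "classifier": f"svm_{mode}",
                                 "ppv": m.ppv, "ppv_sd": m.ppv_sd,
                                 "sensitivity": m.sensitivity,
                                 "sensitivity_sd": m.sensitivity_sd,
                                 "f1": m.f1, "f1_sd": m.f1_sd})
                rows.append({"k": k, "n_users": sub.n_users,
                             "classifier": "naive_all_positive",
                             "ppv": 1.0 / (1.0 + k), "ppv_sd": None,
                             "sensitivity": 1.0, "sensitivity_sd": None,
                             "f1": naive_baseline_f1(k), "f1_sd": None})
            _write_tsv(pd.DataFrame(rows), out / "classify.tsv", cfg_hash)
            outputs["classify"] = out / "classify.tsv"
            logger.info("classify in %.1fs", time.time() - t0)
            done.append("classify")

        temporal_cohorts = {}
        if _stage("temporal") or _stage("sentiment"):
            for k in config.temporal_k_values:
                temporal_cohorts[k] = temporal_subset(
                    cohort, window_weeks=config.activity_window_weeks, k_out=k,
                    seed=config.seed + _STAGE_SEED["temporal"] + k)

        if _stage("temporal"):
            t0 = time.time()
            rows = []
            for k, sub in temporal_cohorts.items():
                for weeks in config.window_weeks:
                    ds = build_windowed_dataset(sub, weeks=weeks)
                    m = crossval(ds, feature_mode="tfidf", folds=config.folds,
                                 repeats=config.repeats,
                                 seed=config.seed + _STAGE_SEED["temporal"])
                    rows.append({"k": k, "weeks": weeks, "n_users": sub.n_users,
                                 "classifier": "svm_tfidf",
                                 "ppv": m.ppv, "sensitivity": m.sensitivity,
                                 "f1": m.f1, "f1_sd": m.f1_sd})
                rows.append({"k": k, "weeks": None, "n_users": sub.n_users,
                             "classifier": "naive_all_positive", "ppv": 1 / (1 + k),
                             "sensitivity": 1.0, "f1": naive_baseline_f1(k),
                             "f1_sd": None})
            _write_tsv(pd.DataFrame(rows), out / "temporal.tsv", cfg_hash)
            outputs["temporal"] = out / "temporal.tsv"
            logger.info("temporal in %.1fs", time.time() - t0)
            done.append("temporal")

        if _stage("sentiment"):
            t0 = time.time()
            k_sent = max(config.temporal_k_values)
            obs = make_observations(temporal_cohorts[k_sent],
                                    scorer=LexiconSentimentScorer())
            bands = band_percentages(obs).reset_index()
            _write_tsv(bands, out / "bands.tsv", cfg_hash)
            logistic = fit_sentimentality_logistic(obs)
            tables = [logistic.table.assign(model=logistic.model,
                                            term=logistic.table.index)]
            for outcome, tab in fit_multinomial(obs).items():
                tables.append(tab.table.assign(model=tab.model,
                                               term=tab.table.index))
            models = pd.concat(tables, ignore_index=True)
            _write_tsv(models[["model", "term", "beta", "odds_ratio", "se", "p"]],
                       out / "models.tsv", cfg_hash)
            outputs["bands"] = out / "bands.tsv"
            outputs["models"] = out / "models.tsv"
            logger.info("sentiment in %.1fs", time.time() - t0)
            done.append("sentiment")

    except Exception as exc:
        stage = next((s for s in config.stages if s not in done), "?")
        raise RuntimeError(
            f"pipeline aborted in stage {stage!r} (completed: {done}): {exc}"
        ) from exc

    report = out / "report.md"
    _write_report(report, config, cfg_hash, outputs, done,
                  time.time() - t_start)
    outputs["report"] = report
    return outputs


def _write_report(path, config, cfg_hash, outputs, done, elapsed) -> None:
    import numpy, pandas, scipy, sklearn

    lines = [
        "# Pipeline report",
        "",
        f"- generated: {_dt.datetime.now().isoformat(timespec='seconds')}",
        f"- config hash: `{cfg_hash}`  |  master seed: {config.seed}",
        f"- versions: prodromal-text {__version__}, numpy {numpy.__version__}, "
        f"scipy {scipy.__version__}, pandas {pandas.__version__}, "
        f"scikit-learn {sklearn.__version__}",
        f"- stages completed: {', '.join(done)} ({elapsed:.1f}s)",
        "",
    ]
    for name, p in outputs.items():
        if p.suffix == ".tsv":
            lines.append(f"## {name}\n")
            lines.append(pd.read_csv(p, sep="\t", comment="#").to_markdown(
                index=False))
            lines.append("")
    Path(path).write_text("\n".join(lines))
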