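"""End-to-end orchestration: inputs -> screening -> PCA -> orthogonalized
fusion -> nested CV -> multi-setting comparison report.

Every requested feature setting is evaluated with the same sequence of
seeds, so the with/without-orthogonalization contrast is paired by seed
and the percentile bootstrap of the per-seed differences is meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustic import load_acoustic_table
from .blocks import BlockSet, FeatureBlock
from .evaluation import (
    BootstrapResult,
    CVConfig,
    EvaluationReport,
    bootstrap_ci_diff,
    repeated_cv,
    summarize_repeats,
)
from .fusion import SETTINGS, FeaturePipeline
from .linguistic import KeywordLexicon, build_term_matrix, read_transcripts
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_study_inputs"]


@dataclass
class PipelineConfig:
    """Configuration of one comparison run.

    Either ``synthetic`` is set (a cohort is generated) or the four input
    paths are set (transcript TSV, acoustic CSV, lexicon YAML, labels
    TSV).  ``feature_settings`` picks which rows of the comparison table
    to compute; all settings share seeds so contrasts are paired.
    """

    synthetic: SyntheticConfig | None = None
    transcripts: str | None = None
    acoustic_table: str | None = None
    lexicon: str | None = None
    labels: str | None = None
    feature_settings: tuple[str, ...] = SETTINGS
    variance_fraction: float = 0.95
    screen: str = "fold"
    min_total: int = 2
    cv: CVConfig = field(default_factory=CVConfig)
    n_repeats: int = 5
    output_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.feature_settings) - set(SETTINGS)
        if unknown:
            raise ValueError(f"unknown feature settings: {sorted(unknown)}")
        if not self.feature_settings:
            raise ValueError("at least one feature setting is required")
        if self.synthetic is None:
            missing = [
                n for n in ("transcripts", "acoustic_table", "lexicon", "labels")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(f"non-synthetic run needs input paths: {missing}")

    def to_jsonable(self) -> dict:
        payload = {
            "synthetic": None if self.synthetic is None else vars(self.synthetic).copy(),
            "transcripts": self.transcripts,
            "acoustic_table": self.acoustic_table,
            "lexicon": self.lexicon,
            "labels": self.labels,
            "feature_settings": list(self.feature_settings),
            "variance_fraction": self.variance_fraction,
            "screen": self.screen,
            "min_total": self.min_total,
            "cv": {
                "outer_k": self.cv.outer_k,
                "inner_k": self.cv.inner_k,
                "stratified": self.cv.stratified,
                "seed": self.cv.seed,
                "model_grid": self.cv.model_grid,
                "tie_break": self.cv.tie_break,
            },
            "n_repeats": self.n_repeats,
        }
        return payload

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """One comparison report: per-setting repeated-CV reports plus the
    paired bootstrap for the orthogonalization contrast when both combined
    settings were run."""

    config: PipelineConfig
    reports: dict[str, list[EvaluationReport]]
    contrast: BootstrapResult | None

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for setting, reps in self.reports.items():
            summary = summarize_repeats(reps)
            row = {"feature_setting": setting}
            for m, stats in summary.items():
                row[f"{m}_mean"] = round(stats["mean"], 2)
                row[f"{m}_sd"] = round(stats["sd"], 2)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "config": self.config.to_jsonable(),
            "config_hash": self.config.config_hash(),
            "seeds": list(range(self.config.cv.seed, self.config.cv.seed + self.config.n_repeats)),
            "reports": {
                s: [rep.to_dict() for rep in reps] for s, reps in self.reports.items()
            },
            "summaries": {s: summarize_repeats(reps) for s, reps in self.reports.items()},
            "ortho_contrast": None if self.contrast is None else self.contrast.to_dict(),
        }

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "report.json").write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        self.summary_table().to_csv(d / "summary.csv", index=False)


def load_study_inputs(cfg: PipelineConfig) -> tuple[BlockSet, np.ndarray, KeywordLexicon]:
    """Assemble id-aligned blocks and labels from file inputs."""
    labels_frame = pd.read_csv(cfg.labels, sep="\t", dtype={"id": str})
    if "label" not in labels_frame.columns:
        if "cbi_score" not in labels_frame.columns:
            raise ValueError("labels TSV needs a 'label' or 'cbi_score' column")
        labels_frame["label"] = (labels_frame["cbi_score"] > 36).astype(int)
    ids = labels_frame["id"].tolist()
    lexicon = KeywordLexicon.from_yaml(cfg.lexicon)
    corpus = read_transcripts(cfg.transcripts)
    corpus_ids = {t.participant_id for t in corpus}
    missing = sorted(set(ids) - corpus_ids)
    if missing:
        raise ValueError(f"transcripts missing for participants: {missing}")
    order = {t.participant_id: t for t in corpus}
    tm = build_term_matrix([order[i] for i in ids], vocabulary=sorted(lexicon.entries))
    acoustic = load_acoustic_table(cfg.acoustic_table, participant_ids=ids)
    return (
        BlockSet(tm.to_block(), acoustic),
        labels_frame["label"].to_numpy(dtype=int),
        lexicon,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every requested feature setting and the paired contrast."""
    if cfg.synthetic is not None:
        cohort = generate_cohort(cfg.synthetic)
        blocks, labels, lexicon = cohort.blocks, cohort.label, cohort.lexicon
    else:
        blocks, labels, lexicon = load_study_inputs(cfg)

    reports: dict[str, list[EvaluationReport]] = {}
    for setting in cfg.feature_settings:
        logger.info("evaluating feature setting %s", setting)
        pipeline = FeaturePipeline(
            setting=setting,
            variance_fraction=cfg.variance_fraction,
            lexicon=lexicon,
            screen=cfg.screen,
            min_total=cfg.min_total,
        )
        reports[setting] = repeated_cv(
            blocks, labels, cfg.cv, n_repeats=cfg.n_repeats, preprocessing=pipeline
        )

    contrast = None
    if {"combined_ortho", "combined_raw"} <= set(reports):
        contrast = bootstrap_ci_diff(reports["combined_ortho"], reports["combined_raw"])

    result = PipelineResult(cfg, reports, contrast)
    if cfg.output_dir is not None:
        result.write(cfg.output_dir)
    return result
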