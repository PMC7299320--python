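"""End-to-end orchestration: cohort -> masks -> features -> screen -> LASSO
-> LOOCV classifiers -> ROC report.

All randomness flows from one top-level seed through named sub-seeds
(phantom generation, CV fold assignment), so a config and seed reproduce a
bundle bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import run_report
from .modeling import ClassifierSpec, CVScores, fit_predict_loocv
from .phantom import CohortCase, PhantomConfig, generate_cohort
from .preprocessing import normalize_quantize, subtract
from .screening import ScreeningConfig, screen_table
from .segmentation import MorphologyParams, SegmentationError, segment_lesion, transfer_mask
from .selection import lasso_select
from .texture import DWTConfig, GLCMConfig, GRLMConfig, extract_features

logger = logging.getLogger("texomri")

PHASES = ("pre", "post", "subtraction")


@dataclass
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    phases: Sequence[str] = PHASES
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    grlm: GRLMConfig = field(default_factory=GRLMConfig)
    dwt: DWTConfig = field(default_factory=DWTConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    selection_folds: int = 10
    selection_lambdas: int = 100
    selection_one_se: bool = True   # parsimony rule; see docs/methods.md
    classifiers: Sequence[ClassifierSpec] = field(
        default_factory=lambda: [
            ClassifierSpec("lra"),
            ClassifierSpec("qda"),
            ClassifierSpec("svm"),
        ]
    )
    mode: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("at least one phase is required")
        bad = set(self.phases) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phases: {sorted(bad)}")
        if not self.classifiers:
            raise ValueError("at least one classifier is required")


@dataclass
class PipelineResult:
    feature_tables: Dict[str, pd.DataFrame]       # phase -> patients x (488 + label)
    screening: Dict[str, list]                    # phase -> FeatureScreenRecords
    selected: Dict[str, List[str]]                # phase -> selected feature names
    cv_scores: List[CVScores]
    report: Dict[str, pd.DataFrame]
    masks: Dict[str, np.ndarray]                  # patient_id -> lesion mask

    def auc(self, phase: str, classifier: str) -> float:
        perf = self.report["performance"]
        row = perf[(perf.phase == phase) & (perf.classifier == classifier.upper())]
        return float(row["AUC"].iloc[0])


def extract_feature_table(
    cases: List[CohortCase],
    phase: str,
    morphology: MorphologyParams | None = None,
    glcm_cfg: GLCMConfig | None = None,
    grlm_cfg: GRLMConfig | None = None,
    dwt_cfg: DWTConfig | None = None,
    masks: Optional[Dict[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Segment (on the subtraction image) and extract one phase's features.

    Returns a patients-by-features frame indexed by patient id with a binary
    ``label`` column (1 = positive).  Pass a precomputed ``masks`` dict to
    avoid re-segmenting when extracting several phases.
    """
    morphology = morphology or MorphologyParams()
    rows = {}
    for case in cases:
        sub = subtract(case.post, case.pre)
        if masks is not None and case.patient_id in masks:
            mask = masks[case.patient_id]
        else:
            mask = segment_lesion(sub, case.seed_roi, morphology)
            if masks is not None:
                masks[case.patient_id] = mask
        image = {"pre": case.pre, "post": case.post, "subtraction": sub}[phase]
        q = normalize_quantize(image, transfer_mask(mask, image))
        feats = extract_features(q, glcm_cfg, grlm_cfg, dwt_cfg)
        feats["label"] = 1 if case.label == "positive" else 0
        rows[case.patient_id] = feats
    return pd.DataFrame.from_dict(rows, orient="index")


def analyze_phase(
    table: pd.DataFrame,
    classifiers: Sequence[ClassifierSpec],
    screening_cfg: ScreeningConfig,
    phase: str,
    mode: str = "paper",
    seed: int = 0,
    selection_folds: int = 10,
    selection_lambdas: int = 100,
    selection_one_se: bool = True,
):
    """Screen, select, and LOOCV-classify one phase's feature table."""
    y = table["label"].to_numpy()
    feat_cols = [c for c in table.columns if c != "label"]
    records = screen_table(table, screening_cfg)
    kept = [r.feature_name for r in records if r.kept]
    logger.info("phase=%s screened %d/%d features", phase, len(kept), len(feat_cols))
    if mode == "paper":
        if kept:
            sel = lasso_select(
                table[kept].to_numpy(),
                y,
                feature_names=kept,
                k_folds=selection_folds,
                seed=seed,
                n_lambdas=selection_lambdas,
                one_se_rule=selection_one_se,
            )
            selected = sel.selected or kept
        else:
            selected = feat_cols  # nothing survived: fall back to everything
        X = table[selected].to_numpy()
        names = selected
    else:
        X = table[feat_cols].to_numpy()
        names = feat_cols
        selected = kept
    scores = []
    for spec in classifiers:
        scores.append(
            fit_predict_loocv(
                X,
                y,
                spec,
                mode=mode,
                patient_ids=list(table.index),
                feature_names=names,
                phase=phase,
                seed=seed,
                screening_cfg=screening_cfg,
                selection_folds=selection_folds,
                selection_lambdas=selection_lambdas,
            )
        )
    return records, selected, scores


def run_pipeline(
    config: PipelineConfig,
    cases: Optional[List[CohortCase]] = None,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the full analysis; optionally persist every intermediate artifact."""
    if cases is None:
        phantom_cfg = config.phantom
        if phantom_cfg.seed != config.seed:
            phantom_cfg = PhantomConfig(**{**asdict_shallow(phantom_cfg), "seed": config.seed})
        cases = generate_cohort(phantom_cfg)
    masks: Dict[str, np.ndarray] = {}
    feature_tables = {}
    screening_out = {}
    selected_out = {}
    all_scores: List[CVScores] = []
    for phase in config.phases:
        try:
            table = extract_feature_table(
                cases, phase, config.morphology, config.glcm, config.grlm, config.dwt,
                masks=masks,
            )
        except SegmentationError as exc:
            raise SegmentationError(f"[phase={phase}] {exc}") from exc
        feature_tables[phase] = table
        records, selected, scores = analyze_phase(
            table,
            config.classifiers,
            config.screening,
            phase,
            mode=config.mode,
            seed=config.seed,
            selection_folds=config.selection_folds,
            selection_lambdas=config.selection_lambdas,
            selection_one_se=config.selection_one_se,
        )
        screening_out[phase] = records
        selected_out[phase] = selected
        all_scores.extend(scores)
    report = run_report(all_scores)
    result = PipelineResult(
        feature_tables=feature_tables,
        screening=screening_out,
        selected=selected_out,
        cv_scores=all_scores,
        report=report,
        masks=masks,
    )
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def asdict_shallow(obj) -> dict:
    """dataclass -> dict without recursing into nested dataclasses."""
    return {f: getattr(obj, f) for f in obj.__dataclass_fields__}


def _persist(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for phase, table in result.feature_tables.items():
        table.to_csv(outdir / f"features_{phase}.csv", float_format="%.10g")
        recs = result.screening[phase]
        pd.DataFrame(
            [
                {
                    "feature": r.feature_name,
                    "positive": r.summary_pos,
                    "negative": r.summary_neg,
                    "test": r.test_used,
                    "p_value": r.p_value,
                    "kept": r.kept,
                }
                for r in recs
            ]
        ).to_csv(outdir / f"screening_{phase}.csv", index=False, float_format="%.10g")
        (outdir / f"selected_{phase}.json").write_text(
            json.dumps(result.selected[phase], indent=1)
        )
    pd.concat([cv.to_frame() for cv in result.cv_scores]).to_csv(
        outdir / "cv_scores.csv", index=False, float_format="%.10g"
    )
    for name, frame in result.report.items():
        frame.to_csv(outdir / f"report_{name}.csv", float_format="%.10g")
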