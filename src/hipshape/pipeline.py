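"""End-to-end orchestration: generate -> align -> measure -> model -> regress.

``run_pipeline`` executes every stage on a synthetic cohort and returns a
machine-readable report with the angle summary, per-angle mixed-ANOVA
p-values, the mode counts explaining 95% of variance, leave-one-out AUCs
for sex (combined model) and per-side hip dysplasia, and the leave-one-out
residual intervals for angle prediction. Everything is deterministic given
the generator's master seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .alignment import AlignedCohort, align_cohort
from .angles import classify_dysplasia, measure_subject
from .core import ANGLE_NAMES, SIDES, CorrespondedShape
from .io import PipelineConfig
from .regression import (
    fit_linear_direction,
    fit_logistic_direction,
    loo_evaluate,
    loo_evaluate_rebuilt_basis,
)
from .ssm import build_pdm, modes_for_variance, training_scores
from .stats import mixed_anova, summarize_angles
from .synthetic import generate_cohort

__all__ = ["run_pipeline", "measure_cohort", "build_models", "PipelineResult"]

logger = logging.getLogger("hipshape")

MODEL_BONES = {
    "combined": ("pelvis_L", "pelvis_R", "femur_L", "femur_R"),
    "left": ("pelvis_L", "femur_L"),
    "right": ("pelvis_R", "femur_R"),
}
PREDICTED_ANGLES = ("ce", "ai", "acav")  # angle-value regressions in the report


def measure_cohort(source) -> pd.DataFrame:
    """Per-hip measured angle table from a :class:`Cohort` or AlignedCohort.

    Columns: subject_id, side, sex, the six measured angles, the dysplasia
    flag from the measured CE angle, and the ground-truth angles/labels when
    the cohort carries them.
    """
    if isinstance(source, AlignedCohort):
        cohort = source.cohort
        shape_sets = [
            {
                bone: CorrespondedShape(bone, pts, cohort.subjects[i].shapes[bone].landmark_index_map)
                for bone, pts in source.aligned[i].items()
            }
            for i in range(len(source.aligned))
        ]
    else:
        cohort = source
        shape_sets = [subj.shapes for subj in cohort.subjects]

    rows = []
    for subj, shapes in zip(cohort.subjects, shape_sets):
        measured = measure_subject(shapes)
        for side in SIDES:
            ang = measured[side]
            row = {
                "subject_id": subj.subject_id,
                "side": side,
                "sex": subj.sex,
                **{k: getattr(ang, k) for k in ANGLE_NAMES},
                "dysplasia": classify_dysplasia(ang),
            }
            if subj.true_angles:
                row.update({f"true_{k}": getattr(subj.true_angles[side], k) for k in ANGLE_NAMES})
                row["true_dysplasia"] = subj.dysplasia[side]
            rows.append(row)
    return pd.DataFrame(rows)


def build_models(aligned: AlignedCohort) -> dict:
    """The three point-distribution models: combined, left-side, right-side."""
    models = {}
    for name, bones in MODEL_BONES.items():
        comp = [(b, aligned.cohort.subjects[0].shapes[b].n_points) for b in bones]
        models[name] = build_pdm(aligned.stacked(bones), composition=comp)
    return models


class PipelineResult:
    """Report dict plus the heavyweight intermediates, for inspection/tests."""

    def __init__(self, report, cohort, aligned, angles, models, scores, loo):
        self.report = report
        self.cohort = cohort
        self.aligned = aligned
        self.angles = angles
        self.models = models
        self.scores = scores
        self.loo = loo


def run_pipeline(config: PipelineConfig | None = None, return_intermediates: bool = False):
    """Run every stage on a synthetic cohort; return the JSON-ready report."""
    cfg = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    logger.info("generating cohort: %d subjects", cfg.generator.n_subjects)
    cohort = generate_cohort(cfg.generator)

    logger.info("aligning (GPA + femur pose correction)")
    aligned = align_cohort(
        cohort,
        allow_scale=cfg.allow_scale,
        gpa_tol=cfg.gpa_tol,
        pose_tol=cfg.pose_tol,
        max_iter=cfg.max_iter,
    )

    logger.info("measuring angles")
    angles = measure_cohort(aligned)

    summary = summarize_angles(angles)
    anova = {}
    for angle in ANGLE_NAMES:
        res = mixed_anova(angles.rename(columns={angle: "value"}), value="value")
        anova[angle] = {term: res.terms[term]["p"] for term in res.terms}

    logger.info("building shape models")
    models = build_models(aligned)
    n95 = {name: modes_for_variance(m, cfg.variance_fraction) for name, m in models.items()}
    scores = {
        name: training_scores(m, aligned.stacked(MODEL_BONES[name])) for name, m in models.items()
    }

    logger.info("regressions + leave-one-out")
    loo = {}
    subj_df = angles.drop_duplicates("subject_id")
    sex_labels = (subj_df["sex"] == "F").to_numpy()
    n_modes = {name: (cfg.n_modes or n95[name]) for name in models}

    def _loo(model_name, targets, kind):
        if cfg.refit_basis_per_fold:
            return loo_evaluate_rebuilt_basis(
                aligned.stacked(MODEL_BONES[model_name]), targets, kind,
                variance_fraction=cfg.variance_fraction, ridge=cfg.ridge,
            )
        return loo_evaluate(
            scores[model_name], targets, kind, n_modes=n_modes[model_name], ridge=cfg.ridge
        )

    loo["sex"] = _loo("combined", sex_labels, "logistic")
    fit_logistic_direction(  # full-data direction; kept for shape visualisation
        scores["combined"], sex_labels, n_modes=n_modes["combined"], ridge=cfg.ridge, target_name="sex"
    )
    dys_auc = {}
    for side, model_name in (("L", "left"), ("R", "right")):
        labels = angles.loc[angles["side"] == side, "dysplasia"].to_numpy()
        loo[f"dysplasia_{side}"] = _loo(model_name, labels, "logistic")
        dys_auc[side] = loo[f"dysplasia_{side}"].auc

    angle_pred = {}
    for angle in PREDICTED_ANGLES:
        values = angles.loc[angles["side"] == "R", angle].to_numpy()
        res = _loo("right", values, "linear")
        loo[f"{angle}_R"] = res
        fit_linear_direction(scores["right"], values, n_modes=n_modes["right"], target_name=angle)
        angle_pred[angle] = {
            "interval": [res.interval[0], res.interval[1]],
            "width": res.interval_width,
        }

    report = {
        "seed": cfg.generator.seed,
        "n_subjects": len(cohort),
        "n_female": cohort.n_female,
        "angle_summary": {
            row: {k: (None if pd.isna(v) else float(v)) for k, v in summary.loc[row].items()}
            for row in summary.index
        },
        "anova_p": anova,
        "n_modes_95": n95,
        "sex_auc": loo["sex"].auc,
        "dysplasia_auc": {"left": dys_auc["L"], "right": dys_auc["R"]},
        "angle_prediction": angle_pred,
        "gpa_iterations": len(aligned.gpa_iterations),
    }
    if return_intermediates:
        return PipelineResult(report, cohort, aligned, angles, models, scores, loo)
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
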