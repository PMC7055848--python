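"""Head-to-head evaluation of adaptive testing versus trees.

For each questionnaire, complete cases are split 75/25 into training and
validation.  The tree arm fits, per questionnaire, a classification and a
regression tree, each with and without demographic predictors (four models
per questionnaire — 28 for the full seven-questionnaire battery), pruned by
10-fold cross-validated cost-complexity pruning.  The adaptive arm
calibrates a graded response model on the training data, maps the raw-score
class cutoffs onto the latent scale through the test characteristic curve,
and replays every validation respondent through the 95%-confidence
stopping rule.  Both arms are scored on the validation set against the
class from the fully observed questionnaire: one-vs-rest sensitivity and
specificity per class, RMSE and range-normalised NRMSE for regression
trees, and min/mean/max administered items with the implied percentage
questionnaire-length reduction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cart
from .cat import CATConfig, administer_cat, cat_length_stats
from .grm import calibrate_grm, score_cutoffs_to_theta
from .instruments import (
    Instrument,
    ResponseMatrix,
    classify_score,
    default_instruments,
    filter_complete,
    total_score,
)
from .splitting import SplitIndices, kfold_indices, split_train_validation
from .synthetic import SimulatedCohort, SimulationConfig, generate_cohort

__all__ = [
    "ClasswiseMetrics",
    "EvaluationConfig",
    "EvaluationReport",
    "one_vs_rest_sens_spec",
    "rmse_nrmse",
    "reduction_percentage",
    "run_comparison",
    "split_train_validation",
    "kfold_indices",
]

log = logging.getLogger(__name__)

NOT_APPLICABLE = None  # explicit marker: metric undefined for this cell


@dataclass(frozen=True)
class ClasswiseMetrics:
    """One-vs-rest sensitivity/specificity per class label."""

    sensitivity: dict[str, float | None]
    specificity: dict[str, float | None]
    support: dict[str, int]

    def mean_sensitivity(self) -> float:
        vals = [v for v in self.sensitivity.values() if v is not None]
        return float(np.mean(vals)) if vals else np.nan

    def mean_specificity(self) -> float:
        vals = [v for v in self.specificity.values() if v is not None]
        return float(np.mean(vals)) if vals else np.nan


def one_vs_rest_sens_spec(
    true_labels, predicted_labels, class_labels: list[str]
) -> ClasswiseMetrics:
    """Per-class sensitivity and specificity, each class against the rest.

    A class absent from the truth has no true positives to find; its
    sensitivity is reported as not-applicable rather than 0/0.
    """
    t = np.asarray([str(x) for x in true_labels])
    p = np.asarray([str(x) for x in predicted_labels])
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    known = set(class_labels)
    for v in np.unique(np.concatenate([t, p])):
        if v not in known:
            raise ValueError(f"unknown class label {v!r}")
    sens: dict[str, float | None] = {}
    spec: dict[str, float | None] = {}
    support: dict[str, int] = {}
    for c in class_labels:
        tp = int(((t == c) & (p == c)).sum())
        fn = int(((t == c) & (p != c)).sum())
        tn = int(((t != c) & (p != c)).sum())
        fp = int(((t != c) & (p == c)).sum())
        support[c] = tp + fn
        sens[c] = tp / (tp + fn) if (tp + fn) > 0 else NOT_APPLICABLE
        spec[c] = tn / (tn + fp) if (tn + fp) > 0 else NOT_APPLICABLE
    return ClasswiseMetrics(sensitivity=sens, specificity=spec, support=support)


def rmse_nrmse(true_scores, predicted_scores) -> tuple[float, float | None]:
    """Root mean squared error and its range-normalised form.

    NRMSE divides by the observed range of the true scores; with a
    constant truth the range is zero and NRMSE is not applicable.
    """
    t = np.asarray(true_scores, dtype=float)
    p = np.asarray(predicted_scores, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("score vectors must be non-empty and equal length")
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))
    rng = float(t.max() - t.min())
    nrmse = rmse / rng if rng > 0 else NOT_APPLICABLE
    return rmse, nrmse


def reduction_percentage(n_items: int, mean_administered: float) -> float:
    if not 0.0 <= mean_administered <= n_items:
        raise ValueError("mean administered items must lie in [0, n_items]")
    return 100.0 * (1.0 - mean_administered / n_items)


# ---------------------------------------------------------------------------
# full comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationConfig:
    seed: int = 0
    train_fraction: float = 0.75
    confidence: float = 0.95
    tree_params: cart.TreeParams | None = None
    min_training_cases: int = 200
    simulation: SimulationConfig | None = None


@dataclass
class MethodResult:
    """One instrument x method cell of the comparison grid."""

    instrument_id: str
    method: str  # "cat" | "classification_tree" | "regression_tree"
    with_demographics: bool
    metrics: ClasswiseMetrics
    rmse: float | None
    nrmse: float | None
    length: dict[str, float]
    extra: dict = field(default_factory=dict)


@dataclass
class EvaluationReport:
    config_echo: dict
    results: list[MethodResult]
    completion: dict[str, dict]
    n_tree_models: int
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for c in r.metrics.sensitivity:
                rows.append(
                    {
                        "instrument": r.instrument_id,
                        "method": r.method,
                        "with_demographics": r.with_demographics,
                        "class": c,
                        "sensitivity": r.metrics.sensitivity[c],
                        "specificity": r.metrics.specificity[c],
                        "support": r.metrics.support[c],
                        "rmse": r.rmse,
                        "nrmse": r.nrmse,
                        "min_items": r.length["min_items"],
                        "mean_items": r.length["mean_items"],
                        "max_items": r.length["max_items"],
                        "pct_decrease": r.length["pct_decrease"],
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": self.config_echo,
            "n_tree_models": self.n_tree_models,
            "skipped": self.skipped,
            "completion": self.completion,
            "results": [
                {
                    "instrument": r.instrument_id,
                    "method": r.method,
                    "with_demographics": r.with_demographics,
                    "sensitivity": r.metrics.sensitivity,
                    "specificity": r.metrics.specificity,
                    "support": r.metrics.support,
                    "rmse": r.rmse,
                    "nrmse": r.nrmse,
                    "length": r.length,
                    "extra": r.extra,
                }
                for r in self.results
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def method_summary(self) -> pd.DataFrame:
        """Mean sensitivity/specificity/length reduction per method."""
        rows = []
        for method in ("cat", "classification_tree", "regression_tree"):
            cells = [r for r in self.results if r.method == method
                     and not r.with_demographics]
            if not cells:
                continue
            sens = [v for r in cells for v in r.metrics.sensitivity.values()
                    if v is not None]
            spec = [v for r in cells for v in r.metrics.specificity.values()
                    if v is not None]
            rows.append(
                {
                    "method": method,
                    "mean_sensitivity": float(np.mean(sens)),
                    "mean_specificity": float(np.mean(spec)),
                    "mean_items": float(np.mean([r.length["mean_items"] for r in cells])),
                    "mean_pct_decrease": float(
                        np.mean([r.length["pct_decrease"] for r in cells])
                    ),
                }
            )
        return pd.DataFrame(rows)


def _scores_and_classes(
    matrix: ResponseMatrix, instrument: Instrument
) -> tuple[np.ndarray, np.ndarray]:
    values = matrix.data.to_numpy()
    scores = np.array([total_score(row, instrument) for row in values])
    classes = np.array([classify_score(s, instrument) for s in scores])
    return scores, classes


def _evaluate_tree_arm(
    instrument: Instrument,
    train_items: pd.DataFrame,
    valid_items: pd.DataFrame,
    train_demo: pd.DataFrame | None,
    valid_demo: pd.DataFrame | None,
    y_train_class: np.ndarray,
    y_train_score: np.ndarray,
    y_valid_class: np.ndarray,
    y_valid_score: np.ndarray,
    params: cart.TreeParams,
) -> list[MethodResult]:
    results = []
    item_set = set(train_items.columns)
    feature_sets: list[tuple[bool, pd.DataFrame, pd.DataFrame]] = [
        (False, train_items, valid_items)
    ]
    if train_demo is not None:
        feature_sets.append(
            (
                True,
                pd.concat([train_items, train_demo], axis=1),
                pd.concat([valid_items, valid_demo], axis=1),
            )
        )
    for kind, criterion in (("classification_tree", "gini"), ("regression_tree", "sse")):
        outcome_train = y_train_class if criterion == "gini" else y_train_score
        p = cart.TreeParams(
            criterion=criterion,
            min_node_size=params.min_node_size,
            min_leaf_size=params.min_leaf_size,
            cp=params.cp,
            max_depth=params.max_depth,
            cv_folds=params.cv_folds,
            seed=params.seed,
        )
        for with_demo, x_train, x_valid in feature_sets:
            tree = cart.grow_tree(x_train, outcome_train, p)
            pruned, _ = cart.cost_complexity_prune(tree, x_train, outcome_train, p)
            preds = cart.predict_batch(pruned, x_valid)
            if criterion == "gini":
                pred_class = preds.astype(str)
                rmse = nrmse = None
            else:
                pred_score = preds.astype(float)
                lo, hi = instrument.score_range
                pred_score = np.clip(pred_score, lo, hi)
                pred_class = np.array(
                    [classify_score(s, instrument) for s in pred_score]
                )
                rmse, nrmse = rmse_nrmse(y_valid_score, pred_score)
            metrics = one_vs_rest_sens_spec(
                y_valid_class, pred_class, instrument.class_labels
            )
            length = cart.tree_length_stats(
                pruned, x_valid, instrument.n_items, item_predictors=item_set
            )
            results.append(
                MethodResult(
                    instrument_id=instrument.id,
                    method=kind,
                    with_demographics=with_demo,
                    metrics=metrics,
                    rmse=rmse,
                    nrmse=nrmse,
                    length=length,
                    extra={
                        "n_leaves": len(pruned.leaves()),
                        "depth": pruned.depth(),
                        "predictors_used": sorted(pruned.predictors_used()),
                        "demographic_predictors_used": sorted(
                            pruned.predictors_used() - item_set
                        ),
                    },
                )
            )
    return results


def _evaluate_cat_arm(
    instrument: Instrument,
    train_values: np.ndarray,
    valid_values: np.ndarray,
    y_valid_class: np.ndarray,
    confidence: float,
) -> MethodResult:
    calib = calibrate_grm(train_values, instrument)
    cutoffs = score_cutoffs_to_theta(calib.bank, instrument)
    config = CATConfig(confidence=confidence)
    transcripts = [
        administer_cat(row, calib.bank, instrument, cutoffs, config, respondent_id=i)
        for i, row in enumerate(valid_values)
    ]
    pred_class = np.array([t.final_class for t in transcripts])
    metrics = one_vs_rest_sens_spec(
        y_valid_class, pred_class, instrument.class_labels
    )
    length = cat_length_stats(transcripts, instrument.n_items)
    return MethodResult(
        instrument_id=instrument.id,
        method="cat",
        with_demographics=False,
        metrics=metrics,
        rmse=None,
        nrmse=None,
        length=length,
        extra={
            "em_cycles": calib.n_cycles,
            "em_converged": calib.converged,
            "theta_cutoffs": list(cutoffs.cutoffs),
            "n_classified_early": int(
                sum(t.stop_reason == "classified" for t in transcripts)
            ),
        },
    )


def run_comparison(
    config: EvaluationConfig | None = None,
    cohort: SimulatedCohort | None = None,
    instruments: dict[str, Instrument] | None = None,
) -> EvaluationReport:
    """The full study pipeline on a cohort (synthetic unless supplied)."""
    config = config or EvaluationConfig()
    instruments = instruments or default_instruments()
    if cohort is None:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        cohort = generate_cohort(sim, instruments)
    tree_params = config.tree_params or cart.TreeParams(seed=config.seed)

    results: list[MethodResult] = []
    completion: dict[str, dict] = {}
    skipped: list[str] = []
    n_tree_models = 0

    for inst_id in sorted(instruments):
        instrument = instruments[inst_id]
        matrix = cohort.responses[inst_id]
        complete, report = filter_complete(matrix, instrument)
        completion[inst_id] = {
            "fully": report.n_fully,
            "missing": report.n_missing,
            "insufficient": report.n_insufficient,
            "pct_fully": report.pct_fully,
            "pct_missing": report.pct_missing,
            "pct_insufficient": report.pct_insufficient,
        }
        n = complete.n_respondents
        n_train_target = int(np.floor(config.train_fraction * n))
        if n_train_target < config.min_training_cases:
            log.warning("skipping %s: only %d training cases", inst_id, n_train_target)
            skipped.append(inst_id)
            continue

        split = split_train_validation(n, config.train_fraction, config.seed)
        values = complete.data.to_numpy()
        train_values = values[split.training]
        valid_values = values[split.validation]
        scores, classes = _scores_and_classes(complete, instrument)
        y_train_score, y_valid_score = scores[split.training], scores[split.validation]
        y_train_class, y_valid_class = classes[split.training], classes[split.validation]

        items_df = complete.data.reset_index(drop=True)
        train_items = items_df.iloc[split.training].reset_index(drop=True)
        valid_items = items_df.iloc[split.validation].reset_index(drop=True)
        demo = cohort.demographics.loc[complete.respondent_ids].reset_index(drop=True)
        train_demo = demo.iloc[split.training].reset_index(drop=True)
        valid_demo = demo.iloc[split.validation].reset_index(drop=True)

        tree_results = _evaluate_tree_arm(
            instrument,
            train_items,
            valid_items,
            train_demo,
            valid_demo,
            y_train_class,
            y_train_score,
            y_valid_class,
            y_valid_score,
            tree_params,
        )
        n_tree_models += len(tree_results)
        results.extend(tree_results)
        results.append(
            _evaluate_cat_arm(
                instrument,
                train_values,
                valid_values,
                y_valid_class,
                config.confidence,
            )
        )

    return EvaluationReport(
        config_echo={
            "seed": config.seed,
            "train_fraction": config.train_fraction,
            "confidence": config.confidence,
            "n_respondents": cohort.config.n_respondents,
            "simulation_seed": cohort.config.seed,
        },
        results=results,
        completion=completion,
        n_tree_models=n_tree_models,
        skipped=skipped,
    )
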