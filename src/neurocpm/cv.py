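"""Leave-one-out cross-validation of the CPM pipeline.

Each of the N subjects is held out once; edge selection, summary values
and both summary models are computed strictly on the remaining N - 1
subjects, and the held-out subject's score is predicted from their own
edge weights summed over the *training* networks. Folds where a network
is empty (nothing passed the threshold) predict the training score mean;
they count toward N rather than being dropped, and their count is
reported.

Per-fold association values and selection masks are retained because the
edge-ranking step aggregates them across all folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import core
from .io import Cohort

__all__ = [
    "FoldResult",
    "CvRun",
    "Evaluation",
    "loo_splits",
    "run_cpm_loo",
    "evaluate_predictions",
    "consistent_edges",
    "welch_t_test",
]

logger = logging.getLogger(__name__)

MIN_SUBJECTS = 6  # fewer leaves too little to fit the robust screen


@dataclass
class FoldResult:
    """Everything fitted with subject ``fold_index`` held out."""

    fold_index: int
    selection: core.EdgeSelectionResult
    pos_model: core.SummaryModel
    neg_model: core.SummaryModel
    pos_pred: float
    neg_pred: float


@dataclass
class CvRun:
    """Complete record of one leave-one-out pass over a cohort."""

    folds: list[FoldResult]
    observed: np.ndarray
    pos_predictions: np.ndarray
    neg_predictions: np.ndarray
    per_fold_r: np.ndarray  # N x E association values per training fold
    pos_masks: np.ndarray  # N x E bool
    neg_masks: np.ndarray  # N x E bool
    n_rois: int
    degenerate_pos_folds: int = 0
    degenerate_neg_folds: int = 0
    config: core.CpmConfig = field(default_factory=core.CpmConfig)

    def all_degenerate(self, side: str) -> bool:
        count = (
            self.degenerate_pos_folds if side == "positive" else self.degenerate_neg_folds
        )
        return count == self.n_folds

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class Evaluation:
    """Predicted-vs-observed agreement: Pearson r, r^2 and its p."""

    r: float
    r_squared: float
    p: float


def loo_splits(n_subjects: int):
    """The N leave-one-out splits; split k holds out subject k."""
    if n_subjects < MIN_SUBJECTS:
        raise ValueError(f"leave-one-out needs at least {MIN_SUBJECTS} subjects")
    all_idx = np.arange(n_subjects)
    return [
        (np.delete(all_idx, k), k)
        for k in range(n_subjects)
    ]


def run_cpm_loo(cohort: Cohort, config: core.CpmConfig | None = None) -> CvRun:
    """Run the full CPM leave-one-out loop over one cohort.

    The held-out subject's data never touches selection or model fitting;
    their summary values are computed over the masks selected on the
    training block only.
    """
    config = config or core.CpmConfig()
    X, y = cohort.edges, cohort.scores
    n, e = X.shape

    folds: list[FoldResult] = []
    pos_preds = np.empty(n)
    neg_preds = np.empty(n)
    per_fold_r = np.zeros((n, e))
    pos_masks = np.zeros((n, e), dtype=bool)
    neg_masks = np.zeros((n, e), dtype=bool)
    n_degen_pos = n_degen_neg = 0

    for train_idx, test_idx in loo_splits(n):
        try:
            selection = core.select_edges(
                X[train_idx], y[train_idx],
                alpha=config.alpha, method=config.method, config=config,
            )
        except ValueError as exc:
            raise ValueError(f"fold {test_idx}: {exc}") from exc

        pos_sum, neg_sum = core.summary_matrix(X[train_idx], selection, config.summary)
        # degenerate-fold warnings are counted and logged below instead
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos_model = core.fit_summary_model(pos_sum, y[train_idx], side="positive")
            neg_model = core.fit_summary_model(neg_sum, y[train_idx], side="negative")
        if pos_model.degenerate:
            n_degen_pos += 1
            logger.warning("fold %d: empty/constant positive network", test_idx)
        if neg_model.degenerate:
            n_degen_neg += 1
            logger.warning("fold %d: empty/constant negative network", test_idx)

        test_summary = core.summary_values(X[test_idx], selection, config.summary)
        pos_preds[test_idx] = core.predict_score(pos_model, test_summary.pos_sum)
        neg_preds[test_idx] = core.predict_score(neg_model, test_summary.neg_sum)

        per_fold_r[test_idx] = selection.association.r
        pos_masks[test_idx] = selection.pos_mask
        neg_masks[test_idx] = selection.neg_mask
        folds.append(
            FoldResult(
                fold_index=test_idx,
                selection=selection,
                pos_model=pos_model,
                neg_model=neg_model,
                pos_pred=float(pos_preds[test_idx]),
                neg_pred=float(neg_preds[test_idx]),
            )
        )
        logger.info(
            "fold %d: %d positive, %d negative edges selected",
            test_idx, int(selection.pos_mask.sum()), int(selection.neg_mask.sum()),
        )

    return CvRun(
        folds=folds,
        observed=y.copy(),
        pos_predictions=pos_preds,
        neg_predictions=neg_preds,
        per_fold_r=per_fold_r,
        pos_masks=pos_masks,
        neg_masks=neg_masks,
        n_rois=cohort.n_rois,
        degenerate_pos_folds=n_degen_pos,
        degenerate_neg_folds=n_degen_neg,
        config=config,
    )


def evaluate_predictions(predicted, observed) -> Evaluation:
    """Pearson r of predicted vs observed scores, its square, and its p.

    If every fold fell back to the mean the predictions are constant and
    carry no information: r = 0, p = 1 (with a warning).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be aligned 1-D vectors")
    if predicted.size < 3:
        raise ValueError("need at least 3 predictions to evaluate")
    if np.ptp(observed) == 0:
        raise ValueError("observed scores are constant")
    if np.ptp(predicted) == 0:
        logger.warning("constant predictions (all folds degenerate): r set to 0")
        return Evaluation(r=0.0, r_squared=0.0, p=1.0)
    r, p = core.pearson_association(predicted, observed)
    return Evaluation(r=r, r_squared=r * r, p=p)


def evaluate_cvrun(run: CvRun, side: str) -> Evaluation:
    """Evaluate one side of a finished run, honoring degenerate folds.

    When *every* fold fell back to the mean (the network was empty in all
    N training sets) the prediction vector carries nothing but the
    leave-one-out jitter of the training means — an artifact that is
    perfectly anti-correlated with the observed scores at slope -1/(N-1)
    despite containing no model at all. That case is reported as r = 0,
    p = 1 rather than a spurious |r| of 1.
    """
    preds = run.pos_predictions if side == "positive" else run.neg_predictions
    if run.all_degenerate(side):
        logger.warning(
            "all %d folds degenerate on the %s side: no model was ever fit; "
            "reporting r=0", run.n_folds, side,
        )
        return Evaluation(r=0.0, r_squared=0.0, p=1.0)
    return evaluate_predictions(preds, run.observed)


def consistent_edges(run: CvRun, side: str) -> np.ndarray:
    """Edges selected (on one side) in every single fold.

    The reported networks are the connections present across *all*
    leave-one-out runs; an edge missing from even one fold is excluded.
    """
    masks = _side_masks(run, side)
    return masks.all(axis=0)


def _side_masks(run: CvRun, side: str) -> np.ndarray:
    if side == "positive":
        return run.pos_masks
    if side == "negative":
        return run.neg_masks
    raise ValueError("side must be 'positive' or 'negative'")


def welch_t_test(mean1, sd1, n1, mean2, sd2, n2):
    """Two-tailed two-sample t-test from summary statistics.

    Unequal-variance (Welch) form with Welch-Satterthwaite degrees of
    freedom; used to compare cohort demographics (age, FIQ, VIQ) between
    groups. Returns (t, df, p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)
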