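"""Normalized-rank edge scoring across all leave-one-out folds.

Because edge selection is re-run inside every fold, the selected
networks can differ from fold to fold. Each edge f_k is therefore scored
by its selection-weighted mean absolute association across the N folds:

    score(f_k) = ( sum over folds i of  delta_i(f_k) * |r_i(f_k)| ) / N

where delta_i(f_k) = 1 if the edge was selected (on the given side) in
fold i and 0 otherwise, and r_i(f_k) is that fold's association value.
An edge selected in every fold with |r| = 1 scores 1; an edge never
selected scores 0. Positive and negative networks are ranked
independently, and the top five edges per side are the reported
connections.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cv import CvRun, _side_masks, evaluate_predictions
from .io import AtlasLabels, edge_index_to_pair, edge_to_roi_pair, load_aal_labels

__all__ = [
    "EdgeRanking",
    "normalized_rank",
    "rank_oracle",
    "top_k_edges",
    "write_report",
    "DEFAULT_TOP_K",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 5

TOP_EDGES_COLUMNS = ["rank", "edge_index", "roi_i", "roi_j", "score", "folds_selected"]


@dataclass
class EdgeRanking:
    """Per-edge normalized rank scores for one side of the model."""

    scores: np.ndarray  # length E, each in [0, 1]
    side: str
    n_folds: int
    folds_selected: np.ndarray  # per-edge selection count across folds


def normalized_rank(run: CvRun, side: str) -> EdgeRanking:
    """Selection-weighted mean |association| per edge over all folds."""
    masks = _side_masks(run, side)
    scores = (masks * np.abs(run.per_fold_r)).sum(axis=0) / run.n_folds
    return EdgeRanking(
        scores=scores,
        side=side,
        n_folds=run.n_folds,
        folds_selected=masks.sum(axis=0),
    )


def rank_oracle(run: CvRun, side: str, edge: int) -> float:
    """Brute-force recomputation of one edge's normalized rank.

    Explicit loop over folds and stored selections; must agree exactly
    with :func:`normalized_rank`.
    """
    masks = _side_masks(run, side)
    total = 0.0
    for i in range(run.n_folds):
        if masks[i, edge]:
            total += abs(run.per_fold_r[i, edge])
    return total / run.n_folds


def top_k_edges(
    ranking: EdgeRanking,
    k: int,
    labels: AtlasLabels,
    n_rois: int,
) -> pd.DataFrame:
    """Top-k edges by normalized rank, with ROI-pair display names.

    Ties break by ascending edge index so reports are byte-stable.
    Edges never selected (score 0) are not ranked; if fewer than k edges
    were ever selected the table is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nonzero = np.flatnonzero(ranking.scores > 0)
    if nonzero.size < k:
        warnings.warn(
            f"only {nonzero.size} {ranking.side}-side edges were ever "
            f"selected; truncating top-{k} table",
            stacklevel=2,
        )
    # stable sort on (-score, edge_index)
    order = nonzero[np.lexsort((nonzero, -ranking.scores[nonzero]))][:k]
    rows = []
    for position, edge in enumerate(order, start=1):
        roi_i, roi_j = edge_to_roi_pair(int(edge), n_rois, labels)
        rows.append(
            {
                "rank": position,
                "edge_index": int(edge),
                "roi_i": roi_i,
                "roi_j": roi_j,
                "score": float(ranking.scores[edge]),
                "folds_selected": int(ranking.folds_selected[edge]),
            }
        )
    return pd.DataFrame(rows, columns=TOP_EDGES_COLUMNS)


def write_report(
    run: CvRun,
    rankings: dict[str, EdgeRanking],
    tables: dict[str, pd.DataFrame],
    out_dir,
) -> dict[str, Path]:
    """Write the per-side report artifacts for one cross-validated run.

    Per side: a top-edges CSV, a full ranking CSV and an edge-list TSV
    (``roi_i  roi_j  score``, nonzero-score edges only) consumable by
    connectogram tools; plus one evaluation JSON covering both sides.
    Outputs are deterministic for a fixed run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for side, ranking in rankings.items():
        table = tables[side]
        top_path = out_dir / f"top_edges_{side}.csv"
        table.to_csv(top_path, index=False)
        paths[f"top_edges_{side}"] = top_path

        full = pd.DataFrame(
            {
                "edge_index": np.arange(ranking.scores.size),
                "score": ranking.scores,
                "folds_selected": ranking.folds_selected,
            }
        )
        full_path = out_dir / f"ranking_{side}.csv"
        full.to_csv(full_path, index=False)
        paths[f"ranking_{side}"] = full_path

        edge_list_path = out_dir / f"edge_list_{side}.tsv"
        nonzero = np.flatnonzero(ranking.scores > 0)
        with open(edge_list_path, "w") as fh:
            fh.write("roi_i\troi_j\tscore\n")
            if nonzero.size and run.n_rois == 116:
                atlas = load_aal_labels()
                for edge in nonzero:
                    roi_i, roi_j = edge_to_roi_pair(int(edge), run.n_rois, atlas)
                    fh.write(f"{roi_i}\t{roi_j}\t{ranking.scores[edge]:.12g}\n")
            else:
                for edge in nonzero:
                    i, j = edge_index_to_pair(int(edge), run.n_rois)
                    fh.write(f"ROI{i + 1}\tROI{j + 1}\t{ranking.scores[edge]:.12g}\n")
        paths[f"edge_list_{side}"] = edge_list_path

    evaluation = {
        "positive": vars(evaluate_predictions(run.pos_predictions, run.observed)),
        "negative": vars(evaluate_predictions(run.neg_predictions, run.observed)),
        "n_folds": run.n_folds,
        "degenerate_pos_folds": run.degenerate_pos_folds,
        "degenerate_neg_folds": run.degenerate_neg_folds,
    }
    eval_path = out_dir / "evaluation.json"
    with open(eval_path, "w") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["evaluation"] = eval_path
    return paths
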