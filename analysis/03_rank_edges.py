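#!/usr/bin/env python
"""Rank edges across all leave-one-out folds and report the top five.

Scores every edge by its normalized rank — selection-frequency-weighted
mean absolute association across folds — separately for the positive and
negative networks, maps the top five per side to AAL ROI-pair names, and
checks them against the planted ground truth. Writes the report tables
to results/.
"""

import pickle
import sys
from pathlib import Path

import neurocpm as cpm
from neurocpm.ranking import normalized_rank, top_k_edges, write_report
from neurocpm.synthetic import read_ground_truth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    labels = cpm.load_aal_labels()
    for name in ("asd_fiq", "nt_fiq"):
        pkl = ROOT / "scratch" / f"cvrun_{name}.pkl"
        if not pkl.exists():
            print(f"missing {pkl}; run 02_run_cpm.py first")
            return 1
        with open(pkl, "rb") as fh:
            run = pickle.load(fh)

        rankings, tables = {}, {}
        for side in ("positive", "negative"):
            rankings[side] = normalized_rank(run, side)
            tables[side] = top_k_edges(rankings[side], 5, labels, 116)
        write_report(run, rankings, tables, ROOT / "results" / f"report_{name}")

        truth_pos, truth_neg = read_ground_truth(
            ROOT / "scratch" / "cohorts" / name / "ground_truth.tsv"
        )
        print(f"\n=== {name} ===")
        for side, planted in (("positive", truth_pos), ("negative", truth_neg)):
            table = tables[side]
            hits = set(table["edge_index"]) & set(planted)
            print(f"top-5 {side} edges ({len(hits)}/5 are planted):")
            print(table.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
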