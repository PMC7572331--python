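#!/usr/bin/env python
"""Run the leave-one-out CPM analysis on both simulated cohorts.

For each cohort: per-fold robust (Huber IRLS) edge screening at
p < 0.01, sign-split network summary values, univariate positive and
negative prediction models, and out-of-fold score prediction for every
subject. Writes predictions and evaluation statistics to results/ and
the full cross-validation record (needed by the ranking step) to
scratch/.
"""

import json
import pickle
import sys
import time
from pathlib import Path

import pandas as pd

import neurocpm as cpm
from neurocpm.cv import evaluate_cvrun

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name in ("asd_fiq", "nt_fiq"):
        manifest = ROOT / "scratch" / "cohorts" / name / "manifest.tsv"
        if not manifest.exists():
            print(f"missing {manifest}; run 01_simulate_cohorts.py first")
            return 1
        cohort = cpm.read_cohort(manifest, "FIQ")
        t0 = time.time()
        run = cpm.run_cpm_loo(cohort)  # robust screen, alpha=0.01
        elapsed = time.time() - t0

        pd.DataFrame(
            {
                "subject_id": cohort.subject_ids,
                "observed": run.observed,
                "pos_pred": run.pos_predictions,
                "neg_pred": run.neg_predictions,
            }
        ).to_csv(results / f"predictions_{name}.csv", index=False)

        evaluation = {}
        for side in ("positive", "negative"):
            ev = evaluate_cvrun(run, side)
            evaluation[side] = vars(ev)
            print(f"{name} {side} model: r={ev.r:.3f}, r^2={ev.r_squared:.3f}, "
                  f"p={ev.p:.3g}")
        evaluation["n_subjects"] = run.n_folds
        evaluation["degenerate_pos_folds"] = run.degenerate_pos_folds
        evaluation["degenerate_neg_folds"] = run.degenerate_neg_folds
        with open(results / f"evaluation_{name}.json", "w") as fh:
            json.dump(evaluation, fh, indent=2, sort_keys=True)
            fh.write("\n")

        with open(ROOT / "scratch" / f"cvrun_{name}.pkl", "wb") as fh:
            pickle.dump(run, fh)
        print(f"{name}: {run.n_folds} folds in {elapsed:.0f}s")
    return 0


if __name__ == "__main__":
    sys.exit(main())
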