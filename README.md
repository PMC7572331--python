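# neurocpm

Connectome-based predictive modelling (CPM) of intelligence scores from
functional connectomes, for researchers studying brain–behavior
relationships in neurotypical and autism-spectrum populations — plus a
seeded synthetic cohort generator so every stage of the pipeline can be
exercised, calibrated and stress-tested without access to a clinical
dataset.

## The method

A functional connectome is a symmetric R × R matrix (R = 116 AAL
regions) of correlations between regional resting-state fMRI signals;
its E = R(R−1)/2 upper-triangle entries ("edges") are the features. For
a cohort of N subjects with scores y, under leave-one-out
cross-validation the pipeline, per training set:

1. regresses y on each edge weight with a Huber IRLS robust regression
   and keeps edges with slope-test p < 0.01 (raw threshold, no
   multiple-testing correction);
2. splits the selected edges by association sign into a *positive* and
   a *negative network*;
3. collapses each subject to two summary values — the sum of their edge
   weights over each network — and fits one line per network mapping
   summary value to score;
4. predicts the held-out subject's score from their own summary values
   over the training networks.

Prediction quality is the Pearson r (and r²) between out-of-fold
predictions and observed scores, reported separately for the positive
and negative models. Finally each edge f_k is scored by its
**normalized rank** across folds,

    score(f_k) = ( Σ_i δ_i(f_k) · |r_i(f_k)| ) / N ,

(δ_i = selection indicator in fold i), and the top five edges per side,
mapped to AAL ROI-pair names, are the reported connections. See
`docs/methods.md` for estimator details, conventions and limitations.

## Worked example

The analysis scripts simulate two full-atlas cohorts (ASD-like:
N = 202, FIQ 106.5 ± 15.2; NT-like: N = 226, FIQ 111.7 ± 12.0; five
positively- and five negatively-coupled edges planted per cohort at a
population edge–score correlation of 0.4) and run the full pipeline:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_run_cpm.py
python analysis/03_rank_edges.py
python analysis/04_calibration_and_robustness.py
```

Output of the run committed under `results/`:

```
asd_fiq positive model: r=0.499, r^2=0.249, p=4.12e-14
asd_fiq negative model: r=0.341, r^2=0.116, p=7.05e-07
nt_fiq  positive model: r=0.421, r^2=0.177, p=4.03e-11
nt_fiq  negative model: r=0.157, r^2=0.025, p=0.0178
```

i.e. the out-of-fold predictions of the positive model explain ~25% of
FIQ variance in the ASD-like cohort, and all twenty planted edges are
recovered: the top-5 normalized-rank tables per side contain only
planted edges, each selected in every single fold, e.g.

```
rank  edge_index   roi_i   roi_j    score  folds_selected
   1        2091   SMA.R   C45.R 0.487602             202
```

(the strongest positive ASD-like edge links the right supplementary
motor area to right cerebellar lobule IV–V, with a mean absolute
association of 0.49 across all 202 folds). The calibration script
confirms the screen's type-I error sits at the nominal level
(selection rate 0.0089 Pearson / 0.0099 robust at α = 0.01 on
pure-noise cohorts) and that gross score outliers move the robust
slopes about a third as much as the OLS slopes (ratio 0.37).

The same pipeline is scriptable on any cohort laid out as per-subject
connectome CSVs plus a TSV manifest:

```bash
cpm simulate --n-subjects 150 --n-rois 20 --seed 1 --out demo/
cpm run --manifest demo/manifest.tsv --target fiq --out demo_run/
cpm rank --run-dir demo_run/ --k 5 --out demo_report/
```

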