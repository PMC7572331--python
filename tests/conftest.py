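import numpy as np
import pytest

import neurocpm as cpm
from neurocpm.cv import CvRun, FoldResult


@pytest.fixture(scope="session")
def aal_labels():
    return cpm.load_aal_labels()


@pytest.fixture(scope="session")
def planted_cohort():
    """One seeded draw of the default planted-signal cohort (N=150, R=20)."""
    spec = cpm.SyntheticSpec(seed=42)
    return cpm.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast, high-SNR planted cohort for pipeline-level unit tests."""
    spec = cpm.SyntheticSpec(
        n_subjects=40, n_rois=8, n_pos_edges=3, n_neg_edges=3,
        effect=cpm.effect_for_correlation(0.7, 0.2), seed=7,
    )
    return cpm.generate_cohort(spec)


def make_random_cvrun(rng, n_folds=6, n_edges_=15, n_rois=6):
    """A CvRun with arbitrary association values and selection masks.

    Only the fields the ranking step reads are meaningful.
    """
    per_fold_r = rng.uniform(-1, 1, size=(n_folds, n_edges_))
    pos_masks = rng.random((n_folds, n_edges_)) < 0.3
    neg_masks = ~pos_masks & (rng.random((n_folds, n_edges_)) < 0.3)
    observed = rng.normal(100, 15, size=n_folds)
    return CvRun(
        folds=[
            FoldResult(fold_index=i, selection=None, pos_model=None,
                       neg_model=None, pos_pred=0.0, neg_pred=0.0)
            for i in range(n_folds)
        ],
        observed=observed,
        pos_predictions=observed + rng.normal(0, 5, size=n_folds),
        neg_predictions=observed + rng.normal(0, 5, size=n_folds),
        per_fold_r=per_fold_r,
        pos_masks=pos_masks,
        neg_masks=neg_masks,
        n_rois=n_rois,
    )
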