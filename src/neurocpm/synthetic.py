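"""Synthetic connectome cohorts with planted brain-behavior structure.

The generator produces exactly the statistical structure CPM assumes and
nothing more: a continuous intelligence-like score, a small set of edges
whose strengths are linearly coupled to that score (with both positive
and negative coupling signs), independent Gaussian background variation
on every other edge, and — optionally — gross corruption of a fraction
of the *recorded* scores, the failure mode robust regression defends
against.

Generative model, for subject i and edge k (single seeded RNG stream):

1. latent score  y_i ~ Normal(score_mean, score_sd)
2. standardize   z_i = (y_i - score_mean) / score_sd
3. background    w_ik ~ Normal(0, edge_noise_sd), independent
4. planted positive edges: w_ik += effect * z_i
   planted negative edges: w_ik -= effect * z_i
5. squash        w_ik <- tanh(w_ik)   (keeps weights in (-1, 1))
6. assemble symmetric matrices with unit diagonal
7. corrupt floor(outlier_fraction * N) recorded scores by
   +/- outlier_shift * score_sd, alternating sign

Before the tanh squash, the population correlation between a planted
edge and the score is effect / sqrt(effect^2 + edge_noise_sd^2); the
helper :func:`effect_for_correlation` inverts this to calibrate the
coupling. Matrices are symmetric, unit-diagonal and elementwise in
(-1, 1) but not guaranteed positive semidefinite — CPM treats edges as
independent features, so no step relies on PSD-ness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Cohort, PhenotypeRecord, n_edges, unvectorize

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "effect_for_correlation",
    "generate_cohort",
    "generate_null_cohort",
    "write_cohort",
    "read_ground_truth",
]

#: target population edge-score correlation of a planted edge
DEFAULT_PLANTED_CORRELATION = 0.4
#: background edge variability on the Fisher-ish pre-tanh scale
DEFAULT_EDGE_NOISE_SD = 0.2


def effect_for_correlation(rho: float, edge_noise_sd: float) -> float:
    """Coupling beta giving population corr(edge, score) = rho (pre-tanh).

    From corr = beta / sqrt(beta^2 + sigma_e^2) for a standardized score.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    return rho * edge_noise_sd / math.sqrt(1.0 - rho * rho)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic cohort draw.

    Defaults emulate an ASD-like study population: score distribution
    106.5 +/- 15.2 points, 150 subjects, and ten planted edges (five per
    sign) calibrated to a population edge-score correlation of 0.4.
    """

    n_subjects: int = 150
    n_rois: int = 20
    n_pos_edges: int = 5
    n_neg_edges: int = 5
    effect: float = effect_for_correlation(
        DEFAULT_PLANTED_CORRELATION, DEFAULT_EDGE_NOISE_SD
    )
    edge_noise_sd: float = DEFAULT_EDGE_NOISE_SD
    score_mean: float = 106.5
    score_sd: float = 15.2
    outlier_fraction: float = 0.0
    outlier_shift: float = 5.0
    seed: int = 0
    group: str = "ASD"
    target: str = "FIQ"

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_rois < 3:
            raise ValueError("need at least 2 subjects and 3 ROIs")
        if self.n_pos_edges < 0 or self.n_neg_edges < 0:
            raise ValueError("planted edge counts must be non-negative")
        if self.n_pos_edges + self.n_neg_edges > n_edges(self.n_rois):
            raise ValueError("more planted edges than edges available")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if self.edge_noise_sd <= 0 or self.score_sd <= 0:
            raise ValueError("edge_noise_sd and score_sd must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Oracle record of what was planted, for recovery tests."""

    pos_edge_indices: tuple[int, ...]
    neg_edge_indices: tuple[int, ...]
    true_scores: np.ndarray
    outlier_ids: tuple[str, ...]

    def __post_init__(self):
        if set(self.pos_edge_indices) & set(self.neg_edge_indices):
            raise ValueError("planted positive and negative edges must be disjoint")


def generate_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort from the generative model. Same spec => same bytes."""
    rng = np.random.default_rng(spec.seed)
    n, e = spec.n_subjects, n_edges(spec.n_rois)

    # planted edge indices: without replacement, positive drawn before negative
    planted = rng.choice(e, size=spec.n_pos_edges + spec.n_neg_edges, replace=False)
    pos_idx = np.sort(planted[: spec.n_pos_edges])
    neg_idx = np.sort(planted[spec.n_pos_edges:])

    y = rng.normal(spec.score_mean, spec.score_sd, size=n)
    z = (y - spec.score_mean) / spec.score_sd
    weights = rng.normal(0.0, spec.edge_noise_sd, size=(n, e))
    weights[:, pos_idx] += spec.effect * z[:, None]
    weights[:, neg_idx] -= spec.effect * z[:, None]
    weights = np.tanh(weights)

    recorded = y.copy()
    n_out = int(spec.outlier_fraction * n)
    out_positions = np.sort(rng.choice(n, size=n_out, replace=False)) if n_out else np.array([], dtype=int)
    for rank, pos in enumerate(out_positions):
        sign = 1.0 if rank % 2 == 0 else -1.0
        recorded[pos] += sign * spec.outlier_shift * spec.score_sd

    subject_ids = [f"sim{idx:04d}" for idx in range(n)]
    phenotypes = [
        PhenotypeRecord(
            subject_id=sid,
            group=spec.group,
            age=math.nan,
            fiq=float(score) if spec.target == "FIQ" else math.nan,
            viq=float(score) if spec.target == "VIQ" else math.nan,
        )
        for sid, score in zip(subject_ids, recorded)
    ]
    cohort = Cohort(
        subject_ids=subject_ids,
        edges=weights,
        scores=recorded,
        n_rois=spec.n_rois,
        target=spec.target,
        group=spec.group,
        phenotypes=phenotypes,
    )
    truth = GroundTruth(
        pos_edge_indices=tuple(int(i) for i in pos_idx),
        neg_edge_indices=tuple(int(i) for i in neg_idx),
        true_scores=y,
        outlier_ids=tuple(subject_ids[int(i)] for i in out_positions),
    )
    return cohort, truth


def generate_null_cohort(n_subjects: int, n_rois: int, seed: int) -> Cohort:
    """Cohort with no planted signal at all (effect = 0, no outliers)."""
    if n_subjects < 10 or n_rois < 3:
        raise ValueError("null cohort needs N >= 10 and R >= 3")
    spec = SyntheticSpec(
        n_subjects=n_subjects,
        n_rois=n_rois,
        n_pos_edges=0,
        n_neg_edges=0,
        effect=0.0,
        outlier_fraction=0.0,
        seed=seed,
    )
    cohort, _ = generate_cohort(spec)
    return cohort


def write_cohort(
    cohort: Cohort,
    ground_truth: GroundTruth | None,
    directory,
    spec: SyntheticSpec | None = None,
) -> Path:
    """Write per-subject connectome CSVs, a manifest TSV and a sidecar.

    The layout round-trips exactly through :func:`neurocpm.io.read_cohort`
    (weights written with 17 significant digits). The ground-truth sidecar
    is a TSV ``edge_index  sign`` with the generating spec embedded as a
    ``# key=value ...`` comment line.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    conn_dir = directory / "connectomes"
    conn_dir.mkdir(exist_ok=True)

    rows = []
    for idx, (sid, pheno) in enumerate(zip(cohort.subject_ids, cohort.phenotypes)):
        matrix = unvectorize(cohort.edges[idx], cohort.n_rois)
        rel = Path("connectomes") / f"{sid}.csv"
        np.savetxt(directory / rel, matrix.values, delimiter=",", fmt="%.17g")
        rows.append(
            {
                "subject_id": sid,
                "connectome_path": str(rel),
                "group": pheno.group,
                "age": "NA" if math.isnan(pheno.age) else repr(pheno.age),
                "fiq": "NA" if math.isnan(pheno.fiq) else repr(pheno.fiq),
                "viq": "NA" if math.isnan(pheno.viq) else repr(pheno.viq),
            }
        )
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)

    if ground_truth is not None:
        sidecar = directory / "ground_truth.tsv"
        with open(sidecar, "w") as fh:
            if spec is not None:
                kv = " ".join(f"{k}={v}" for k, v in asdict(spec).items())
                fh.write(f"# {kv}\n")
            fh.write("edge_index\tsign\n")
            for k in ground_truth.pos_edge_indices:
                fh.write(f"{k}\t+1\n")
            for k in ground_truth.neg_edge_indices:
                fh.write(f"{k}\t-1\n")
    return manifest


def read_ground_truth(path) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Planted (positive, negative) edge indices from a sidecar TSV."""
    table = pd.read_csv(path, sep="\t", comment="#")
    pos = tuple(int(k) for k in table.loc[table["sign"] > 0, "edge_index"])
    neg = tuple(int(k) for k in table.loc[table["sign"] < 0, "edge_index"])
    return pos, neg
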