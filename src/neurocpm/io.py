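"""Connectome matrices, edge vectors, cohort manifests and atlas labels.

A functional connectome is a symmetric R x R matrix of correlation-like
connection strengths between brain regions (ROIs); the AAL atlas used for
reporting has R = 116. The feature unit of connectome-based predictive
modelling is the *edge*: one off-diagonal entry of the matrix. Edges are
stored in a fixed vectorized order — the strict upper triangle, row-major,
0-based: (0,1), (0,2), ..., (0,R-1), (1,2), ... — so that selection masks
and rank scores are comparable across modules.

File formats are deliberately plain: one square numeric CSV per subject
(no header) and a TSV cohort manifest with columns
``subject_id  connectome_path  group  age  fiq  viq`` (``NA`` for missing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeMatrix",
    "PhenotypeRecord",
    "Cohort",
    "AtlasLabels",
    "ConnectomeFormatError",
    "ConnectomeValidationError",
    "read_connectome",
    "vectorize",
    "unvectorize",
    "n_edges",
    "edge_index_to_pair",
    "pair_to_edge_index",
    "edge_to_roi_pair",
    "load_aal_labels",
    "read_cohort",
]

logger = logging.getLogger(__name__)

GROUPS = ("ASD", "NT")
TARGETS = ("FIQ", "VIQ")

#: asymmetry beyond this is a validation error; below it, matrices are
#: symmetrized by averaging (file round-trips of correlation matrices
#: introduce last-digit noise)
ASYMMETRY_TOLERANCE = 1e-6


class ConnectomeFormatError(ValueError):
    """Input file is not a square numeric matrix."""


class ConnectomeValidationError(ValueError):
    """Matrix content violates a connectome invariant (symmetry, NaN...)."""


@dataclass(frozen=True)
class ConnectomeMatrix:
    """One subject's R x R symmetric functional connectivity matrix."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectomeFormatError(f"matrix must be square, got shape {v.shape}")
        if np.isnan(v).any():
            i, j = np.argwhere(np.isnan(v))[0]
            raise ConnectomeValidationError(f"NaN entry at cell ({i}, {j})")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PhenotypeRecord:
    """One subject's phenotype row: group membership and IQ scores.

    ``age``, ``fiq`` and ``viq`` may be NaN (missing); missingness is
    handled per target score when the cohort is assembled.
    """

    subject_id: str
    group: str
    age: float = math.nan
    fiq: float = math.nan
    viq: float = math.nan

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    def score(self, target: str) -> float:
        return self.fiq if target == "FIQ" else self.viq


@dataclass
class Cohort:
    """Aligned connectomes + phenotypes for one population and one target.

    ``edges`` is the N x E matrix of vectorized connectomes; ``scores`` is
    the target score vector with no missing values (subjects missing the
    target are excluded at construction time). Models are
    population-specific, so a cohort holds a single group.
    """

    subject_ids: list[str]
    edges: np.ndarray  # N x E
    scores: np.ndarray  # N
    n_rois: int
    target: str
    group: str
    phenotypes: list[PhenotypeRecord] = field(default_factory=list)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.subject_ids)
        if self.edges.shape != (n, n_edges(self.n_rois)):
            raise ValueError(
                f"edges shape {self.edges.shape} inconsistent with "
                f"{n} subjects and R={self.n_rois}"
            )
        if self.scores.shape != (n,):
            raise ValueError("scores must align with subjects")
        if np.isnan(self.scores).any():
            raise ValueError("cohort scores must not contain missing values")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_id in cohort")
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]


@dataclass(frozen=True)
class AtlasLabels:
    """ROI display names, indexed 0-based internally (displayed 1-based)."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("atlas labels must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, i: int) -> str:
        return self.names[i]


def n_edges(n_rois: int) -> int:
    """Number of unordered ROI pairs: R(R-1)/2."""
    return n_rois * (n_rois - 1) // 2


def read_connectome(path, expect_rois: int | None = None) -> ConnectomeMatrix:
    """Read one subject's connectome from a headerless numeric text file.

    Accepts comma- or whitespace-delimited square matrices. Asymmetry up to
    ``ASYMMETRY_TOLERANCE`` is repaired by averaging M and M^T; beyond it,
    a validation error names the worst cell.
    """
    path = Path(path)
    try:
        raw = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        try:
            raw = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ConnectomeFormatError(f"{path}: not a numeric matrix: {exc}") from exc
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ConnectomeFormatError(f"{path}: matrix must be square, got {raw.shape}")
    if np.isnan(raw).any():
        i, j = np.argwhere(np.isnan(raw))[0]
        raise ConnectomeValidationError(f"{path}: NaN entry at cell ({i}, {j})")
    asym = np.abs(raw - raw.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > ASYMMETRY_TOLERANCE:
        cell = (int(worst[0]), int(worst[1]))
        raise ConnectomeValidationError(
            f"{path}: asymmetry {float(asym[worst]):.3g} at cell {cell} exceeds "
            f"tolerance {ASYMMETRY_TOLERANCE:g}"
        )
    values = (raw + raw.T) / 2.0
    if expect_rois is not None and values.shape[0] != expect_rois:
        raise ConnectomeFormatError(
            f"{path}: expected {expect_rois} ROIs, got {values.shape[0]}"
        )
    return ConnectomeMatrix(values)


def vectorize(matrix: ConnectomeMatrix) -> np.ndarray:
    """Strict-upper-triangle edge vector (length R(R-1)/2), row-major."""
    v = matrix.values
    iu, ju = np.triu_indices(v.shape[0], k=1)
    return v[iu, ju].copy()


def unvectorize(edges: np.ndarray, n_rois: int) -> ConnectomeMatrix:
    """Inverse of :func:`vectorize`; the diagonal is regenerated as 1."""
    edges = np.asarray(edges, dtype=float)
    expected = n_edges(n_rois)
    if edges.shape != (expected,):
        raise ValueError(
            f"edge vector length {edges.shape} does not match R={n_rois} "
            f"(expected {expected})"
        )
    m = np.eye(n_rois)
    iu, ju = np.triu_indices(n_rois, k=1)
    m[iu, ju] = edges
    m[ju, iu] = edges
    return ConnectomeMatrix(m)


def edge_index_to_pair(edge_index: int, n_rois: int) -> tuple[int, int]:
    """Map an edge index to its (i, j), i < j, under the fixed ordering."""
    e = n_edges(n_rois)
    if not 0 <= edge_index < e:
        raise IndexError(f"edge index {edge_index} out of range [0, {e})")
    # row i holds (R-1-i) edges starting at offset i*R - i*(i+1)/2
    i = 0
    offset = 0
    while edge_index >= offset + (n_rois - 1 - i):
        offset += n_rois - 1 - i
        i += 1
    j = i + 1 + (edge_index - offset)
    return i, j


def pair_to_edge_index(i: int, j: int, n_rois: int) -> int:
    """Edge index of the unordered pair {i, j} (order-insensitive)."""
    if i == j:
        raise ValueError("diagonal cells are not edges")
    if i > j:
        i, j = j, i
    if not 0 <= i < j < n_rois:
        raise IndexError(f"pair ({i}, {j}) out of range for R={n_rois}")
    return i * n_rois - i * (i + 1) // 2 + (j - i - 1)


def edge_to_roi_pair(
    edge_index: int, n_rois: int, labels: AtlasLabels
) -> tuple[str, str]:
    """ROI display names for one edge, e.g. ``('Ling.R', 'SPG.R')``."""
    if len(labels) != n_rois:
        raise ValueError(f"label table has {len(labels)} entries, R={n_rois}")
    i, j = edge_index_to_pair(edge_index, n_rois)
    return labels[i], labels[j]


def load_aal_labels() -> AtlasLabels:
    """The packaged AAL-116 ROI abbreviation table (standard numbering)."""
    ref = resources.files("neurocpm.data").joinpath("aal116_labels.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    names = tuple(table.sort_values("index")["label"])
    if len(names) != 116:
        raise RuntimeError("packaged AAL table must have 116 rows")
    return AtlasLabels(names)


MANIFEST_COLUMNS = ["subject_id", "connectome_path", "group", "age", "fiq", "viq"]


def read_cohort(manifest, target: str) -> Cohort:
    """Load a cohort from a TSV manifest, excluding missing-target subjects.

    The manifest's ``connectome_path`` entries are resolved relative to the
    manifest's own directory. Subject order is preserved after exclusions;
    the number of excluded subjects is logged (summary statistics in the
    source cohorts are likewise computed after dropping missing phenotype
    values).
    """
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t", dtype={"subject_id": str}, na_values=["NA"])
    missing_cols = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ConnectomeFormatError(f"{manifest}: missing columns {sorted(missing_cols)}")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{manifest}: duplicate subject_id {dupes}")
    groups = set(table["group"])
    if len(groups) != 1:
        raise ValueError(f"{manifest}: cohort must hold a single group, got {groups}")
    (group,) = groups

    score_col = target.lower()
    present = table[score_col].notna()
    n_excluded = int((~present).sum())
    if n_excluded:
        logger.info(
            "excluding %d of %d subjects with missing %s",
            n_excluded, len(table), target,
        )
    kept = table[present]
    if kept.empty:
        raise ValueError(f"{manifest}: no subjects with a recorded {target} score")

    phenotypes, vectors = [], []
    n_rois = None
    for row in kept.itertuples(index=False):
        conn_path = Path(row.connectome_path)
        if not conn_path.is_absolute():
            conn_path = manifest.parent / conn_path
        matrix = read_connectome(conn_path, expect_rois=n_rois)
        if n_rois is None:
            n_rois = matrix.n_rois
        phenotypes.append(
            PhenotypeRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                age=float(row.age) if pd.notna(row.age) else math.nan,
                fiq=float(row.fiq) if pd.notna(row.fiq) else math.nan,
                viq=float(row.viq) if pd.notna(row.viq) else math.nan,
            )
        )
        vectors.append(vectorize(matrix))

    return Cohort(
        subject_ids=[p.subject_id for p in phenotypes],
        edges=np.vstack(vectors),
        scores=kept[score_col].to_numpy(dtype=float),
        n_rois=n_rois,
        target=target,
        group=group,
        phenotypes=phenotypes,
    )
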