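"""Per-training-set CPM computation: edge screening and summary models.

The method treats every connectome edge as an independent candidate
feature. On a training set of n subjects it

1. associates each edge's weight vector with the behavioral score —
   either plain Pearson correlation or a robust (Huber IRLS) regression
   that down-weights outlying subjects;
2. keeps edges with a two-tailed p below a raw significance threshold
   (default alpha = 0.01, no multiple-testing correction — the raw
   threshold is the method) and splits them by association sign into a
   *positive network* and a *negative network*;
3. collapses each subject to two summary values (the sum of their edge
   weights over each network) and fits one simple linear regression per
   network mapping summary value to score.

The two fitted models predict a held-out subject's score from their own
summary values computed over the *training* networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CpmConfig",
    "EdgeAssociation",
    "EdgeSelectionResult",
    "SummaryPair",
    "SummaryModel",
    "pearson_association",
    "robust_association",
    "mass_association",
    "select_edges",
    "summary_values",
    "fit_summary_model",
    "predict_score",
]

logger = logging.getLogger(__name__)

HUBER_C = 1.345  # 95% Gaussian efficiency
MAD_SCALE = 1.4826  # consistency factor for Gaussian sigma


@dataclass(frozen=True)
class CpmConfig:
    """Tunable knobs of the CPM pipeline.

    alpha: per-edge significance threshold (raw, uncorrected).
    method: 'robust' (Huber IRLS, the default) or 'pearson'.
    summary: 'raw' sums signed edge weights over a network; 'clipped'
        zeroes weights whose sign disagrees with the network's sign
        before summing (the literal "positive values in the positive
        matrix" reading).
    loss: robust weight function, 'huber' or 'bisquare'.
    """

    alpha: float = 0.01
    method: str = "robust"
    summary: str = "raw"
    huber_c: float = HUBER_C
    bisquare_c: float = 4.685
    irls_max_iter: int = 50
    irls_tol: float = 1e-8
    loss: str = "huber"

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.method not in ("robust", "pearson"):
            raise ValueError("method must be 'robust' or 'pearson'")
        if self.summary not in ("raw", "clipped"):
            raise ValueError("summary must be 'raw' or 'clipped'")
        if self.loss not in ("huber", "bisquare"):
            raise ValueError("loss must be 'huber' or 'bisquare'")


@dataclass
class EdgeAssociation:
    """Per-edge association of weight with score over a training set."""

    r: np.ndarray  # association coefficient, |r| <= 1
    p: np.ndarray  # two-tailed p-value
    slope: np.ndarray  # fitted slope of score on edge weight
    method: str


@dataclass
class EdgeSelectionResult:
    """Significant edges split by association sign."""

    association: EdgeAssociation
    threshold: float
    pos_mask: np.ndarray  # selected with r > 0
    neg_mask: np.ndarray  # selected with r < 0


@dataclass(frozen=True)
class SummaryPair:
    """One subject's positive- and negative-network summary values."""

    pos_sum: float
    neg_sum: float


@dataclass(frozen=True)
class SummaryModel:
    """Simple linear map from a network summary value to the score.

    When the summary values are constant on the training set (e.g. no
    edge was ever selected) the model is degenerate and predicts the
    training score mean for every input.
    """

    slope: float
    intercept: float
    side: str
    degenerate: bool = False
    fallback_mean: float = float("nan")


def _validate_xy(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(y) == 0:
        raise ValueError("score vector is constant")
    return x, y


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p of a correlation via t = r sqrt((n-2)/(1-r^2)), n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def pearson_association(x, y) -> tuple[float, float]:
    """Pearson r of one edge with the score and its two-tailed p.

    A constant edge carries no association: returns (0, 1) rather than
    failing mid-sweep.
    """
    x, y = _validate_xy(x, y, min_n=3)
    r, p, _ = _mass_pearson(x[:, None], y)
    return float(r[0]), float(p[0])


def _mass_pearson(X: np.ndarray, y: np.ndarray):
    """Vectorized Pearson r, p and OLS slope for all edge columns of X."""
    n = y.size
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    syy = float(yc @ yc)
    sxy = yc @ xc
    constant = sxx <= 0
    denom = np.sqrt(np.where(constant, 1.0, sxx) * syy)
    r = np.where(constant, 0.0, sxy / denom)
    r = np.clip(r, -1.0, 1.0)
    p = np.where(constant, 1.0, _t_pvalue(r, n))
    slope = np.where(constant, 0.0, sxy / np.where(constant, 1.0, sxx))
    return r, p, slope


def _robust_weights(u: np.ndarray, config: CpmConfig) -> np.ndarray:
    if config.loss == "huber":
        au = np.abs(u)
        return np.where(au <= config.huber_c, 1.0, config.huber_c / np.maximum(au, 1e-300))
    w = 1.0 - (u / config.bisquare_c) ** 2
    return np.where(np.abs(u) <= config.bisquare_c, w * w, 0.0)


def _mass_robust(X: np.ndarray, y: np.ndarray, config: CpmConfig):
    """Huber/bisquare IRLS of score on each edge column, vectorized.

    For every column of X fits y = a + b*x by iteratively reweighted
    least squares: residual scale is MAD_SCALE * median |e - median(e)|,
    recomputed each iteration; weights come from the chosen psi function;
    convergence when the largest coefficient change drops below
    ``irls_tol`` (cap ``irls_max_iter``, with a logged warning on
    non-convergence). Columns with zero residual MAD fall back to their
    OLS fit. Returns (r, p, slope) where r is the weighted Pearson
    correlation under the final weights (sign-consistent with the slope)
    and p the two-tailed slope t-test with n-2 df under the final
    weighted covariance.
    """
    n, e = X.shape
    r0, p0, b0 = _mass_pearson(X, y)
    b = b0.copy()
    ybar = y.mean()
    a = ybar - b * X.mean(axis=0)
    W = np.ones((n, e))
    converged = np.zeros(e, dtype=bool)
    ols_frozen = np.zeros(e, dtype=bool)  # zero-MAD columns keep OLS coefs

    for _ in range(config.irls_max_iter):
        resid = y[:, None] - (a[None, :] + b[None, :] * X)
        med = np.median(resid, axis=0)
        scale = MAD_SCALE * np.median(np.abs(resid - med[None, :]), axis=0)
        zero_mad = scale <= 0
        ols_frozen |= zero_mad
        safe_scale = np.where(zero_mad, 1.0, scale)
        W = _robust_weights(resid / safe_scale[None, :], config)
        W[:, ols_frozen] = 1.0

        sw = W.sum(axis=0)
        xbar = np.einsum("ij,ij->j", W, X) / sw
        ybar_w = (y @ W) / sw
        xc = X - xbar[None, :]
        sxx = np.einsum("ij,ij,ij->j", W, xc, xc)
        sxy = np.einsum("ij,ij,i->j", W, xc, y) - ybar_w * np.einsum("ij,ij->j", W, xc)
        degenerate = sxx <= 0
        b_new = np.where(degenerate, 0.0, sxy / np.where(degenerate, 1.0, sxx))
        a_new = ybar_w - b_new * xbar

        active = ~(converged | ols_frozen)
        delta = np.maximum(np.abs(b_new - b), np.abs(a_new - a))
        b = np.where(active, b_new, b)
        a = np.where(active, a_new, a)
        converged |= delta < config.irls_tol
        if (converged | ols_frozen).all():
            break
    else:
        n_bad = int((~(converged | ols_frozen)).sum())
        logger.warning(
            "IRLS did not converge for %d of %d edges after %d iterations; "
            "using last iterate", n_bad, e, config.irls_max_iter,
        )

    # association coefficient: weighted Pearson under the final weights
    # (sign-consistent with the slope by construction)
    resid = y[:, None] - (a[None, :] + b[None, :] * X)
    sw = W.sum(axis=0)
    xbar = np.einsum("ij,ij->j", W, X) / sw
    ybar_w = (y @ W) / sw
    xc = X - xbar[None, :]
    yc = y[:, None] - ybar_w[None, :]
    sxx = np.einsum("ij,ij,ij->j", W, xc, xc)
    syy = np.einsum("ij,ij,ij->j", W, yc, yc)
    sxy = np.einsum("ij,ij,ij->j", W, xc, yc)
    constant = sxx <= 0
    r = np.where(constant, 0.0, sxy / np.sqrt(np.where(constant, 1.0, sxx * syy)))
    r = np.clip(r, -1.0, 1.0)

    # slope standard error via the Huber (1973) robust covariance (the
    # robustfit/RLM convention): a naive WLS-style error is anti-conservative
    # because the weights were chosen to shrink exactly the large residuals
    med = np.median(resid, axis=0)
    scale = MAD_SCALE * np.median(np.abs(resid - med[None, :]), axis=0)
    safe_scale = np.where(scale <= 0, 1.0, scale)
    u = resid / safe_scale[None, :]
    if config.loss == "huber":
        psi = np.clip(u, -config.huber_c, config.huber_c)
        psi_prime = (np.abs(u) <= config.huber_c).astype(float)
    else:
        c_b = config.bisquare_c
        inside = np.abs(u) <= c_b
        t2 = (u / c_b) ** 2
        psi = np.where(inside, u * (1.0 - t2) ** 2, 0.0)
        psi_prime = np.where(inside, (1.0 - t2) * (1.0 - 5.0 * t2), 0.0)
    m1 = psi_prime.mean(axis=0)
    m2 = psi_prime.var(axis=0)
    n_params = 2
    kappa = 1.0 + (n_params / n) * m2 / np.maximum(m1, 1e-12) ** 2
    s_psi2 = safe_scale**2 * (psi**2).sum(axis=0) / (n - n_params)
    sxx_plain = np.einsum("ij,ij->j", X - X.mean(axis=0), X - X.mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = kappa**2 * s_psi2 / np.maximum(m1, 1e-12) ** 2 / np.where(
            sxx_plain <= 0, 1.0, sxx_plain
        )
        se = np.sqrt(var_b)
        t = np.where(constant | (se <= 0), 0.0, b / np.where(se <= 0, 1.0, se))
    p = np.where(constant, 1.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    b = np.where(constant, 0.0, b)

    # zero-MAD columns report their plain OLS/Pearson fit
    r = np.where(ols_frozen, r0, r)
    p = np.where(ols_frozen, p0, p)
    b = np.where(ols_frozen, b0, b)
    return r, p, b


def robust_association(x, y, config: CpmConfig | None = None) -> tuple[float, float]:
    """Huber-IRLS association of one edge with the score: (r, p).

    r is the weighted Pearson correlation under the converged IRLS
    weights, guaranteed sign-consistent with the fitted slope; p is the
    two-tailed slope t-test (n-2 df). On clean Gaussian data all weights
    converge to 1 and the result collapses to :func:`pearson_association`.
    """
    config = config or CpmConfig()
    x, y = _validate_xy(x, y, min_n=5)
    r, p, _ = _mass_robust(x[:, None], y, config)
    return float(r[0]), float(p[0])


def mass_association(
    edge_matrix: np.ndarray, y: np.ndarray, method: str, config: CpmConfig | None = None
) -> EdgeAssociation:
    """Associate every edge column of an N x E matrix with the score."""
    config = config or CpmConfig()
    X = np.asarray(edge_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("edge matrix must be N x E with N matching scores")
    if np.ptp(y) == 0:
        raise ValueError("score vector is constant")
    if method == "pearson":
        r, p, slope = _mass_pearson(X, y)
    elif method == "robust":
        r, p, slope = _mass_robust(X, y, config)
    else:
        raise ValueError(f"unknown association method {method!r}")
    return EdgeAssociation(r=r, p=p, slope=slope, method=method)


def select_edges(
    edge_matrix: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.01,
    method: str = "robust",
    config: CpmConfig | None = None,
) -> EdgeSelectionResult:
    """Threshold per-edge p-values and split selected edges by sign.

    No multiple-testing correction is applied: the raw alpha threshold is
    part of the method. Edges with r exactly 0 (a measure-zero event) are
    assigned to neither network, keeping the sign split disjoint and
    exhaustive over selected edges.
    """
    X = np.asarray(edge_matrix, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 training subjects")
    assoc = mass_association(X, y, method=method, config=config)
    significant = assoc.p < alpha
    pos_mask = significant & (assoc.r > 0)
    neg_mask = significant & (assoc.r < 0)
    return EdgeSelectionResult(
        association=assoc, threshold=alpha, pos_mask=pos_mask, neg_mask=neg_mask
    )


def summary_values(
    edges: np.ndarray, selection: EdgeSelectionResult, summary: str = "raw"
) -> SummaryPair:
    """Collapse one subject's edge vector to (pos_sum, neg_sum).

    'raw' sums the signed weights of each network's edges (a positively
    correlated edge may still carry a negative weight in some subject);
    'clipped' first zeroes weights whose sign disagrees with the network.
    An empty network sums to exactly 0.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.shape != selection.pos_mask.shape:
        raise ValueError("edge vector length does not match selection masks")
    if summary == "raw":
        pos = edges[selection.pos_mask].sum()
        neg = edges[selection.neg_mask].sum()
    elif summary == "clipped":
        pos = np.clip(edges[selection.pos_mask], 0.0, None).sum()
        neg = np.clip(edges[selection.neg_mask], None, 0.0).sum()
    else:
        raise ValueError(f"unknown summary mode {summary!r}")
    return SummaryPair(pos_sum=float(pos), neg_sum=float(neg))


def summary_matrix(
    edge_matrix: np.ndarray, selection: EdgeSelectionResult, summary: str = "raw"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`summary_values` over the rows of an N x E matrix."""
    X = np.asarray(edge_matrix, dtype=float)
    if summary == "raw":
        pos = X[:, selection.pos_mask].sum(axis=1)
        neg = X[:, selection.neg_mask].sum(axis=1)
    elif summary == "clipped":
        pos = np.clip(X[:, selection.pos_mask], 0.0, None).sum(axis=1)
        neg = np.clip(X[:, selection.neg_mask], None, 0.0).sum(axis=1)
    else:
        raise ValueError(f"unknown summary mode {summary!r}")
    return pos, neg


def fit_summary_model(summaries, y, side: str) -> SummaryModel:
    """OLS simple regression of score on network summary value.

    Constant summaries (no edges ever selected) yield a degenerate model
    whose predictions fall back to the training score mean.
    """
    s = np.asarray(summaries, dtype=float)
    y = np.asarray(y, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("summaries and scores must be aligned 1-D vectors")
    if s.size < 3:
        raise ValueError("refusing to fit on fewer than 3 training points")
    if np.ptp(s) == 0:
        warnings.warn(
            f"constant {side} summary values; falling back to mean prediction",
            stacklevel=2,
        )
        return SummaryModel(
            slope=0.0, intercept=float(y.mean()), side=side,
            degenerate=True, fallback_mean=float(y.mean()),
        )
    sc = s - s.mean()
    slope = float((sc @ (y - y.mean())) / (sc @ sc))
    intercept = float(y.mean() - slope * s.mean())
    return SummaryModel(slope=slope, intercept=intercept, side=side)


def predict_score(model: SummaryModel, summary: float) -> float:
    """Affine prediction, or the training mean for a degenerate model."""
    if model.degenerate:
        return model.fallback_mean
    return model.slope * float(summary) + model.intercept
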