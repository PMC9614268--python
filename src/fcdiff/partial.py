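"""Graphical-LASSO partial correlation per subject and binarization.

The precision (inverse covariance) matrix Theta of each subject's standardized
time series is estimated by l1-penalised Gaussian maximum likelihood
(graphical LASSO); partial correlations follow as
pc[i,j] = -Theta[i,j] / sqrt(Theta[i,i] * Theta[j,j]).  Each subject's partial
correlation matrix is then binarized at |pc| > threshold (default 0.1, strict
inequality) to form the binary adjacency graphs consumed by the edge
prevalence Score statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import GraphicalLasso, GraphicalLassoCV

__all__ = [
    "PartialCorrMatrix",
    "BinaryAdjacency",
    "glasso_partial_corr",
    "binarize",
    "write_adjacency_stack",
    "read_adjacency_stack",
    "DEFAULT_ALPHA_GRID",
]

#: Penalty grid searched when ``alpha="cv"`` (3-fold over time points).
DEFAULT_ALPHA_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5)

BINARIZE_THRESHOLD = 0.1


@dataclass
class PartialCorrMatrix:
    """Symmetric partial-correlation matrix (diagonal 1) with the penalty used."""

    subject_id: str
    pc: np.ndarray
    alpha: float


@dataclass
class BinaryAdjacency:
    """Thresholded partial-correlation graph: adj[i,j] = 1 iff |pc[i,j]| > threshold."""

    subject_id: str
    adj: np.ndarray
    threshold: float = BINARIZE_THRESHOLD


class GlassoConvergenceError(RuntimeError):
    def __init__(self, alpha: float, max_iter: int, cause: Exception):
        super().__init__(
            f"graphical LASSO failed to converge (alpha={alpha}, max_iter={max_iter}): {cause}"
        )
        self.alpha = alpha
        self.max_iter = max_iter


def _precision_to_partial(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    pc = (pc + pc.T) / 2.0
    np.fill_diagonal(pc, 1.0)
    return np.clip(pc, -1.0, 1.0)


def glasso_partial_corr(
    series: np.ndarray,
    alpha: float | str = "cv",
    subject_id: str = "",
    alpha_grid=DEFAULT_ALPHA_GRID,
    cv: int = 3,
    max_iter: int = 200,
) -> PartialCorrMatrix:
    """Sparse partial-correlation matrix of a T x R time-series matrix.

    Columns are standardized internally (zero mean, unit variance) so the
    penalty ``alpha`` acts on the correlation scale.  ``alpha="cv"`` selects
    the penalty by K-fold log-likelihood over ``alpha_grid``; a positive float
    fixes it.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 10:
        raise ValueError("series must be a T x R matrix with T >= 10")
    x = series - series.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"ROI column(s) {np.flatnonzero(sd == 0).tolist()} have zero variance")
    x /= sd
    if alpha == "cv":
        est = GraphicalLassoCV(alphas=list(alpha_grid), cv=cv, max_iter=max_iter)
    else:
        alpha = float(alpha)
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        est = GraphicalLasso(alpha=alpha, max_iter=max_iter)
    try:
        with np.errstate(invalid="raise"):
            est.fit(x)
    except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
        raise GlassoConvergenceError(
            est.alpha if hasattr(est, "alpha") and not isinstance(est, GraphicalLassoCV) else -1.0,
            max_iter,
            exc,
        ) from exc
    used_alpha = float(est.alpha_) if isinstance(est, GraphicalLassoCV) else float(alpha)
    return PartialCorrMatrix(subject_id, _precision_to_partial(est.precision_), used_alpha)


def binarize(pcm: PartialCorrMatrix, threshold: float = BINARIZE_THRESHOLD) -> BinaryAdjacency:
    """Binary adjacency at |pc| > threshold (strict), diagonal 0."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    adj = (np.abs(pcm.pc) > threshold).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return BinaryAdjacency(pcm.subject_id, adj, threshold)


# ---------------------------------------------------------------------------
# Stacked cohort I/O: one row per subject, one column per upper-triangle edge
# ---------------------------------------------------------------------------

def _edge_columns(n_rois: int) -> list[str]:
    iu, ju = np.triu_indices(n_rois, k=1)
    return [f"e{i}_{j}" for i, j in zip(iu, ju)]


def write_adjacency_stack(adjacencies: list[BinaryAdjacency], path: str | Path) -> None:
    n_rois = adjacencies[0].adj.shape[0]
    iu, ju = np.triu_indices(n_rois, k=1)
    df = pd.DataFrame(
        [a.adj[iu, ju] for a in adjacencies],
        columns=_edge_columns(n_rois),
    )
    df.insert(0, "subject_id", [a.subject_id for a in adjacencies])
    df.to_csv(path, sep="\t", index=False)


def read_adjacency_stack(path: str | Path, threshold: float = BINARIZE_THRESHOLD) -> list[BinaryAdjacency]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    edge_cols = [c for c in df.columns if c != "subject_id"]
    n_edges = len(edge_cols)
    n_rois = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    iu, ju = np.triu_indices(n_rois, k=1)
    out = []
    for row in df.itertuples(index=False):
        adj = np.zeros((n_rois, n_rois), dtype=np.uint8)
        vals = np.array(row[1:], dtype=np.uint8)
        adj[iu, ju] = vals
        adj[ju, iu] = vals
        out.append(BinaryAdjacency(row.subject_id, adj, threshold))
    return out
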