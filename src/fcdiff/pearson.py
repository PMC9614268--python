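"""Pearson functional connectivity with Fisher z transform and edge-wise group tests.

For each subject, the R x R matrix of pairwise Pearson correlations between
ROI time series is computed and variance-stabilised with the Fisher transform
z = arctanh(r).  Group differences are then assessed edge-by-edge with a
two-sample t-test across subjects, corrected for multiple comparisons with
Benjamini-Hochberg FDR over all unordered ROI pairs in one family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._groups import resolve_groups

__all__ = ["FCMatrix", "fisher_z", "pearson_fc_matrix", "edge_group_ttest"]

#: Correlations are clipped to |r| <= 1 - CLIP_EPS before arctanh so that
#: numerically degenerate inputs (duplicated or perfectly anti-correlated
#: columns) produce large finite z values instead of infinities.
CLIP_EPS = 1e-7


@dataclass
class FCMatrix:
    """Fisher-z Pearson connectivity matrix for one subject.

    Symmetric, diagonal exactly 0 (self-connections carry no information and
    arctanh(1) is infinite), all off-diagonal entries finite.
    """

    subject_id: str
    z: np.ndarray


def fisher_z(r):
    """Fisher variance-stabilising transform arctanh(r) for |r| < 1.

    Odd and strictly increasing.  Accepts scalars or arrays; raises
    ``ValueError`` if any |r| >= 1 (the diagonal convention of
    :func:`pearson_fc_matrix` is handled by the caller, not here).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def pearson_fc_matrix(series: np.ndarray, subject_id: str = "") -> FCMatrix:
    """Fisher-z Pearson correlation matrix of a T x R time-series matrix.

    Correlations are clipped at |r| <= 1 - 1e-7 before the transform; the
    diagonal is forced to 0.  A zero-variance ROI raises ``ValueError`` naming
    the offending column.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 3:
        raise ValueError("series must be a T x R matrix with T >= 3")
    sd = series.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"ROI column(s) {bad.tolist()} have zero variance")
    r = np.corrcoef(series, rowvar=False)
    r = np.clip(r, -1.0 + CLIP_EPS, 1.0 - CLIP_EPS)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FCMatrix(subject_id, z)


def _stack_z(cohort_z) -> tuple[np.ndarray, int]:
    mats = [fc.z if isinstance(fc, FCMatrix) else np.asarray(fc, float) for fc in cohort_z]
    n_rois = mats[0].shape[0]
    if any(m.shape != (n_rois, n_rois) for m in mats):
        raise ValueError("all FC matrices must share the same ROI count")
    iu, ju = np.triu_indices(n_rois, k=1)
    return np.stack([m[iu, ju] for m in mats]), n_rois


def edge_group_ttest(
    cohort_z,
    labels,
    group_order: tuple[str, str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
    roi_names: list[str] | None = None,
) -> pd.DataFrame:
    """Edge-wise two-sample t-test on Fisher-z values with BH-FDR correction.

    Parameters
    ----------
    cohort_z
        Sequence of :class:`FCMatrix` (or raw R x R z matrices), one per subject.
    labels
        Group label per subject (exactly two distinct values).
    group_order
        Which label is group 1 (the difference tested is group1 - group2);
        defaults to order of first appearance.
    alpha
        FDR significance level for the ``significant`` flag (default 0.05).
    equal_var
        Classical pooled-variance t-test when True (default); Welch otherwise.

    Returns a table with one row per unordered ROI pair i < j and columns
    ``roi_i, roi_j, t_score, p, p_fdr, significant``, FDR-corrected over all
    R(R-1)/2 edges as a single family.
    """
    values, n_rois = _stack_z(cohort_z)
    g1_mask, g2_mask, order = resolve_groups(labels, group_order)
    if g1_mask.sum() < 2 or g2_mask.sum() < 2:
        raise ValueError("each group needs at least 2 subjects for the t-test")
    t, p = stats.ttest_ind(values[g1_mask], values[g2_mask], axis=0, equal_var=equal_var)
    _, p_fdr, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    iu, ju = np.triu_indices(n_rois, k=1)
    name = (lambda k: roi_names[k]) if roi_names is not None else (lambda k: k)
    table = pd.DataFrame(
        {
            "roi_i": [name(k) for k in iu],
            "roi_j": [name(k) for k in ju],
            "t_score": t,
            "p": p,
            "p_fdr": p_fdr,
            "significant": p_fdr < alpha,
        }
    )
    table.attrs["group_order"] = order
    return table
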