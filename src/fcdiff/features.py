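"""Effect-size screening of connectivity features and square channel layouts.

Features (upper-triangle connectivity entries) are ranked by an absolute
standardized mean difference between groups,

    ES_i = |xbar_{i,1} - xbar_{i,2}| / S_i,
    S_i  = sqrt( ((n1-1) S_{i,1}^2 + (n2-1) S_{i,2}^2) / (n1 + n2) ),

with S_{i,g} the per-group sample standard deviations (ddof 1).  Note the
pooled denominator uses n1+n2; the textbook Cohen's d denominator (n1+n2-2)
is available via ``denominator="textbook"`` and differs only by the constant
factor sqrt((n1+n2)/(n1+n2-2)), so the two produce identical rankings.

The top side*side features by ES (default 22*22 = 484) are arranged row-major
in descending-ES order into a square channel; the layout is serialisable so a
downstream run can reconstruct the exact feature map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["cohens_effect_size", "ChannelLayout", "select_channel"]

DEFAULT_SIDE = 22
ORDERING_RULE = "descending_es_row_major_ties_by_index"


def cohens_effect_size(
    values1: np.ndarray,
    values2: np.ndarray,
    denominator: str = "as_defined",
) -> pd.DataFrame:
    """Per-feature absolute standardized mean difference between two groups.

    Parameters
    ----------
    values1, values2
        (n_subjects x n_features) matrices for groups 1 and 2; n1, n2 >= 2.
    denominator
        ``"as_defined"`` pools over n1+n2 (the default, see module docstring);
        ``"textbook"`` pools over n1+n2-2 (classical Cohen's d).

    Returns a table with columns ``feature_index, es, mean1, mean2, sd1, sd2,
    degenerate``; group sizes are stored in ``table.attrs``.  A feature whose
    pooled deviation is 0 gets ES = +inf (flagged degenerate) if the means
    differ, ES = 0 otherwise.
    """
    x1 = np.atleast_2d(np.asarray(values1, dtype=float))
    x2 = np.atleast_2d(np.asarray(values2, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("groups must have the same number of features")
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    if denominator not in ("as_defined", "textbook"):
        raise ValueError(f"unknown denominator {denominator!r}")
    dof = n1 + n2 if denominator == "as_defined" else n1 + n2 - 2
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    s1, s2 = x1.std(axis=0, ddof=1), x2.std(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / dof)
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        es = diff / pooled
    degenerate = (pooled == 0) & (diff > 0)
    es = np.where(degenerate, np.inf, np.where((pooled == 0) & (diff == 0), 0.0, es))
    table = pd.DataFrame(
        {
            "feature_index": np.arange(x1.shape[1]),
            "es": es,
            "mean1": m1,
            "mean2": m2,
            "sd1": s1,
            "sd2": s2,
            "degenerate": degenerate,
        }
    )
    table.attrs.update(n1=n1, n2=n2, denominator=denominator)
    return table


@dataclass
class ChannelLayout:
    """Ordered mapping of the side^2 selected features into a square channel.

    ``selected_indices`` is row-major: entry k of the flattened side x side
    grid holds feature ``selected_indices[k]``.
    """

    side: int = DEFAULT_SIDE
    selected_indices: list[int] = field(default_factory=list)
    ordering: str = ORDERING_RULE

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "side": self.side,
                    "selected_indices": [int(i) for i in self.selected_indices],
                    "ordering": self.ordering,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelLayout":
        d = json.loads(Path(path).read_text())
        return cls(d["side"], list(d["selected_indices"]), d["ordering"])

    def fill(self, features: np.ndarray) -> np.ndarray:
        """Arrange one subject's feature vector into the side x side channel."""
        features = np.asarray(features, dtype=float)
        return features[np.asarray(self.selected_indices)].reshape(self.side, self.side)


def select_channel(es_table: pd.DataFrame, side: int = DEFAULT_SIDE) -> ChannelLayout:
    """Top side^2 features by descending ES, ties broken by ascending index.

    The resulting order is the row-major filling order of the square channel.
    Raises ``ValueError`` when fewer than side^2 features are available.
    """
    k = side * side
    if len(es_table) < k:
        raise ValueError(f"need at least {k} features, got {len(es_table)}")
    es = es_table["es"].to_numpy()
    idx = es_table["feature_index"].to_numpy()
    # descending es, ascending index on ties
    order = np.lexsort((idx, -es))
    return ChannelLayout(side, [int(idx[o]) for o in order[:k]])
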