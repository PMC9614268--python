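"""Shared two-group label handling."""

from __future__ import annotations

import numpy as np

__all__ = ["resolve_groups"]


def resolve_groups(labels, group_order=None):
    """Boolean masks for the two groups plus the (group1, group2) label order.

    ``group_order`` fixes which label counts as group 1 (the patient group in
    the statistics' sign conventions); by default the label of the first
    subject is group 1.
    """
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two group labels, found {uniq}")
    if group_order is None:
        group_order = (uniq[0], uniq[1])
    g1, g2 = group_order
    if set((g1, g2)) != set(uniq):
        raise ValueError(f"group_order {group_order} does not match labels {uniq}")
    return labels == g1, labels == g2, (g1, g2)
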