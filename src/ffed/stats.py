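"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust"]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries pass through.

    NaN p-values (untestable genes/bins) are excluded from the family and
    returned as NaN, so they neither gain nor grant significance.
    """
    p = np.asarray(pvalues, dtype=float)
    adjusted = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        adjusted[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adjusted
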