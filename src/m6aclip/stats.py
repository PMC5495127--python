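"""Shared statistical kernels: Fisher's exact test and BH adjustment."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def fisher_exact_p(a: int, b: int, c: int, d: int,
                   alternative: str = "greater") -> float:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Degenerate tables (an empty margin, which carry no information about
    association) return p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Returns an array aligned with the input order; empty input yields an
    empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
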