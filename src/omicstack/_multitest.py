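"""Multiple-testing adjustments (Benjamini-Hochberg and Bonferroni)."""

from __future__ import annotations

import numpy as np


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone, capped at 1).

    NaN entries are passed through and excluded from the test count.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    """Bonferroni: min(1, m * p) with m the number of non-NaN tests."""
    p = np.asarray(p, dtype=float)
    m = int((~np.isnan(p)).sum())
    return np.where(np.isnan(p), np.nan, np.minimum(1.0, p * m))


def adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bh":
        return bh_adjust(p)
    if method == "bonferroni":
        return bonferroni_adjust(p)
    raise ValueError(f"unknown adjustment method {method!r} (use 'bh' or 'bonferroni')")
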