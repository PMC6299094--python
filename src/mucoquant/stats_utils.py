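"""Shared statistical helpers (multiple-comparison adjustment)."""

from __future__ import annotations

import numpy as np

__all__ = ["holm_sidak"]


def holm_sidak(p_values) -> list[float]:
    """Holm-Sidak step-down adjusted p-values.

    Sorted ascending, the i-th p-value (0-based) is adjusted to
    ``1 - (1 - p)**(m - i)`` with monotonicity enforced by a running
    maximum; values are returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        a = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, a)
        adj_sorted[idx] = min(1.0, running)
    return adj_sorted.tolist()
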