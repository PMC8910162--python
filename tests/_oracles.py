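"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths they check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_force_max_matching(iou: np.ndarray, iou_min: float) -> float:
    """Maximum total IoU over all partial one-to-one matchings.

    Exhaustive enumeration: every subset assignment of rows to distinct
    columns, pairs below ``iou_min`` excluded.  Exponential — fine for
    matrices up to ~6x6.
    """
    n, m = iou.shape
    best = 0.0
    cols = list(range(m)) + [None] * n  # None = leave the row unmatched
    for perm in set(permutations(cols, n)):
        used = [c for c in perm if c is not None]
        if len(used) != len(set(used)):
            continue
        total = 0.0
        ok = True
        for i, c in enumerate(perm):
            if c is None:
                continue
            if iou[i, c] < iou_min:
                ok = False
                break
            total += iou[i, c]
        if ok and total > best:
            best = total
    return best


def set_iou(a: set, b: set) -> float:
    """IoU of two pixel-index sets (independent of the mask code path)."""
    if not a and not b:
        raise ValueError("undefined")
    return len(a & b) / len(a | b)
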