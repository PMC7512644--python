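"""Exact pair counting under the Chebyshev (maximum) norm.

Match counts are integers: a pair of delay vectors matches when the largest
absolute component-wise difference is at most ``r`` (inclusive).  The
counting is delegated to a k-d tree, which gives the same integer count as
an O(n^2) double loop at a fraction of the cost.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["count_matching_pairs", "pair_match_fraction"]


def count_matching_pairs(vectors: np.ndarray, r: float) -> int:
    """Number of unordered vector pairs with max-norm distance <= r.

    Self-pairs (a vector with itself) are excluded.  ``vectors`` is an
    (n, d) array with n >= 2.
    """
    v = np.ascontiguousarray(np.atleast_2d(vectors), dtype=float)
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least two vectors to count pairs")
    if r <= 0:
        raise ValueError("similarity threshold r must be positive")
    tree = cKDTree(v)
    ordered = tree.count_neighbors(tree, r, p=np.inf)
    # ordered counts include the n self-pairs and both (i, j) orderings
    return int(ordered - n) // 2


def pair_match_fraction(vectors: np.ndarray, r: float) -> float:
    """Fraction of unordered, non-self vector pairs within ``r`` (max norm)."""
    v = np.atleast_2d(vectors)
    n = v.shape[0]
    matches = count_matching_pairs(v, r)
    return matches / (n * (n - 1) / 2.0)
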