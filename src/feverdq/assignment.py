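"""Maximum-cardinality, priority-weighted one-to-one assignment.

Shared by profile linkage and episode pairing. Weights encode
admissibility and preference: inadmissible pairs get weight 0, every
admissible pair gets a large base weight plus a small preference bonus,
so maximizing total weight first maximizes the number of pairs and only
then the preferences. Deterministic for a fixed weight matrix.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

#: Base weight guaranteeing cardinality dominance; bonuses must stay below it.
BASE_WEIGHT = 1_000_000.0


def max_weight_pairs(weights: np.ndarray) -> list[tuple[int, int]]:
    """Return (row, col) pairs of an optimal assignment; zero-weight pairs dropped.

    ``weights[i, j]`` must be 0 for inadmissible pairs and in
    ``[BASE_WEIGHT, 2 * BASE_WEIGHT)`` for admissible ones.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        return []
    rows, cols = linear_sum_assignment(w, maximize=True)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if w[i, j] > 0]
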