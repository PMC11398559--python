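"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming implementation:
DTW costs are computed by enumerating *every* admissible warping path.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def all_warping_paths(n: int, m: int) -> tuple:
    """Every monotone endpoint-aligned path with steps (1,0), (0,1), (1,1)."""
    if n == 1 and m == 1:
        return (((0, 0),),)
    out = []
    for pn, pm in ((n - 1, m), (n, m - 1), (n - 1, m - 1)):
        if pn >= 1 and pm >= 1:
            for p in all_warping_paths(pn, pm):
                out.append(p + ((n - 1, m - 1),))
    return tuple(out)


def dtw_by_enumeration(x, y) -> float:
    """Minimal sqrt accumulated squared cost over all enumerated paths."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = min(
        sum((x[a] - y[b]) ** 2 for a, b in path)
        for path in all_warping_paths(len(x), len(y))
    )
    return float(np.sqrt(best))


def path_cost(x, y, path) -> float:
    """Accumulated squared cost of a given alignment path."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(sum((x[a] - y[b]) ** 2 for a, b in path))
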