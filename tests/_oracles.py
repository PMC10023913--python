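"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own algorithms: d-separation is
decided by exhaustive enumeration of simple undirected paths with the
chain/fork/collider blocking rules applied literally, and regression slopes
come from the closed-form least-squares formula.
"""
from __future__ import annotations

import numpy as np


def dsep_path_enumeration(parents: dict, x, y, z: set) -> bool:
    """True iff every undirected simple path from x to y is blocked given z.

    ``parents`` maps each node to the set of its direct causes.  A
    non-collider on a path blocks when it is in z; a collider blocks unless
    it or one of its descendants is in z.
    """
    children: dict = {n: set() for n in parents}
    for b, ps in parents.items():
        for a in ps:
            children[a].add(b)

    def descendants(n):
        out, stack = set(), [n]
        while stack:
            m = stack.pop()
            if m in out:
                continue
            out.add(m)
            stack.extend(children[m])
        return out

    desc = {n: descendants(n) for n in parents}

    neighbors = {n: parents[n] | children[n] for n in parents}

    def path_blocked(path):
        for i in range(1, len(path) - 1):
            prev, mid, nxt = path[i - 1], path[i], path[i + 1]
            into_left = prev in parents[mid]
            into_right = nxt in parents[mid]
            if into_left and into_right:  # collider
                if not (desc[mid] & z):
                    return True
            else:  # chain or fork
                if mid in z:
                    return True
        return False

    stack = [(x, [x])]
    while stack:
        node, path = stack.pop()
        for nb in neighbors[node]:
            if nb in path:
                continue
            if nb == y:
                if not path_blocked(path + [y]):
                    return False
            else:
                stack.append((nb, path + [nb]))
    return True


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple-regression slope and its naive standard error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    se = float(np.sqrt(resid @ resid / (n - 2) / (xc @ xc)))
    return slope, se
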