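"""Brute-force oracle for the dip statistic, derived from its definition.

dip(F_n) = min over unimodal CDFs G of sup_x |F_n(x) - G(x)|.

For a mode located at a data point x_k, a unimodal G within a +-d band
around F_n is described by values a_1..a_k (G at x_1..x_{k-1} and the
left limit at x_k) and b_k..b_n (G at x_k..x_n) satisfying

  * a convex-sequence shape on the left (slopes nondecreasing, first
    slope >= 0, a_1 >= 0, so G can fall convexly to 0 at -inf),
  * a concave-sequence shape on the right (slopes nonincreasing, last
    slope >= 0, b_n <= 1, so G can rise concavely to 1 at +inf),
  * band constraints  i/n - d <= G(x_i) <= (i-1)/n + d  at continuity
    points and the left-limit band (k-1)/n +- d at the mode, and
  * a_k <= b_k (an atom at the mode is allowed, so only monotonicity
    links the two sides).

Modes strictly between data points reduce to one of the flanking
data-point modes (the binding constraints are monotone in the mode
position), so scanning k = 1..n is exhaustive.  Everything is linear in
(a, b, d), so minimizing d directly is a linear program; the dip is the
minimum over k.  Requires distinct sample values (ties would make the
slope constraints unbounded).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _min_d_for_mode(x: np.ndarray, k: int) -> float | None:
    n = x.size
    na, nb = k, n - k + 1
    nv = na + nb + 1  # a_1..a_k, b_k..b_n, d last
    D = nv - 1
    A_ub: list[np.ndarray] = []
    b_ub: list[float] = []

    def row(pairs):
        r = np.zeros(nv)
        for idx, coef in pairs:
            r[idx] = coef
        return r

    # band constraints, d as a variable
    for i in range(1, k):  # a_i at continuity points (1-based i)
        A_ub.append(row([(i - 1, 1.0), (D, -1.0)]))
        b_ub.append((i - 1) / n)
        A_ub.append(row([(i - 1, -1.0), (D, -1.0)]))
        b_ub.append(-i / n)
    A_ub.append(row([(na - 1, 1.0), (D, -1.0)]))  # a_k: left limit at x_k
    b_ub.append((k - 1) / n)
    A_ub.append(row([(na - 1, -1.0), (D, -1.0)]))
    b_ub.append(-(k - 1) / n)
    for i in range(k, n + 1):  # b_i
        j = na + (i - k)
        A_ub.append(row([(j, 1.0), (D, -1.0)]))
        b_ub.append((i - 1) / n)
        A_ub.append(row([(j, -1.0), (D, -1.0)]))
        b_ub.append(-i / n)

    dx = np.diff(x)
    # left convexity, first slope >= 0
    if na >= 2:
        A_ub.append(row([(0, 1.0), (1, -1.0)]))
        b_ub.append(0.0)
    for i in range(na - 2):
        h1, h2 = dx[i], dx[i + 1]
        A_ub.append(row([(i, -h2), (i + 1, h1 + h2), (i + 2, -h1)]))
        b_ub.append(0.0)
    # right concavity, last slope >= 0
    if nb >= 2:
        A_ub.append(row([(nv - 3, 1.0), (nv - 2, -1.0)]))
        b_ub.append(0.0)
    for i in range(nb - 2):
        h1, h2 = dx[k - 1 + i], dx[k + i]
        j = na + i
        A_ub.append(row([(j, h2), (j + 1, -(h1 + h2)), (j + 2, h1)]))
        b_ub.append(0.0)
    # connection across the (possible) atom at the mode
    A_ub.append(row([(na - 1, 1.0), (na, -1.0)]))
    b_ub.append(0.0)

    c = np.zeros(nv)
    c[D] = 1.0
    res = linprog(
        c,
        A_ub=np.asarray(A_ub),
        b_ub=np.asarray(b_ub),
        bounds=[(0.0, 1.0)] * (nv - 1) + [(0.0, 0.5)],
        method="highs",
    )
    return float(res.fun) if res.status == 0 else None


def dip_oracle(values) -> float:
    """Exact dip statistic via per-mode linear programs."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2:
        return 0.0
    assert np.unique(x).size == n, "oracle requires distinct values"
    best = np.inf
    for k in range(1, n + 1):
        d = _min_d_for_mode(x, k)
        if d is not None:
            best = min(best, d)
    return best
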