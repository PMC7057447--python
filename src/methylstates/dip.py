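"""Hartigan's dip statistic for unimodality, with a Monte-Carlo p-value.

The dip of an empirical distribution function F_n is the smallest
sup-norm distance between F_n and any unimodal distribution function
(one whose CDF is convex up to a mode and concave after it).  Large dip
means the sample is poorly approximated by any unimodal shape.

The computation follows the classical greatest-convex-minorant /
least-concave-majorant narrowing scheme: fit the GCM and LCM of F_n over
a working interval, find where the two hulls are farthest apart, record
the deviations of F_n from the hulls outside that span, and shrink the
working interval to it; iterate until no improvement is possible.  The
result is exact (it is validated in the test suite against an
independent linear-programming formulation of the definition).

The p-value is calibrated by simulation against the uniform null, the
asymptotically least-favorable unimodal distribution, so it is mildly
conservative for peaked unimodal alternatives.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def dip_statistic(values) -> float:
    """Dip statistic of a 1-D sample.

    Returns 0.0 for samples of size < 2 or constant samples; otherwise a
    value in [1/(2n), 1/4].
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    if not np.isfinite(x).all():
        raise ValidationError("dip_statistic requires finite values")

    low, high = 0, n - 1
    best = 1.0  # dip in count units; the minimum achievable is one jump
    mn = np.empty(n, dtype=np.int64)  # GCM predecessor links
    mj = np.empty(n, dtype=np.int64)  # LCM successor links
    gcm = np.empty(n + 1, dtype=np.int64)
    lcm = np.empty(n + 1, dtype=np.int64)

    while True:
        # greatest convex minorant touch points over [low, high]
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                mnmnj = mn[mnj]
                if mnj == low or (x[j] - x[mnj]) * (mnj - mnmnj) < (
                    x[mnj] - x[mnmnj]
                ) * (j - mnj):
                    break
                mn[j] = mnmnj
        # least concave majorant touch points
        mj[high] = high
        for k in range(high - 1, low - 1, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                mjmjk = mj[mjk]
                if mjk == high or (x[k] - x[mjk]) * (mjk - mjmjk) < (
                    x[mjk] - x[mjmjk]
                ) * (k - mjk):
                    break
                mj[k] = mjmjk

        ic = 0
        gcm[0] = high
        while gcm[ic] > low:
            gcm[ic + 1] = mn[gcm[ic]]
            ic += 1
        ig = l_gcm = ic  # gcm[l_gcm] == low
        ix = ig - 1

        ic = 0
        lcm[0] = low
        while lcm[ic] < high:
            lcm[ic + 1] = mj[lcm[ic]]
            ic += 1
        ih = l_lcm = ic  # lcm[l_lcm] == high
        iv = 1

        # largest vertical distance between the two hulls, in counts
        d = 0.0
        if l_gcm != 1 or l_lcm != 1:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # LCM vertex lies inside a GCM segment
                    gcmi1 = gcm[ix + 1]
                    span = x[gcmix] - x[gcmi1]
                    if span > 0:
                        interp = (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / span
                    else:
                        interp = 0.0
                    dx = (lcmiv - gcmi1 + 1) - interp
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # GCM vertex lies inside an LCM segment
                    lcmiv1 = lcm[iv - 1]
                    span = x[lcmiv] - x[lcmiv1]
                    if span > 0:
                        interp = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / span
                    else:
                        interp = float(lcmiv - lcmiv1)
                    dx = interp - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < best:
            break

        # deviation of F_n above the GCM, left of the new working interval
        dl = 0.0
        for j in range(ig, l_gcm):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if max_t > dl:
                dl = max_t
        # deviation of F_n below the LCM, right of the new working interval
        du = 0.0
        for j in range(ih, l_lcm):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if max_t > du:
                du = max_t

        best = max(best, dl, du)
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    best = max(best, d)
    return best / (2.0 * n)


def dip_pvalue(
    dip: float, n: int, n_boot: int = 200, rng: np.random.Generator | None = None
) -> float:
    """Monte-Carlo p-value of a dip value against the uniform(0,1) null.

    Simulates ``n_boot`` uniform samples of size ``n`` and returns the
    add-one estimate P(dip_null >= dip).
    """
    if n < 2:
        return 1.0
    rng = np.random.default_rng(rng)
    null = np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])
    return float((1 + np.sum(null >= dip)) / (1 + n_boot))


def dip_test(
    values, n_boot: int = 200, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Convenience wrapper returning (dip, Monte-Carlo p-value)."""
    d = dip_statistic(values)
    return d, dip_pvalue(d, len(np.asarray(values).ravel()), n_boot=n_boot, rng=rng)
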