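"""Hartigan's dip statistic and test of unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and the class of unimodal distribution functions (convex
below the mode, concave above). It is computed by the classical iterative
algorithm: within a shrinking modal interval, fit the greatest convex
minorant (GCM) and least concave majorant (LCM) of F_n, find their largest
separation, accumulate the deviations of F_n from the hulls outside the
candidate modal interval, and stop when the hull separation no longer exceeds
the accumulated deviation. The result, in units of probability, lies in
[1/(2n), 1/4]; it is invariant under affine rescaling of the data (but not
under general monotone transforms, which change convexity).

P-values are obtained by a seeded parametric bootstrap from the uniform
distribution — the least-favorable unimodal null — and cached per sample
size, since the null distribution of the dip depends only on n.

All computations are in "count" units internally (the ECDF scaled by n);
the GCM is fit to the lower ECDF values (i at x_i, 0-based) and the LCM to
the upper values (i + 1), which is where the +-1 terms in the separation
formulas come from. The final count-scale dip is divided by 2n.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _cross(xp, yp, xq, yq, xr, yr) -> float:
    return (xq - xp) * (yr - yp) - (xr - xp) * (yq - yp)


def _lower_hull(x: np.ndarray, lo: int, hi: int) -> list[int]:
    """Indices of the greatest convex minorant of (x_i, i), i in [lo, hi]."""
    hull: list[int] = []
    for i in range(lo, hi + 1):
        while len(hull) >= 2 and _cross(
                x[hull[-2]], hull[-2], x[hull[-1]], hull[-1], x[i], i) <= 0:
            hull.pop()
        hull.append(i)
    return hull


def _upper_hull(x: np.ndarray, lo: int, hi: int) -> list[int]:
    """Indices of the least concave majorant of (x_i, i), i in [lo, hi]."""
    hull: list[int] = []
    for i in range(lo, hi + 1):
        while len(hull) >= 2 and _cross(
                x[hull[-2]], hull[-2], x[hull[-1]], hull[-1], x[i], i) >= 0:
            hull.pop()
        hull.append(i)
    return hull


def dip_statistic(values: np.ndarray) -> float:
    """The dip statistic of a 1-D sample (probability units)."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if n == 1 or x[0] == x[-1]:
        return 0.0

    low, high = 0, n - 1
    dip = 1.0  # count units; 1 is the minimal attainable separation

    while True:
        gcm = _lower_hull(x, low, high)[::-1]   # stored high -> low
        lcm = _upper_hull(x, low, high)         # stored low -> high
        l_gcm, l_lcm = len(gcm), len(lcm)

        if l_gcm == 2 and l_lcm == 2:
            d = 1.0
            ig, ih = l_gcm - 1, l_lcm - 1
        else:
            # walk the two hulls to find their largest vertical separation
            d = 0.0
            ix, iv = l_gcm - 2, 1
            ig, ih = l_gcm - 1, l_lcm - 1
            while True:
                gx, lv = gcm[ix], lcm[iv]
                if gx > lv:
                    # LCM corner (upper value lv+1) against the GCM chord
                    g1 = gcm[ix + 1]
                    dx = (lv - g1 + 1) - (x[lv] - x[g1]) * (gx - g1) / (x[gx] - x[g1])
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv - 1
                else:
                    # GCM corner (lower value gx) against the LCM chord
                    l1 = lcm[iv - 1]
                    dx = (x[gx] - x[l1]) * (lv - l1) / (x[lv] - x[l1]) \
                        - (gx - l1 - 1)
                    ix -= 1
                    if dx > d:
                        d, ig, ih = dx, ix + 1, iv
                ix = max(ix, 0)
                iv = min(iv, l_lcm - 1)
                if gcm[ix] == lcm[iv]:
                    break

        if d < dip:
            break

        # deviation of F_n above the GCM hull left of the modal interval
        dl = 0.0
        for i in range(ig, l_gcm - 1):
            je, jb = gcm[i], gcm[i + 1]   # jb < je
            t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for j in range(jb, je + 1):
                    t = max(t, (j - jb + 1) - (x[j] - x[jb]) * c)
            dl = max(dl, t)
        # deviation of F_n below the LCM hull right of the modal interval
        du = 0.0
        for i in range(ih, l_lcm - 1):
            jb, je = lcm[i], lcm[i + 1]
            t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for j in range(jb, je + 1):
                    t = max(t, (x[j] - x[jb]) * c - (j - jb - 1))
            du = max(du, t)

        dip = max(dip, dl, du)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return float(dip / (2.0 * n))


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    key = (n, n_boot, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.array([
            dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)
        ])
    return _NULL_CACHE[key]


def dip_test(values: np.ndarray, n_boot: int = 500, seed: int = 0
             ) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform null.

    Small p-values indicate multimodality. The null table is simulated once
    per (n, n_boot, seed) and cached, so repeated tests at the same sample
    size are cheap.
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n < 10:
        raise ValueError("dip test requires at least 10 observations")
    d = dip_statistic(values)
    null = _null_dips(n, n_boot, seed)
    p = float((np.sum(null >= d) + 1) / (n_boot + 1))
    return d, p
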