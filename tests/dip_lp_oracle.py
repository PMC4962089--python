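"""Exact LP oracle for Hartigan's dip statistic (small samples only).

The dip is the minimal sup-norm distance between the empirical CDF and any
unimodal CDF (convex left of the mode, concave right of it, with at most
one atom, located at the mode). For a fixed mode location this minimization
is a linear program over the CDF's values at the data points plus the two
one-sided mode values; the oracle takes the minimum over every data point
as mode and a grid of interior positions within every inter-point gap.
Independent of the production algorithm — used only to validate it.
"""

import numpy as np
from scipy.optimize import linprog


def _solve_fixed_mode(xs, cum, low, n, k_left, xm, band_lo, band_hi):
    m = len(xs)
    at_knot = k_left < m and xs[k_left] == xm
    left_knots = list(range(k_left)) if at_knot else list(range(k_left + 1))
    right_knots = list(range(k_left + 1, m))
    idx = {j: i for i, j in enumerate(left_knots + right_knots)}
    GM = len(idx)  # left limit at the mode
    GP = GM + 1  # CDF value at the mode (after a possible atom)
    D = GM + 2
    nv = D + 1
    c = np.zeros(nv)
    c[D] = 1.0
    A, b = [], []

    def ub(coefs, rhs):
        row = np.zeros(nv)
        for i, v in coefs:
            row[i] += v
        A.append(row)
        b.append(rhs)

    for j in idx:  # sup-norm bands at the data points
        ub([(idx[j], -1), (D, -1)], -cum[j] / n)
        ub([(idx[j], 1), (D, -1)], low[j] / n)
    ub([(GM, -1), (D, -1)], -band_hi / n)
    ub([(GM, 1), (D, -1)], band_hi / n)
    ub([(GP, -1), (D, -1)], -band_lo / n)
    ub([(GP, 1), (D, -1)], band_lo / n)
    ub([(GM, 1), (GP, -1)], 0.0)  # the atom can only jump up

    chain_l = [(xs[j], idx[j]) for j in left_knots] + [(xm, GM)]
    chain_r = [(xm, GP)] + [(xs[j], idx[j]) for j in right_knots]
    for ch in (chain_l, chain_r):  # monotonicity
        for (_, i1), (_, i2) in zip(ch, ch[1:]):
            ub([(i1, 1), (i2, -1)], 0.0)
    for ch, sign in ((chain_l, 1.0), (chain_r, -1.0)):  # convex / concave
        for (x1, i1), (x2, i2), (x3, i3) in zip(ch, ch[1:], ch[2:]):
            d1, d2 = x2 - x1, x3 - x2
            if d1 <= 0 or d2 <= 0:
                continue
            ub([(i1, -sign * d2), (i2, sign * (d1 + d2)), (i3, -sign * d1)], 0.0)

    res = linprog(
        c, A_ub=np.array(A), b_ub=np.array(b),
        bounds=[(0, 1)] * nv, method="highs",
    )
    return res.fun if res.status == 0 else np.inf


def dip_lp(sample, gap_grid: int = 15) -> float:
    x = np.sort(np.asarray(sample, dtype=float))
    xs, counts = np.unique(x, return_counts=True)
    n = len(x)
    cum = np.cumsum(counts).astype(float)
    low = (cum - counts).astype(float)
    m = len(xs)
    best = np.inf
    for k in range(m):  # mode at a data point
        best = min(
            best, _solve_fixed_mode(xs, cum, low, n, k, xs[k], cum[k], low[k])
        )
    for k in range(m - 1):  # mode inside a gap (F flat at cum[k])
        for f in np.linspace(0, 1, gap_grid + 2)[1:-1]:
            xm = xs[k] + f * (xs[k + 1] - xs[k])
            best = min(
                best,
                _solve_fixed_mode(xs, cum, low, n, k, xm, cum[k], cum[k]),
            )
    return float(best)
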