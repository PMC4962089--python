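"""Population statistics of recovery halftimes.

Covers the population-level questions raised by a sample of rupture-recovery
halftimes: is the distribution unimodal (Hartigan & Hartigan's dip test,
calibrated by bootstrap against the uniform null), what are the fast and
slow sub-populations (two-component normal mixture by maximum likelihood /
EM), where is the tipping point (the halftime with equal posterior
membership probability in either component), and how strongly does the
halftime scale with rupture extent (ordinary least squares with R^2 and a
normal-theory confidence band).

The dip statistic is computed with the iterative greatest-convex-minorant /
least-concave-majorant algorithm of Hartigan & Hartigan: the statistic is
the smallest sup-norm distance between the empirical CDF and any unimodal
CDF, and satisfies dip >= 1/(2n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "DipResult",
    "MixtureFit",
    "RegressionFit",
    "dip_statistic",
    "dip_test",
    "fit_two_component_mixture",
    "tipping_point",
    "bootstrap_mixture_ci",
    "linear_fit_r2",
]


# ---------------------------------------------------------------------------
# Hartigan's dip


@dataclass(frozen=True)
class DipResult:
    dip: float
    pvalue: float
    n: int
    n_boot: int


def dip_statistic(sample) -> float:
    """Hartigan's dip: min over unimodal CDFs G of sup |F_n - G|.

    Iteratively fits the greatest convex minorant and least concave majorant
    of the empirical CDF over a shrinking modal interval; the returned value
    is in CDF units and is at least 1/(2n) for non-degenerate samples.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n == 1 or x[0] == x[-1]:
        return 0.0
    if n <= 3:
        return 1.0 / (2 * n)

    # mn[j]: predecessor vertex of the greatest convex minorant at j,
    # mj[k]: successor vertex of the least concave majorant at k
    # (Graham-scan style slope comparisons on the empirical CDF).
    mn = np.zeros(n, dtype=np.intp)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            a = mn[j]
            b = mn[a]
            if a == 0 or (x[j] - x[a]) * (a - b) < (x[a] - x[b]) * (j - a):
                break
            mn[j] = b
    mj = np.zeros(n, dtype=np.intp)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            a = mj[k]
            b = mj[a]
            if a == n - 1 or (x[k] - x[a]) * (a - b) < (x[a] - x[b]) * (k - a):
                break
            mj[k] = b

    low, high = 0, n - 1
    dip = 1.0  # in units of counts; converted to CDF units at the end
    while True:
        # convex minorant change points, high -> low
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        # concave majorant change points, low -> high
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        gcm = [0] + gcm  # 1-based working arrays
        lcm = [0] + lcm
        l_gcm = len(gcm) - 1
        l_lcm = len(lcm) - 1
        ig, ih = l_gcm, l_lcm
        ix, iv = l_gcm - 1, 2

        # largest distance between the two fits inside [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # lcm vertex falls inside a gcm segment
                    g1 = gcm[ix + 1]
                    dx = (lcmiv - g1 + 1) - (x[lcmiv] - x[g1]) * (
                        gcmix - g1
                    ) / (x[gcmix] - x[g1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # gcm vertex falls inside an lcm segment
                    l1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[l1]) * (lcmiv - l1) / (
                        x[lcmiv] - x[l1]
                    ) - (gcmix - l1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # dip of the convex-minorant fit on the left flank
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            dip_l = max(dip_l, max_t)
        # dip of the concave-majorant fit on the right flank
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            dip_u = max(dip_u, max_t)

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if (new_low, new_high) == (low, high):
            break
        low, high = new_low, new_high
    return dip / (2.0 * n)


def dip_test(sample, n_boot: int = 2000, seed: int | None = None) -> DipResult:
    """Dip test of unimodality with a bootstrap p-value.

    The null reference is the uniform distribution (the asymptotically least
    favorable unimodal law): ``n_boot`` uniform samples of the same size
    give the null dip distribution and the p-value is the fraction of null
    dips at least as large as the observed one.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("dip test needs n >= 4")
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    boot = np.array(
        [dip_statistic(rng.uniform(size=x.size)) for _ in range(n_boot)]
    )
    p = float((1 + np.sum(boot >= d)) / (1 + n_boot))
    return DipResult(dip=d, pvalue=p, n=int(x.size), n_boot=n_boot)


# ---------------------------------------------------------------------------
# two-component normal mixture


@dataclass
class MixtureFit:
    """Two-component normal mixture fit (components sorted mean-ascending)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    n: int
    degenerate: bool = False
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _em_once(
    x: np.ndarray,
    mu: np.ndarray,
    sd: np.ndarray,
    w: np.ndarray,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> MixtureFit:
    n = x.size
    history = []
    ll_prev = -np.inf
    converged = False
    degenerate = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log domain for numerical safety)
        logp = np.log(w)[:, None] + sps.norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        logtot = np.logaddexp(logp[0], logp[1])
        ll = float(logtot.sum())
        if history and ll < history[-1] - 1e-8 * (1 + abs(ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{history[-1]} -> {ll}"
            )
        history.append(ll)
        resp = np.exp(logp - logtot[None, :])
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2
        sd = np.sqrt(np.maximum(var, 0.0))
        if np.any(sd < sd_floor):
            degenerate = True
            sd = np.maximum(sd, sd_floor)
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
    order = np.argsort(mu)
    return MixtureFit(
        means=mu[order],
        sds=sd[order],
        weights=w[order],
        log_likelihood=history[-1],
        converged=converged,
        n_iter=it,
        n=n,
        degenerate=degenerate,
        loglik_history=np.asarray(history),
    )


def fit_two_component_mixture(
    sample,
    n_starts: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Maximum-likelihood two-component normal mixture via multi-start EM.

    The best of ``n_starts`` seeded initializations is returned, components
    sorted mean-ascending. Component SDs are floored at a small fraction of
    the sample spread; a fit that hit the floor is flagged ``degenerate``.
    The per-iteration log-likelihood is recorded and verified to be
    non-decreasing.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("mixture fit needs n >= 10")
    spread = float(x.std())
    if spread == 0:
        raise ValueError("all observations identical: no two-component fit")
    sd_floor = max(1e-3 * spread, 1e-12)
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for s in range(n_starts):
        if s == 0:
            mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
        else:
            mu = rng.choice(x, size=2, replace=False).astype(float)
            if mu[0] == mu[1]:
                mu[1] += spread * 0.1
        fit = _em_once(
            x,
            mu=mu.copy(),
            sd=np.array([spread, spread]),
            w=np.array([0.5, 0.5]),
            tol=tol,
            max_iter=max_iter,
            sd_floor=sd_floor,
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def tipping_point(fit: MixtureFit) -> float:
    """Halftime with equal posterior probability of either component.

    Solves ``w1 phi1(x) = w2 phi2(x)`` (a quadratic in x once logs are
    taken) and returns the root lying between the two component means. If no
    root falls between the means (extreme variance ratios), the crossing
    nearest to the inter-mean midpoint is returned with a warning.
    """
    (m1, m2), (s1, s2), (w1, w2) = fit.means, fit.sds, fit.weights
    if m1 == m2:
        raise ValueError("tipping point undefined for coincident means")
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = (
        0.5 * m2**2 / s2**2
        - 0.5 * m1**2 / s1**2
        + math.log((w1 * s2) / (w2 * s1))
    )
    if abs(a) < 1e-300:
        roots = np.array([-c / b]) if b != 0 else np.empty(0)
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            roots = np.empty(0)
        else:
            sq = math.sqrt(disc)
            roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    if roots.size == 0:
        raise ValueError("posterior-equality equation has no real root")
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size:
        return float(inside[0])
    mid = 0.5 * (m1 + m2)
    nearest = float(roots[np.argmin(np.abs(roots - mid))])
    warnings.warn(
        "no density crossing between the component means; returning the "
        f"nearest crossing ({nearest:.3g})",
        RuntimeWarning,
        stacklevel=2,
    )
    return nearest


def bootstrap_mixture_ci(
    sample,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int | None = None,
    **fit_kwargs,
) -> dict:
    """Percentile bootstrap confidence intervals on mixture parameters."""
    x = np.asarray(sample, dtype=float)
    rng = np.random.default_rng(seed)
    draws = {"means": [], "sds": [], "weights": []}
    for _ in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        try:
            fit = fit_two_component_mixture(
                xb, seed=int(rng.integers(2**31)), **fit_kwargs
            )
        except (ValueError, RuntimeError):
            continue
        draws["means"].append(fit.means)
        draws["sds"].append(fit.sds)
        draws["weights"].append(fit.weights)
    alpha = (1 - level) / 2
    out = {}
    for key, vals in draws.items():
        arr = np.asarray(vals)
        out[key] = {
            "lower": np.quantile(arr, alpha, axis=0).tolist(),
            "upper": np.quantile(arr, 1 - alpha, axis=0).tolist(),
        }
    out["n_boot_effective"] = len(draws["means"])
    return out


# ---------------------------------------------------------------------------
# extent-vs-halftime regression


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    n: int
    band_level: float
    residual_sd: float
    x_mean: float
    x_ss: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x_grid) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band for the mean response (for plotting)."""
        xg = np.asarray(x_grid, dtype=float)
        tcrit = sps.t.ppf(0.5 + self.band_level / 2, self.n - 2)
        half = (
            tcrit
            * self.residual_sd
            * np.sqrt(1.0 / self.n + (xg - self.x_mean) ** 2 / self.x_ss)
        )
        y = self.predict(xg)
        return y - half, y + half


def linear_fit_r2(x, y, band_level: float = 0.99) -> RegressionFit:
    """Ordinary least squares of halftime on rupture extent with R^2.

    ``R^2 = 1 - SS_res / SS_tot``; the stored band parameters give the
    ``band_level`` (default 99%) confidence band for the fitted line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("regression needs at least 3 finite points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression undefined")
    res = sps.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        n=int(x.size),
        band_level=band_level,
        residual_sd=math.sqrt(ss_res / (x.size - 2)) if x.size > 2 else 0.0,
        x_mean=float(x.mean()),
        x_ss=float(np.sum((x - x.mean()) ** 2)),
    )
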