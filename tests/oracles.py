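"""Independent reference implementations used only to cross-check clamap.

Everything here is deliberately written by a different route than the
package: exhaustive enumeration, grid search, and naive per-position loops.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats


def grid_ml_rf(n: int, k: int, population_type: str, grid_size: int = 400001):
    """ML estimate of r by dense grid search over the binomial likelihood.

    k discordant pairs out of n, with P(discordant) = R(r).
    """
    r = np.linspace(0.0, 0.499999, grid_size)
    if population_type == "DH":
        R = r
    else:
        R = 2 * r / (1 + 2 * r)
    R = np.clip(R, 1e-12, 1 - 1e-12)
    ll = k * np.log(R) + (n - k) * np.log(1 - R)
    return float(r[np.argmax(ll)])


def brute_force_sarf(dist: np.ndarray, perms: np.ndarray) -> float:
    """Vectorized exhaustive SARF minimum given precomputed permutations."""
    seg = dist[perms[:, :-1], perms[:, 1:]]
    return float(seg.sum(axis=1).min())


def all_path_orders(m: int) -> np.ndarray:
    """All m!/2 distinct open-path orders (first endpoint < last endpoint)."""
    rows = [
        p
        for p in itertools.permutations(range(m))
        if p[0] < p[-1]
    ]
    return np.array(rows, dtype=int)


def lis_dp(seq) -> int:
    """Longest strictly increasing subsequence by O(n^2) dynamic programming."""
    seq = list(seq)
    n = len(seq)
    best = [1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i]:
                best[i] = max(best[i], best[j] + 1)
    return max(best) if n else 0


def spearman_closed_form(rank_a, rank_b) -> float:
    """1 - 6 sum d^2 / (n (n^2-1)) for tie-free ranks."""
    d = np.asarray(rank_a, float) - np.asarray(rank_b, float)
    n = len(d)
    return 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))


def chain_conditional_prob(r_left, r_right, g_left, g_right, population_type):
    """P(QTL = parent-1 | flanks) by exhaustive enumeration of the 3-locus chain."""
    if population_type == "DH":
        RL, RR = r_left, r_right
    else:
        RL = 2 * r_left / (1 + 2 * r_left)
        RR = 2 * r_right / (1 + 2 * r_right)
    total = {0: 0.0, 1: 0.0}
    for a in (0, 1):
        for q in (0, 1):
            for b in (0, 1):
                p = 0.5
                p *= RL if a != q else (1 - RL)
                p *= RR if q != b else (1 - RR)
                if a == g_left and b == g_right:
                    total[q] += p
    z = total[0] + total[1]
    return total[0] / z


def plain_interval_mapping_lod(y, codes, pos, grid, population_type="RIL_selfing"):
    """Simple interval mapping by a naive per-position EM loop.

    Independent of the package: flanking markers found by linear search,
    EM iterated on scalars, LOD vs the single-Gaussian null.
    """
    y = np.asarray(y, float)
    n = len(y)
    lods = np.zeros(len(grid))
    for gi, x in enumerate(grid):
        probs = np.empty(n)
        for i in range(n):
            # nearest observed marker left and right
            gl = dl = gr = dr = None
            for j in range(len(pos) - 1, -1, -1):
                if pos[j] <= x + 1e-9 and not np.isnan(codes[i, j]):
                    gl, dl = codes[i, j], x - pos[j]
                    break
            for j in range(len(pos)):
                if pos[j] >= x - 1e-9 and not np.isnan(codes[i, j]):
                    gr, dr = codes[i, j], pos[j] - x
                    break
            def factor(g, d, q):
                if g is None:
                    return 1.0
                r = 0.5 * (1 - np.exp(-d / 50.0))
                R = 2 * r / (1 + 2 * r) if population_type == "RIL_selfing" else r
                return (1 - R) if g == q else R
            num = factor(gl, dl, 0) * factor(gr, dr, 0)
            den = num + factor(gl, dl, 1) * factor(gr, dr, 1)
            probs[i] = num / den
        lods[gi] = _em_lod_scalar(y, probs)
    return lods


def _em_lod_scalar(y, q, tol=1e-12, max_iter=500):
    n = len(y)
    x = 2 * q - 1
    vx = x.var()
    s0 = y.var()
    ll0 = -n / 2 * (np.log(2 * np.pi * s0) + 1)
    if vx < 1e-12:
        return 0.0
    a = np.cov(x, y, bias=True)[0, 1] / vx
    mu = y.mean() - a * x.mean()
    m1, m2 = mu + a, mu - a
    s = max(((y - mu - a * x) ** 2).mean(), 1e-12)
    prev = -np.inf
    for _ in range(max_iter):
        d1 = stats.norm.pdf(y, m1, np.sqrt(s))
        d2 = stats.norm.pdf(y, m2, np.sqrt(s))
        mix = q * d1 + (1 - q) * d2
        ll = np.log(np.maximum(mix, 1e-300)).sum()
        w = q * d1 / np.maximum(mix, 1e-300)
        m1 = (w * y).sum() / max(w.sum(), 1e-12)
        m2 = ((1 - w) * y).sum() / max((1 - w).sum(), 1e-12)
        s = max((w * (y - m1) ** 2 + (1 - w) * (y - m2) ** 2).mean(), 1e-12)
        if abs(ll - prev) < tol * (abs(ll) + 1):
            break
        prev = ll
    return max((ll - ll0) / np.log(10), 0.0)


def direct_ml_mixture_lod(y, q, n_starts=8, seed=0):
    """Maximize the mixture likelihood directly (Nelder-Mead, multistart)."""
    y = np.asarray(y, float)
    n = len(y)

    def nll(theta):
        mu, a, log_s = theta
        s = np.exp(log_s)
        d1 = stats.norm.pdf(y, mu + a, np.sqrt(s))
        d2 = stats.norm.pdf(y, mu - a, np.sqrt(s))
        return -np.log(np.maximum(q * d1 + (1 - q) * d2, 1e-300)).sum()

    rng = np.random.default_rng(seed)
    best = np.inf
    sd = y.std()
    for _ in range(n_starts):
        x0 = [
            y.mean() + rng.normal(0, 0.3 * sd),
            rng.normal(0, sd),
            np.log(max(y.var() * rng.uniform(0.3, 1.2), 1e-6)),
        ]
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    s0 = y.var()
    ll0 = -n / 2 * (np.log(2 * np.pi * s0) + 1)
    return max((-best - ll0) / np.log(10), 0.0)


def marker_regression_lod(y, x) -> float:
    """Closed-form LOD of regressing y on a fully observed marker code."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    ss0 = ((y - y.mean()) ** 2).sum()
    b = np.polyfit(x, y, 1)
    ss1 = ((y - np.polyval(b, x)) ** 2).sum()
    return n / 2 * np.log10(ss0 / ss1)
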