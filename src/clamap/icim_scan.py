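"""Inclusive composite interval mapping (ICIM) for additive QTL in RIL/DH lines.

The scan proceeds in two phases.  Phase 1 selects background markers by
forward-backward stepwise linear regression with entry/removal p-value
thresholds (PIN/POUT).  Phase 2 walks a position grid along each linkage
group; at each position the phenotype is adjusted by the selected cofactors
except those flanking the current interval, per-line QTL genotype
probabilities are computed from the flanking markers, and a two-component
Gaussian mixture (means mu +/- a, common variance, mixing weights fixed at
the per-line probabilities) is fitted by EM.  LOD is the log10 likelihood
ratio against the single-Gaussian null on the same adjusted phenotype.

Genotype probabilities condition, per line, on the nearest marker with an
observed genotype on each side of the scanned position, so fully missing
marker columns (a consensus map's extra markers in a population that never
scored them) cost no positional information.  Cofactor shielding, in
contrast, is strictly interval-local: only cofactors that are the current
map interval's own flanking markers are excluded from the background
adjustment.  On a dense consensus map the shielded window around a selected
cofactor is therefore narrower than on a sparse individual map, which
truncates one-LOD support intervals (narrower confidence intervals) while
leaving the peak position and detection power essentially unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .map_model import GeneticMap, GenotypeMatrix
from .recombination import inverse_map_distance, observed_recombination

__all__ = [
    "ScanSettings",
    "ScanResult",
    "QTLCall",
    "stepwise_select",
    "adjust_phenotype",
    "conditional_qtl_probs",
    "em_interval_mapping",
    "icim_scan",
    "call_qtls",
]

LN10 = np.log(10.0)


@dataclass
class ScanSettings:
    """ICIM tuning knobs (defaults follow common wheat QTL practice)."""

    step: float = 0.2  # cM between scanned positions
    p_in: float = 0.001  # stepwise entry threshold
    p_out: float = 0.002  # stepwise removal threshold
    lod_threshold: float = 2.5
    mapping_function: str = "haldane"
    em_tol: float = 1e-10  # relative log-likelihood change
    em_max_iter: int = 200
    peak_min_dip: float = 1.0  # LOD dip separating distinct peaks
    peak_min_distance: float = 5.0  # or cM separation

    def __post_init__(self) -> None:
        if not 0 < self.p_in < self.p_out < 1:
            raise ValueError("need 0 < p_in < p_out < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")


@dataclass
class ScanResult:
    chromosomes: np.ndarray  # per-position group label
    positions: np.ndarray  # cM
    lod: np.ndarray
    additive: np.ndarray
    pve: np.ndarray
    cofactors: list[int] = field(default_factory=list)  # marker indices
    cofactor_betas: np.ndarray = field(default_factory=lambda: np.empty(0))
    em_converged: np.ndarray | None = None


@dataclass
class QTLCall:
    chromosome: str
    position_cM: float
    lod: float
    additive: float
    pve: float
    ci_lo: float
    ci_hi: float

    @property
    def ci_length(self) -> float:
        return self.ci_hi - self.ci_lo


# ---------------------------------------------------------------------------
# Phase 1: stepwise cofactor selection


def _design_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """Markers coded +1/-1 with missing imputed to 0 (the 1:1 expectation)."""
    X = 1.0 - 2.0 * geno.codes  # code 0 -> +1, code 1 -> -1
    return np.where(np.isnan(X), 0.0, X)


def _dedupe_columns(X: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Among identical columns keep only the lowest index."""
    seen: dict[bytes, int] = {}
    keep = []
    for j in candidates:
        key = X[:, j].tobytes()
        if key not in seen:
            seen[key] = j
            keep.append(j)
    return np.array(keep, dtype=int)


def stepwise_select(
    y: np.ndarray,
    X: np.ndarray,
    settings: ScanSettings | None = None,
) -> tuple[list[int], np.ndarray, float]:
    """Forward-backward stepwise regression of y on marker columns.

    Forward: add the candidate with the smallest partial-F p-value if below
    ``p_in``.  Backward: after each addition drop any included variable whose
    p-value exceeds ``p_out``.  Ties break to the lower marker index; exact
    duplicate columns never co-enter.  Returns (selected indices in entry
    order, their joint OLS coefficients, intercept).
    """
    settings = settings or ScanSettings()
    y = np.asarray(y, float)
    n, m = X.shape
    sd = X.std(axis=0)
    candidates = _dedupe_columns(X, np.where(sd > 0)[0])

    selected: list[int] = []
    while True:
        k = len(selected)
        if n <= k + 3:
            break
        avail = np.array([j for j in candidates if j not in selected], dtype=int)
        if len(avail) == 0:
            break
        # residualize y and candidates against [1, X_selected]
        base = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        Q, _ = np.linalg.qr(base)
        ry = y - Q @ (Q.T @ y)
        RC = X[:, avail] - Q @ (Q.T @ X[:, avail])
        nrm = np.linalg.norm(RC, axis=0)
        ok = nrm > 1e-8 * np.sqrt(n)
        if not ok.any():
            break
        ry_nrm = np.linalg.norm(ry)
        if ry_nrm < 1e-12:
            break
        rho = (ry @ RC[:, ok]) / (ry_nrm * nrm[ok])
        rho2 = np.clip(rho**2, 0.0, 1.0 - 1e-15)
        dfe = n - k - 2
        F = rho2 * dfe / (1.0 - rho2)
        pvals = stats.f.sf(F, 1, dfe)
        best = int(np.argmin(pvals))
        if pvals[best] >= settings.p_in:
            break
        selected.append(int(avail[ok][best]))
        # backward sweep
        while len(selected) > 1:
            Xs = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
            beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            resid = y - Xs @ beta
            dfe2 = n - Xs.shape[1]
            s2 = resid @ resid / dfe2
            XtX_inv = np.linalg.pinv(Xs.T @ Xs)
            se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 1e-300))
            t = beta / se
            p = 2 * stats.t.sf(np.abs(t[1:]), dfe2)  # skip intercept
            worst = int(np.argmax(p))
            if p[worst] <= settings.p_out:
                break
            del selected[worst]
    if selected:
        Xs = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        intercept, betas = float(beta[0]), beta[1:]
    else:
        intercept, betas = float(np.mean(y)), np.empty(0)
    return selected, betas, intercept


def adjust_phenotype(
    y: np.ndarray,
    X: np.ndarray,
    cofactors: Sequence[int],
    betas: np.ndarray,
    exclude: Sequence[int] = (),
) -> np.ndarray:
    """Subtract fitted cofactor effects, skipping the excluded (flanking) ones."""
    dy = np.asarray(y, float).copy()
    excl = set(exclude)
    for j, b in zip(cofactors, betas):
        if j not in excl:
            dy -= b * X[:, j]
    return dy


# ---------------------------------------------------------------------------
# Phase 2: conditional QTL probabilities


def conditional_qtl_probs(
    g_left: np.ndarray,
    g_right: np.ndarray,
    r_left: float,
    r_right: float,
    population_type: str = "RIL_selfing",
) -> np.ndarray:
    """P(QTL is the parent-1 homozygote | flanking genotypes), per line.

    ``r_left``/``r_right`` are meiotic recombination fractions between the
    QTL position and each flank; they are converted to the population's
    observable discordance metric, and recombination events in the two
    sub-intervals are taken as independent on that metric (the model under
    which RIL/DH genomes are simulated and two-point estimates are made).
    Missing flanks contribute a flat factor; both missing gives (0.5, 0.5).
    """
    RL = float(observed_recombination(np.asarray(r_left), population_type))
    RR = float(observed_recombination(np.asarray(r_right), population_type))
    gl = np.asarray(g_left, float)
    gr = np.asarray(g_right, float)
    # likelihood factors for QTL = parent-1 (code 0) vs parent-2 (code 1)
    fl0 = np.where(np.isnan(gl), 1.0, np.where(gl == 0, 1 - RL, RL))
    fl1 = np.where(np.isnan(gl), 1.0, np.where(gl == 0, RL, 1 - RL))
    fr0 = np.where(np.isnan(gr), 1.0, np.where(gr == 0, 1 - RR, RR))
    fr1 = np.where(np.isnan(gr), 1.0, np.where(gr == 0, RR, 1 - RR))
    num = fl0 * fr0
    den = num + fl1 * fr1
    return num / den


# ---------------------------------------------------------------------------
# EM mixture fit (vectorized over scan positions)


def _em_mixture(
    dy: np.ndarray,
    p1: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the two-homozygote Gaussian mixture at many positions at once.

    dy, p1: (P, n) adjusted phenotypes and P(QTL = parent-1) per line.
    Returns (loglik, mu, a, sigma2, converged) each of shape (P,).
    The two component means are mu + a (parent-1) and mu - a.
    """
    P, n = dy.shape
    x = 2.0 * p1 - 1.0
    mx = x.mean(axis=1)
    vx = x.var(axis=1)
    my = dy.mean(axis=1)
    cov = ((x - mx[:, None]) * (dy - my[:, None])).mean(axis=1)
    informative = vx > 1e-12
    a = np.where(informative, cov / np.where(vx > 0, vx, 1.0), 0.0)
    mu = my - a * mx
    resid = dy - mu[:, None] - a[:, None] * x
    sigma2 = np.maximum((resid**2).mean(axis=1), 1e-12)

    m1 = mu + a
    m2 = mu - a
    loglik = np.full(P, -np.inf)
    converged = np.zeros(P, dtype=bool)
    active = informative.copy()
    # non-informative rows: mixture collapses to the null Gaussian
    if (~informative).any():
        s0 = np.maximum(dy.var(axis=1), 1e-12)
        ll0 = -n / 2.0 * (np.log(2 * np.pi * s0) + 1.0)
        loglik[~informative] = ll0[~informative]
        m1[~informative] = my[~informative]
        m2[~informative] = my[~informative]
        sigma2[~informative] = s0[~informative]
        converged[~informative] = True

    idx = np.where(active)[0]
    for _ in range(max_iter):
        if len(idx) == 0:
            break
        d = dy[idx]
        q = p1[idx]
        c1 = m1[idx][:, None]
        c2 = m2[idx][:, None]
        s = sigma2[idx][:, None]
        la = -((d - c1) ** 2) / (2 * s)
        lb = -((d - c2) ** 2) / (2 * s)
        hi = np.maximum(la, lb)
        ea = np.exp(la - hi)
        eb = np.exp(lb - hi)
        mix = q * ea + (1 - q) * eb
        ll = (hi + np.log(mix)).sum(axis=1) - n / 2.0 * np.log(
            2 * np.pi * sigma2[idx]
        )
        w = q * ea / mix
        s1 = w.sum(axis=1)
        s2 = n - s1
        new_m1 = np.where(s1 > 1e-12, (w * d).sum(axis=1) / np.maximum(s1, 1e-12), m1[idx])
        new_m2 = np.where(
            s2 > 1e-12, ((1 - w) * d).sum(axis=1) / np.maximum(s2, 1e-12), m2[idx]
        )
        new_s = (
            (w * (d - new_m1[:, None]) ** 2 + (1 - w) * (d - new_m2[:, None]) ** 2)
        ).sum(axis=1) / n
        m1[idx] = new_m1
        m2[idx] = new_m2
        sigma2[idx] = np.maximum(new_s, 1e-12)
        prev = loglik[idx]
        done = np.abs(ll - prev) <= tol * (np.abs(ll) + 1.0)
        loglik[idx] = ll
        converged[idx] = done
        idx = idx[~done]
    mu = (m1 + m2) / 2.0
    a = (m1 - m2) / 2.0
    return loglik, mu, a, sigma2, converged


def em_interval_mapping(
    dy: np.ndarray,
    p1: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> dict:
    """EM fit at a single position; returns LOD, additive effect and fit info.

    The null is the single Gaussian on the same adjusted phenotype; LOD is
    the log10 likelihood ratio.  Non-convergence within ``max_iter`` returns
    the capped values with ``converged=False``.
    """
    dy = np.asarray(dy, float)[None, :]
    p1 = np.asarray(p1, float)[None, :]
    n = dy.shape[1]
    ll1, mu, a, s2, conv = _em_mixture(dy, p1, tol, max_iter)
    s0 = max(float(dy.var()), 1e-12)
    ll0 = -n / 2.0 * (np.log(2 * np.pi * s0) + 1.0)
    lod = max((float(ll1[0]) - ll0) / LN10, 0.0)
    return {
        "lod": lod,
        "additive": float(a[0]),
        "mu": float(mu[0]),
        "sigma2": float(s2[0]),
        "converged": bool(conv[0]),
        "loglik": float(ll1[0]),
        "loglik_null": ll0,
    }


# ---------------------------------------------------------------------------
# The scan


def _position_grid(pos: np.ndarray, step: float) -> np.ndarray:
    lo, hi = pos[0], pos[-1]
    n_steps = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n_steps + 1)
    if grid[-1] < hi - 1e-9:
        grid = np.append(grid, hi)
    return np.round(grid, 9)


def _flank_indices(pos: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map-interval flanks of every grid position (marker itself when on one)."""
    left = np.searchsorted(pos, grid + 1e-9, side="left") - 1
    right = np.searchsorted(pos, grid - 1e-9, side="left")
    left = np.clip(left, 0, len(pos) - 1)
    right = np.clip(right, 0, len(pos) - 1)
    return left, right


def _side_flank_data(
    codes: np.ndarray, pos: np.ndarray, grid: np.ndarray, side: str
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype and distance of the nearest observed marker on one side.

    Per line: genotype (NaN when no observed marker exists on that side) and
    cM distance, for every grid position.  Columns with some observed lines
    are resolved with a vectorized first pass; sporadic per-line missing
    calls walk outward marker by marker.
    """
    n, m = codes.shape
    P = len(grid)
    informative = np.where(~np.isnan(codes).all(axis=0))[0]
    g = np.full((P, n), np.nan)
    d = np.zeros((P, n))
    if len(informative) == 0:
        return g, d
    pin = pos[informative]
    if side == "L":
        # nearest informative marker at pos <= x, then walk further left
        k0 = np.searchsorted(pin, grid + 1e-9, side="left") - 1
        step_dir = -1
    else:
        k0 = np.searchsorted(pin, grid - 1e-9, side="left")
        k0 = np.where(k0 >= len(informative), -1, k0)
        step_dir = +1
    pending = np.ones((P, n), dtype=bool)
    k = k0.copy()
    while True:
        valid = (k >= 0) & (k < len(informative))
        if not valid.any() or not pending[valid].any():
            break
        rows = np.where(valid)[0]
        rows = rows[pending[rows].any(axis=1)]
        if len(rows) == 0:
            break
        cols = informative[k[rows]]
        vals = codes[:, cols].T  # (rows, n)
        hit = pending[rows] & ~np.isnan(vals)
        g[rows] = np.where(hit, vals, g[rows])
        dist = np.abs(grid[rows] - pos[cols])[:, None]
        d[rows] = np.where(hit, dist, d[rows])
        pending[rows] &= ~hit
        k = k + step_dir
        k[~valid] = -1
    return g, d


def _line_probs_for_group(
    codes: np.ndarray,
    pos: np.ndarray,
    grid: np.ndarray,
    population_type: str,
    mapping_function: str,
) -> np.ndarray:
    """(P, n) array of P(QTL = parent-1 | flanking genotypes) per grid position.

    Each line conditions on its nearest observed marker on each side of the
    position; recombination in the two sub-intervals is independent on the
    observable (discordance) metric.  A side with no observed marker
    contributes a flat factor; both sides missing gives 0.5.
    """
    gl, dl = _side_flank_data(codes, pos, grid, "L")
    gr, dr = _side_flank_data(codes, pos, grid, "R")
    rl = inverse_map_distance(dl, mapping_function)
    rr = inverse_map_distance(dr, mapping_function)
    RL = np.asarray(observed_recombination(rl, population_type))
    RR = np.asarray(observed_recombination(rr, population_type))
    fl0 = np.where(np.isnan(gl), 1.0, np.where(gl == 0, 1 - RL, RL))
    fl1 = np.where(np.isnan(gl), 1.0, np.where(gl == 0, RL, 1 - RL))
    fr0 = np.where(np.isnan(gr), 1.0, np.where(gr == 0, 1 - RR, RR))
    fr1 = np.where(np.isnan(gr), 1.0, np.where(gr == 0, RR, 1 - RR))
    num = fl0 * fr0
    return num / (num + fl1 * fr1)


def icim_scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    settings: ScanSettings | None = None,
) -> ScanResult:
    """Full ICIM additive scan over every linkage group of ``gmap``.

    Stepwise cofactor selection runs once on all markers; the EM interval
    fit then runs at every grid position with the phenotype adjusted by all
    cofactors except those that are the current map interval's flanking
    markers.
    """
    settings = settings or ScanSettings()
    y = np.asarray(y, float)
    order = [m for m in gmap.markers if m in set(geno.markers)]
    if order != list(gmap.markers):
        missing = set(gmap.markers) - set(geno.markers)
        raise ValueError(f"map markers absent from genotypes: {sorted(missing)[:5]}")
    geno = geno.subset_markers(list(gmap.markers))
    X = _design_matrix(geno)
    cofactors, betas, _ = stepwise_select(y, X, settings)
    var_y = float(np.var(y))

    chrom_out, pos_out, lod_out, add_out, pve_out, conv_out = [], [], [], [], [], []
    marker_offset = 0
    for chrom in gmap.chromosomes:
        gpos = gmap.positions(chrom)
        m = len(gpos)
        codes = geno.codes[:, marker_offset : marker_offset + m]
        grid = _position_grid(gpos, settings.step)
        p1 = _line_probs_for_group(
            codes,
            gpos,
            grid,
            geno.population_type,
            settings.mapping_function,
        )
        li, ri = _flank_indices(gpos, grid)
        li_g = li + marker_offset
        ri_g = ri + marker_offset
        # group positions by identical cofactor-exclusion sets
        cof = np.array(cofactors, dtype=int)
        if len(cof):
            excl_mask = (li_g[:, None] == cof[None, :]) | (
                ri_g[:, None] == cof[None, :]
            )
        else:
            excl_mask = np.zeros((len(grid), 0), dtype=bool)
        dy = np.empty((len(grid), len(y)))
        keys, inverse = np.unique(excl_mask, axis=0, return_inverse=True)
        for kk, key in enumerate(keys):
            adj = adjust_phenotype(y, X, cofactors, betas, exclude=cof[key])
            dy[inverse == kk] = adj

        ll1, _, a, _, conv = _em_mixture(dy, p1, settings.em_tol, settings.em_max_iter)
        s0 = np.maximum(dy.var(axis=1), 1e-12)
        ll0 = -len(y) / 2.0 * (np.log(2 * np.pi * s0) + 1.0)
        lod = np.maximum((ll1 - ll0) / LN10, 0.0)
        x_exp = 2.0 * p1 - 1.0
        pve = 100.0 * a**2 * x_exp.var(axis=1) / max(var_y, 1e-12)

        chrom_out.append(np.full(len(grid), chrom, dtype=object))
        pos_out.append(grid)
        lod_out.append(lod)
        add_out.append(a)
        pve_out.append(pve)
        conv_out.append(conv)
        marker_offset += m

    return ScanResult(
        chromosomes=np.concatenate(chrom_out),
        positions=np.concatenate(pos_out),
        lod=np.concatenate(lod_out),
        additive=np.concatenate(add_out),
        pve=np.concatenate(pve_out),
        cofactors=cofactors,
        cofactor_betas=betas,
        em_converged=np.concatenate(conv_out),
    )


# ---------------------------------------------------------------------------
# Peak calling


def _local_maxima(lod: np.ndarray) -> list[int]:
    """Indices of local maxima (plateau-aware: first index of a plateau)."""
    peaks = []
    i = 0
    n = len(lod)
    while i < n:
        j = i
        while j + 1 < n and lod[j + 1] == lod[i]:
            j += 1
        left_ok = i == 0 or lod[i - 1] < lod[i]
        right_ok = j == n - 1 or lod[j + 1] < lod[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def call_qtls(scan: ScanResult, settings: ScanSettings | None = None) -> list[QTLCall]:
    """Call QTL peaks from a LOD profile with one-LOD-drop support intervals.

    Local maxima at or above the LOD threshold are accepted, highest first; a
    lower candidate is kept only if it is separated from every accepted peak
    by a dip of at least one LOD below the lower of the two, or by at least
    the minimum peak distance in cM.
    """
    settings = settings or ScanSettings()
    calls: list[QTLCall] = []
    for chrom in dict.fromkeys(scan.chromosomes):
        sel = scan.chromosomes == chrom
        lod = scan.lod[sel]
        pos = scan.positions[sel]
        add = scan.additive[sel]
        pve = scan.pve[sel]
        cand = [i for i in _local_maxima(lod) if lod[i] >= settings.lod_threshold]
        cand.sort(key=lambda i: (-lod[i], pos[i]))
        accepted: list[int] = []
        for i in cand:
            ok = True
            for j in accepted:
                lo, hi = min(i, j), max(i, j)
                dip = lod[lo : hi + 1].min()
                dist = abs(pos[i] - pos[j])
                if not (
                    dip <= min(lod[i], lod[j]) - settings.peak_min_dip
                    or dist >= settings.peak_min_distance
                ):
                    ok = False
                    break
            if ok:
                accepted.append(i)
        for i in sorted(accepted, key=lambda i: pos[i]):
            drop = lod[i] - 1.0
            lo = i
            while lo > 0 and lod[lo - 1] >= drop:
                lo -= 1
            hi = i
            while hi < len(lod) - 1 and lod[hi + 1] >= drop:
                hi += 1
            calls.append(
                QTLCall(
                    chromosome=str(chrom),
                    position_cM=float(pos[i]),
                    lod=float(lod[i]),
                    additive=float(add[i]),
                    pve=float(pve[i]),
                    ci_lo=float(pos[lo]),
                    ci_hi=float(pos[hi]),
                )
            )
    return calls
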