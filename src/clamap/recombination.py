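"""Two-point recombination-frequency estimation and inverse-variance combination.

For fully homozygous populations the observable discordance R between two
markers relates to the meiotic recombination fraction r as

    DH:           R = r
    RIL (F-inf):  R = 2r / (1 + 2r)

so the maximum-likelihood estimate of r has closed form in both cases:
R_hat = k/n over informative line pairs, then invert R(r).  Sampling
variances follow from the binomial variance of R_hat by the delta method.
Per-population estimates are combined across populations with weights equal
to the reciprocal sampling variance; populations in which a pair cannot be
estimated receive weight zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .map_model import GenotypeMatrix

__all__ = [
    "RFEstimate",
    "RFMatrix",
    "ril_rf_estimate",
    "combine_rf",
    "map_distance",
    "inverse_map_distance",
    "observed_recombination",
    "inverse_observed_recombination",
    "build_rf_matrix",
    "pairwise_rf",
]

logger = logging.getLogger(__name__)

R_MAX = 0.4999
DEFAULT_N_MIN = 20


@dataclass
class RFEstimate:
    """A recombination-frequency estimate with its sampling variance."""

    r_hat: float
    variance: float
    n_informative: int
    estimable: bool = True

    def weight(self) -> float:
        """Inverse-variance weight; zero when non-estimable.

        A variance floor of (1/(n+2))^2 keeps perfect data (R_hat = 0,
        variance 0) dominant without producing an infinite weight.
        """
        if not self.estimable:
            return 0.0
        floor = (1.0 / (self.n_informative + 2)) ** 2
        return 1.0 / max(self.variance, floor)


@dataclass
class RFMatrix:
    """Symmetric matrix of combined pairwise recombination estimates."""

    markers: list[str]
    r: np.ndarray  # (m, m) combined r_hat, NaN where non-estimable
    variance: np.ndarray  # (m, m) combined variance, inf where non-estimable
    n: np.ndarray  # (m, m) total informative pairs

    @property
    def estimable(self) -> np.ndarray:
        return ~np.isnan(self.r)

    def to_frame(self):
        import pandas as pd

        m = len(self.markers)
        iu = np.triu_indices(m, k=1)
        return pd.DataFrame(
            {
                "marker_i": [self.markers[i] for i in iu[0]],
                "marker_j": [self.markers[j] for j in iu[1]],
                "r": self.r[iu],
                "variance": self.variance[iu],
                "n": self.n[iu],
            }
        )


# ---------------------------------------------------------------------------
# Observable discordance <-> meiotic r


def observed_recombination(r, population_type: str):
    """Expected discordance R between homozygous lines at meiotic fraction r."""
    r = np.asarray(r, float)
    if population_type == "DH":
        return r
    if population_type == "RIL_selfing":
        return 2 * r / (1 + 2 * r)
    raise ValueError(f"unknown population type {population_type!r}")


def inverse_observed_recombination(R, population_type: str):
    r = np.asarray(R, float)
    if population_type == "DH":
        return r
    if population_type == "RIL_selfing":
        return r / (2 * (1 - r))
    raise ValueError(f"unknown population type {population_type!r}")


# ---------------------------------------------------------------------------
# Mapping functions


def map_distance(r, function: str = "kosambi"):
    """cM distance for recombination fraction r (Haldane or Kosambi)."""
    r = np.asarray(r, float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("r must lie in [0, 0.5)")
    if function == "haldane":
        return -50.0 * np.log1p(-2 * r)
    if function == "kosambi":
        return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    raise ValueError(f"unknown mapping function {function!r}")


def inverse_map_distance(d, function: str = "kosambi"):
    """Recombination fraction for a cM distance (exact inverse)."""
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if function == "haldane":
        return 0.5 * (1 - np.exp(-d / 50.0))
    if function == "kosambi":
        return 0.5 * np.tanh(d / 50.0)
    raise ValueError(f"unknown mapping function {function!r}")


# ---------------------------------------------------------------------------
# Two-point estimation


def ril_rf_estimate(
    g1: np.ndarray,
    g2: np.ndarray,
    population_type: str = "RIL_selfing",
    *,
    n_min: int = DEFAULT_N_MIN,
) -> RFEstimate:
    """Closed-form ML estimate of r between two genotype columns.

    With n line pairs where both markers are observed and k of them
    discordant, R_hat = k/n.  For DH, r_hat = R_hat with binomial variance
    R_hat(1-R_hat)/n.  For selfing RILs, r_hat = R_hat/(2(1-R_hat)) with the
    delta-method variance [R_hat(1-R_hat)/n] * [1/(2(1-R_hat)^2)]^2.
    Pairs with fewer than ``n_min`` informative lines or R_hat >= 0.5 are
    non-estimable (weight zero downstream).
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    n = int(ok.sum())
    if n == 0:
        return RFEstimate(np.nan, np.inf, 0, estimable=False)
    k = int((g1[ok] != g2[ok]).sum())
    R = k / n
    if n < n_min or R >= 0.5:
        return RFEstimate(np.nan, np.inf, n, estimable=False)
    varR = R * (1 - R) / n
    if population_type == "DH":
        r_hat, var = R, varR
    elif population_type == "RIL_selfing":
        r_hat = R / (2 * (1 - R))
        var = varR * (1.0 / (2 * (1 - R) ** 2)) ** 2
    else:
        raise ValueError(f"unknown population type {population_type!r}")
    return RFEstimate(min(r_hat, R_MAX), var, n, estimable=True)


def combine_rf(estimates: Sequence[RFEstimate]) -> RFEstimate:
    """Inverse-variance-weighted combination across populations.

    r_c = sum(w_i r_i) / sum(w_i) with w_i = 1/Var_i (zero when
    non-estimable) and Var(r_c) = 1/sum(w_i).  Exact zero-variance inputs
    dominate; if several of them disagree they are averaged and the conflict
    is logged.  A single estimate is returned unchanged.
    """
    if len(estimates) == 0:
        raise ValueError("combine_rf needs at least one estimate")
    if len(estimates) == 1:
        return estimates[0]
    exact = [e for e in estimates if e.estimable and e.variance == 0.0]
    if exact:
        vals = np.array([e.r_hat for e in exact])
        if np.ptp(vals) > 1e-12:
            logger.warning(
                "conflicting zero-variance rf estimates %s; averaging", vals
            )
        n_tot = sum(e.n_informative for e in exact)
        w_tot = sum(e.weight() for e in exact)
        return RFEstimate(float(vals.mean()), 1.0 / w_tot, n_tot, estimable=True)
    weights = np.array([e.weight() for e in estimates])
    if weights.sum() == 0:
        n_tot = sum(e.n_informative for e in estimates)
        return RFEstimate(np.nan, np.inf, n_tot, estimable=False)
    r = np.array([e.r_hat if e.estimable else 0.0 for e in estimates])
    r_c = float((weights * r).sum() / weights.sum())
    var_c = float(1.0 / weights.sum())
    n_tot = sum(e.n_informative for e in estimates if e.estimable)
    return RFEstimate(min(r_c, R_MAX), var_c, n_tot, estimable=True)


# ---------------------------------------------------------------------------
# Pairwise matrices


def pairwise_rf(
    geno: GenotypeMatrix, *, n_min: int = DEFAULT_N_MIN
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized all-pairs (r, variance, n) for one population.

    Returns arrays (m, m); r is NaN and variance inf where non-estimable.
    """
    G = geno.codes
    obs = ~np.isnan(G)
    A = np.where(obs, G, 0.0)  # parent-2 indicator
    B = np.where(obs, 1.0 - G, 0.0)  # parent-1 indicator
    M = obs.astype(float)
    n = M.T @ M
    same = A.T @ A + B.T @ B
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n > 0, (n - same) / n, np.nan)
    estimable = (n >= n_min) & (R < 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        varR = R * (1 - R) / n
        if geno.population_type == "DH":
            r, var = R, varR
        else:
            r = R / (2 * (1 - R))
            var = varR * (1.0 / (2 * (1 - R) ** 2)) ** 2
    r = np.where(estimable, np.minimum(r, R_MAX), np.nan)
    var = np.where(estimable, var, np.inf)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(var, 0.0)
    return r, var, n.astype(int)


def build_rf_matrix(
    populations: Sequence[GenotypeMatrix],
    markers: Sequence[str],
    *,
    n_min: int = DEFAULT_N_MIN,
) -> RFMatrix:
    """Combined recombination matrix over the union marker list.

    Each population contributes the inverse of its sampling variance as
    weight; entries estimable in no population are marked non-estimable.
    Every population pair is estimated exactly once (vectorized all-pairs
    pass per population).
    """
    markers = list(markers)
    m = len(markers)
    index = {mk: i for i, mk in enumerate(markers)}
    absent = set(markers)
    for pop in populations:
        absent -= set(pop.markers)
    if absent:
        raise ValueError(
            f"markers absent from every population: {sorted(absent)[:5]}"
        )

    sum_w = np.zeros((m, m))
    sum_wr = np.zeros((m, m))
    n_tot = np.zeros((m, m), dtype=int)
    floor_hit = np.zeros((m, m), dtype=bool)
    for pop in populations:
        present = [mk for mk in pop.markers if mk in index]
        sub = pop.subset_markers(present)
        r, var, n = pairwise_rf(sub, n_min=n_min)
        idx = np.array([index[mk] for mk in present])
        est = ~np.isnan(r)
        floor = (1.0 / (n + 2.0)) ** 2
        w = np.where(est, 1.0 / np.maximum(var, floor), 0.0)
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        sum_w[ii, jj] += w
        sum_wr[ii, jj] += np.where(est, w * r, 0.0)
        n_tot[ii, jj] += np.where(est, n, 0)
        floor_hit[ii, jj] |= est & (var < floor)

    with np.errstate(divide="ignore", invalid="ignore"):
        r_c = np.where(sum_w > 0, sum_wr / sum_w, np.nan)
        var_c = np.where(sum_w > 0, 1.0 / sum_w, np.inf)
    r_c = np.where(sum_w > 0, np.minimum(r_c, R_MAX), np.nan)
    np.fill_diagonal(r_c, 0.0)
    np.fill_diagonal(var_c, 0.0)
    return RFMatrix(markers, r_c, var_c, n_tot)
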