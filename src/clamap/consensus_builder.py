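"""Consensus-map construction from multiple populations' genotypes and maps.

Markers are first grouped by the chromosome information of the individual
maps; markers placed on the same chromosome in every contributing map act as
anchors, and conflicting assignments are resolved toward the chromosome
whose anchors show the strongest combined linkage.  Within each group a
combined recombination matrix is turned into map distances, marker order is
found with a nearest-neighbor construction polished by 2-opt (the classic
traveling-salesman heuristic pair, minimizing the sum of adjacent
distances), cM positions accumulate from adjacent combined estimates, and
markers that inflate the map beyond a per-marker budget are pruned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .map_model import GeneticMap, GenotypeMatrix, spearman_collinearity
from .recombination import RFMatrix, build_rf_matrix, map_distance

__all__ = [
    "ChromosomeGroup",
    "ConsensusMap",
    "ConsensusConfig",
    "assign_groups",
    "order_markers_tsp",
    "sarf",
    "assign_positions",
    "prune_inflators",
    "build_consensus",
]

logger = logging.getLogger(__name__)


@dataclass
class ChromosomeGroup:
    chromosome: str
    markers: list[str]
    anchors: list[str]


@dataclass
class ConsensusConfig:
    mapping_function: str = "kosambi"
    n_min: int = 20
    r_link: float = 0.3  # max rf for anchor-linkage evidence
    max_contrib: float = 10.0  # cM a single marker may add before pruning
    collinearity_gain: float = 0.02  # pruning trigger vs physical map


@dataclass
class ConsensusMap:
    map: GeneticMap
    provenance: pd.DataFrame  # marker, populations carrying it
    pruning_log: pd.DataFrame
    assignment_log: pd.DataFrame
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Step: chromosome grouping


def assign_groups(
    individual_maps: Sequence[GeneticMap],
    populations: Sequence[GenotypeMatrix] | None = None,
    config: ConsensusConfig | None = None,
) -> tuple[list[ChromosomeGroup], pd.DataFrame]:
    """Group markers by chromosome across the individual maps.

    Markers with a consistent chromosome go to that group (anchors when
    present in all maps).  Conflicting markers are resolved, when genotypes
    are supplied, toward the candidate chromosome maximizing the summed
    inverse variance of estimable recombination (r <= r_link) to that
    chromosome's anchors; otherwise they are dropped.  Returns the groups
    and a log of every conflict resolution or drop.
    """
    config = config or ConsensusConfig()
    chrom_votes: dict[str, list[str]] = {}
    for gmap in individual_maps:
        for mk, ch in gmap.chromosome_of().items():
            chrom_votes.setdefault(mk, []).append(ch)
    n_maps = len(individual_maps)

    members: dict[str, list[str]] = {}
    anchors: dict[str, list[str]] = {}
    conflicts: list[str] = []
    log_rows = []
    for mk, votes in chrom_votes.items():
        if len(set(votes)) == 1:
            ch = votes[0]
            members.setdefault(ch, []).append(mk)
            if len(votes) == n_maps:
                anchors.setdefault(ch, []).append(mk)
        else:
            conflicts.append(mk)

    if conflicts and populations:
        anchor_weights = _anchor_linkage_weights(
            conflicts, chrom_votes, anchors, populations, config
        )
        for mk in conflicts:
            weights = anchor_weights.get(mk, {})
            if weights:
                best = max(sorted(weights), key=lambda ch: weights[ch])
                members.setdefault(best, []).append(mk)
                log_rows.append(
                    (mk, "conflict_resolved", best, f"candidates={sorted(set(chrom_votes[mk]))}")
                )
            else:
                log_rows.append((mk, "dropped_no_anchor_linkage", "", ""))
    else:
        for mk in conflicts:
            log_rows.append((mk, "dropped_conflict_unresolvable", "", ""))

    groups = [
        ChromosomeGroup(ch, sorted(members[ch]), sorted(anchors.get(ch, [])))
        for ch in sorted(members)
    ]
    log = pd.DataFrame(log_rows, columns=["marker", "event", "chromosome", "detail"])
    return groups, log


def _anchor_linkage_weights(conflicts, chrom_votes, anchors, populations, config):
    """Sum of 1/Var over estimable rf (r <= r_link) to each chromosome's anchors."""
    from .recombination import pairwise_rf

    out: dict[str, dict[str, float]] = {}
    for pop in populations:
        have = set(pop.markers)
        pop_conflicts = [m for m in conflicts if m in have]
        if not pop_conflicts:
            continue
        for ch, anchor_list in anchors.items():
            pop_anchors = [a for a in anchor_list if a in have]
            if not pop_anchors:
                continue
            sub = pop.subset_markers(pop_conflicts + pop_anchors)
            r, var, _ = pairwise_rf(sub, n_min=config.n_min)
            nc = len(pop_conflicts)
            for i, mk in enumerate(pop_conflicts):
                rv = r[i, nc:]
                vv = var[i, nc:]
                ok = ~np.isnan(rv) & (rv <= config.r_link)
                if ok.any():
                    w = float((1.0 / vv[ok]).sum())
                    out.setdefault(mk, {})
                    out[mk][ch] = out[mk].get(ch, 0.0) + w
    return out


# ---------------------------------------------------------------------------
# Step: marker ordering (nearest neighbor + 2-opt on a path)


def sarf(order: Sequence[int], dist: np.ndarray) -> float:
    """Sum of adjacent distances of an order (the TSP path objective)."""
    order = np.asarray(order)
    return float(dist[order[:-1], order[1:]].sum())


def _nearest_neighbor_order(dist: np.ndarray, start: int) -> list[int]:
    m = len(dist)
    visited = np.zeros(m, dtype=bool)
    order = [start]
    visited[start] = True
    for _ in range(m - 1):
        d = dist[order[-1]].copy()
        d[visited] = np.inf
        order.append(int(np.argmin(d)))  # ties: lowest index
        visited[order[-1]] = True
    return order


def _two_opt_sweep(order: list[int], dist: np.ndarray) -> bool:
    """One first-improvement 2-opt sweep on an open path (in place).

    Reversing order[i..j] replaces edges (i-1,i) and (j,j+1); endpoint moves
    drop one of the two edges.  Deterministic left-to-right sweep.
    """
    m = len(order)
    improved = False
    for i in range(m - 1):
        for j in range(i + 1, m):
            a = dist[order[i - 1], order[i]] if i > 0 else 0.0
            b = dist[order[j], order[j + 1]] if j < m - 1 else 0.0
            na = dist[order[i - 1], order[j]] if i > 0 else 0.0
            nb = dist[order[i], order[j + 1]] if j < m - 1 else 0.0
            if na + nb < a + b - 1e-12:
                order[i : j + 1] = order[i : j + 1][::-1]
                improved = True
    return improved


def _or_opt_sweep(order: list[int], dist: np.ndarray, max_seg: int = 3) -> bool:
    """One first-improvement Or-opt sweep: relocate short segments.

    Moves a segment of 1..max_seg markers to another cut point (orientation
    kept).  Complements 2-opt, which cannot undo single-marker
    displacements on a path.
    """
    m = len(order)
    improved = False
    for seg in range(1, max_seg + 1):
        i = 0
        while i + seg <= m:
            j = i + seg - 1
            prev_e = dist[order[i - 1], order[i]] if i > 0 else 0.0
            next_e = dist[order[j], order[j + 1]] if j < m - 1 else 0.0
            join_e = dist[order[i - 1], order[j + 1]] if 0 < i and j < m - 1 else 0.0
            removal_gain = prev_e + next_e - join_e
            if removal_gain <= 1e-12:
                i += 1
                continue
            best_delta = -1e-12
            best_k = None
            rest = order[:i] + order[j + 1 :]
            for k in range(len(rest) + 1):
                left_e = dist[rest[k - 1], order[i]] if k > 0 else 0.0
                right_e = dist[order[j], rest[k]] if k < len(rest) else 0.0
                cut_e = dist[rest[k - 1], rest[k]] if 0 < k < len(rest) else 0.0
                delta = (left_e + right_e - cut_e) - removal_gain
                if delta < best_delta:
                    best_delta = delta
                    best_k = k
            if best_k is not None:
                segment = order[i : j + 1]
                order[:] = rest[:best_k] + segment + rest[best_k:]
                improved = True
            else:
                i += 1
    return improved


def _local_search(order: list[int], dist: np.ndarray) -> list[int]:
    order = list(order)
    while True:
        changed = _two_opt_sweep(order, dist)
        changed |= _or_opt_sweep(order, dist)
        if not changed:
            return order


def completed_distance_matrix(rf: RFMatrix, mapping_function: str) -> np.ndarray:
    """Ordering distances: map distances completed along the linkage graph.

    Estimable pairs use their combined-rf map distance.  Non-estimable pairs
    use the shortest-path distance through estimable links — map distances
    are additive along a chromosome, so the graph metric approximates the
    true separation far better than a flat penalty.  Pairs in different
    connected components fall back to twice the largest finite distance,
    which discourages adjacency without forbidding it.
    """
    geo, finite = _geodesic_distances(rf.r, mapping_function)
    if not finite.all():
        cap = 2.0 * geo[finite].max() if finite.any() else 1.0
        geo = np.where(finite, geo, cap)
    return geo


def _geodesic_distances(r: np.ndarray, mapping_function: str):
    """Shortest-path completion of the map-distance graph; (geo, finite)."""
    from scipy.sparse.csgraph import shortest_path

    with np.errstate(invalid="ignore"):
        d = np.where(
            np.isnan(r),
            np.inf,
            np.asarray(
                map_distance(
                    np.minimum(np.nan_to_num(r, nan=0.0), 0.4999), mapping_function
                )
            ),
        )
    np.fill_diagonal(d, 0.0)
    geo = shortest_path(d, method="D", directed=False)
    return geo, np.isfinite(geo)


def _double_bridge(order: list[int], rng: np.random.Generator) -> list[int]:
    """Classic 4-segment reconnection; the escape move 2-opt cannot undo."""
    m = len(order)
    cuts = np.sort(rng.choice(np.arange(1, m), size=3, replace=False))
    a, b, c = (int(x) for x in cuts)
    return order[:a] + order[b:c] + order[a:b] + order[c:]


def order_markers_tsp(dist: np.ndarray, *, n_restarts: int | None = None) -> list[int]:
    """Order markers to minimize the sum of adjacent distances (SARF).

    Construction starts a nearest-neighbor tour from the marker with the
    largest distance to its own nearest neighbor (a likely terminal
    marker); first-improvement 2-opt sweeps interleaved with Or-opt segment
    relocations then run to a joint fixed point.  An iterated local search
    (double-bridge perturbations from a fixed-seed generator, keeping the
    best order found) guards against the comb-shaped folds plain 2-opt
    cannot escape.  Deterministic given the distance matrix.
    """
    dist = np.asarray(dist, float)
    m = len(dist)
    if m < 2:
        raise ValueError("need at least two markers to order")
    off = dist + np.diag(np.full(m, np.inf))
    start = int(np.argmax(off.min(axis=1)))
    best = _local_search(_nearest_neighbor_order(dist, start), dist)
    best_cost = sarf(best, dist)
    if m >= 5:
        if n_restarts is None:
            n_restarts = 30 if m > 8 else 10
        rng = np.random.default_rng(12345)
        for _ in range(n_restarts):
            cand = _local_search(_double_bridge(best, rng), dist)
            cost = sarf(cand, dist)
            if cost < best_cost - 1e-12:
                best, best_cost = cand, cost
    return best


# ---------------------------------------------------------------------------
# Step: position assignment


def assign_positions(
    order: Sequence[str],
    rf: RFMatrix,
    mapping_function: str = "kosambi",
    *,
    bridge: str = "downstream",
) -> tuple[pd.DataFrame, list[str]]:
    """Cumulative cM positions along an ordered group.

    Adjacent combined recombination fractions convert to cM via the mapping
    function.  When an adjacent pair is non-estimable, a bridge is used:
    with ``bridge="downstream"`` the nearest downstream marker with an
    estimable rf to the last placed marker defines the interval and the
    intervening markers are spaced by even interpolation (logged); with
    ``bridge="geodesic"`` every adjacent distance is the shortest-path
    distance through the group's estimable linkage graph (restricted to the
    ordered markers), which is what the ordering itself minimizes.  If no
    bridge exists the group splits into sub-groups.

    Returns a frame (marker, position_cM, segment) and the bridge log.
    """
    idx = {m: i for i, m in enumerate(rf.markers)}
    order_i = [idx[m] for m in order]
    if bridge == "geodesic":
        return _assign_positions_geodesic(order, order_i, rf, mapping_function)
    if bridge != "downstream":
        raise ValueError("bridge must be 'downstream' or 'geodesic'")
    m = len(order_i)
    pos = np.zeros(m)
    segment = np.zeros(m, dtype=int)
    log: list[str] = []
    seg = 0
    i = 0
    while i < m - 1:
        a = order_i[i]
        b = order_i[i + 1]
        r = rf.r[a, b]
        if not np.isnan(r):
            pos[i + 1] = pos[i] + float(map_distance(min(r, 0.4999), mapping_function))
            segment[i + 1] = seg
            i += 1
            continue
        # bridge: nearest downstream marker estimable against marker i
        bridge = None
        for j in range(i + 2, m):
            rj = rf.r[a, order_i[j]]
            if not np.isnan(rj):
                bridge = j
                break
        if bridge is None:
            seg += 1
            segment[i + 1 :] = seg
            pos[i + 1] = pos[i]
            log.append(
                f"split:{order[i]}|{order[i+1]} (no estimable bridge downstream)"
            )
            i += 1
            continue
        span = float(
            map_distance(min(rf.r[a, order_i[bridge]], 0.4999), mapping_function)
        )
        k = bridge - i
        for t in range(1, k + 1):
            pos[i + t] = pos[i] + span * t / k
            segment[i + t] = seg
        log.append(
            f"bridge:{order[i]}->{order[bridge]} spans {k} intervals ({span:.2f} cM)"
        )
        i = bridge
    frame = pd.DataFrame({"marker": list(order), "position_cM": pos, "segment": segment})
    # each segment restarts at 0 cM
    frame["position_cM"] -= frame.groupby("segment")["position_cM"].transform("min")
    return frame, log


def _assign_positions_geodesic(order, order_i, rf: RFMatrix, mapping_function: str):
    sub_r = rf.r[np.ix_(order_i, order_i)]
    geo, finite = _geodesic_distances(sub_r, mapping_function)
    m = len(order_i)
    pos = np.zeros(m)
    segment = np.zeros(m, dtype=int)
    log: list[str] = []
    seg = 0
    for i in range(m - 1):
        if not finite[i, i + 1]:
            seg += 1
            log.append(f"split:{order[i]}|{order[i+1]} (disconnected linkage graph)")
        else:
            pos[i + 1] = pos[i] + geo[i, i + 1]
        segment[i + 1] = seg
    frame = pd.DataFrame(
        {"marker": list(order), "position_cM": pos, "segment": segment}
    )
    frame["position_cM"] -= frame.groupby("segment")["position_cM"].transform("min")
    return frame, log


# ---------------------------------------------------------------------------
# Step: pruning of map-inflating markers


def prune_inflators(
    order: list[str],
    rf: RFMatrix,
    *,
    mapping_function: str = "kosambi",
    max_contrib: float = 10.0,
    physical_order: Sequence[str] | None = None,
    collinearity_gain: float = 0.02,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Iteratively drop markers that inflate the map or break collinearity.

    Map length is measured as the sum of adjacent completed (geodesic)
    distances along the order — the quantity the ordering minimizes.  While
    some marker's removal shortens the group by more than ``max_contrib``
    cM, the marker with the largest reduction is removed and lengths are
    re-evaluated.  With a physical order supplied, markers whose removal
    raises the Spearman collinearity by more than ``collinearity_gain`` are
    also removed.  Returns the pruned order and a log of
    (marker, reason, statistic).
    """
    order = list(order)
    log: list[tuple[str, str, float]] = []
    idx = {m: i for i, m in enumerate(rf.markers)}
    dist = completed_distance_matrix(rf, mapping_function)
    while len(order) > 2:
        oi = [idx[m] for m in order]
        m = len(oi)
        reductions = np.empty(m)
        for i in range(m):
            prev_e = dist[oi[i - 1], oi[i]] if i > 0 else 0.0
            next_e = dist[oi[i], oi[i + 1]] if i < m - 1 else 0.0
            join_e = dist[oi[i - 1], oi[i + 1]] if 0 < i < m - 1 else 0.0
            reductions[i] = prev_e + next_e - join_e
        best = int(np.argmax(reductions))
        if reductions[best] <= max_contrib * (1 + 1e-9) + 1e-9:
            break
        log.append((order[best], "length_inflation_cM", float(reductions[best])))
        del order[best]
    if physical_order is not None and len(order) > 3:
        improved = True
        while improved and len(order) > 3:
            improved = False
            try:
                base = spearman_collinearity(order, list(physical_order))
            except ValueError:
                break
            gains = []
            for i in range(len(order)):
                trial = order[:i] + order[i + 1 :]
                try:
                    gains.append(spearman_collinearity(trial, list(physical_order)) - base)
                except ValueError:
                    gains.append(-np.inf)
            best = int(np.argmax(gains))
            if gains[best] > collinearity_gain:
                log.append((order[best], "collinearity_gain", float(gains[best])))
                del order[best]
                improved = True
    return order, log


# ---------------------------------------------------------------------------
# Full pipeline


def _orient_group(frame: pd.DataFrame, anchors: list[str]) -> pd.DataFrame:
    """Canonical orientation: the smallest-named anchor sorts first."""
    names = list(frame["marker"])
    ref_pool = [a for a in anchors if a in names] or names
    ref = min(ref_pool)
    i = names.index(ref)
    if i > len(names) - 1 - i or (
        2 * i == len(names) - 1 and names[-1] < names[0]
    ):
        frame = frame.iloc[::-1].reset_index(drop=True)
        top = frame["position_cM"].max()
        frame["position_cM"] = top - frame["position_cM"]
        frame["segment"] = frame["segment"].max() - frame["segment"]
    frame["position_cM"] -= frame.groupby("segment")["position_cM"].transform("min")
    return frame


def build_consensus(
    populations: Sequence[GenotypeMatrix],
    individual_maps: Sequence[GeneticMap],
    config: ConsensusConfig | None = None,
) -> ConsensusMap:
    """Group, estimate, order, position and prune: the full consensus pipeline."""
    config = config or ConsensusConfig()
    groups, assignment_log = assign_groups(individual_maps, populations, config)

    rows = []
    prune_rows = []
    diag_rows = []
    prov_rows = []
    for grp in groups:
        markers = [
            m
            for m in grp.markers
            if any(m in set(p.markers) for p in populations)
        ]
        if not markers:
            continue
        if len(markers) == 1:
            rows.append((markers[0], grp.chromosome, 0.0, 0))
            continue
        rf = build_rf_matrix(populations, markers, n_min=config.n_min)
        dist = completed_distance_matrix(rf, config.mapping_function)
        order_idx = order_markers_tsp(dist)
        order = [markers[i] for i in order_idx]
        order, plog = prune_inflators(
            order,
            rf,
            mapping_function=config.mapping_function,
            max_contrib=config.max_contrib,
        )
        prune_rows += [(grp.chromosome, m, why, stat) for m, why, stat in plog]
        frame, bridge_log = assign_positions(
            order, rf, config.mapping_function, bridge="geodesic"
        )
        frame = _orient_group(frame, grp.anchors)
        for msg in bridge_log:
            prune_rows.append((grp.chromosome, "", "bridge_or_split", msg))
        for seg, sub in frame.groupby("segment"):
            label = (
                grp.chromosome if frame["segment"].nunique() == 1
                else f"{grp.chromosome}.{seg+1}"
            )
            for _, rec in sub.iterrows():
                rows.append((rec["marker"], label, rec["position_cM"], seg))
        # diagnostics: collinearity vs each individual map
        for k, imap in enumerate(individual_maps):
            common_order = [
                m for m in imap.markers if m in set(order)
            ]
            try:
                rho = spearman_collinearity(order, common_order)
            except ValueError:
                rho = np.nan
            diag_rows.append((grp.chromosome, f"map{k+1}", rho))
    for pop_i, pop in enumerate(populations):
        for m in pop.markers:
            prov_rows.append((m, f"pop{pop_i+1}"))

    table = pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM", "segment"])
    table = table.sort_values(
        ["chromosome", "position_cM"], kind="stable"
    ).reset_index(drop=True)
    gmap = GeneticMap(table[["marker", "chromosome", "position_cM"]])
    provenance = (
        pd.DataFrame(prov_rows, columns=["marker", "population"])
        .groupby("marker")["population"]
        .agg(",".join)
        .reset_index()
    )
    return ConsensusMap(
        map=gmap,
        provenance=provenance,
        pruning_log=pd.DataFrame(
            prune_rows, columns=["chromosome", "marker", "reason", "detail"]
        ),
        assignment_log=assignment_log,
        diagnostics=pd.DataFrame(
            diag_rows, columns=["chromosome", "versus", "spearman"]
        ),
    )
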