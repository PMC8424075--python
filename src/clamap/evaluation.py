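"""Simulation experiments (power/FDR), QTL bookkeeping rules, and prediction.

The experiment harness replays the study design many times: simulate an RIL
population with known QTLs, map it under a chosen map scenario, scan with
ICIM, call peaks, and score detections against the truth using a fixed
support window centered on each true QTL.  A call inside a window counts for
that QTL (only the highest-LOD call per QTL per replicate); calls outside
every window are false positives.  Power is the per-QTL detection fraction;
FDR is false positives over all counted detections, pooled over replicates.

Also here: the bookkeeping rules used on real multi-environment QTL records
-- commonality (<20 cM genetic, <25 Mb physical across populations),
stability (detected in at least half the tested environments), clustering of
stable QTLs across traits (<15 cM between confidence intervals), and
genotypic-value prediction from stable-QTL additive effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .icim_scan import QTLCall, ScanSettings, call_qtls, icim_scan
from .ril_simulator import (
    SimulationDesign,
    map_scenario,
    model_catalog,
    simulate_population,
)

__all__ = [
    "ReplicateOutcome",
    "ExperimentSummary",
    "evaluate_detection",
    "summarize_experiment",
    "run_experiment",
    "qtl_commonality",
    "stability_filter",
    "cluster_qtls",
    "predict_genotypic_values",
]


@dataclass
class ReplicateOutcome:
    replicate: int
    detected: np.ndarray  # per true QTL
    position: np.ndarray  # NaN when not detected
    additive: np.ndarray
    lod: np.ndarray
    ci_length: np.ndarray
    n_false_positives: int


@dataclass
class ExperimentSummary:
    per_qtl: pd.DataFrame  # power_pct, pos/add/cil/lod mean & sd
    fdr_pct: float
    n_replicates: int
    n_true_positives: int
    n_false_positives: int


def evaluate_detection(
    calls: Sequence[QTLCall],
    truth_positions: Sequence[float],
    *,
    support_half_width: float = 2.5,
    replicate: int = 0,
) -> ReplicateOutcome:
    """Score one replicate's calls against the true QTL positions.

    Each call is assigned to the nearest true QTL whose support window
    (+/- ``support_half_width`` cM) contains it (ties to the lower
    position); per QTL, only the highest-LOD assigned call is counted, and
    further assigned calls are neither hits nor false positives.  Calls in
    no window are false positives.
    """
    truth = np.asarray(truth_positions, float)
    q = len(truth)
    assigned: list[list[QTLCall]] = [[] for _ in range(q)]
    n_fp = 0
    for call in calls:
        d = np.abs(truth - call.position_cM)
        inside = d <= support_half_width + 1e-9
        if inside.any():
            cand = np.where(inside)[0]
            best = cand[np.lexsort((truth[cand], d[cand]))][0]
            assigned[int(best)].append(call)
        else:
            n_fp += 1
    detected = np.zeros(q, dtype=bool)
    position = np.full(q, np.nan)
    additive = np.full(q, np.nan)
    lod = np.full(q, np.nan)
    cil = np.full(q, np.nan)
    for i in range(q):
        if assigned[i]:
            top = max(assigned[i], key=lambda c: c.lod)
            detected[i] = True
            position[i] = top.position_cM
            additive[i] = top.additive
            lod[i] = top.lod
            cil[i] = top.ci_length
    return ReplicateOutcome(replicate, detected, position, additive, lod, cil, n_fp)


def summarize_experiment(outcomes: Sequence[ReplicateOutcome]) -> ExperimentSummary:
    """Per-QTL power and conditional-on-detection summaries; pooled FDR."""
    if not outcomes:
        raise ValueError("no replicate outcomes to summarize")
    det = np.array([o.detected for o in outcomes])  # (reps, q)
    reps, q = det.shape
    rows = []
    for i in range(q):
        hit = det[:, i]
        sub = {
            "qtl": i + 1,
            "power_pct": 100.0 * hit.mean(),
        }
        for name, attr in (
            ("pos", "position"),
            ("add", "additive"),
            ("cil", "ci_length"),
            ("lod", "lod"),
        ):
            vals = np.array([getattr(o, attr)[i] for o in outcomes])[hit]
            sub[f"{name}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            sub[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        rows.append(sub)
    n_tp = int(det.sum())
    n_fp = int(sum(o.n_false_positives for o in outcomes))
    fdr = 100.0 * n_fp / (n_fp + n_tp) if (n_fp + n_tp) else 0.0
    return ExperimentSummary(pd.DataFrame(rows), fdr, reps, n_tp, n_fp)


def run_experiment(
    model: str,
    h2: float,
    scenario: str,
    *,
    reps: int = 1000,
    n: int = 200,
    seed: int | None = None,
    step: float = 0.1,
    support_half_width: float = 2.5,
    settings: ScanSettings | None = None,
) -> ExperimentSummary:
    """Replay one study cell: model x heritability x map scenario.

    Fully seeded: replicate r uses the r-th child of SeedSequence(seed).
    """
    design = model_catalog(model, h2, n_lines=n)
    if settings is None:
        settings = ScanSettings(step=step)
    truth = [qtl.position_cM for qtl in design.qtls]
    children = np.random.SeedSequence(seed).spawn(reps)
    outcomes = []
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        pop = simulate_population(design, rng)
        geno, gmap = map_scenario(pop, scenario)
        scan = icim_scan(pop.phenotype, geno, gmap, settings)
        calls = call_qtls(scan, settings)
        outcomes.append(
            evaluate_detection(
                calls, truth, support_half_width=support_half_width, replicate=r
            )
        )
    return summarize_experiment(outcomes)


# ---------------------------------------------------------------------------
# QTL record bookkeeping (real-data style rules)


def _single_linkage_groups(n: int, linked) -> list[int]:
    """Union-find closure over a pairwise predicate; returns group labels."""
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if linked(i, j):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    relabel = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    return [relabel[r] for r in roots]


def qtl_commonality(
    records: pd.DataFrame,
    *,
    max_cm: float = 20.0,
    max_mb: float = 25.0,
) -> pd.DataFrame:
    """Group QTL records that represent the same underlying locus.

    Same-population pairs merge when their positions are within ``max_cm``
    (strict).  Cross-population pairs additionally require the minimum gap
    between the flanking-marker physical intervals to be under ``max_mb``
    Mb; records without physical data fall back to the genetic rule alone
    and the group is flagged.  Grouping is single linkage per chromosome.

    ``records`` columns: population, chromosome, position_cM and optionally
    phys_lo_mb, phys_hi_mb.
    """
    rec = records.reset_index(drop=True)
    has_phys = {"phys_lo_mb", "phys_hi_mb"}.issubset(rec.columns)
    labels = np.full(len(rec), -1)
    flagged = np.zeros(len(rec), dtype=bool)
    next_label = 0
    for chrom, idx in rec.groupby("chromosome").groups.items():
        idx = list(idx)
        sub = rec.loc[idx]
        pos = sub["position_cM"].to_numpy(float)
        popn = sub["population"].to_numpy()

        def linked(i, j):
            if abs(pos[i] - pos[j]) >= max_cm:
                return False
            if popn[i] == popn[j]:
                return True
            if has_phys:
                lo_i, hi_i = sub.iloc[i][["phys_lo_mb", "phys_hi_mb"]]
                lo_j, hi_j = sub.iloc[j][["phys_lo_mb", "phys_hi_mb"]]
                if not (
                    np.isnan(lo_i) or np.isnan(lo_j) or np.isnan(hi_i) or np.isnan(hi_j)
                ):
                    gap = max(lo_j - hi_i, lo_i - hi_j, 0.0)
                    return gap < max_mb
            flagged[idx[i]] = flagged[idx[j]] = True
            return True  # genetic rule only

        grp = _single_linkage_groups(len(idx), linked)
        for local, g in enumerate(grp):
            labels[idx[local]] = next_label + g
        next_label = labels.max() + 1
    out = rec.copy()
    out["common_group"] = labels
    out["genetic_rule_only"] = flagged
    return out


def stability_filter(
    detections: pd.DataFrame, environments_tested: dict
) -> pd.DataFrame:
    """Flag QTLs detected in at least half of the environments tested.

    ``detections`` columns: qtl (or common_group), population, environment.
    ``environments_tested`` maps population -> number of environments.
    """
    key = "common_group" if "common_group" in detections.columns else "qtl"
    counts = (
        detections.drop_duplicates([key, "population", "environment"])
        .groupby([key, "population"])
        .size()
        .rename("n_detected")
        .reset_index()
    )
    counts["n_tested"] = counts["population"].map(environments_tested)
    counts["stable"] = counts["n_detected"] >= np.ceil(counts["n_tested"] / 2.0)
    return counts


def cluster_qtls(records: pd.DataFrame, *, max_gap_cm: float = 15.0) -> pd.DataFrame:
    """Cluster stable QTLs of different traits by confidence-interval gap.

    Single linkage within each chromosome; two records join when the gap
    between their CIs (0 when overlapping) is strictly below ``max_gap_cm``.
    ``records`` columns: chromosome, ci_lo, ci_hi (cM), plus any identifiers.
    """
    rec = records.reset_index(drop=True)
    labels = np.full(len(rec), -1)
    next_label = 0
    for chrom, idx in rec.groupby("chromosome").groups.items():
        idx = list(idx)
        lo = rec.loc[idx, "ci_lo"].to_numpy(float)
        hi = rec.loc[idx, "ci_hi"].to_numpy(float)

        def linked(i, j):
            gap = max(lo[j] - hi[i], lo[i] - hi[j], 0.0)
            return gap < max_gap_cm

        grp = _single_linkage_groups(len(idx), linked)
        for local, g in enumerate(grp):
            labels[idx[local]] = next_label + g
        next_label = labels.max() + 1
    out = rec.copy()
    out["cluster"] = labels
    return out


def predict_genotypic_values(
    qtl_genotypes: np.ndarray,
    effects: Sequence[float],
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Predicted genotypic value and positive-allele count per line.

    ``qtl_genotypes``: (lines, Q) codes in {+1, -1, NaN}; NaN loci are
    skipped for that line (flagged in ``n_missing``).  The positive allele
    at a locus is the one whose carried code has the same sign as the
    effect, i.e. increases the trait.
    """
    G = np.asarray(qtl_genotypes, float)
    a = np.asarray(effects, float)
    contrib = G * a[None, :]
    miss = np.isnan(G)
    ghat = intercept + np.where(miss, 0.0, contrib).sum(axis=1)
    positive = (~miss) & (contrib > 0)
    return pd.DataFrame(
        {
            "predicted_value": ghat,
            "positive_alleles": positive.sum(axis=1),
            "n_missing": miss.sum(axis=1),
        }
    )
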