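"""Simulation of RIL/DH populations on a known map, with additive QTL.

Lines are generated as a Markov chain along the ordered loci of a chromosome:
the first locus is Bernoulli(0.5) over the two parental homozygotes and the
genotype switches between adjacent loci with probability equal to the
expected observable discordance R of the interval (Haldane distances, no
interference; for selfing RILs R = 2r/(1+2r)).  QTLs are simulated as hidden
loci inside the same chain, so their genotypes are exactly consistent with
the flanking-marker recombination model.  Phenotypes are the additive
genetic value plus Gaussian noise scaled to a target broad-sense
heritability computed against the realized genetic variance of the sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .map_model import GeneticMap, GenotypeMatrix
from .recombination import (
    inverse_map_distance,
    observed_recombination,
)

__all__ = [
    "QTL",
    "SimulationDesign",
    "SimulatedPopulation",
    "model_catalog",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_population",
    "map_scenario",
    "multi_population_fixture",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QTL:
    position_cM: float
    additive_effect: float


@dataclass
class SimulationDesign:
    """One simulated study condition: map grid, QTL model, H2, sample size."""

    chromosome_length_cM: float = 100.0
    marker_positions_cM: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 101.0)
    )
    qtls: tuple[QTL, ...] = ()
    heritability: float = 0.2
    n_lines: int = 200
    population_type: str = "RIL_selfing"
    replicates: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.heritability < 1:
            raise ValueError("heritability must lie in (0, 1)")
        for q in self.qtls:
            if not 0 <= q.position_cM <= self.chromosome_length_cM:
                raise ValueError("QTL position outside the chromosome")

    @property
    def marker_names(self) -> list[str]:
        return [f"M{i+1}" for i in range(len(self.marker_positions_cM))]

    def truth_map(self) -> GeneticMap:
        return GeneticMap.from_positions(
            self.marker_names, self.marker_positions_cM, chromosome="1"
        )


@dataclass
class SimulatedPopulation:
    geno: GenotypeMatrix  # marker genotypes only
    qtl_geno: np.ndarray  # (n_lines, n_qtl) in {0, 1}
    genetic_value: np.ndarray
    phenotype: np.ndarray
    design: SimulationDesign


# ---------------------------------------------------------------------------
# The three study models

_MODEL_QTLS = {
    "I": (QTL(34.5, 1.0),),
    "II": (QTL(26.5, 1.0), QTL(34.5, 1.0)),
    "III": (QTL(26.5, -1.0), QTL(34.5, 1.0)),
}
_MODEL_H2 = {
    "I": (0.05, 0.1, 0.2),
    "II": (0.1, 0.2, 0.4),
    "III": (0.1, 0.2, 0.4),
}


def model_catalog(model_id: str, h2: float, *, n_lines: int = 200) -> SimulationDesign:
    """Standard simulation designs on a 100 cM chromosome with 101 markers.

    Model I: one QTL at 34.5 cM, effect +1 (H2 in 0.05/0.1/0.2).
    Model II: two QTLs in coupling at 26.5 and 34.5 cM, effects (+1, +1).
    Model III: the same positions in repulsion, effects (-1, +1).
    Models II/III use H2 in 0.1/0.2/0.4.  The two linked-QTL positions are a
    package convention (configurable via SimulationDesign directly).
    """
    model_id = str(model_id).upper()
    if model_id not in _MODEL_QTLS:
        raise ValueError(f"unknown model {model_id!r}")
    if not any(np.isclose(h2, lvl) for lvl in _MODEL_H2[model_id]):
        raise ValueError(
            f"H2={h2} not a study level for model {model_id}: {_MODEL_H2[model_id]}"
        )
    return SimulationDesign(
        qtls=_MODEL_QTLS[model_id], heritability=float(h2), n_lines=n_lines
    )


# ---------------------------------------------------------------------------
# Genotype and phenotype generation


def _chain_switch_probs(loci_cM: np.ndarray, population_type: str) -> np.ndarray:
    d = np.diff(loci_cM)
    r = inverse_map_distance(d, "haldane")
    return np.asarray(observed_recombination(r, population_type), float)


def simulate_genotypes(
    design: SimulationDesign, rng: np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate marker and QTL genotypes for one population.

    Returns the marker GenotypeMatrix and the hidden (n, n_qtl) QTL genotype
    array in {0, 1}.
    """
    marker_pos = np.asarray(design.marker_positions_cM, float)
    qtl_pos = np.array([q.position_cM for q in design.qtls], float)
    loci = np.concatenate([marker_pos, qtl_pos])
    order = np.argsort(loci, kind="stable")
    loci_sorted = loci[order]
    R = _chain_switch_probs(loci_sorted, design.population_type)

    n = design.n_lines
    start = rng.random(n) < 0.5
    switches = rng.random((n, len(R))) < R[None, :]
    # cumulative XOR along loci: genotype flips at each realized switch
    states = np.empty((n, len(loci_sorted)), dtype=bool)
    states[:, 0] = start
    if len(R):
        states[:, 1:] = switches
        np.bitwise_xor.accumulate(states, axis=1, out=states)

    # undo the sort to address marker vs QTL columns
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    codes = states[:, inv].astype(float)
    marker_codes = codes[:, : len(marker_pos)]
    qtl_codes = codes[:, len(marker_pos):]

    geno = GenotypeMatrix(
        [f"L{i+1}" for i in range(n)],
        design.marker_names,
        marker_codes,
        design.population_type,
    )
    return geno, qtl_codes


def expected_genetic_variance(design: SimulationDesign) -> float:
    """Theoretical Var(g) under the chain model (used when realized Var is 0)."""
    q = design.qtls
    a = np.array([x.additive_effect for x in q])
    pos = np.array([x.position_cM for x in q])
    var = float((a**2).sum())
    for i in range(len(q)):
        for j in range(i + 1, len(q)):
            R = observed_recombination(
                inverse_map_distance(abs(pos[i] - pos[j]), "haldane"),
                design.population_type,
            )
            var += 2 * a[i] * a[j] * (1 - 2 * float(R))
    return var


def simulate_phenotypes(
    qtl_geno: np.ndarray, design: SimulationDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Additive genetic values and phenotypes at the design heritability.

    QTL genotypes are coded +1 (parent-1 homozygote, code 0) / -1, so an
    additive effect a means a 2a difference between the homozygotes.  The
    error variance is V_G (1 - H2)/H2 with V_G the realized sample variance
    of g, so the nominal heritability is exact in expectation under linkage.
    """
    x = 1.0 - 2.0 * np.asarray(qtl_geno, float)  # code 0 -> +1, code 1 -> -1
    a = np.array([q.additive_effect for q in design.qtls])
    g = x @ a if len(a) else np.zeros(len(x))
    v_g = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
    if v_g <= 0:
        v_g = expected_genetic_variance(design)
        logger.warning(
            "realized genetic variance is zero; using expected V_G=%.4f", v_g
        )
    h2 = design.heritability
    sigma_e = np.sqrt(v_g * (1 - h2) / h2)
    y = g + rng.normal(0.0, sigma_e, size=len(g))
    return g, y


def simulate_population(
    design: SimulationDesign, seed: int | np.random.Generator | None = None
) -> SimulatedPopulation:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geno, qtl_geno = simulate_genotypes(design, rng)
    g, y = simulate_phenotypes(qtl_geno, design, rng)
    return SimulatedPopulation(geno, qtl_geno, g, y, design)


# ---------------------------------------------------------------------------
# Map scenarios (individual vs consensus)


def map_scenario(
    pop: SimulatedPopulation, scenario: str
) -> tuple[GenotypeMatrix, GeneticMap]:
    """Prepare the genotypes and map used for QTL mapping.

    ``individual``: only markers at even cM (every second marker, 2 cM
    density) are genotyped and mapped.  ``consensus``: the map carries all
    markers, but those absent from the individual map are missing for every
    line.  The observed data coincide between the two scenarios; only the
    map (and the missing-marker columns) differ.
    """
    design = pop.design
    pos = np.asarray(design.marker_positions_cM, float)
    even = np.isclose(np.mod(pos, 2.0), 0.0)
    names = np.array(design.marker_names)
    if scenario == "individual":
        keep = list(names[even])
        geno = pop.geno.subset_markers(keep)
        gmap = GeneticMap.from_positions(keep, pos[even], chromosome="1")
        return geno, gmap
    if scenario == "consensus":
        codes = pop.geno.codes.copy()
        codes[:, ~even] = np.nan
        geno = GenotypeMatrix(
            list(pop.geno.lines), list(names), codes, design.population_type
        )
        gmap = GeneticMap.from_positions(list(names), pos, chromosome="1")
        return geno, gmap
    raise ValueError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# Multi-population fixtures for consensus-map construction


def multi_population_fixture(
    truth_map: GeneticMap,
    k: int,
    overlap: float,
    n: int,
    seed: int | None = None,
    *,
    population_type: str = "RIL_selfing",
    mapping_function: str = "haldane",
) -> tuple[list[GenotypeMatrix], list[GeneticMap]]:
    """Simulate k populations observing partially overlapping marker subsets.

    Each marker enters each population independently with probability
    sqrt(overlap), so the expected fraction of all markers shared by any
    *pair* of populations is about ``overlap``.  Markers sampled into no
    population are assigned to one population at random so the union equals
    the truth map.  Per-population maps are re-estimated from that
    population's own genotypes (truth order, adjacent distances from the
    population's own recombination estimates).
    """
    if not 0 < overlap <= 1:
        raise ValueError("overlap must lie in (0, 1]")
    incl = float(np.sqrt(overlap))
    rng = np.random.default_rng(seed)
    from .recombination import map_distance, pairwise_rf

    chroms = truth_map.chromosomes
    # which population observes which marker, per chromosome
    include: dict[str, np.ndarray] = {}
    for chrom in chroms:
        m = len(truth_map.group(chrom))
        inc = rng.random((k, m)) < incl
        orphan = ~inc.any(axis=0)
        if orphan.any():
            owners = rng.integers(0, k, size=int(orphan.sum()))
            inc[owners, np.where(orphan)[0]] = True
        include[chrom] = inc

    pops: list[GenotypeMatrix] = []
    maps: list[GeneticMap] = []
    for i in range(k):
        blocks, names, map_rows = [], [], []
        for chrom in chroms:
            grp = truth_map.group(chrom)
            design = SimulationDesign(
                chromosome_length_cM=float(grp["position_cM"].iloc[-1]),
                marker_positions_cM=grp["position_cM"].to_numpy(float),
                qtls=(),
                heritability=0.5,
                n_lines=n,
                population_type=population_type,
            )
            geno, _ = simulate_genotypes(design, rng)
            inc = include[chrom][i]
            keep_idx = np.where(inc)[0]
            blocks.append(geno.codes[:, keep_idx])
            kept = [grp["marker"].iloc[j] for j in keep_idx]
            names.extend(kept)
            map_rows.append((chrom, kept))
        pop = GenotypeMatrix(
            [f"P{i+1}_L{j+1}" for j in range(n)],
            names,
            np.concatenate(blocks, axis=1),
            population_type,
        )
        pops.append(pop)
        # per-population map: truth order, distances re-estimated from own data
        import pandas as pd

        rows = []
        for chrom, kept in map_rows:
            sub = pop.subset_markers(kept)
            r, _, _ = pairwise_rf(sub)
            if len(kept) > 1 and np.isnan(np.diag(r, k=1)).all():
                logger.warning(
                    "population %d chromosome %s has no estimable adjacent "
                    "pairs; group may disconnect",
                    i + 1,
                    chrom,
                )
            pos = 0.0
            for j, mk in enumerate(kept):
                if j > 0:
                    rj = r[j - 1, j]
                    if np.isnan(rj):
                        rj = 0.25  # sparse data; coarse placeholder distance
                    pos += float(map_distance(rj, mapping_function))
                rows.append((mk, chrom, pos))
        maps.append(
            GeneticMap(
                pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"])
            )
        )
    return pops, maps
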