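"""Build a consensus map from three RIL populations with partial overlap.

Each population genotypes ~63% of the markers of a 100 cM chromosome (so
any pair of populations shares ~40% of them).  Pairwise recombination
fractions are estimated per population, combined across populations with
inverse-variance weights, ordered with the traveling-salesman heuristic on
the completed distance matrix, and positioned in cM.  The result is
compared with the known simulated truth.
"""

import numpy as np

import clamap

truth = clamap.GeneticMap.from_positions(
    [f"m{i:02d}" for i in range(51)], np.arange(0.0, 101.0, 2.0), chromosome="3B"
)
pops, individual_maps = clamap.multi_population_fixture(
    truth, k=3, overlap=0.4, n=200, seed=42
)
print("population marker counts:", [p.n_markers for p in pops])

config = clamap.ConsensusConfig(mapping_function="haldane")
cons = clamap.build_consensus(pops, individual_maps, config)

rho = clamap.spearman_collinearity(cons.map.markers, truth.markers)
summary = clamap.map_summary(cons.map)
print(f"consensus markers: {len(cons.map)} (truth: {len(truth)})")
print(f"consensus length: {summary.total['length_cM']:.1f} cM (truth: 100 cM)")
print(f"Spearman collinearity with the true order: {abs(rho):.4f}")
print(cons.diagnostics.to_string(index=False))
# -> all 51 markers are placed on one group whose order agrees with the
#    simulated truth at Spearman ~0.99+; the length is close to 100 cM
#    (estimation noise inflates it slightly).  The diagnostics table shows
#    the collinearity against each contributing individual map.
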