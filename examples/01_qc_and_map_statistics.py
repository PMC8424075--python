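"""Marker quality control and map summary statistics.

Simulates a small RIL population, injects missing calls and a distorted
marker, runs the standard QC filters (missing fraction > 10% removed, then
minor-allele frequency < 0.30 removed), and summarizes a linkage map the
way map tables report them: length, bin count, adjacent-bin distances and
long gaps.
"""

import numpy as np

import clamap

rng = np.random.default_rng(1)
design = clamap.SimulationDesign(
    marker_positions_cM=np.arange(0.0, 101.0, 5.0), heritability=0.5, n_lines=100
)
geno, _ = clamap.simulate_genotypes(design, rng)

# spoil two markers: one with 15% missing calls, one with allele imbalance
codes = geno.codes.copy()
codes[: int(0.15 * 100), 3] = np.nan
codes[:85, 7] = 0.0  # MAF 0.15
geno = clamap.GenotypeMatrix(geno.lines, geno.markers, codes, geno.population_type)

filtered, report = clamap.qc_filter_markers(geno)
print(f"markers in: {report.n_input}, retained: {report.n_retained}")
print(report.removed.to_string(index=False))
# -> the missing-heavy marker is removed for missingness (0.15 > 0.10) and
#    the imbalanced one for MAF (0.15 < 0.30); all other markers survive.

gmap = design.truth_map()
summary = clamap.map_summary(gmap, gap_threshold=15.0)
print(summary.per_group.to_string(index=False))
print("totals:", summary.total)
# -> one 100 cM group of 21 markers in 21 bins, mean adjacent-bin distance
#    5 cM, and no gap longer than 15 cM.
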