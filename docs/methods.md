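# Methods

`clamap` implements three connected pieces of machinery for biparental
inbred-line genetics: (1) construction of a consensus linkage map from
several RIL/DH populations by combined linkage analysis — per-population
recombination-fraction estimation, inverse-variance meta-combination, and
traveling-salesman marker ordering; (2) inclusive composite interval
mapping (ICIM) of additive QTL; and (3) a simulation harness that measures
QTL detection power, false discovery rate and localization accuracy of the
scanner under individual-map versus consensus-map scenarios.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic data do and do not emulate.

## Genetic model and recombination estimation

Populations are fully homozygous inbred lines from a biparental cross,
coded 0 (parent-1 homozygote) and 1 (parent-2 homozygote) with missing
calls as NaN; residual heterozygotes are treated as missing on input, as is
standard for such panels.  Between two loci with meiotic recombination
fraction `r`, the probability that two lines' genotypes disagree
("observable discordance" `R`) is

- doubled haploids: `R = r`,
- selfing RILs at fixation (F-infinity): `R = 2r/(1+2r)`.

With `n` line-pairs scored at both markers and `k` discordant, `R̂ = k/n`
is the binomial MLE, so the MLE of `r` is the inverse transform:
`r̂ = R̂` (DH) or `r̂ = R̂/(2(1−R̂))` (RIL), with delta-method sampling
variance `Var(r̂) = [R̂(1−R̂)/n]·[dr/dR]²`.  A pair is non-estimable when
`n < n_min` (default 20 — below that the delta-method variance is
unreliable) or `R̂ ≥ 0.5` (no linkage signal; clamping such pairs into the
estimable range would fabricate long-range constraints).

Per-population estimates are combined on the `r` scale with
inverse-variance weights, `r̂_c = Σ w_i r̂_i / Σ w_i`, `w_i = 1/Var_i`,
`Var(r̂_c) = 1/Σ w_i`; a population in which the pair is non-estimable
contributes weight 0.  The `r` scale is the common currency across
population types whose `R→r` transforms differ.  Perfect data (`R̂ = 0`)
would give an infinite weight; weights are floored with
`Var ≥ (1/(n+2))²`, which preserves the dominance of perfect data while
keeping the combination finite.  F2/F3-style populations, whose likelihood
needs EM/Newton iteration, are out of scope; the `population_type` hook
reserves the interface.

Map distances use Haldane (`d = −50·ln(1−2r)`) or Kosambi
(`d = 25·ln((1+2r)/(1−2r))`) mapping functions with exact inverses.
Kosambi is the package default for real wheat data (the field convention);
every simulation in the test and acceptance suites uses Haldane because the
simulator generates crossovers without interference, keeping simulation and
estimation internally consistent.

## Consensus-map construction

**Grouping.**  Markers are grouped by the chromosome labels of the
individual maps.  Markers consistent across maps nucleate the group and are
*anchors* when present in every map.  A marker with conflicting labels is
assigned, when genotypes are available, to the candidate chromosome
maximizing the summed inverse variance of its estimable recombination
(`r ≤ 0.3`) to that chromosome's anchors; unresolvable markers are dropped
and logged.  The conflict rule is a package choice — published accounts of
consensus maps describe the outcome of such reassignments, not the rule.

**Ordering.**  Within a group, combined recombination fractions become map
distances.  Pairs estimable in no population get the shortest-path
(geodesic) distance through the estimable linkage graph: map distances are
additive along a chromosome, so the graph metric is a far better stand-in
for the true separation than any flat penalty, which we found distorts the
ordering objective badly once a material fraction of adjacent pairs is
unmeasured.  Pairs in a different connected component fall back to twice
the largest finite distance (discourages adjacency without forbidding it).
The order minimizing SARF (the sum of adjacent distances) is sought with a
nearest-neighbor construction started from the marker with the largest
nearest-neighbor distance (a likely chromosome terminal), refined by
first-improvement 2-opt sweeps interleaved with Or-opt segment relocations
(lengths 1–3) to a joint fixed point, inside a deterministic iterated local
search (30 double-bridge perturbations from a fixed-seed generator, best
order kept).  Plain 2-opt alone leaves comb-shaped folds on noisy
map-scale instances; Or-opt and the double-bridge restarts remove them.
On random ≤8-marker instances the search returns the exhaustive optimum in
over 95% of cases and never exceeds it by more than 5% (asserted in the
acceptance suite).  Output orientation is canonical: each group is flipped,
if necessary, so its smallest-named anchor sorts first.

**Positions and pruning.**  Consensus positions accumulate the geodesic
adjacent distances along the final order (the same metric the ordering
minimized); markers at zero recombination share a position and form a bin.
The operation `assign_positions` also offers the simpler `downstream`
bridge rule (the nearest downstream marker with an estimable rf to the last
placed marker defines the interval; intervening markers interpolate
evenly), which is its default for direct use.  Pruning then removes, one at
a time, any marker whose removal shortens the group by more than
`max_contrib` (default 10 cM), measured as the marker's SARF contribution;
with a physical map supplied, markers whose removal raises the group's
Spearman collinearity by more than 0.02 are also removed.  Published
consensus maps describe this step as manual curation; the thresholds here
are an automated surrogate and are configurable.  All removals, bridges and
splits are logged in the returned `ConsensusMap`.

## ICIM additive-QTL scan

Markers are coded +1/−1 (missing imputed to 0, the expectation under 1:1
segregation) for regression.  **Cofactor selection** is forward–backward
stepwise linear regression: the candidate with the smallest partial-F
p-value enters while `p < PIN` (default 0.001); after each entry, included
variables with `p > POUT` (default 0.002) leave.  Ties break to the lower
marker index and exact duplicate columns never co-enter.

The scan walks a cM grid (default step 0.2; the simulation study uses 0.1).
At each position the phenotype is adjusted by all cofactors *except those
that are the current map interval's own flanking markers*, using the joint
OLS coefficients; this shields the tested interval from absorbing its own
QTL.  Per line, the QTL genotype probability conditions on the nearest
marker with an observed genotype on each side of the position, with
recombination in the two sub-intervals independent on the observable
(`R`) metric — exactly the model under which the simulator generates data
(see below).  A side with no observed marker contributes a flat factor;
both sides missing gives (0.5, 0.5).

The two interval-local rules interact in a way that matters for consensus
maps carrying markers a given population never scored.  Conditioning on
nearest *observed* flanks keeps the information content, and hence the
peak position and LOD, identical to what the sparser individual map gives
— position estimates stay unbiased.  But the shielded window around a
selected cofactor extends only one *map interval* on each side, so on a
map twice as dense the background adjustment resumes twice as close to the
peak, truncating the LOD profile there.  The one-LOD support interval is
correspondingly shorter — the mechanism behind the narrower confidence
intervals a consensus map yields from the same genotype data (about 1.7 cM
versus 2.9 cM in the headline simulation cell below).

**Mixture fit.**  At a position with per-line probabilities `p_i` of the
parent-1 QTL genotype, the adjusted phenotype is modeled as a two-component
Gaussian mixture with means `μ+a`, `μ−a`, common variance, and fixed
mixing weights `p_i`.  EM runs to a relative log-likelihood change below
1e-10 (cap 200 iterations; the cap returns flagged, capped values),
initialized from the regression of the adjusted phenotype on the expected
QTL code `2p−1`.  The tolerance is deliberately below the 1e-6 LOD
agreement asserted against an independent simple-interval-mapping oracle,
so residual EM error cannot masquerade as agreement.  LOD is the log10
likelihood ratio against the single-Gaussian null *on the same adjusted
phenotype*; with fully known QTL genotypes this reduces exactly to the
closed-form marker-regression LOD `n/2·log10(SS0/SS1)`.  PVE is
`100·â²·Var(2p−1)/Var(y)` with `y` the unadjusted phenotype — a definition
chosen to degrade smoothly with missing data; exact formulas used by
closed-source implementations are unpublished, so PVE is validated only
distributionally.  All positions of a chromosome are fitted as one
vectorized EM over a (positions × lines) array, which is what keeps a
1001-position scan of 200 lines at tens of milliseconds.

**Peak calling.**  Peaks are LOD local maxima at or above the threshold
(default 2.5), accepted highest-first; a lower candidate also needs either
a dip of ≥1 LOD below the smaller peak or ≥5 cM separation from every
accepted peak — our disambiguation of "multiple peaks", configurable.
Support intervals are the contiguous one-LOD-drop region, clipped at
chromosome ends.

## The simulator

Lines are Markov chains along the ordered loci of a chromosome: the first
locus is Bernoulli(0.5), and the genotype switches between adjacent loci
with probability equal to the interval's observable discordance `R`
(Haldane distance → `r` → population transform; no crossover
interference).  QTLs are inserted as hidden loci inside the chain, so
their genotypes are exactly consistent with the flanking-marker model the
scanner assumes.  Phenotypes are `g = Σ a_q x_q` (`x = ±1`; an "additive
effect of 1" is a 2-unit homozygote difference) plus Gaussian noise with
variance `V_G(1−H²)/H²`, where `V_G` is the *realized* sample variance of
`g` in that population — heritability is exact in expectation under
linkage, including the covariance between coupling- or repulsion-linked
QTLs.  If `V_G = 0` the theoretical variance replaces it (logged).

The standard study conditions (`model_catalog`): a 100 cM chromosome with
101 evenly spaced markers; model I has one QTL at 34.5 cM with effect +1
(H² ∈ {0.05, 0.1, 0.2}); models II and III have two QTLs at 26.5 and
34.5 cM with effects (+1, +1) (coupling) and (−1, +1) (repulsion)
respectively (H² ∈ {0.1, 0.2, 0.4}); populations are 200 selfing RILs.
The two linked-QTL positions are a package convention (the primary source
leaves them to supplementary material); they are configurable, and the
repulsion-model results are sensitive to them.  The *individual* map
scenario keeps the 51 even-cM markers; the *consensus* scenario maps all
101 markers but sets the 50 odd-cM markers missing for every line — the
observed data coincide, only the map differs.

What the generator does **not** emulate: crossover interference, residual
heterozygosity, segregation distortion, genotyping error, dominance or
epistasis, multi-chromosome genomes (groups are simulated independently),
and selective genotyping.  Passing tests therefore certify the estimators
and the scan machinery under the stated model, not robustness to those
realities.

`multi_population_fixture` builds partially overlapping designs for
consensus construction: each marker enters each population independently
with probability `sqrt(overlap)`, so any *pair* of populations shares about
`overlap` of all markers; markers sampled nowhere are assigned to one
random population so the union is preserved.  Per-population maps are
re-estimated from each population's own data in the true order.

## The evaluation harness

`run_experiment(model, h2, scenario, reps, n, seed)` replays one study
cell: simulate → apply the map scenario → ICIM (step 0.1 cM) → call peaks
→ score.  A true QTL is detected when a call lands within ±2.5 cM (a 5 cM
support window); per QTL, only the highest-LOD call inside its window
counts, and further in-window calls are neither hits nor false positives.
Calls outside every window are false positives.  Power is the per-QTL
detection fraction over replicates; FDR is pooled
(`total FP / (total FP + total detections)`), chosen over per-replicate
averaging for stability when detections are rare.  Position, effect, CI
length and LOD are summarized over detecting replicates only (the cells of
published tables exist even at single-digit power, implying conditional
summaries).  Replicate `t` draws its generator from the `t`-th child of
`SeedSequence(seed)`, making every summary bit-reproducible.

At 1,000 replicates the headline cell (model I, H² = 0.2, consensus map)
reproduces the published simulation closely: power ≈ 90%, FDR ≈ 10–12%,
mean position ≈ 34.3–34.5 cM, mean additive effect ≈ 1.01–1.03, mean CI
length ≈ 1.7 cM (vs ≈ 3 cM on the individual map), mean LOD ≈ 10.  The
known exception is the repulsion model at H² = 0.4, where detection is
bimodal on whether stepwise selection admits any cofactor: the best
marker's marginal partial-F p-value sits almost exactly at PIN = 0.001, so
power equals the probability of first entry and is acutely sensitive to
unpublished details of the entry test in the software the published
numbers came from.  Our canonical partial-F implementation yields ≈ 86%
power against a published 74.8%; every other statistic of that cell
(position, effect, CI length, LOD, FDR) matches.

**Bookkeeping rules** for real multi-environment records: same-population
records are one QTL when <20 cM apart; cross-population records
additionally require <25 Mb between flanking-marker physical intervals
(records without physical data use the genetic rule alone and are
flagged); both merge by single linkage within a chromosome.  A QTL is
stable when detected in at least half the environments tested
(`⌈n_env/2⌉`).  Stable QTLs of different traits join a cluster when their
confidence intervals come within 15 cM (single linkage, strict).
Genotypic values are `ĝ = intercept + Σ a_q x_q` over stable-QTL
genotypes (±1; missing loci skipped and flagged), with the phenotype mean
as the default intercept, and the positive-allele count tallies loci where
the carried allele increases the trait.

## Numerical choices and degenerate inputs

- QC thresholds are strict inequalities: exactly 10% missing or MAF
  exactly 0.30 is retained.
- MAF is computed over non-missing calls only.
- "Consistent order proportion" against a physical map is the longest
  subsequence of the genetic order monotone in physical position divided
  by the common-marker count, after choosing the orientation maximizing it
  (map strand is arbitrary); computed by patience sorting, O(n log n).
- Spearman collinearity uses mid-ranks for ties and requires ≥3 common
  markers.
- Empty QC output, non-estimable rf, disconnected groups and zero-variance
  phenotypes warn or log rather than raise; genuinely malformed input
  (ragged files, duplicate names, illegal codes) raises.
- EM rows with uninformative probabilities (`Var(2p−1) ≈ 0`) short-circuit
  to LOD 0, effect 0 rather than entering EM.
- All stochastic components accept explicit seeds; the ordering heuristic's
  internal restarts use a fixed constant seed so identical inputs give
  identical maps.

## Problem sizes used in the shipped checks

The test suite replays the simulation cells at 500 replicates; the
reproduction script (`scripts/acceptance.py`) uses the full 1,000.  The
consensus end-to-end checks use 3 populations × 200 lines on a 51-marker,
100 cM chromosome at 40–50% pairwise overlap.  These sizes were chosen to
match the study design where stated and to keep a full run in minutes on
one core.

## Known limitations

- Two-point estimation only; no multilocus likelihood ordering and no
  segregation-distortion correction of rf estimates.
- The consensus builder needs raw genotypes; it does not merge published
  cM maps without data (a different problem with different tools).
- One-LOD support intervals are a convention, not a calibrated confidence
  procedure; their coverage is validated only against the simulation
  study's reported lengths.
- The stepwise entry test at p ≈ PIN is a knife edge (see the repulsion
  model note above); comparisons with other ICIM implementations should
  expect power differences concentrated in such cells.
- PVE and the genotypic-value intercept follow the package's stated
  definitions; other implementations may print slightly different values.
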