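# clamap

Consensus genetic linkage maps from multiple biparental populations by
**c**ombined **l**inkage **a**nalysis, with an ICIM QTL scanner and a
simulation harness that quantifies what a denser consensus map buys you in
QTL mapping.

## Who this is for

Geneticists and breeders working with recombinant inbred line (RIL) or
doubled-haploid (DH) populations — wheat and other selfing crops are the
archetype — who want to (1) integrate marker data from several mapping
populations into one consensus map at the raw-genotype level rather than by
merging published cM coordinates, (2) scan for additive QTL with inclusive
composite interval mapping, and (3) understand, by simulation, the power,
false-discovery and localization behavior of that scan on their map.

## The method in brief

**Consensus map.**  For markers *i, j* in population *p* with `n` doubly
scored lines and `k` discordant, the observable discordance `R̂ = k/n` has
closed-form ML inverse

&nbsp;&nbsp;&nbsp;&nbsp;DH: `r̂ = R̂`,&nbsp;&nbsp;RIL: `r̂ = R̂ / (2(1−R̂))` (from `R = 2r/(1+2r)`),

with delta-method variance `Var(r̂)`.  Populations combine by inverse
variance, `r̂_c = Σ w_p r̂_p / Σ w_p`, `w_p = 1/Var_p` (weight 0 where a
pair is not estimable).  Markers group by the chromosome labels of the
individual maps (consistent markers in all maps act as anchors); within a
group, marker order minimizes the sum of adjacent distances (SARF) via
nearest-neighbor construction plus 2-opt/Or-opt local search, distances
being Haldane/Kosambi transforms of the combined `r̂_c` completed by
shortest paths through the estimable linkage graph.  Positions accumulate
along the order; markers inflating the map beyond a per-marker budget are
pruned and logged.

**ICIM scan.**  Stepwise regression (entry p < 0.001, removal p > 0.002)
picks background cofactors; at each scanned position the phenotype is
adjusted by all cofactors except the current interval's flanking markers,
and a two-component Gaussian mixture over the two QTL homozygote classes
(per-line mixing weights from the flanking genotypes) is fitted by EM.
LOD is the log10 likelihood ratio to the single-Gaussian null; peaks at
LOD ≥ 2.5 are called with one-LOD-drop support intervals.

**Evaluation.**  Simulated RIL populations (Haldane crossovers, additive
QTLs, heritability-scaled Gaussian noise) are scanned under an
individual-map scenario (51 markers at 2 cM) and a consensus-map scenario
(101 markers at 1 cM, the extra 50 missing in the genotypes); detection is
scored in a 5 cM window around each true QTL, giving power, pooled FDR and
conditional summaries of position, effect and confidence-interval length.

## Worked example

```python
import clamap

pop = clamap.simulate_population(clamap.model_catalog("I", 0.2), seed=7)
settings = clamap.ScanSettings(step=0.1)

for scenario in ("individual", "consensus"):
    geno, gmap = clamap.map_scenario(pop, scenario)
    scan = clamap.icim_scan(pop.phenotype, geno, gmap, settings)
    for c in clamap.call_qtls(scan, settings):
        print(scenario, f"QTL at {c.position_cM:.1f} cM LOD {c.lod:.2f} "
              f"add {c.additive:+.3f} CI {c.ci_length:.1f} cM")
```

prints

```
individual QTL at 33.9 cM LOD 12.31 add +1.085 CI 2.5 cM
consensus QTL at 33.9 cM LOD 12.31 add +1.085 CI 1.8 cM
```

The simulated QTL sits at 34.5 cM with additive effect +1 at heritability
0.2 (n = 200 RILs).  Both maps localize it with the same peak and effect —
the observed genotypes are identical — but the consensus map's denser
interval grid narrows the one-LOD support interval from 2.5 to 1.8 cM.
Aggregated over 100 replicates (`examples/04_power_simulation.py`):

```
individual  power  93.0%  FDR  7.00%  pos 34.60±0.96 cM  add 1.034±0.148  CI length 2.99±0.62 cM
consensus   power  92.0%  FDR  8.00%  pos 34.57±0.93 cM  add 1.034±0.149  CI length 1.74±0.19 cM
```

Power, FDR and bias match between scenarios while the consensus map cuts
the confidence interval nearly in half — the quantitative argument for
building consensus maps at all.  The `examples/` directory has one short
script per capability: QC and map statistics, consensus construction from
three overlapping populations, the ICIM scan, the power simulation, and
the QTL commonality/stability/cluster/prediction rules.

A thin CLI mirrors the library for shell use: `clamap qc`, `clamap
mapstats`, `clamap collinearity`, `clamap consensus`, `clamap simulate`,
`clamap scan`, `clamap evaluate`, `clamap qtltools …` (see `--help`).

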