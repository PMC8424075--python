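"""ICIM additive-QTL scan on one simulated RIL population.

One QTL of additive effect 1 sits at 34.5 cM on a 100 cM chromosome;
heritability is 0.2, population size 200.  The same population is mapped
with its own 51-marker (2 cM) map and with a denser 101-marker consensus
map on which the extra 50 markers were never genotyped (all missing), to
show the consensus map's narrower support interval.
"""

import numpy as np

import clamap

pop = clamap.simulate_population(clamap.model_catalog("I", 0.2), seed=7)
settings = clamap.ScanSettings(step=0.1)  # PIN 0.001, POUT 0.002, LOD >= 2.5

for scenario in ("individual", "consensus"):
    geno, gmap = clamap.map_scenario(pop, scenario)
    scan = clamap.icim_scan(pop.phenotype, geno, gmap, settings)
    calls = clamap.call_qtls(scan, settings)
    print(f"--- {scenario} map ({geno.n_markers} markers) ---")
    print(f"cofactors selected (marker indices): {scan.cofactors}")
    for c in calls:
        print(
            f"QTL at {c.position_cM:.1f} cM  LOD {c.lod:.2f}  "
            f"add {c.additive:+.3f}  PVE {c.pve:.1f}%  "
            f"CI [{c.ci_lo:.1f}, {c.ci_hi:.1f}] ({c.ci_length:.1f} cM)"
        )
# -> both scans peak within ~1 cM of the true 34.5 cM with LOD ~10 and an
#    additive effect near +1 (about 20% PVE).  The one-LOD support interval
#    is distinctly shorter on the consensus map: its denser interval grid
#    narrows the window shielded from the background-marker adjustment.
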