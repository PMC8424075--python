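"""Commonality, stability, clustering and genotypic-value prediction.

Works on a small hand-made table of QTL records of the kind a
multi-environment study produces: same-population records within 20 cM are
the same QTL, cross-population records additionally need flanking physical
intervals within 25 Mb, a QTL is stable when found in at least half the
environments tested, and stable QTLs of different traits cluster when
their confidence intervals come within 15 cM.
"""

import numpy as np
import pandas as pd

import clamap

records = pd.DataFrame(
    {
        "population": ["DS", "DS", "GZ", "DS", "ZC"],
        "chromosome": ["4B", "4B", "4B", "4B", "2D"],
        "position_cM": [52.0, 60.0, 57.0, 120.0, 33.0],
        "phys_lo_mb": [30.0, 32.0, 35.0, 600.0, 20.0],
        "phys_hi_mb": [34.0, 36.0, 40.0, 610.0, 25.0],
    }
)
common = clamap.qtl_commonality(records)
print(common[["population", "chromosome", "position_cM", "common_group"]].to_string(index=False))
# -> the three 4B records near 52-60 cM merge into one common QTL (the DS
#    pair by the genetic rule, the GZ record via the <25 Mb physical rule);
#    the distal 4B record and the 2D record stay separate.

detections = pd.DataFrame(
    {
        "qtl": ["q1"] * 3 + ["q2"] * 1,
        "population": ["DS"] * 3 + ["DS"],
        "environment": ["e1", "e3", "e5", "e2"],
    }
)
stable = clamap.stability_filter(detections, {"DS": 6})
print(stable.to_string(index=False))
# -> q1 (3 of 6 environments) is stable; q2 (1 of 6) is not.

stable_records = pd.DataFrame(
    {
        "trait": ["PH", "SL", "TKW"],
        "chromosome": ["4B", "4B", "4B"],
        "ci_lo": [50.0, 57.0, 80.0],
        "ci_hi": [55.0, 62.0, 88.0],
    }
)
clusters = clamap.cluster_qtls(stable_records)
print(clusters[["trait", "ci_lo", "ci_hi", "cluster"]].to_string(index=False))
# -> the PH and SL intervals (gap 2 cM) share a cluster; TKW (gap 18 cM)
#    forms its own.

# genotypic values of lines from stable-QTL effects (+1/-1 coding)
genotypes = np.array([[+1, +1, -1], [+1, -1, -1], [-1, -1, +1]], float)
effects = [1.2, 0.8, -0.5]
pred = clamap.predict_genotypic_values(genotypes, effects, intercept=100.0)
print(pred.to_string(index=False))
# -> line 1 carries the trait-increasing allele at all three loci
#    (positive_alleles = 3) and has the highest predicted value.
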