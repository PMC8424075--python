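"""Detection power and FDR of ICIM on individual vs consensus maps.

Replays a small version of the simulation experiment: RIL populations of
200 lines, one additive QTL (effect 1 at 34.5 cM), heritability 0.2, with
detection scored inside a 5 cM window centered on the truth.  100
replicates keep this example quick; the full study uses 1,000 (see
scripts/acceptance.py).
"""

import clamap

for scenario in ("individual", "consensus"):
    summary = clamap.run_experiment(
        "I", 0.2, scenario, reps=100, n=200, seed=2024
    )
    row = summary.per_qtl.iloc[0]
    print(
        f"{scenario:10s}  power {row.power_pct:5.1f}%  FDR {summary.fdr_pct:5.2f}%  "
        f"pos {row.pos_mean:.2f}±{row.pos_sd:.2f} cM  "
        f"add {row.add_mean:.3f}±{row.add_sd:.3f}  "
        f"CI length {row.cil_mean:.2f}±{row.cil_sd:.2f} cM"
    )
# -> power ~90% and FDR ~10% on both maps, positions unbiased around
#    34.5 cM and effects around 1, but the consensus map's mean support
#    interval is roughly 1.7 cM against ~3 cM for the individual map:
#    denser maps localize the QTL more sharply from the same genotype data.
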