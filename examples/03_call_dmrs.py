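"""Detect differentially methylated regions between two groups.

Plants five DMRs (|delta M| = 3 over 6 CpGs each) in the cultured group,
runs the full pipeline, and calls DMRs with the region-chaining +
Mann-Whitney + Benjamini-Hochberg procedure in both parameterizations.
"""

import numpy as np

from metharray import dmr
from metharray import preprocess as pp
from metharray import synthetic as syn

rng = np.random.default_rng(3)
planted = []
for i, chrom in enumerate(("1", "3", "7", "12", "X")):
    start = int(rng.integers(1, syn.DEFAULT_CHROM_LENGTHS[chrom] - 5000))
    planted.append(syn.PlantedDMR(chrom, start, start + 2500, 6,
                                  -3.0 if i % 2 else 3.0, group="LT_PTC"))

config = syn.SimulationConfig(
    seed=3, n_probes=12_000,
    n_samples_per_group={"d0_PTC": 4, "LT_PTC": 4},
    planted_dmrs=tuple(planted),
)
manifest = syn.generate_manifest(config)
raw, _ = syn.generate_cohort(config, manifest)
meth, _ = pp.preprocess_pipeline(raw, manifest)

for mode in ("methods", "results"):
    records = dmr.call_dmrs(meth, manifest, "d0_PTC", "LT_PTC",
                            dmr.DMRParams(mode=mode))
    called = [r for r in records if r.is_dmr]
    print(f"{mode} mode: {len(records)} CpG-dense candidate regions, "
          f"{len(called)} called as DMRs")

print("\ntop calls (delta = d0_PTC minus LT_PTC):")
for r in called[:5]:
    print(f"  chr{r.chrom}:{r.start}-{r.end}  n={r.n_probes}  "
          f"dM={r.delta_median_m:+.2f}  dBeta={r.delta_median_beta:+.2f}  "
          f"p_adj={r.p_adj:.2e}")
print("a negative delta means the region gained methylation in the cultured "
      "cells, a positive one that it lost methylation; every call survived "
      "BH correction and the effect-size gate")
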