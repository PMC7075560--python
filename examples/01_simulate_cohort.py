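"""Simulate a small 450k-like cohort with planted ground truth.

Builds a cohort of uncultured (d0_PTC) and cultured (LT_PTC) testicular
cell samples, seminomas (SE) and a copy-stable female control cohort, with
one planted DMR and one planted chromosome-12 gain, then prints what was
planted and what the raw data look like.
"""

import numpy as np

from metharray import synthetic as syn

config = syn.SimulationConfig(
    seed=1,
    n_probes=8000,
    n_samples_per_group={"d0_PTC": 4, "LT_PTC": 4, "SE": 3, "control": 10},
    planted_dmrs=(syn.PlantedDMR("2", 100_000, 110_000, 6, -3.0, group="LT_PTC"),),
    planted_cnvs=(syn.PlantedCNV("SE", "12", 1, 600_000, 3),),
)
manifest = syn.generate_manifest(config)
cohort, truth = syn.generate_cohort(config, manifest)

n_cpg = int(manifest["is_cpg_target"].sum())
print(f"manifest: {len(manifest)} probes ({n_cpg} CpG targets, "
      f"{int(manifest['is_negative_control'].sum())} negative controls)")
print(f"cohort: {len(cohort.samples)} samples in groups "
      f"{sorted(set(cohort.group.values()))}")

d = truth.dmr_regions[0]
print(f"planted DMR: chr{d.chrom}:{d.start}-{d.end}, {d.n_probes} probes, "
      f"delta M {d.delta_m:+.1f} in group {d.group}")
c = truth.cnv_segments[0]
print(f"planted CNV: chr{c.chrom}:{c.start}-{c.end}, copy {c.copy_number} in {c.target}")

# the raw observable: total fluorescence scales with copy number
seg = (manifest["chrom"] == "12") & manifest["pos"].le(600_000) & manifest["is_cpg_target"]
se = cohort.total().loc[seg.to_numpy(), cohort.samples_in_group("SE")].to_numpy().mean()
ctl = cohort.total().loc[seg.to_numpy(), cohort.samples_in_group("control")].to_numpy().mean()
print(f"mean total fluorescence in the gained segment, SE vs control: "
      f"{se:.0f} vs {ctl:.0f} (log2 ratio {np.log2(se / ctl):+.2f}; "
      f"copy 3 predicts {np.log2(3 / 2):+.2f})")
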