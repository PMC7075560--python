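"""Planted-truth benchmark scenarios for the whole pipeline.

Each function builds a synthetic cohort under stated study conditions, runs
the relevant pipeline stage from scratch, and measures recovery of the
planted truth. The reference computations used for cross-checking
(permutation enumeration for the rank test, the naive step-up loop for the
FDR correction) are deliberately written independently of the optimized
implementations they check.

Problem sizes are chosen so every scenario runs in seconds on one core:
20,000 probes on the 1/100-scale genome for recovery benchmarks, and a
20-seed ensemble of ~3,000-probe cohorts for null calibration.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from metharray import cnv, preprocess as pp, qpcr
from metharray import class_profile as cp
from metharray import dmr as dmr_mod
from metharray import synthetic as syn

GROUP_A, GROUP_B = "d0_PTC", "LT_PTC"


def _spread_dmrs(rng: np.random.Generator, n_dmrs: int, n_probes: int, delta_m: float,
                 group: str) -> tuple[syn.PlantedDMR, ...]:
    chroms = list(syn.DEFAULT_CHROM_LENGTHS)
    out = []
    for i in range(n_dmrs):
        c = chroms[i % len(chroms)]
        length = syn.DEFAULT_CHROM_LENGTHS[c]
        start = int(rng.integers(1, length - 3000))
        sign = 1.0 if i % 2 else -1.0
        out.append(syn.PlantedDMR(c, start, start + 2500, n_probes, sign * delta_m, group=group))
    return tuple(out)


def _overlaps(rec, planted) -> bool:
    return rec.chrom == planted.chrom and rec.start <= planted.end and rec.end >= planted.start


def dmr_recovery(seed: int, n_dmrs: int = 30, delta_m: float = 3.0,
                 probes_per_dmr: int = 6, n_probes: int = 20_000) -> dict:
    """Sensitivity / false regions for planted DMRs, methods-mode thresholds.

    4 vs 4 samples, |delta M| = 3 over 6 probes per region, beta noise 0.02.
    A planted region counts as recovered when any called DMR overlaps it; a
    call overlapping no planted region is a false region.
    """
    rng = np.random.default_rng(seed)
    planted = _spread_dmrs(rng, n_dmrs, probes_per_dmr, delta_m, GROUP_B)
    config = syn.SimulationConfig(
        seed=seed, n_probes=n_probes,
        n_samples_per_group={GROUP_A: 4, GROUP_B: 4},
        planted_dmrs=planted,
    )
    manifest = syn.generate_manifest(config)
    raw, _ = syn.generate_cohort(config, manifest)
    meth, _ = pp.preprocess_pipeline(raw, manifest)
    records = dmr_mod.call_dmrs(meth, manifest, GROUP_A, GROUP_B)
    called = [r for r in records if r.is_dmr]
    recovered = sum(any(_overlaps(r, d) for r in called) for d in planted)
    false = sum(not any(_overlaps(r, d) for d in planted) for r in called)
    return {
        "n_planted": n_dmrs,
        "n_recovered": recovered,
        "sensitivity_pct": 100.0 * recovered / n_dmrs,
        "false_regions": false,
        "n_candidates": len(records),
    }


def dmr_null_calibration(seed: int, n_seeds: int = 20, n_probes: int = 3_000) -> dict:
    """False-call proportion of the region test under the global null.

    No planted DMRs, no hypomethylation: both groups share one beta model,
    so every candidate region is a true null. The proportion of regions
    with raw Mann-Whitney p <= 0.05 measures the test's calibration (BH
    would shrink it further); the probe-level clustering of pooled values
    makes the test conservative, so the realized proportion sits below the
    nominal level.
    """
    dense = {c: length // 20 for c, length in syn.DEFAULT_CHROM_LENGTHS.items()}
    n_regions = n_sig = 0
    base = np.random.SeedSequence(seed).generate_state(n_seeds)
    for s in base:
        config = syn.null_config(
            int(s % 2**31), n_probes=n_probes,
            n_samples_per_group={GROUP_A: 4, GROUP_B: 4}, chrom_lengths=dense,
        )
        manifest = syn.generate_manifest(config)
        raw, _ = syn.generate_cohort(config, manifest)
        meth, _ = pp.preprocess_pipeline(raw, manifest)
        records = dmr_mod.call_dmrs(meth, manifest, GROUP_A, GROUP_B)
        ps = [r.p_raw for r in records if not r.untestable]
        n_regions += len(ps)
        n_sig += sum(p <= 0.05 for p in ps)
    return {
        "n_regions": n_regions,
        "n_seeds": n_seeds,
        "false_call_rate": n_sig / max(n_regions, 1),
    }


def _brute_force_mw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Reference two-sided Mann-Whitney p by full permutation enumeration."""
    z = np.concatenate([a, b])
    n_a, n = len(a), len(z)

    def u_of(idx: tuple[int, ...]) -> float:
        sel = set(idx)
        u = 0.0
        for i in idx:
            for j in range(n):
                if j in sel:
                    continue
                if z[i] > z[j]:
                    u += 1.0
                elif z[i] == z[j]:
                    u += 0.5
        return u

    observed = u_of(tuple(range(n_a)))
    us = [u_of(c) for c in combinations(range(n), n_a)]
    lo = sum(u <= observed + 1e-9 for u in us)
    hi = sum(u >= observed - 1e-9 for u in us)
    return min(1.0, 2.0 * min(lo, hi) / len(us))


def mann_whitney_vs_enumeration(seed: int, n_instances: int = 200) -> dict:
    """Exact-test path vs brute-force enumeration, combined n <= 10."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    n_agree = 0
    for _ in range(n_instances):
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 11 - n_a))
        # integer draws force ties often; normal draws give the no-tie path
        if rng.random() < 0.5:
            a = rng.integers(0, 4, size=n_a).astype(float)
            b = rng.integers(0, 4, size=n_b).astype(float)
        else:
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b)
        _, p = dmr_mod.mann_whitney(a, b)
        p_ref = _brute_force_mw_p(a, b)
        diff = abs(p - p_ref)
        max_diff = max(max_diff, diff)
        n_agree += diff < 1e-12
    return {"n_instances": n_instances, "n_agree": n_agree, "max_abs_diff": max_diff}


def _stepup_reference(p: np.ndarray) -> np.ndarray:
    """Naive O(m^2) step-up: p_adj(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def bh_vs_reference(seed: int, n_vectors: int = 1000, max_len: int = 40) -> dict:
    """Vectorized BH against the naive step-up loop on random p-vectors."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    n_agree = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        p = rng.random(m)
        if rng.random() < 0.3:  # duplicated p-values exercise tie handling
            p[rng.integers(0, m)] = p[0]
        diff = float(np.max(np.abs(dmr_mod.adjust_bh(p) - _stepup_reference(p))))
        max_diff = max(max_diff, diff)
        n_agree += diff < 1e-12
    return {"n_vectors": n_vectors, "n_agree": n_agree, "max_abs_diff": max_diff}


def cnv_recovery(seed: int, n_probes: int = 20_000) -> dict:
    """Arm-level gain/loss recovery and the 10%-mosaic detection limit.

    One group of 3 samples vs the 10-sample copy-stable control cohort:
    a uniform copy-3 gain (expected ratio +0.585) and copy-1 loss (expected
    -1) across most of one chromosome each, plus a 10%-mosaic copy-3 gain
    (expected ratio log2(1.05) ~ 0.07, below the duplication cutoff).
    "Correctly stated" means a gain state with gain_loss +1 for gain bins
    and a deletion state with gain_loss -1 for loss bins.
    """
    planted = (
        syn.PlantedCNV("SE", "4", 1, 950_000, 3),
        syn.PlantedCNV("SE", "5", 1, 900_000, 1),
        syn.PlantedCNV("SE", "8", 1, 700_000, 3, mosaic_fraction=0.1),
    )
    config = syn.SimulationConfig(
        seed=seed, n_probes=n_probes,
        n_samples_per_group={"SE": 3, "control": 10},
        planted_cnvs=planted,
    )
    manifest = syn.generate_manifest(config)
    raw, _ = syn.generate_cohort(config, manifest)
    controls = raw.subset(samples=raw.samples_in_group("control"))
    tumors = raw.subset(samples=raw.samples_in_group("SE"))
    profiles = cnv.call_cnvs(tumors, controls, manifest, sex="female")

    def bins_within(profile, chrom, end):
        return [i for i, b in enumerate(profile.bins) if b.chrom == chrom and b.end <= end]

    gain_ok = gain_n = loss_ok = loss_n = mosaic_calls = mosaic_n = 0
    for p in profiles:
        g = bins_within(p, "4", 950_000)
        l = bins_within(p, "5", 900_000)
        m = bins_within(p, "8", 700_000)
        gain_ok += int((p.gain_loss[g] == 1).sum())
        gain_n += len(g)
        loss_ok += int((p.gain_loss[l] == -1).sum())
        loss_n += len(l)
        mosaic_calls += int((p.gain_loss[m] == 1).sum())
        mosaic_n += len(m)
    return {
        "gain_bin_accuracy_pct": 100.0 * gain_ok / gain_n,
        "loss_bin_accuracy_pct": 100.0 * loss_ok / loss_n,
        "mosaic_dup_calls": mosaic_calls,
        "n_gain_bins": gain_n,
        "n_loss_bins": loss_n,
        "n_mosaic_bins": mosaic_n,
    }


#: ratio -> expected state for the published five-state cutoffs
THRESHOLD_TABLE = {
    -1.0: "hom_del", -0.96: "hom_del", -0.5: "hemi_del", -0.24: "hemi_del",
    0.0: "neutral", 0.12: "dup", 0.5: "dup", 0.72: "high_gain", 1.0: "high_gain",
}


def cnv_threshold_table() -> dict:
    """How many of the boundary ratios map to their dictated state."""
    thresholds = cnv.CNVThresholds()
    correct = sum(thresholds.classify(r) == s for r, s in THRESHOLD_TABLE.items())
    return {"n_correct": correct, "n_ratios": len(THRESHOLD_TABLE)}


def qpcr_roundtrip(seed: int, noise: float = 0.01) -> dict:
    """N0 recovery across efficiencies and four decades of input at 1% noise."""
    rng = np.random.default_rng(seed)
    max_fold = 0.0
    n = 0
    for eff in (1.8, 1.9, 2.0):
        for n0 in (1.0, 10.0, 100.0, 1_000.0, 10_000.0):
            curves = syn.generate_qpcr_curves(
                eff, n0, n_cycles=40, plateau=n0 * eff**30, noise=noise,
                n_replicates=3, seed=int(rng.integers(2**31)),
            )
            est = qpcr.mean_n0(curves)
            fold = max(est / n0, n0 / est)
            max_fold = max(max_fold, fold)
            n += 1
    return {"n_conditions": n, "max_fold_error": max_fold}


def beta_m_identities() -> dict:
    """Defining identities of the beta and M transforms."""
    b1 = pp.beta_from_channels([100.0], [100.0])[0]
    m1 = pp.m_from_beta(b1)
    b2 = pp.beta_from_channels([800.0], [200.0])[0]
    m2 = pp.m_from_beta(b2)
    b3 = pp.beta_from_channels([1000.0], [0.0])[0]
    m3 = pp.m_from_beta(b3)
    err = max(
        abs(b1 - 0.5), abs(float(m1)), abs(b2 - 0.8), abs(float(m2) - 2.0),
        abs(float(m3) - np.log2(999.0)),
    )
    return {"max_abs_error": float(err), "m_bound": float(np.log2(999.0))}


PROMOTER_CLASSES = ("CGI", "TSS")
NON_PROMOTER_CLASSES = ("gene_body", "5UTR", "3UTR", "LINE", "SINE", "LTR", "enhancer")


def class_profile_pattern(seed: int, n_probes: int = 20_000) -> dict:
    """Promoter-sparing hypomethylation pattern across genomic classes.

    Tumor hypomethylation is excluded from CGI and TSS probes; the per-class
    median beta shift (tumor minus normal) should be ~0 for CGI/TSS and
    clearly negative for the repeat/gene classes.
    """
    config = syn.SimulationConfig(
        seed=seed, n_probes=n_probes,
        n_samples_per_group={"d0_PTC": 4, "SE": 3},
        hypometh_exclude_classes=PROMOTER_CLASSES,
    )
    manifest = syn.generate_manifest(config)
    raw, _ = syn.generate_cohort(config, manifest)
    # beta from filtered channels without cross-sample quantile
    # normalization: equalizing marginal distributions between a globally
    # hypomethylated group and normal cells would artificially inflate the
    # spared promoter probes, which is exactly the comparison profiled here
    filtered, _ = pp.filter_probes(raw, manifest)
    meth = pp.compute_beta_m(filtered)
    dists = cp.class_distributions(
        meth, manifest, classes=PROMOTER_CLASSES + NON_PROMOTER_CLASSES,
        groups=("d0_PTC", "SE"),
    )
    med = {(d.class_label, d.group): d.median_beta for d in dists}
    shifts = {c: med[(c, "SE")] - med[(c, "d0_PTC")] for c in PROMOTER_CLASSES + NON_PROMOTER_CLASSES}
    return {
        "max_promoter_abs_shift": max(abs(shifts[c]) for c in PROMOTER_CLASSES),
        "n_hypomethylated_nonpromoter": sum(shifts[c] < -0.05 for c in NON_PROMOTER_CLASSES),
        "n_nonpromoter_classes": len(NON_PROMOTER_CLASSES),
        "shifts": shifts,
    }
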