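"""Synthetic 450k-like cohorts with planted ground truth.

The generator emulates the observables the analysis chain consumes:

* bimodal beta in normal cells — most CpGs are either essentially
  unmethylated (mode near 0.05) or essentially methylated (mode near 0.95);
* globally hypomethylated tumor profiles — in tumor groups a configurable
  fraction of methylated-mode probes is re-drawn from the unmethylated mode
  (optionally sparing promoter/CGI classes);
* planted DMRs — CpG-dense regions (probe spacing <= 200 bp) whose M-values
  are shifted by a stated effect size in one group;
* planted CNV segments — total probe intensity scales with copy number
  (expected log2 ratio log2(copy/2)); a mosaic fraction f dilutes the
  effective copy toward 2 as 2(1-f) + f*copy;
* a copy-stable control cohort (10 female blood samples by default) that is
  copy-number 2 everywhere, by construction;
* negative-control probes and planted detection failures at background
  fluorescence, so detection p-values can be derived from the data.

Channel decomposition is exact before noise (meth/(meth+unmeth) == true
beta); measurement noise is then applied on the beta scale and the channels
recomposed at fixed total, keeping methylation (channel split) and copy
number (total intensity) orthogonal by construction.

The default genome is 23 chromosomes (1-22, X) at 1/100 of the human
chromosome lengths with ~20,000 probes, so the full pipeline runs in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from metharray.data_model import (
    ALLOWED_CHROMS,
    GENOMIC_CLASSES,
    IntensityDataset,
    manifest_to_frame,
    probe_classes,
    ProbeAnnotation,
)
from metharray.errors import ConfigError
from metharray.qpcr import AmplificationCurve

# hg38 chromosome lengths scaled to 1/100, in bp
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "1": 2_489_600, "2": 2_421_900, "3": 1_983_000, "4": 1_902_100,
    "5": 1_815_400, "6": 1_708_100, "7": 1_593_500, "8": 1_451_400,
    "9": 1_383_900, "10": 1_338_000, "11": 1_350_900, "12": 1_332_800,
    "13": 1_143_600, "14": 1_070_400, "15": 1_019_900, "16": 903_400,
    "17": 832_600, "18": 803_700, "19": 586_200, "20": 644_400,
    "21": 467_100, "22": 508_200, "X": 1_560_400,
}

DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "TSS": 0.10, "5UTR": 0.05, "gene_body": 0.30, "3UTR": 0.04,
    "LINE": 0.12, "SINE": 0.14, "LTR": 0.05, "CGI": 0.22, "enhancer": 0.06,
}


@dataclass(frozen=True)
class PlantedDMR:
    """A differentially methylated region planted in one group.

    ``delta_m`` shifts the region probes' M-values in ``group`` relative to
    every other group; probes are placed with consecutive gaps <= 200 bp.
    """

    chrom: str
    start: int
    end: int
    n_probes: int
    delta_m: float
    group: str = "SE"


@dataclass(frozen=True)
class PlantedCNV:
    """A copy-number segment planted in one sample or one whole group.

    ``copy_number`` is the integer copy state in affected cells;
    ``mosaic_fraction`` is the proportion of cells carrying it, so the
    effective copy seen by the array is ``2*(1-f) + f*copy``.
    """

    target: str  # sample name or group name
    chrom: str
    start: int
    end: int
    copy_number: int
    mosaic_fraction: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_probes: int = 20_000
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"d0_PTC": 4, "LT_PTC": 4, "SE": 3, "control": 10}
    )
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    #: Beta-distribution (a, b) parameters of the unmethylated (~0.05) and
    #: methylated (~0.95) modes.
    beta_modes: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 38.0), (38.0, 2.0))
    unmeth_mode_weight: float = 0.5
    tumor_hypometh_fraction: float = 0.5
    tumor_groups: tuple[str, ...] = ("SE",)
    #: Genomic classes spared by tumor hypomethylation (probes belonging to
    #: any of them keep their methylated-mode beta).
    hypometh_exclude_classes: tuple[str, ...] = ()
    #: (mean, sd) of log base total intensity per probe (natural log).
    #: The base is a probe "affinity" shared across samples, as on real
    #: arrays, so it cancels in copy-number ratios against the baseline.
    intensity_scale: tuple[float, float] = (np.log(5000.0), 0.4)
    #: Per-(probe, sample) multiplicative technical noise, log-scale sd.
    #: Calibrated so the per-bin copy-number noise floor reproduces the
    #: platform's detection limit (no calls below ~10% mosaic fraction).
    intensity_tech_sd: float = 0.02
    noise_sd: float = 0.02
    planted_dmrs: tuple[PlantedDMR, ...] = ()
    planted_cnvs: tuple[PlantedCNV, ...] = ()
    failed_probe_fraction: float = 0.005
    snp_probe_fraction: float = 0.01
    multi_target_fraction: float = 0.005
    n_negative_controls: int = 100
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    design_type_I_fraction: float = 0.28
    #: Passing probes draw detect_p ~ U(0, this); failed probes ~ U(0, 1).
    detection_p_passing_max: float = 0.005
    #: Totals are floored here before any log2 (keeps copy-0 finite).
    intensity_floor: float = 1.0

    def validate(self) -> None:
        if not 0 < self.unmeth_mode_weight < 1:
            raise ConfigError("unmeth_mode_weight must be in (0, 1)")
        if not 0 <= self.tumor_hypometh_fraction <= 1:
            raise ConfigError("tumor_hypometh_fraction must be in [0, 1]")
        n_planted = sum(d.n_probes for d in self.planted_dmrs)
        if self.n_probes < n_planted:
            raise ConfigError(f"n_probes ({self.n_probes}) < planted DMR probes ({n_planted})")
        groups = set(self.n_samples_per_group)
        for d in self.planted_dmrs:
            self._check_region(d.chrom, d.start, d.end)
            if d.n_probes < 4:
                raise ConfigError(f"planted DMR needs >= 4 probes, got {d.n_probes}")
            if d.group not in groups:
                raise ConfigError(f"planted DMR group {d.group!r} not in config groups")
        sample_names = set(self.sample_names())
        for c in self.planted_cnvs:
            self._check_region(c.chrom, c.start, c.end)
            if c.copy_number not in (0, 1, 2, 3, 4):
                raise ConfigError(f"copy_number must be in 0..4, got {c.copy_number}")
            if not 0 < c.mosaic_fraction <= 1:
                raise ConfigError("mosaic_fraction must be in (0, 1]")
            if c.target not in groups and c.target not in sample_names:
                raise ConfigError(f"planted CNV target {c.target!r} is neither a group nor a sample")
            if c.target == "control" or (
                c.target in sample_names and c.target.startswith("control_")
            ):
                raise ConfigError("the control cohort is copy-stable; cannot plant a CNV in it")

    def _check_region(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_lengths:
            raise ConfigError(f"planted region on unknown chromosome {chrom!r}")
        if not 1 <= start < end <= self.chrom_lengths[chrom]:
            raise ConfigError(
                f"planted region {chrom}:{start}-{end} exceeds chromosome length "
                f"{self.chrom_lengths[chrom]}"
            )

    def sample_names(self) -> list[str]:
        return [
            f"{g}_{i + 1}"
            for g in self.n_samples_per_group
            for i in range(self.n_samples_per_group[g])
        ]

    def group_map(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_names()}


@dataclass
class GroundTruth:
    """Planted truth serialized alongside a synthetic cohort."""

    dmr_regions: tuple[PlantedDMR, ...]
    cnv_segments: tuple[PlantedCNV, ...]
    true_beta: pd.DataFrame  # probe x group
    copy_state: pd.DataFrame  # probe x sample (effective copy, float)
    failed_probes: tuple[str, ...]

    def to_json_dict(self) -> dict:
        return {
            "dmr_regions": [vars(d) | {} for d in map(lambda d: d, self.dmr_regions)],
            "cnv_segments": [d.__dict__ for d in self.cnv_segments],
            "failed_probes": list(self.failed_probes),
        }


def _logit2(beta: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    b = np.clip(beta, eps, 1 - eps)
    return np.log2(b / (1 - b))


def _inv_logit2(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + 2.0 ** (-m))


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate a probe manifest with planted CpG-dense regions.

    Probes come back sorted by (chromosome, position); planted DMR probes are
    laid down with consecutive gaps <= 200 bp inside their regions. SNP and
    multi-target flags are assigned to background probes only, keeping
    planted regions orthogonal to probe filtering.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    entries: list[dict] = []

    # planted DMR probes: gaps drawn in [20, 180] so chains satisfy <= 200 bp
    for d in config.planted_dmrs:
        span_needed = (d.n_probes - 1) * 180 + 1
        if d.end - d.start + 1 < span_needed:
            gaps = np.full(d.n_probes - 1, max(1, (d.end - d.start) // max(d.n_probes - 1, 1)))
            if gaps.max(initial=0) > 200:
                raise ConfigError(
                    f"planted DMR {d.chrom}:{d.start}-{d.end} too wide for {d.n_probes} "
                    "probes at <= 200 bp spacing"
                )
        else:
            gaps = rng.integers(20, 181, size=d.n_probes - 1)
        pos = d.start + np.concatenate([[0], np.cumsum(gaps)])
        for p in pos:
            entries.append({"chrom": d.chrom, "pos": int(p), "planted": True})

    # background CpG probes, proportional to chromosome length
    n_bg = config.n_probes - sum(d.n_probes for d in config.planted_dmrs)
    chroms = [c for c in ALLOWED_CHROMS if c in config.chrom_lengths]
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(n_bg * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-(n_bg * lengths / lengths.sum() - counts))[: n_bg - counts.sum()]:
        counts[i] += 1
    for c, k in zip(chroms, counts):
        pos = rng.choice(np.arange(1, config.chrom_lengths[c] + 1), size=k, replace=False)
        for p in np.sort(pos):
            entries.append({"chrom": c, "pos": int(p), "planted": False})

    # negative controls: background fluorescence probes with no annotation
    for _ in range(config.n_negative_controls):
        c = chroms[rng.integers(len(chroms))]
        entries.append(
            {"chrom": c, "pos": int(rng.integers(1, config.chrom_lengths[c] + 1)),
             "planted": False, "neg": True}
        )

    order = {c: i for i, c in enumerate(ALLOWED_CHROMS)}
    entries.sort(key=lambda e: (order[e["chrom"]], e["pos"], e.get("neg", False)))

    class_names = list(config.class_proportions)
    class_p = np.array([config.class_proportions[c] for c in class_names])
    records: list[ProbeAnnotation] = []
    n_cpg = sum(1 for e in entries if not e.get("neg"))
    bg_cpg_idx = [i for i, e in enumerate(entries) if not e.get("neg") and not e["planted"]]
    n_snp = int(round(config.snp_probe_fraction * n_cpg))
    n_multi = int(round(config.multi_target_fraction * n_cpg))
    flagged = rng.choice(bg_cpg_idx, size=min(n_snp + n_multi, len(bg_cpg_idx)), replace=False)
    snp_set = set(flagged[:n_snp].tolist())
    multi_set = set(flagged[n_snp:].tolist())

    i_cg = i_neg = 0
    for i, e in enumerate(entries):
        if e.get("neg"):
            i_neg += 1
            records.append(
                ProbeAnnotation(
                    probe_id=f"neg{i_neg:05d}", chrom=e["chrom"], pos=e["pos"],
                    design_type="II", is_cpg_target=False, classes=frozenset(),
                    is_negative_control=True,
                )
            )
            continue
        i_cg += 1
        member = rng.random(len(class_names)) < class_p
        classes = frozenset(c for c, m in zip(class_names, member) if m)
        gene = ""
        if classes & {"TSS", "5UTR", "gene_body", "3UTR", "TSS1500", "TSS200", "first_exon"}:
            gene = f"G{e['chrom']}_{e['pos'] // 50_000}"
        records.append(
            ProbeAnnotation(
                probe_id=f"cg{i_cg:07d}", chrom=e["chrom"], pos=e["pos"],
                design_type="I" if rng.random() < config.design_type_I_fraction else "II",
                is_cpg_target=True, classes=classes, gene_symbol=gene or None,
                snp_within_10bp_maf05=i in snp_set, multi_target=i in multi_set,
            )
        )
    return manifest_to_frame(records)


def _planted_probe_mask(manifest: pd.DataFrame, chrom: str, start: int, end: int) -> pd.Series:
    return (
        (manifest["chrom"] == chrom)
        & (manifest["pos"] >= start)
        & (manifest["pos"] <= end)
        & manifest["is_cpg_target"]
    )


def generate_cohort(
    config: SimulationConfig, manifest: pd.DataFrame
) -> tuple[IntensityDataset, GroundTruth]:
    """Simulate raw intensities for every sample plus the planted truth.

    Per probe and sample: a true beta is drawn from the group model (tumor
    groups apply the hypomethylation re-draw, planted DMRs override their
    regions), total intensity T ~ lognormal * copy/2, channels are composed
    as meth = beta*T and unmeth = (1-beta)*T, then beta-scale noise is added
    and the channels recomposed at the same total.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    probes = list(manifest.index)
    n = len(probes)
    groups = list(config.n_samples_per_group)
    samples = config.sample_names()
    group_map = config.group_map()
    is_neg = manifest["is_negative_control"].to_numpy(bool)
    cls = probe_classes(manifest)

    (a0, b0), (a1, b1) = config.beta_modes
    meth_mode = rng.random(n) >= config.unmeth_mode_weight
    base_beta = np.where(
        meth_mode, rng.beta(a1, b1, size=n), rng.beta(a0, b0, size=n)
    )

    exclude = set(config.hypometh_exclude_classes)
    sparable = np.array([bool(c & exclude) for c in cls], dtype=bool)

    true_beta = pd.DataFrame(index=probes, columns=groups, dtype=float)
    for g in groups:
        beta_g = base_beta.copy()
        if g in config.tumor_groups and config.tumor_hypometh_fraction > 0:
            redraw = (
                meth_mode
                & ~sparable
                & (rng.random(n) < config.tumor_hypometh_fraction)
            )
            beta_g[redraw] = rng.beta(a0, b0, size=int(redraw.sum()))
        true_beta[g] = beta_g
    # Planted DMRs are coherent: all probes of the region share one base
    # mode in every group (methylated when the shift is a loss, unmethylated
    # when it is a gain, so the shifted group moves into the observable
    # middle of the beta range), and the target group's M is offset delta_m.
    for d in config.planted_dmrs:
        mask = _planted_probe_mask(manifest, d.chrom, d.start, d.end).to_numpy()
        k = int(mask.sum())
        a, b = (a1, b1) if d.delta_m < 0 else (a0, b0)
        region_base = rng.beta(a, b, size=k)
        for g in groups:
            col = true_beta[g].to_numpy()
            col[mask] = region_base
            true_beta[g] = col
        col = true_beta[d.group].to_numpy()
        col[mask] = _inv_logit2(_logit2(region_base) + d.delta_m)
        true_beta[d.group] = col

    # effective copy per probe x sample
    copy = pd.DataFrame(2.0, index=probes, columns=samples)
    for c in config.planted_cnvs:
        targets = (
            [c.target]
            if c.target in samples
            else [s for s in samples if group_map[s] == c.target]
        )
        mask = _planted_probe_mask(manifest, c.chrom, c.start, c.end).to_numpy()
        eff = 2.0 * (1 - c.mosaic_fraction) + c.copy_number * c.mosaic_fraction
        for s in targets:
            col = copy[s].to_numpy()
            col[mask] = eff
            copy[s] = col

    # detection failures: background CpG probes drawn to low fluorescence
    planted_mask = np.zeros(n, dtype=bool)
    for d in config.planted_dmrs:
        planted_mask |= _planted_probe_mask(manifest, d.chrom, d.start, d.end).to_numpy()
    cpg_bg = np.flatnonzero(manifest["is_cpg_target"].to_numpy(bool) & ~planted_mask)
    n_failed = int(round(config.failed_probe_fraction * int(manifest["is_cpg_target"].sum())))
    failed_idx = rng.choice(cpg_bg, size=min(n_failed, len(cpg_bg)), replace=False)
    failed_mask = np.zeros(n, dtype=bool)
    failed_mask[failed_idx] = True

    mu, sd = config.intensity_scale
    bg_mu = mu - np.log(50.0)  # background fluorescence ~2% of signal
    meth = np.empty((n, len(samples)))
    unmeth = np.empty((n, len(samples)))
    detect_p = np.empty((n, len(samples)))
    low_signal = is_neg | failed_mask
    base_total = rng.lognormal(mu, sd, size=n)  # probe affinity, shared
    base_total[low_signal] = rng.lognormal(bg_mu, 0.3, size=int(low_signal.sum()))
    for j, s in enumerate(samples):
        g = group_map[s]
        beta_s = true_beta[g].to_numpy().copy()
        tech = (
            rng.lognormal(0.0, config.intensity_tech_sd, size=n)
            if config.intensity_tech_sd > 0
            else 1.0
        )
        total = base_total * tech * (copy[s].to_numpy() / 2.0)
        total[low_signal] = base_total[low_signal] * (tech[low_signal] if config.intensity_tech_sd > 0 else 1.0)
        beta_s[is_neg] = 0.5
        if config.noise_sd > 0:
            beta_s = np.clip(beta_s + rng.normal(0, config.noise_sd, size=n), 0.0, 1.0)
        total = np.maximum(total, config.intensity_floor)
        meth[:, j] = beta_s * total
        unmeth[:, j] = (1 - beta_s) * total
        p = rng.uniform(0, config.detection_p_passing_max, size=n)
        p[failed_mask] = rng.uniform(0, 1, size=int(failed_mask.sum()))
        detect_p[:, j] = p

    ds = IntensityDataset(
        meth=pd.DataFrame(meth, index=probes, columns=samples),
        unmeth=pd.DataFrame(unmeth, index=probes, columns=samples),
        detect_p=pd.DataFrame(detect_p, index=probes, columns=samples),
        group=group_map,
    )
    truth = GroundTruth(
        dmr_regions=config.planted_dmrs,
        cnv_segments=config.planted_cnvs,
        true_beta=true_beta,
        copy_state=copy,
        failed_probes=tuple(np.array(probes)[failed_mask]),
    )
    return ds, truth


def generate_qpcr_curves(
    efficiency: float,
    n0: float,
    n_cycles: int = 40,
    plateau: float | None = None,
    noise: float = 0.0,
    n_replicates: int = 1,
    seed: int | None = None,
    target: str = "target",
    sample: str = "sample",
) -> list[AmplificationCurve]:
    """Simulate qPCR amplification curves with geometric growth.

    Fluorescence at cycle c is ``min(plateau, n0 * efficiency**c)`` times a
    multiplicative noise term of relative s.d. ``noise`` (so ``noise=0.01``
    is 1% fluorescence noise). Triplicates are separate draws sharing n0.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ConfigError(f"efficiency must be in (1, 2], got {efficiency}")
    if n0 <= 0:
        raise ConfigError("n0 must be positive")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1)
    ideal = n0 * efficiency ** cycles.astype(float)
    if plateau is not None:
        ideal = np.minimum(ideal, plateau)
    curves = []
    for r in range(n_replicates):
        f = ideal * (1 + rng.normal(0, noise, size=n_cycles)) if noise > 0 else ideal.copy()
        curves.append(
            AmplificationCurve(
                reaction_id=f"{sample}:{target}:{r + 1}",
                target=target,
                sample=sample,
                cycles=cycles.copy(),
                fluorescence=np.maximum(f, 0.0),
                replicate=r + 1,
            )
        )
    return curves


def null_config(seed: int, **overrides) -> SimulationConfig:
    """A no-effect configuration: no planted DMRs/CNVs, no hypomethylation."""
    return replace(
        SimulationConfig(seed=seed, tumor_hypometh_fraction=0.0), **overrides
    )
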