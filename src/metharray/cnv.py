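"""Copy-number calling from total probe fluorescence.

Copy number scales the total (methylated + unmethylated) fluorescence of a
probe, so per-bin log2 ratios against a copy-stable baseline recover gains
and losses: an effective copy c gives an expected ratio log2(c/2), i.e.
+0.585 for a uniform single-copy gain, -1 for a uniform single-copy loss,
and a ratio diluted toward 0 by the mosaic fraction.

Pipeline: CpG probes on autosomes + X are divided into equal-probe-count
bins per chromosome (remainder merged into the last bin); every sample is
library-scaled by subtracting its median log2 total; a baseline (median and
MAD across control samples of the per-bin median log2 total) is built from
a copy-stable female control cohort; each experimental bin's log2 ratio is
its median log2 total minus the baseline median, flagged significant when
|ratio| > k * max(MAD, mad_floor). States follow the five published
cutoffs: homozygous deletion (<= -0.96), hemizygous/mosaic deletion
(<= -0.24), neutral (-0.24 .. 0.12 exclusive), duplication (>= +0.12) and
high-copy gain (>= +0.72); the per-bin gain/loss track is +1 for a
significant gain state and -1 for a significant deletion state. For male
samples against the all-female baseline, chrX ratios are shifted +1 before
thresholding; with sex unspecified chrX calls are suppressed.

Note the published cutoffs are deliberately coarse: a uniform single-copy
loss (expected ratio -1 < -0.96) lands in the homozygous-deletion state.
That coarseness is preserved, not corrected. A 10%-mosaic single-copy gain
has expected ratio log2(1.05) ~ 0.07 < 0.12 and is by design below the
detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from metharray.data_model import ALLOWED_CHROMS, IntensityDataset
from metharray.errors import ConfigError, IntegrityError, MethArrayError

STATES = ("hom_del", "hemi_del", "neutral", "dup", "high_gain")
_DELETION_STATES = frozenset({"hom_del", "hemi_del"})
_GAIN_STATES = frozenset({"dup", "high_gain"})


@dataclass(frozen=True)
class CNVThresholds:
    """Five-state log2-ratio cutoffs (published values as defaults)."""

    homozygous_del_max: float = -0.96
    hemizygous_del_max: float = -0.24
    neutral_high: float = 0.12
    duplication_min: float = 0.12
    high_gain_min: float = 0.72

    def __post_init__(self) -> None:
        if not (
            self.homozygous_del_max
            < self.hemizygous_del_max
            < self.neutral_high
            <= self.duplication_min
            < self.high_gain_min
        ):
            raise ConfigError("CNV thresholds must be strictly ordered")

    def classify(self, log2_ratio: float) -> str:
        """Map a finite log2 ratio to exactly one of the five states."""
        if not np.isfinite(log2_ratio):
            raise ConfigError(f"log2_ratio must be finite, got {log2_ratio}")
        if log2_ratio <= self.homozygous_del_max:
            return "hom_del"
        if log2_ratio <= self.hemizygous_del_max:
            return "hemi_del"
        if log2_ratio >= self.high_gain_min:
            return "high_gain"
        if log2_ratio >= self.duplication_min:
            return "dup"
        return "neutral"


@dataclass(frozen=True)
class CNVBin:
    """A run of consecutive CpG probes on one chromosome."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    undersized: bool = False

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class Baseline:
    """Per-bin control median and MAD of the median log2 totals."""

    bins: tuple[CNVBin, ...]
    median: np.ndarray
    mad: np.ndarray
    n_controls: int


@dataclass
class CNVProfile:
    """Per-bin ratios, significance, state and gain/loss for one sample."""

    sample: str
    bins: tuple[CNVBin, ...]
    log2_ratio: np.ndarray
    significant: np.ndarray
    state: np.ndarray  # of STATES strings
    gain_loss: np.ndarray  # -1 / 0 / +1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample,
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "n_probes_or_bins": [b.n_probes for b in self.bins],
                "log2_ratio": self.log2_ratio,
                "state": self.state,
                "significant": self.significant,
                "gain_loss": self.gain_loss,
            }
        )


def probe_totals(raw: IntensityDataset, floor: float = 1.0) -> pd.DataFrame:
    """Per-probe total fluorescence (meth + unmeth), floored at ``floor``.

    The floor keeps log2 finite for fully deleted segments; symmetric in
    the two channels by construction.
    """
    return raw.total().clip(lower=floor)


def build_bins(
    manifest: pd.DataFrame,
    probes_per_bin: int = 50,
    min_probes_per_bin: int = 10,
) -> list[CNVBin]:
    """Equal-probe-count bins per chromosome, remainder merged into the last.

    Only CpG-target probes on autosomes + X participate. A chromosome with
    fewer than ``min_probes_per_bin`` probes yields one undersized bin,
    flagged rather than dropped.
    """
    if probes_per_bin < 2:
        raise ConfigError("probes_per_bin must be >= 2")
    mf = manifest[
        manifest["is_cpg_target"].astype(bool)
        & manifest["chrom"].isin(ALLOWED_CHROMS)
    ].sort_values(["chrom", "pos"], key=lambda s: s.map(
        {c: i for i, c in enumerate(ALLOWED_CHROMS)}) if s.name == "chrom" else s,
        kind="mergesort",
    )
    bins: list[CNVBin] = []
    for chrom in ALLOWED_CHROMS:
        sub = mf[mf["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        n = len(ids)
        if n < min_probes_per_bin:
            bins.append(CNVBin(chrom, int(pos[0]), int(pos[-1]), tuple(ids), undersized=True))
            continue
        n_bins = max(1, n // probes_per_bin)
        for k in range(n_bins):
            lo = k * probes_per_bin
            hi = (k + 1) * probes_per_bin if k < n_bins - 1 else n  # remainder merged
            bins.append(CNVBin(chrom, int(pos[lo]), int(pos[hi - 1]), tuple(ids[lo:hi])))
    return bins


def _scaled_log_totals(totals: pd.DataFrame) -> pd.DataFrame:
    """log2 totals, library-scaled by subtracting each sample's median."""
    logt = np.log2(totals)
    return logt - logt.median(axis=0)


def _bin_medians(logt: pd.DataFrame, bins: Sequence[CNVBin]) -> np.ndarray:
    """Median over bin probes of log2 totals; bins x samples."""
    out = np.empty((len(bins), logt.shape[1]))
    for i, b in enumerate(bins):
        out[i] = np.nanmedian(logt.loc[list(b.probe_ids)].to_numpy(float), axis=0)
    return out


def control_baseline(
    controls: IntensityDataset,
    bins: Sequence[CNVBin],
    floor: float = 1.0,
) -> Baseline:
    """Copy-stable baseline: per-bin median and MAD across control samples.

    Controls are library-scaled per sample first. All-identical controls
    yield MAD 0 per bin, which downstream calls replace by the mad_floor.
    """
    if len(controls.samples) < 3:
        raise MethArrayError(
            f"need >= 3 control samples for a baseline dispersion, got {len(controls.samples)}"
        )
    logt = _scaled_log_totals(probe_totals(controls, floor))
    bm = _bin_medians(logt, bins)  # bins x controls
    med = np.median(bm, axis=1)
    mad = np.median(np.abs(bm - med[:, None]), axis=1)
    return Baseline(bins=tuple(bins), median=med, mad=mad, n_controls=len(controls.samples))


def sample_profile(
    sample_totals: pd.Series,
    baseline: Baseline,
    thresholds: CNVThresholds | None = None,
    sex: str | None = None,
    k_sigma: float = 3.0,
    mad_floor: float = 0.05,
    sample: str = "sample",
    floor: float = 1.0,
) -> CNVProfile:
    """Per-bin log2 ratios and five-state calls for one sample.

    ``sample_totals`` is the per-probe total fluorescence (index: probe_id).
    The sample is library-scaled exactly as the controls were; the ratio is
    the bin's median log2 total minus the baseline median. Male samples get
    a +1 shift on chrX before thresholding (the female baseline carries two
    X copies); with ``sex=None`` chrX calls are suppressed with a warning.
    ``gain_loss`` is nonzero only where the ratio is significant
    (|ratio| > k_sigma * max(MAD, mad_floor)).
    """
    thresholds = thresholds or CNVThresholds()
    logt = np.log2(sample_totals.clip(lower=floor).astype(float))
    logt = logt - logt.median()
    bins = baseline.bins
    ratios = np.empty(len(bins))
    for i, b in enumerate(bins):
        ratios[i] = np.nanmedian(logt.loc[list(b.probe_ids)].to_numpy(float)) - baseline.median[i]
    on_x = np.array([b.chrom == "X" for b in bins])
    if sex == "male":
        ratios[on_x] += 1.0
    sigma = k_sigma * np.maximum(baseline.mad, mad_floor)
    significant = np.abs(ratios) > sigma
    if sex is None and on_x.any():
        warnings.warn("sample sex unspecified: chrX calls suppressed", stacklevel=2)
        significant[on_x] = False
    state = np.array([thresholds.classify(r) for r in ratios], dtype=object)
    gain_loss = np.zeros(len(bins), dtype=int)
    gain_loss[significant & np.isin(state, list(_GAIN_STATES))] = 1
    gain_loss[significant & np.isin(state, list(_DELETION_STATES))] = -1
    return CNVProfile(
        sample=sample, bins=tuple(bins), log2_ratio=ratios,
        significant=significant, state=state, gain_loss=gain_loss,
    )


def call_cnvs(
    raw: IntensityDataset,
    controls: IntensityDataset,
    manifest: pd.DataFrame,
    probes_per_bin: int = 50,
    thresholds: CNVThresholds | None = None,
    sex: dict[str, str] | str | None = None,
    k_sigma: float = 3.0,
    mad_floor: float = 0.05,
) -> list[CNVProfile]:
    """Bin, baseline and profile every sample of ``raw`` against controls."""
    bins = build_bins(manifest, probes_per_bin=probes_per_bin)
    present = set(raw.probes) & set(controls.probes)
    shared = [b for b in bins if all(p in present for p in b.probe_ids)]
    baseline = control_baseline(controls, shared)
    totals = probe_totals(raw)
    profiles = []
    for s in raw.samples:
        sx = sex.get(s) if isinstance(sex, dict) else sex
        profiles.append(
            sample_profile(
                totals[s], baseline, thresholds=thresholds, sex=sx,
                k_sigma=k_sigma, mad_floor=mad_floor, sample=s,
            )
        )
    return profiles


def cohort_summary(profiles: Sequence[CNVProfile]) -> pd.DataFrame:
    """Per-bin aggregate over samples: mean log2 ratio and majority call.

    Opposite calls in a bin cancel to 0 (strict majority). All profiles
    must share the same bin definition.
    """
    if not profiles:
        raise MethArrayError("at least one profile required")
    ref = profiles[0].bins
    for p in profiles[1:]:
        if p.bins != ref:
            raise IntegrityError("profiles have mixed bin definitions")
    ratios = np.stack([p.log2_ratio for p in profiles])
    calls = np.stack([p.gain_loss for p in profiles])
    majority = np.sign(calls.sum(axis=0)).astype(int)
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in ref],
            "start": [b.start for b in ref],
            "end": [b.end for b in ref],
            "n_probes_or_bins": [b.n_probes for b in ref],
            "mean_log2_ratio": ratios.mean(axis=0),
            "majority_gain_loss": majority,
        }
    )


def profiles_to_seg(profiles: Sequence[CNVProfile]) -> pd.DataFrame:
    """Stack profiles into a SEG-compatible frame (see data_model.write_seg)."""
    frames = [p.to_frame() for p in profiles]
    df = pd.concat(frames, ignore_index=True)
    return df[["sample", "chrom", "start", "end", "n_probes_or_bins", "log2_ratio", "state"]]
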