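"""Global and per-genomic-class beta distributions.

Methylation in normal cells is bimodal: most CpGs sit in either the 0-10%
or the 90-100% beta bin, while hypomethylated tumors shift mass out of the
top bin. Profiles are histograms over ten beta bins of width 0.1 —
[0, 0.1), ..., [0.9, 1.0] (last bin closed) — pooled over all samples of a
group, either genome-wide or per genomic class (a probe contributes to
every class it belongs to).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from metharray.data_model import GENOMIC_CLASSES, MethylationDataset, probe_classes
from metharray.errors import MethArrayError

BIN_EDGES = np.linspace(0.0, 1.0, 11)


@dataclass
class ClassDistribution:
    """Beta histogram of one (class, group) pair."""

    class_label: str
    group: str
    counts: np.ndarray  # length 10; sums to n_values
    n_probes: int
    median_beta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_label,
                "group": self.group,
                "bin_low": BIN_EDGES[:-1],
                "bin_high": BIN_EDGES[1:],
                "count": self.counts,
            }
        )


def _distribution(values: np.ndarray, class_label: str, group: str, n_probes: int) -> ClassDistribution:
    values = values[~np.isnan(values)]
    counts, _ = np.histogram(values, bins=BIN_EDGES)
    med = float(np.median(values)) if values.size else float("nan")
    return ClassDistribution(class_label, group, counts, n_probes, med)


def global_distribution(meth: MethylationDataset, group: str) -> ClassDistribution:
    """Pooled beta histogram over all probes and all samples of a group."""
    samples = meth.samples_in_group(group)
    if not samples:
        raise MethArrayError(f"no samples in group {group!r}")
    values = meth.beta[samples].to_numpy(float).ravel()
    return _distribution(values, "all", group, len(meth.probes))


def class_distributions(
    meth: MethylationDataset,
    manifest: pd.DataFrame,
    classes: tuple[str, ...] = GENOMIC_CLASSES,
    groups: tuple[str, ...] | None = None,
) -> list[ClassDistribution]:
    """One beta histogram per (genomic class, group).

    A probe contributes to every class it belongs to, so class totals can
    exceed the number of annotated probes. ``TSS`` matches probes annotated
    TSS, TSS1500 or TSS200 (the coarse promoter class is the union of the
    fine ones). Unknown class names are rejected with the valid vocabulary.
    """
    vocab = set()
    per_probe = probe_classes(manifest.loc[meth.probes])
    for cs in per_probe:
        vocab |= cs
    unknown = [c for c in classes if c not in vocab and c != "TSS"]
    if unknown:
        raise MethArrayError(
            f"unknown class name(s) {unknown}; valid names here: {sorted(vocab)}"
        )
    if groups is None:
        groups = tuple(dict.fromkeys(meth.group[s] for s in meth.samples))
    out: list[ClassDistribution] = []
    beta = meth.beta
    for cls in classes:
        match = {cls} if cls != "TSS" else {"TSS", "TSS1500", "TSS200"}
        mask = per_probe.map(lambda cs: bool(cs & match)).to_numpy(bool)
        for g in groups:
            samples = meth.samples_in_group(g)
            if not samples:
                raise MethArrayError(f"no samples in group {g!r}")
            values = beta.loc[mask, samples].to_numpy(float).ravel()
            out.append(_distribution(values, cls, g, int(mask.sum())))
    return out


def distributions_to_frame(dists: list[ClassDistribution]) -> pd.DataFrame:
    """Tidy long table (class, group, bin_low, bin_high, count)."""
    if not dists:
        return pd.DataFrame(columns=["class", "group", "bin_low", "bin_high", "count"])
    return pd.concat([d.to_frame() for d in dists], ignore_index=True)
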