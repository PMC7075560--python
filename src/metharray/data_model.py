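"""Shared domain types and tabular I/O for the pipeline.

Coordinates are 1-based inclusive everywhere in memory; BED export converts
to 0-based half-open on write and back on read. Chromosome names are
``1``..``22`` and ``X``; ``Y`` is rejected at manifest load unless the
permissive flag is set, mirroring an autosomes-plus-X analysis scope.

File formats (all tab-separated, header row required):

* manifest: ``probe_id chrom pos design_type is_cpg_target classes
  gene_symbol snp_within_10bp_maf05 multi_target is_negative_control``;
  ``classes`` is a comma-joined list (empty for intergenic probes), boolean
  columns are ``0``/``1``.
* intensities (long format): ``probe_id sample meth unmeth detect_p``;
  empty/NA cells in the intensity columns are stored as missing values and
  counted in the load report, never imputed.
* regions: BED ``chrom start end name``.
* CNV segments: SEG ``sample chrom start end n_probes_or_bins log2_ratio
  state`` with 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from metharray.errors import FormatError, IntegrityError

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
ALLOWED_CHROMS: tuple[str, ...] = AUTOSOMES + ("X",)

#: Canonical sample groups; arbitrary labels are accepted but these names
#: carry meaning for the simulator (``control`` = copy-stable cohort).
GROUPS: tuple[str, ...] = ("d0_PTC", "LT_PTC", "SE", "control", "other")

#: The nine genomic classes used for class-level methylation profiles.
GENOMIC_CLASSES: tuple[str, ...] = (
    "TSS",
    "5UTR",
    "gene_body",
    "3UTR",
    "LINE",
    "SINE",
    "LTR",
    "CGI",
    "enhancer",
)

#: Finer promoter split supported alongside the nine-class vocabulary;
#: ``TSS`` is the union of ``TSS1500`` and ``TSS200``.
EXTENDED_CLASSES: tuple[str, ...] = GENOMIC_CLASSES + ("TSS1500", "TSS200", "first_exon")

MANIFEST_COLUMNS: tuple[str, ...] = (
    "probe_id",
    "chrom",
    "pos",
    "design_type",
    "is_cpg_target",
    "classes",
    "gene_symbol",
    "snp_within_10bp_maf05",
    "multi_target",
    "is_negative_control",
)

_BOOL_COLUMNS = (
    "is_cpg_target",
    "snp_within_10bp_maf05",
    "multi_target",
    "is_negative_control",
)


@dataclass(frozen=True)
class ProbeAnnotation:
    """One manifest row: identity, position, design and class membership."""

    probe_id: str
    chrom: str
    pos: int
    design_type: str  # "I" or "II"
    is_cpg_target: bool = True
    classes: frozenset[str] = frozenset()
    gene_symbol: str | None = None
    snp_within_10bp_maf05: bool = False
    multi_target: bool = False
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise IntegrityError(f"{self.probe_id}: pos must be >= 1, got {self.pos}")
        if self.design_type not in ("I", "II"):
            raise FormatError(
                f"{self.probe_id}: design_type must be 'I' or 'II', got {self.design_type!r}"
            )
        if self.is_negative_control and (self.classes or self.is_cpg_target):
            raise IntegrityError(
                f"{self.probe_id}: a negative control has no classes and is not a CpG target"
            )


class Region(NamedTuple):
    """A genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str = "."


def manifest_to_frame(records: Iterable[ProbeAnnotation]) -> pd.DataFrame:
    """Build a manifest DataFrame (indexed by probe_id) from annotations."""
    rows = []
    for r in records:
        rows.append(
            {
                "probe_id": r.probe_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "design_type": r.design_type,
                "is_cpg_target": r.is_cpg_target,
                "classes": ",".join(sorted(r.classes)),
                "gene_symbol": r.gene_symbol or "",
                "snp_within_10bp_maf05": r.snp_within_10bp_maf05,
                "multi_target": r.multi_target,
                "is_negative_control": r.is_negative_control,
            }
        )
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    _validate_manifest(df)
    return df.set_index("probe_id", drop=False)


def _validate_manifest(df: pd.DataFrame, allow_chrY: bool = False) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest is missing required column(s): {', '.join(missing)}")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate probe_id in manifest: {dup!r}")
    allowed = set(ALLOWED_CHROMS) | ({"Y"} if allow_chrY else set())
    bad = set(df["chrom"].astype(str)) - allowed
    if bad:
        raise IntegrityError(
            f"manifest contains disallowed chromosome(s): {sorted(bad)}; "
            f"allowed: 1-22, X" + (", Y" if allow_chrY else " (pass allow_chrY=True to accept Y)")
        )
    if (df["pos"] < 1).any():
        raise IntegrityError("manifest contains pos < 1")
    neg = df["is_negative_control"].astype(bool)
    if (neg & (df["is_cpg_target"].astype(bool) | (df["classes"].fillna("") != ""))).any():
        raise IntegrityError("negative-control probes must have no classes and is_cpg_target=0")


def read_manifest(path, allow_chrY: bool = False) -> pd.DataFrame:
    """Read a probe manifest TSV into a DataFrame indexed by probe_id.

    Column order in the file is irrelevant; unknown chromosomes are rejected
    (``Y`` accepted only with ``allow_chrY``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str}, keep_default_na=False)
    _validate_manifest(df, allow_chrY=allow_chrY)
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64)
    for c in _BOOL_COLUMNS:
        df[c] = df[c].astype(int).astype(bool)
    return df.set_index("probe_id", drop=False)[list(MANIFEST_COLUMNS)]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest[list(MANIFEST_COLUMNS)].copy()
    for c in _BOOL_COLUMNS:
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False)


def probe_classes(manifest: pd.DataFrame) -> pd.Series:
    """Per-probe class membership as frozensets (empty set for none)."""
    return manifest["classes"].map(
        lambda s: frozenset(s.split(",")) if isinstance(s, str) and s else frozenset()
    )


@dataclass
class IntensityDataset:
    """Probe x sample methylated/unmethylated intensities with detection p.

    All three matrices share the same probe index and sample columns.
    Intensities are arbitrary fluorescence units, finite and >= 0; missing
    cells are NaN (allowed, never imputed here).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detect_p: pd.DataFrame
    group: dict[str, str]
    load_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name, m in (("unmeth", self.unmeth), ("detect_p", self.detect_p)):
            if m.shape != self.meth.shape or not m.index.equals(self.meth.index) or not m.columns.equals(self.meth.columns):
                raise IntegrityError(f"{name} matrix is not aligned with meth matrix")
        for name, m in (("meth", self.meth), ("unmeth", self.unmeth)):
            vals = m.to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise IntegrityError(f"{name} contains non-finite intensities")
            if np.nanmin(vals, initial=0.0) < 0:
                raise FormatError(f"{name} contains negative intensities")
        dp = self.detect_p.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(dp, initial=0.0) < 0 or np.nanmax(dp, initial=1.0) > 1:
                raise FormatError("detect_p outside [0, 1]")
        missing = [s for s in self.samples if s not in self.group]
        if missing:
            raise IntegrityError(f"samples without a group label: {missing}")

    @property
    def probes(self) -> list[str]:
        return list(self.meth.index)

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    def total(self) -> pd.DataFrame:
        """Per-probe total intensity (meth + unmeth), NaN where missing."""
        return self.meth + self.unmeth

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group[s] == group]

    def subset(self, probes: Sequence[str] | None = None, samples: Sequence[str] | None = None) -> "IntensityDataset":
        probes = self.probes if probes is None else list(probes)
        samples = self.samples if samples is None else list(samples)
        return IntensityDataset(
            meth=self.meth.loc[probes, samples],
            unmeth=self.unmeth.loc[probes, samples],
            detect_p=self.detect_p.loc[probes, samples],
            group={s: self.group[s] for s in samples},
        )


@dataclass
class MethylationDataset:
    """Probe x sample beta and M matrices after filtering/normalization.

    ``m`` is the logit2 of ``beta`` computed with the documented clamping
    offset (see :mod:`metharray.preprocess`); ``metadata`` records pipeline
    provenance (filter parameters, normalization and type-bias modes).
    """

    beta: pd.DataFrame
    m: pd.DataFrame
    group: dict[str, str]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.m.shape != self.beta.shape or not self.m.index.equals(self.beta.index):
            raise IntegrityError("beta and m matrices are not aligned")
        b = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(b, initial=0.0) < 0 or np.nanmax(b, initial=1.0) > 1:
                raise IntegrityError("beta outside [0, 1]")

    @property
    def probes(self) -> list[str]:
        return list(self.beta.index)

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group[s] == group]


def read_intensities(path, manifest: pd.DataFrame, group: Mapping[str, str] | None = None) -> IntensityDataset:
    """Read a long-format intensity TSV aligned to manifest probe order.

    Every probe_id in the table must exist in the manifest; matrices come
    back in manifest order with samples in file order. NA intensity cells are
    kept as missing values and counted in ``.load_report["n_missing_cells"]``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sample": str})
    required = {"probe_id", "sample", "meth", "unmeth", "detect_p"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"intensity table missing column(s): {sorted(missing)}")
    unknown = set(df["probe_id"]) - set(manifest.index)
    if unknown:
        raise IntegrityError(
            f"{len(unknown)} probe id(s) absent from manifest, e.g. {sorted(unknown)[:3]}"
        )
    for c in ("meth", "unmeth"):
        if (df[c].dropna() < 0).any():
            raise FormatError(f"negative intensity in column {c!r}")
    sample_order = list(dict.fromkeys(df["sample"]))
    probe_order = [p for p in manifest.index if p in set(df["probe_id"])]
    mats = {}
    for c in ("meth", "unmeth", "detect_p"):
        wide = df.pivot(index="probe_id", columns="sample", values=c)
        mats[c] = wide.reindex(index=probe_order, columns=sample_order)
    n_missing = int(mats["meth"].isna().sum().sum() + mats["unmeth"].isna().sum().sum())
    if group is None:
        group = {s: "other" for s in sample_order}
    ds = IntensityDataset(
        meth=mats["meth"], unmeth=mats["unmeth"], detect_p=mats["detect_p"],
        group=dict(group),
    )
    ds.load_report = {"n_missing_cells": n_missing, "n_rows": len(df)}
    return ds


def write_intensities(ds: IntensityDataset, path) -> None:
    long = (
        ds.meth.stack(future_stack=True).rename("meth").to_frame()
        .join(ds.unmeth.stack(future_stack=True).rename("unmeth"))
        .join(ds.detect_p.stack(future_stack=True).rename("detect_p"))
        .reset_index()
    )
    long.columns = ["probe_id", "sample", "meth", "unmeth", "detect_p"]
    long.to_csv(path, sep="\t", index=False)


def write_groups(group: Mapping[str, str], path) -> None:
    pd.DataFrame({"sample": list(group), "group": list(group.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_groups(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise FormatError("groups table needs columns 'sample' and 'group'")
    return dict(zip(df["sample"], df["group"]))


def write_region_bed(regions: Iterable[Region], path) -> None:
    """Write regions as BED (0-based half-open); 1-based inclusive in memory."""
    lines = []
    for r in regions:
        if r.end <= r.start - 1:  # empty or inverted after conversion
            raise IntegrityError(f"region {r.chrom}:{r.start}-{r.end} has end < start")
        lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_region_bed(path) -> list[Region]:
    regions: list[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with < 3 fields: {line!r}")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start0:
                raise IntegrityError(f"BED interval with end <= start: {line!r}")
            name = parts[3] if len(parts) > 3 else "."
            regions.append(Region(chrom, start0 + 1, end, name))
    return regions


SEG_COLUMNS = ("sample", "chrom", "start", "end", "n_probes_or_bins", "log2_ratio", "state")


def write_seg(rows: pd.DataFrame, path) -> None:
    """Write per-bin CNV rows as a SEG table (1-based inclusive)."""
    missing = [c for c in SEG_COLUMNS if c not in rows.columns]
    if missing:
        raise FormatError(f"SEG frame missing column(s): {missing}")
    rows[list(SEG_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "state": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SEG file missing column(s): {missing}")
    return df[list(SEG_COLUMNS)]
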