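"""Differentially methylated region (DMR) detection.

Candidate regions are maximal chains of CpG probes in which every
consecutive pair lies within ``max_gap_bp`` (default 200 bp); chains with at
least ``min_probes`` (default 4) CpGs are tested. The test populations are
the pooled per-probe-per-sample M-values of the region in each group
(region-level M distributions, n_probes x n_samples values per side),
compared by a two-sided Mann-Whitney U test; p-values are Benjamini-
Hochberg adjusted across all testable regions.

Two calling parameterizations are provided and never reconciled:

* ``methods`` mode — BH-adjusted p <= 0.05 and |difference in median
  M-value| >= 1.4;
* ``results`` mode — BH-adjusted p <= 0.01 and |difference in median beta|
  >= 0.25 (the "25% methylation difference" criterion, taken on the beta
  scale; the assumption is recorded in output metadata).

The Mann-Whitney implementation is self-contained: an exact two-sided p by
tie-aware enumeration of group assignments for small samples, an exact
no-tie null distribution by dynamic programming up to combined n = 30, and
a tie- and continuity-corrected normal approximation beyond that. U is
oriented as the number of (a, b) pairs with a > b (ties count 1/2), and
effect signs are group_a - group_b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from metharray.data_model import MethylationDataset, Region
from metharray.errors import ConfigError, MethArrayError

#: Above this many combinations the tie-aware exact path falls back to the
#: corrected normal approximation.
_MAX_ENUMERATION = 200_000


@dataclass(frozen=True)
class DMRParams:
    """Region-definition and calling thresholds."""

    min_probes: int = 4
    max_gap_bp: int = 200
    min_median_m_diff: float = 1.4
    alpha: float = 0.05
    mode: str = "methods"  # or "results"
    min_median_beta_diff: float = 0.25
    results_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.min_probes < 2:
            raise ConfigError("min_probes must be >= 2")
        if self.max_gap_bp <= 0 or self.min_median_m_diff <= 0 or self.min_median_beta_diff <= 0:
            raise ConfigError("thresholds must be positive")
        if self.mode not in ("methods", "results"):
            raise ConfigError(f"mode must be 'methods' or 'results', got {self.mode!r}")


@dataclass(frozen=True)
class CandidateRegion:
    """A CpG-dense chain: consecutive probe gaps <= max_gap_bp."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class DMRRecord:
    """One tested candidate region with medians, test and call status."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    n_probes: int
    group_a: str
    group_b: str
    median_m_a: float
    median_m_b: float
    delta_median_m: float
    median_beta_a: float
    median_beta_b: float
    delta_median_beta: float
    u_statistic: float
    p_raw: float
    p_adj: float = float("nan")
    is_dmr: bool = False
    untestable: bool = False


def find_candidate_regions(
    manifest: pd.DataFrame, params: DMRParams | None = None
) -> list[CandidateRegion]:
    """Greedy maximal chaining of CpG probes per chromosome.

    A probe extends the open chain iff its position is within
    ``max_gap_bp`` of the previous probe (inclusive); chains never span
    chromosomes and only chains of >= ``min_probes`` survive. The manifest
    is sorted internally (chrom, pos, probe_id) if needed, with a warning.
    """
    params = params or DMRParams()
    mf = manifest[manifest["is_cpg_target"].astype(bool)].reset_index(drop=True)
    unsorted = any(
        not np.all(np.diff(sub["pos"].to_numpy()) >= 0)
        for _, sub in mf.groupby("chrom", sort=False)
    )
    if unsorted:
        warnings.warn("manifest not sorted by position; sorting internally", stacklevel=2)
        mf = mf.sort_values(["chrom", "pos", "probe_id"], kind="mergesort")
    regions: list[CandidateRegion] = []
    for chrom, sub in mf.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        chain_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > params.max_gap_bp:
                if i - chain_start >= params.min_probes:
                    regions.append(
                        CandidateRegion(
                            chrom=str(chrom),
                            start=int(pos[chain_start]),
                            end=int(pos[i - 1]),
                            probe_ids=tuple(ids[chain_start:i]),
                        )
                    )
                chain_start = i
    return regions


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group a: #(a > b) pairs, ties counting one half."""
    n_a = len(a)
    ranks = rankdata(np.concatenate([a, b]))
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)


def _exact_p_no_ties(u: float, n_a: int, n_b: int) -> float:
    """Two-sided exact p from the no-tie null distribution of U.

    Uses the classic count recurrence
    count(u; m, n) = count(u - n; m - 1, n) + count(u; m, n - 1).
    """
    max_u = n_a * n_b
    # c[m, u]: number of m-subsets with statistic u, at the current n
    c = np.zeros((n_a + 1, max_u + 1), dtype=float)
    c[:, 0] = 1.0  # n = 0: the only attainable statistic is 0
    for n_cur in range(1, n_b + 1):
        new = np.zeros_like(c)
        new[0, 0] = 1.0
        for m in range(1, n_a + 1):
            new[m, :] = c[m, :]  # the (m, n_cur - 1) term
            new[m, n_cur:] += new[m - 1, : max_u + 1 - n_cur]
        c = new
    dist = c[n_a]
    total = dist.sum()
    lo = dist[: int(np.floor(u)) + 1].sum()
    hi = dist[int(np.ceil(u)) :].sum()
    return float(min(1.0, 2.0 * min(lo, hi) / total))


def _exact_p_enumeration(z: np.ndarray, n_a: int, u: float) -> float:
    """Two-sided exact p by enumerating group assignments (tie-aware)."""
    n = len(z)
    w = (z[:, None] > z[None, :]).astype(float) + 0.5 * (z[:, None] == z[None, :])
    np.fill_diagonal(w, 0.0)
    rowsum = w.sum(axis=1)
    us = []
    for subset in combinations(range(n), n_a):
        s = list(subset)
        us.append(rowsum[s].sum() - w[np.ix_(s, s)].sum())
    us = np.asarray(us)
    total = len(us)
    lo = (us <= u + 1e-9).sum()
    hi = (us >= u - 1e-9).sum()
    return float(min(1.0, 2.0 * min(lo, hi) / total))


def _normal_p(u: float, a: np.ndarray, b: np.ndarray) -> float:
    """Tie- and continuity-corrected normal approximation, two-sided."""
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    z = np.concatenate([a, b])
    _, counts = np.unique(z, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    d = u - mu
    zscore = (d - 0.5 * np.sign(d)) / np.sqrt(var) if d != 0 else 0.0
    return float(min(1.0, 2.0 * norm.sf(abs(zscore))))


def mann_whitney(a: Sequence[float], b: Sequence[float], exact_max_n: int = 30) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group a, p).

    Exact p for combined n <= ``exact_max_n`` (tie-aware enumeration when
    feasible, no-tie DP otherwise); corrected normal approximation beyond.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MethArrayError("both groups must be non-empty")
    u = _u_statistic(a, b)
    n = a.size + b.size
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    if n <= exact_max_n:
        if not has_ties:
            return u, _exact_p_no_ties(u, a.size, b.size)
        if comb(n, a.size) <= _MAX_ENUMERATION:
            return u, _exact_p_enumeration(np.concatenate([a, b]), a.size, u)
    return u, _normal_p(u, a, b)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_adj at ascending rank i is min over j >= i of (m * p_(j) / j), capped
    at 1; the input order is restored on return.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def _resolve_samples(meth: MethylationDataset, group: str | Sequence[str]) -> tuple[str, list[str]]:
    if isinstance(group, str):
        samples = meth.samples_in_group(group)
        if not samples:
            # pairwise-sample mode: a single sample label is accepted too
            if group in meth.samples:
                return group, [group]
            raise MethArrayError(f"no samples in group {group!r}")
        return group, samples
    samples = list(group)
    missing = [s for s in samples if s not in meth.samples]
    if missing:
        raise MethArrayError(f"unknown sample(s): {missing}")
    return "+".join(samples), samples


def test_region(
    meth: MethylationDataset,
    region: CandidateRegion,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
) -> DMRRecord:
    """Mann-Whitney test of a region's pooled M-values between two groups.

    Each test population pools the region's per-probe-per-sample M-values of
    one group; medians (M and beta) are computed on the same pooled
    populations. A group with no non-missing values in the region yields an
    untestable record (excluded from BH later).
    """
    label_a, samples_a = _resolve_samples(meth, group_a)
    label_b, samples_b = _resolve_samples(meth, group_b)
    probes = [p for p in region.probe_ids if p in meth.m.index]
    if not probes:
        raise MethArrayError(f"region {region.chrom}:{region.start}-{region.end} has no probes in dataset")
    m_a = meth.m.loc[probes, samples_a].to_numpy(float).ravel()
    m_b = meth.m.loc[probes, samples_b].to_numpy(float).ravel()
    b_a = meth.beta.loc[probes, samples_a].to_numpy(float).ravel()
    b_b = meth.beta.loc[probes, samples_b].to_numpy(float).ravel()
    m_a, m_b = m_a[~np.isnan(m_a)], m_b[~np.isnan(m_b)]
    b_a, b_b = b_a[~np.isnan(b_a)], b_b[~np.isnan(b_b)]
    rec = DMRRecord(
        chrom=region.chrom, start=region.start, end=region.end,
        probe_ids=tuple(probes), n_probes=len(probes),
        group_a=label_a, group_b=label_b,
        median_m_a=float(np.median(m_a)) if m_a.size else float("nan"),
        median_m_b=float(np.median(m_b)) if m_b.size else float("nan"),
        delta_median_m=float("nan"), median_beta_a=float(np.median(b_a)) if b_a.size else float("nan"),
        median_beta_b=float(np.median(b_b)) if b_b.size else float("nan"),
        delta_median_beta=float("nan"), u_statistic=float("nan"), p_raw=float("nan"),
    )
    if m_a.size == 0 or m_b.size == 0:
        rec.untestable = True
        return rec
    rec.delta_median_m = rec.median_m_a - rec.median_m_b
    rec.delta_median_beta = rec.median_beta_a - rec.median_beta_b
    rec.u_statistic, rec.p_raw = mann_whitney(m_a, m_b)
    return rec


def call_dmrs(
    meth: MethylationDataset,
    manifest: pd.DataFrame,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    params: DMRParams | None = None,
) -> list[DMRRecord]:
    """Chain candidates, test each region, BH-adjust, and call DMRs.

    In ``methods`` mode a region is a DMR iff p_adj <= alpha and
    |delta median M| >= min_median_m_diff; in ``results`` mode iff
    p_adj <= results_alpha and |delta median beta| >= min_median_beta_diff.
    Records come back sorted by (p_adj, -|effect|). An empty candidate list
    is a valid empty result.
    """
    params = params or DMRParams()
    retained = manifest[manifest.index.isin(set(meth.probes))]
    candidates = find_candidate_regions(retained, params)
    records = [test_region(meth, r, group_a, group_b) for r in candidates]
    testable = [r for r in records if not r.untestable]
    if testable:
        adj = adjust_bh([r.p_raw for r in testable])
        for r, pa in zip(testable, adj):
            r.p_adj = float(pa)
            if params.mode == "methods":
                r.is_dmr = pa <= params.alpha and abs(r.delta_median_m) >= params.min_median_m_diff
            else:
                r.is_dmr = (
                    pa <= params.results_alpha
                    and abs(r.delta_median_beta) >= params.min_median_beta_diff
                )
    effect = (
        (lambda r: abs(r.delta_median_m))
        if params.mode == "methods"
        else (lambda r: abs(r.delta_median_beta))
    )
    records.sort(key=lambda r: (np.inf if np.isnan(r.p_adj) else r.p_adj, -effect(r)))
    return records


def records_to_frame(records: list[DMRRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.__dict__.copy()
        d["probe_ids"] = ",".join(d["probe_ids"])
        rows.append(d)
    return pd.DataFrame(rows)


def records_to_regions(records: list[DMRRecord], only_dmrs: bool = True) -> list[Region]:
    return [
        Region(r.chrom, r.start, r.end, f"DMR_p{r.p_adj:.3g}")
        for r in records
        if r.is_dmr or not only_dmrs
    ]
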