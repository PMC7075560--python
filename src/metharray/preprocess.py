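"""Probe filtering, normalization and beta/M computation.

The stage order is fixed and recorded in the output metadata:

    filter -> quantile normalize (per channel) -> beta -> type-bias correct -> M

Filters are applied sequentially in the documented order (non-CpG probes,
detection limit, multi-target probes, SNP-adjacent probes) so per-criterion
removal counts are well defined. Beta is the methylated-channel fraction
meth/(meth+unmeth); M is log2(beta/(1-beta)) with beta clamped to
[eps, 1-eps], eps = 1e-3, bounding |M| at ~9.97.

Detection p-values, when not supplied with the data, are derived from the
negative-control probes: for probe n in sample s,

    p = 1 - ecdf_neg_s(meth_ns + unmeth_ns),

the fraction of negative-control totals in that sample at or above the
probe's total. Probe-type bias (type II beta distributions are compressed
relative to type I) is corrected by monotone quantile mapping of each
sample's type II beta values onto its type I beta distribution; type I
values are left untouched and the mode is recorded in metadata so results
are never conflated with a beta-mixture (BMIQ-style) fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from metharray.data_model import IntensityDataset, MethylationDataset
from metharray.errors import ConfigError, MethArrayError

#: Beta clamp for the M transform; bounds |M| at log2(999) ~ 9.965.
BETA_EPS = 1e-3


@dataclass(frozen=True)
class FilterParams:
    """Probe-filtering thresholds (defaults follow the study criteria)."""

    detect_p_max: float = 0.01
    detect_sample_frac: float = 0.95
    drop_non_cpg: bool = True
    drop_snp_probes: bool = True  # SNP at/within 10 bp of the CpG, MAF >= 0.05
    drop_multi_target: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.detect_p_max < 1:
            raise ConfigError("detect_p_max must be in (0, 1)")
        if not 0 < self.detect_sample_frac <= 1:
            raise ConfigError("detect_sample_frac must be in (0, 1]")


@dataclass
class FilterReport:
    """Per-criterion removal counts under sequential accounting.

    ``removed`` preserves application order; n_input - sum(removed.values())
    == n_retained always holds. Two probe counts circulate for any filtered
    array dataset — the post-filter count and the count actually pooled into
    downstream distributions — so both are surfaced here (``n_retained`` and
    the caller's own accounting) rather than guessed at.
    """

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_retained": self.n_retained,
        }


def detection_pvalues(raw: IntensityDataset, manifest: pd.DataFrame) -> pd.DataFrame:
    """Empirical detection p-values from negative-control fluorescence.

    Requires >= 20 negative-control probes in the manifest; otherwise the
    supplied ``detect_p`` column of the dataset should be used instead.
    """
    neg_ids = manifest.index[manifest["is_negative_control"]]
    neg_ids = [p for p in neg_ids if p in set(raw.probes)]
    if len(neg_ids) < 20:
        raise MethArrayError(
            f"only {len(neg_ids)} negative-control probes present (need >= 20); "
            "use the detect_p values supplied with the data instead"
        )
    totals = raw.total()
    out = np.empty(totals.shape)
    for j, s in enumerate(raw.samples):
        neg = np.sort(totals.loc[neg_ids, s].dropna().to_numpy())
        t = totals[s].to_numpy()
        frac_leq = np.searchsorted(neg, t, side="right") / len(neg)
        out[:, j] = 1.0 - frac_leq
    out[np.isnan(totals.to_numpy())] = np.nan
    return pd.DataFrame(out, index=totals.index, columns=totals.columns)


def filter_probes(
    raw: IntensityDataset,
    manifest: pd.DataFrame,
    params: FilterParams | None = None,
    detect_p: pd.DataFrame | None = None,
) -> tuple[IntensityDataset, FilterReport]:
    """Apply the probe filters sequentially and account for each.

    Order: non-CpG probes (includes negative controls), probes failing the
    fluorescence detection limit (detectable at p <= detect_p_max in at
    least detect_sample_frac of samples; missing cells are excluded from a
    probe's denominator), multi-target probes, SNP-adjacent probes. The
    retained set equals the intersection of all pass sets.
    """
    params = params or FilterParams()
    mf = manifest.loc[raw.probes]
    keep = pd.Series(True, index=raw.meth.index)
    report = FilterReport(n_input=len(keep))

    if params.drop_non_cpg:
        fail = ~mf["is_cpg_target"].astype(bool)
        report.removed["non_cpg"] = int((keep & fail).sum())
        keep &= ~fail

    dp = detect_p if detect_p is not None else raw.detect_p
    valid = ~(raw.meth.isna() | raw.unmeth.isna())
    passing = (dp <= params.detect_p_max) & valid
    n_valid = valid.sum(axis=1)
    frac = passing.sum(axis=1) / n_valid.replace(0, np.nan)
    fail = ~(frac >= params.detect_sample_frac)  # NaN fraction -> fail
    report.removed["detection"] = int((keep & fail).sum())
    keep &= ~fail

    if params.drop_multi_target:
        fail = mf["multi_target"].astype(bool)
        report.removed["multi_target"] = int((keep & fail).sum())
        keep &= ~fail

    if params.drop_snp_probes:
        fail = mf["snp_within_10bp_maf05"].astype(bool)
        report.removed["snp_within_10bp"] = int((keep & fail).sum())
        keep &= ~fail

    if not keep.any():
        raise MethArrayError("probe filtering removed every probe")
    return raw.subset(probes=list(keep.index[keep])), report


def _reference_quantiles(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Across-sample mean quantile function on the midpoint grid."""
    n = x.shape[0]
    grid = (np.arange(n) + 0.5) / n
    qcols = []
    for j in range(x.shape[1]):
        col = x[:, j]
        col = col[~np.isnan(col)]
        qcols.append(np.interp(grid, (np.arange(len(col)) + 0.5) / len(col), np.sort(col)))
    return grid, np.mean(qcols, axis=0)


def _qn_matrix(x: np.ndarray) -> np.ndarray:
    grid, ref = _reference_quantiles(x)
    out = np.full_like(x, np.nan, dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        ok = ~np.isnan(col)
        ranks = rankdata(col[ok], method="average")
        q = (ranks - 0.5) / ok.sum()
        out[ok, j] = np.interp(q, grid, ref)
    return out


def quantile_normalize(raw: IntensityDataset) -> IntensityDataset:
    """Map every sample's intensity distribution, per channel, onto the
    across-sample mean quantile function.

    Ranks within a sample are preserved; ties share the mean of their target
    quantiles (average ranks). With a single sample this is the identity (a
    warning is emitted).
    """
    if len(raw.samples) < 2:
        warnings.warn("quantile normalization with a single sample is the identity", stacklevel=2)
        return raw
    return IntensityDataset(
        meth=pd.DataFrame(_qn_matrix(raw.meth.to_numpy(float)), index=raw.meth.index, columns=raw.meth.columns),
        unmeth=pd.DataFrame(_qn_matrix(raw.unmeth.to_numpy(float)), index=raw.meth.index, columns=raw.meth.columns),
        detect_p=raw.detect_p.copy(),
        group=dict(raw.group),
    )


def beta_from_channels(meth, unmeth) -> np.ndarray:
    """beta = meth / (meth + unmeth); undefined (NaN) when both are zero."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    total = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, meth / total, np.nan)
    beta[np.isnan(meth) | np.isnan(unmeth)] = np.nan
    return beta


def m_from_beta(beta, eps: float = BETA_EPS) -> np.ndarray:
    """M = log2(beta/(1-beta)) with beta clamped to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    with np.errstate(invalid="ignore"):
        return np.log2(b / (1 - b))


def compute_beta_m(ds: IntensityDataset, eps: float = BETA_EPS) -> MethylationDataset:
    """Beta and M matrices from channel intensities.

    Cells where both channels are zero (or either is missing) propagate as
    missing values.
    """
    beta = beta_from_channels(ds.meth.to_numpy(float), ds.unmeth.to_numpy(float))
    beta_df = pd.DataFrame(beta, index=ds.meth.index, columns=ds.meth.columns)
    m_df = pd.DataFrame(m_from_beta(beta, eps), index=ds.meth.index, columns=ds.meth.columns)
    return MethylationDataset(
        beta=beta_df, m=m_df, group=dict(ds.group),
        metadata={"beta_eps": eps, "stages": ["beta"]},
    )


def correct_type_bias(
    meth: MethylationDataset,
    manifest: pd.DataFrame,
    min_probes_per_type: int = 50,
    eps: float = BETA_EPS,
) -> MethylationDataset:
    """Quantile-map type II beta values onto the type I distribution.

    Per sample: each type II beta at empirical quantile q is replaced by the
    type I beta distribution's quantile at q (piecewise-linear, midpoint
    convention, so identical distributions map to themselves exactly). Type
    I values are unchanged; order within type II is preserved; M is
    recomputed from the corrected beta. Samples with fewer than
    ``min_probes_per_type`` probes of either design are skipped with a
    warning. The mode is recorded in metadata as "quantile-map".
    """
    design = manifest.loc[meth.probes, "design_type"]
    is_ii = (design == "II").to_numpy()
    is_i = (design == "I").to_numpy()
    if is_ii.sum() == 0 or is_i.sum() == 0:
        raise MethArrayError("both probe design types must be present for bias correction")
    beta = meth.beta.to_numpy(float).copy()
    for j, s in enumerate(meth.samples):
        col = beta[:, j]
        ref = col[is_i]
        ref = np.sort(ref[~np.isnan(ref)])
        tgt_idx = np.flatnonzero(is_ii & ~np.isnan(col))
        if len(ref) < min_probes_per_type or len(tgt_idx) < min_probes_per_type:
            warnings.warn(
                f"sample {s}: < {min_probes_per_type} probes of one design type; "
                "type-bias correction skipped", stacklevel=2,
            )
            continue
        ranks = rankdata(col[tgt_idx], method="average")
        q = (ranks - 0.5) / len(tgt_idx)
        grid = (np.arange(len(ref)) + 0.5) / len(ref)
        beta[tgt_idx, j] = np.interp(q, grid, ref)
    beta_df = pd.DataFrame(beta, index=meth.beta.index, columns=meth.beta.columns)
    m_df = pd.DataFrame(m_from_beta(beta, eps), index=meth.beta.index, columns=meth.beta.columns)
    meta = dict(meth.metadata)
    meta["type_bias_mode"] = "quantile-map"
    meta["stages"] = list(meta.get("stages", [])) + ["type_bias"]
    return MethylationDataset(beta=beta_df, m=m_df, group=dict(meth.group), metadata=meta)


def preprocess_pipeline(
    raw: IntensityDataset,
    manifest: pd.DataFrame,
    params: FilterParams | None = None,
    type_bias: str = "quantile-map",
    detect_p: pd.DataFrame | None = None,
) -> tuple[MethylationDataset, FilterReport]:
    """Full preprocessing chain: filter -> QN -> beta -> type-bias -> M."""
    filtered, report = filter_probes(raw, manifest, params=params, detect_p=detect_p)
    normalized = quantile_normalize(filtered)
    meth = compute_beta_m(normalized)
    if type_bias == "quantile-map":
        meth = correct_type_bias(meth, manifest)
    elif type_bias != "none":
        raise ConfigError(f"unknown type-bias mode {type_bias!r}")
    meth.metadata["pipeline"] = ["filter", "quantile_normalize", "beta", f"type_bias:{type_bias}", "m"]
    meth.metadata["filter_report"] = report.to_dict()
    return meth, report
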