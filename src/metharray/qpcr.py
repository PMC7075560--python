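"""Window-of-linearity qPCR quantification.

Per reaction, the amplification efficiency (fold increase per cycle) is
fitted as 2**slope of a linear regression of log2 fluorescence on cycle
number inside the best contiguous window of the exponential phase; the
starting quantity N0 follows by inverting the geometric growth law at a
fluorescence threshold: with Cq the fractional cycle at which fluorescence
crosses the threshold F,

    N0 = F / efficiency**Cq.

Inside the exponential window the estimate is invariant to the threshold
choice, which is the internal consistency check the method rests on.
Target expression is normalized to the geometric mean of two reference
genes (an arithmetic-mean mode is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from metharray.errors import ConfigError, FormatError


@dataclass
class AmplificationCurve:
    """Per-cycle fluorescence of one qPCR reaction."""

    reaction_id: str
    target: str
    sample: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape:
            raise FormatError("cycles and fluorescence must have equal length")
        if len(self.cycles) < 10:
            raise FormatError("an amplification curve needs >= 10 cycles")
        if not np.isfinite(self.fluorescence).all() or (self.fluorescence < 0).any():
            raise FormatError("fluorescence must be finite and non-negative")


@dataclass
class QpcrResult:
    """Efficiency, window fit and N0 for one reaction (or replicate mean)."""

    reaction_id: str
    target: str
    sample: str
    efficiency: float
    window: tuple[int, int]
    r2: float
    n0: float
    flags: tuple[str, ...] = ()
    normalized_expression: float = float("nan")


def _noise_floor(curve: AmplificationCurve, n_baseline: int = 5) -> float:
    """Baseline fluorescence estimate: mean + 3*sd of the first cycles."""
    base = curve.fluorescence[:n_baseline]
    return float(base.mean() + 3 * base.std(ddof=0))


def fit_efficiency(
    curve: AmplificationCurve,
    window_len: tuple[int, int] = (4, 6),
    min_r2: float = 0.99,
) -> tuple[float, tuple[int, int], float, tuple[str, ...]]:
    """Fit amplification efficiency from the best log-linear window.

    Candidate windows are contiguous runs of ``window_len[0]..window_len[1]``
    cycles with positive fluorescence, restricted to cycles above the
    baseline noise floor when enough such cycles exist; the window maximizing
    r^2 of log2(fluorescence) vs cycle wins (longer windows break ties).
    Returns (efficiency, (first_cycle, last_cycle), r2, flags); a best r^2
    below ``min_r2`` flags the fit as low-quality rather than failing.
    """
    lo, hi = window_len
    if lo < 2:
        raise ConfigError("window length must be >= 2 cycles")
    f = curve.fluorescence
    eligible = f > 0
    # drop the saturated plateau, then the baseline below the noise floor;
    # each restriction applies only while >= lo candidate cycles remain
    off_plateau = eligible & (f < 0.9 * f.max())
    if off_plateau.sum() >= lo:
        eligible = off_plateau
    above = eligible & (f > _noise_floor(curve))
    if above.sum() >= lo:
        eligible = above
    idx = np.flatnonzero(eligible)
    best = (-np.inf, 0, None, 1.0)  # (r2, length, window slice, efficiency)
    for L in range(lo, hi + 1):
        for s in range(len(idx) - L + 1):
            w = idx[s : s + L]
            if not np.all(np.diff(w) == 1):
                continue
            y = np.log2(f[w])
            x = curve.cycles[w].astype(float)
            if np.allclose(y, y[0]):
                continue
            res = stats.linregress(x, y)
            r2 = float(res.rvalue**2)
            if (r2, L) > (best[0], best[1]):
                best = (r2, L, w, float(2.0**res.slope))
    flags: list[str] = []
    if best[2] is None:
        # flat or degenerate curve: nothing to fit
        return 1.0, (int(curve.cycles[0]), int(curve.cycles[min(lo - 1, len(f) - 1)])), 0.0, ("low_quality",)
    r2, _, w, eff = best
    if r2 < min_r2:
        flags.append("low_quality")
        warnings.warn(
            f"{curve.reaction_id}: no window with r2 >= {min_r2} (best {r2:.4f})",
            stacklevel=2,
        )
    if not 1.0 < eff <= 2.1:
        flags.append("efficiency_out_of_range")
    return eff, (int(curve.cycles[w[0]]), int(curve.cycles[w[-1]])), r2, tuple(flags)


def estimate_n0(
    curve: AmplificationCurve,
    efficiency: float,
    f_threshold: float,
) -> tuple[float, tuple[str, ...]]:
    """Invert geometric growth at a fluorescence threshold to estimate N0.

    Cq is the fractional cycle where fluorescence first crosses
    ``f_threshold`` (log-linear interpolation between the bracketing
    cycles); N0 = f_threshold / efficiency**Cq. A curve that never reaches
    the threshold yields (0.0, ("undetected",)).
    """
    if efficiency <= 1.0:
        raise ConfigError("efficiency must exceed 1 to invert growth")
    f = curve.fluorescence
    crossing = np.flatnonzero(f >= f_threshold)
    if crossing.size == 0:
        return 0.0, ("undetected",)
    i = int(crossing[0])
    if i == 0:
        cq = float(curve.cycles[0])
    else:
        f0, f1 = f[i - 1], f[i]
        c0, c1 = float(curve.cycles[i - 1]), float(curve.cycles[i])
        if f0 <= 0:
            cq = c1
        else:
            cq = c0 + (c1 - c0) * (np.log2(f_threshold) - np.log2(f0)) / (np.log2(f1) - np.log2(f0))
    return float(f_threshold / efficiency**cq), ()


def quantify(
    curve: AmplificationCurve,
    window_len: tuple[int, int] = (4, 6),
    f_threshold: float | None = None,
) -> QpcrResult:
    """Fit efficiency and N0 for one reaction.

    The default threshold is the geometric midpoint of the fitted window's
    fluorescence range, which keeps it inside the exponential phase.
    """
    eff, window, r2, flags = fit_efficiency(curve, window_len=window_len)
    if "low_quality" in flags and r2 == 0.0:
        return QpcrResult(curve.reaction_id, curve.target, curve.sample, eff, window, r2, 0.0, flags)
    if f_threshold is None:
        in_w = (curve.cycles >= window[0]) & (curve.cycles <= window[1])
        fw = curve.fluorescence[in_w]
        f_threshold = float(np.sqrt(fw.min() * fw.max()))
    n0, n0_flags = estimate_n0(curve, eff, f_threshold)
    return QpcrResult(
        curve.reaction_id, curve.target, curve.sample, eff, window, r2, n0,
        flags + n0_flags,
    )


def mean_n0(curves: Sequence[AmplificationCurve], **kwargs) -> float:
    """Replicate-aggregated N0 (mean of per-replicate estimates)."""
    if not curves:
        raise ConfigError("no curves supplied")
    return float(np.mean([quantify(c, **kwargs).n0 for c in curves]))


def normalize_expression(
    n0_target: float,
    n0_refs: Sequence[float],
    mode: str = "geometric",
) -> tuple[float, tuple[str, ...]]:
    """Normalize a target N0 to reference-gene N0 values.

    Default combines the references by geometric mean (standard
    multi-reference normalization); ``mode="arithmetic"`` averages instead.
    An undetected reference (N0 <= 0) makes the ratio undefined.
    """
    refs = np.asarray(n0_refs, dtype=float)
    if refs.size == 0:
        raise ConfigError("at least one reference N0 required")
    if (refs <= 0).any():
        return float("nan"), ("reference_undetected",)
    if mode == "geometric":
        denom = float(np.exp(np.mean(np.log(refs))))
    elif mode == "arithmetic":
        denom = float(refs.mean())
    else:
        raise ConfigError(f"unknown normalization mode {mode!r}")
    return float(n0_target / denom), ()
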