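"""Fixed sliding-window aggregation of SNP-index statistics and QTL calling.

The coarse genome scan slides a 2 Mb window in 100 kb steps (the fine scan
in `refine` reuses this machinery at smaller sizes), averaging the
delta-SNP index over member SNPs. A window is QTL-significant when (a) its
mean delta is extreme relative to a matched null of window means, resampled
from the depth-indexed per-SNP null, and (b) its |mean delta| clears the
average per-SNP null quantile band — the confidence band drawn in QTL-seq
plots. Significant windows of consistent sign are merged into intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snpindex import NullDistribution, effective_depth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Window size and step in bp; windows start at position 1."""

    size: int = 2_000_000
    step: int = 100_000

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.size):
            raise ValueError("require 1 <= step <= size (gaps would drop SNPs)")


@dataclass(frozen=True)
class QtlInterval:
    """A called or refined candidate region (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    level: float  # significance level the call was made at
    peak_start: int  # start of the window with maximal |mean delta|
    peak_end: int
    peak_delta: float
    allele_effect: str  # "HP3" if donor allele raises the trait, else "M23"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start > end")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def size_mb(self) -> float:
        return self.size_bp / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:
        return (f"{self.chrom}:{self.start}-{self.end} "
                f"({self.size_mb:.2f} Mb, p<{self.level:g}, {self.allele_effect})")


def make_windows(chrom_lengths: list[tuple[str, int]],
                 spec: WindowSpec) -> pd.DataFrame:
    """Window grid over each chromosome.

    Windows are [1 + k*step, 1 + k*step + size - 1] for k = 0, 1, ... while
    the start lies on the chromosome; the last windows are clipped to the
    chromosome end.
    """
    rows = []
    for chrom, length in chrom_lengths:
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom!r}")
        starts = np.arange(1, length + 1, spec.step, dtype=np.int64)
        ends = np.minimum(starts + spec.size - 1, length)
        rows.append(pd.DataFrame({"CHROM": chrom, "START": starts, "END": ends}))
    return pd.concat(rows, ignore_index=True)


def _require_sorted(records: pd.DataFrame) -> None:
    for _, grp in records.groupby("CHROM", sort=False):
        pos = grp["POS"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("records must be sorted by position within chromosome")


def aggregate(records: pd.DataFrame, windows: pd.DataFrame,
              sig_level: float = 0.05, null: NullDistribution | None = None,
              window_reps: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-window SNP counts, mean indices, and empirical significance.

    A SNP contributes to every window whose span covers its position.
    When a :class:`NullDistribution` is supplied, three extra columns are
    computed per window:

    ``WINDOW_P``
        fraction of resampled null window means (same member count, member
        depths) at least as extreme as the observed mean (+1 pseudo-count);
    ``BAND95`` / ``BAND99``
        mean over member SNPs of the per-SNP null 95%/99% |delta| quantile —
        the sliding average of the QTL-seq confidence band.
    """
    _require_sorted(records)
    has_p = "PVAL" in records.columns
    rng = np.random.default_rng(seed)
    out = []
    for chrom, win in windows.groupby("CHROM", sort=False):
        grp = records[records["CHROM"] == chrom]
        pos = grp["POS"].to_numpy()
        delta = grp["DELTA"].to_numpy(dtype=float)
        i1 = np.searchsorted(pos, win["START"].to_numpy(), side="left")
        i2 = np.searchsorted(pos, win["END"].to_numpy(), side="right")
        n = (i2 - i1).astype(np.int64)
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        with np.errstate(invalid="ignore"):
            mean_delta = np.where(n > 0, (csum[i2] - csum[i1]) / np.maximum(n, 1),
                                  np.nan)
        res = win.copy()
        res["N_SNPS"] = n
        res["MEAN_DELTA"] = mean_delta
        for col, name in (("SNP_INDEX1", "MEAN_INDEX1"),
                          ("SNP_INDEX2", "MEAN_INDEX2")):
            if col in grp.columns:
                c = np.concatenate([[0.0], np.cumsum(grp[col].to_numpy(float))])
                res[name] = np.where(n > 0, (c[i2] - c[i1]) / np.maximum(n, 1),
                                     np.nan)
        if has_p:
            sig = (grp["PVAL"].to_numpy() < sig_level).astype(float)
            c = np.concatenate([[0.0], np.cumsum(sig)])
            res["N_SIG"] = (c[i2] - c[i1]).astype(np.int64)
        if null is not None and len(grp):
            res = _window_significance(res, grp, i1, i2, null, window_reps, rng)
        out.append(res)
    result = pd.concat(out, ignore_index=True)
    result.attrs["sig_level"] = sig_level
    return result


def _window_significance(res: pd.DataFrame, grp: pd.DataFrame,
                         i1: np.ndarray, i2: np.ndarray,
                         null: NullDistribution, window_reps: int,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Null window means by resampling per-SNP null deltas at member depths.

    One replicate matrix per chromosome is drawn and window means are read
    off its cumulative sums; marginal per-window p-values are exact while
    overlapping windows share draws (their p-values are correlated, as the
    observed means themselves are).
    """
    depth = effective_depth(grp)
    gi = np.abs(depth[:, None] - null.depths[None, :]).argmin(axis=1)
    m = len(depth)
    n = (i2 - i1).astype(np.int64)
    obs = res["MEAN_DELTA"].to_numpy()
    exceed = np.zeros(len(res), dtype=np.int64)
    # per-SNP 95%/99% band heights, averaged per window
    q95 = np.array([null.quantile(d, 0.95) for d in np.unique(depth)])
    q99 = np.array([null.quantile(d, 0.99) for d in np.unique(depth)])
    uniq, inv = np.unique(depth, return_inverse=True)
    for name, qs in (("BAND95", q95), ("BAND99", q99)):
        c = np.concatenate([[0.0], np.cumsum(qs[inv])])
        res[name] = np.where(n > 0, (c[i2] - c[i1]) / np.maximum(n, 1), np.nan)
    chunk = max(1, min(window_reps, int(5e7 // max(m, 1))))
    done = 0
    while done < window_reps:
        b = min(chunk, window_reps - done)
        idx = rng.integers(0, null.n_reps, size=(b, m))
        draws = null.deltas[gi[None, :], idx]
        c = np.concatenate([np.zeros((b, 1)), np.cumsum(draws, axis=1)], axis=1)
        means = (c[:, i2] - c[:, i1]) / np.maximum(n, 1)[None, :]
        with np.errstate(invalid="ignore"):
            exceed += np.nansum(np.abs(means) >= np.abs(obs)[None, :],
                                axis=0).astype(np.int64)
        done += b
    window_p = (1.0 + exceed) / (window_reps + 1.0)
    window_p[n == 0] = np.nan
    res["WINDOW_P"] = window_p
    return res


def call_intervals(window_stats: pd.DataFrame, alpha: float = 0.05,
                   require_band: bool = True) -> list[QtlInterval]:
    """Merge significant windows of consistent sign into QTL intervals.

    A window is significant when ``WINDOW_P < alpha`` and (by default) its
    |mean delta| also clears the matching per-SNP confidence band
    (``BAND95`` for alpha=0.05, ``BAND99`` for alpha=0.01) — the criterion
    of being above the surrounding-region null band. Windows are merged when
    adjacent on the step grid; a single sub-threshold step splits intervals.
    """
    if "WINDOW_P" not in window_stats.columns:
        raise ValueError("window_stats lacks WINDOW_P; aggregate with a null")
    band_col = "BAND99" if alpha <= 0.01 else "BAND95"
    intervals: list[QtlInterval] = []
    for chrom, win in window_stats.groupby("CHROM", sort=False):
        win = win[win["N_SNPS"] > 0]
        sig = win["WINDOW_P"].to_numpy() < alpha
        if require_band:
            if band_col not in win.columns:
                raise ValueError(f"window_stats lacks {band_col}")
            sig &= np.abs(win["MEAN_DELTA"].to_numpy()) >= win[band_col].to_numpy()
        if not sig.any():
            continue
        starts = win["START"].to_numpy()
        step = int(np.min(np.diff(np.unique(starts)))) if len(starts) > 1 else 1
        sign = np.sign(win["MEAN_DELTA"].to_numpy())
        sidx = np.flatnonzero(sig)
        run = [sidx[0]]
        for j in sidx[1:]:
            prev = run[-1]
            adjacent = starts[j] - starts[prev] <= step
            if adjacent and sign[j] == sign[prev]:
                run.append(j)
            else:
                intervals.append(_run_to_interval(win, run, alpha))
                run = [j]
        intervals.append(_run_to_interval(win, run, alpha))
    return intervals


def _run_to_interval(win: pd.DataFrame, run: list[int],
                     alpha: float) -> QtlInterval:
    sub = win.iloc[run]
    peak = sub.iloc[int(np.argmax(np.abs(sub["MEAN_DELTA"].to_numpy())))]
    direction = "HP3" if peak["MEAN_DELTA"] > 0 else "M23"
    return QtlInterval(
        chrom=str(sub.iloc[0]["CHROM"]),
        start=int(sub["START"].min()),
        end=int(sub["END"].max()),
        level=alpha,
        peak_start=int(peak["START"]),
        peak_end=int(peak["END"]),
        peak_delta=float(peak["MEAN_DELTA"]),
        allele_effect=direction,
    )
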