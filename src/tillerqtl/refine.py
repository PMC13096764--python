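"""Progressive window-refinement of a detected QTL region.

Within a coarse-scan interval, SNPs are first restricted to those with
individually significant delta-SNP indices (p < 0.01 by default), then a
ladder of sliding-window passes with strictly decreasing window sizes —
2 Mb/100 kb down to a final 10 kb/5 kb — is run over the region, each pass
anchored at the region start. Windows containing at least one significant
SNP are retained, and the final pass's retained windows are reduced to a
candidate interval as the longest run of "strong" windows (mean delta in
the top tail of retained windows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import QtlInterval, WindowSpec

logger = logging.getLogger(__name__)

#: (window, step) ladder in bp; first rung matches the coarse scan, the
#: final rung is the 10 kb / 5 kb high-resolution pass
DEFAULT_LADDER: tuple[tuple[int, int], ...] = (
    (2_000_000, 100_000),
    (500_000, 25_000),
    (100_000, 10_000),
    (50_000, 5_000),
    (10_000, 5_000),
)


@dataclass(frozen=True)
class RefineLadder:
    rungs: tuple[tuple[int, int], ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        sizes = [w for w, _ in self.rungs]
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("ladder window sizes must be strictly decreasing")
        for w, s in self.rungs:
            if not (1 <= s <= w):
                raise ValueError(f"invalid rung ({w}, {s})")

    @property
    def final(self) -> WindowSpec:
        return WindowSpec(*self.rungs[-1])


@dataclass(frozen=True)
class CandidateCriteria:
    """How "consistently strong" is formalised: a window is strong when its
    mean delta reaches the ``tau``-quantile of retained-window means within
    the region, and strong windows may be chained across gaps of at most
    ``gap_steps`` grid steps."""

    tau: float = 0.95
    gap_steps: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must be in (0, 1)")
        if self.gap_steps < 0:
            raise ValueError("gap_steps must be >= 0")


@dataclass
class RefinementTrace:
    """Per-rung retained windows and candidate, plus the final candidate."""

    region: QtlInterval
    rungs: list[tuple[WindowSpec, pd.DataFrame]] = field(default_factory=list)
    candidates: list[QtlInterval | None] = field(default_factory=list)

    @property
    def candidate(self) -> QtlInterval | None:
        return self.candidates[-1] if self.candidates else None


def select_significant(records: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """SNPs with individually significant delta (p < alpha), order kept."""
    if "PVAL" not in records.columns:
        raise ValueError("records lack PVAL; assign p-values first")
    out = records[records["PVAL"] < alpha].reset_index(drop=True)
    if out.empty:
        logger.warning("no SNPs significant at p<%g", alpha)
    return out


def _region_windows(region: QtlInterval, spec: WindowSpec) -> pd.DataFrame:
    """Windows anchored at the region start and clipped to its end."""
    starts = np.arange(region.start, region.end + 1, spec.step, dtype=np.int64)
    ends = np.minimum(starts + spec.size - 1, region.end)
    return pd.DataFrame({"CHROM": region.chrom, "START": starts, "END": ends})


def _aggregate_region(records: pd.DataFrame, win: pd.DataFrame,
                      alpha: float) -> pd.DataFrame:
    pos = records["POS"].to_numpy()
    delta = records["DELTA"].to_numpy(dtype=float)
    sig = (records["PVAL"].to_numpy() < alpha).astype(float)
    i1 = np.searchsorted(pos, win["START"].to_numpy(), side="left")
    i2 = np.searchsorted(pos, win["END"].to_numpy(), side="right")
    n = (i2 - i1).astype(np.int64)
    cd = np.concatenate([[0.0], np.cumsum(delta)])
    cs = np.concatenate([[0.0], np.cumsum(sig)])
    out = win.copy()
    out["N_SNPS"] = n
    out["MEAN_DELTA"] = np.where(n > 0, (cd[i2] - cd[i1]) / np.maximum(n, 1),
                                 np.nan)
    out["N_SIG"] = (cs[i2] - cs[i1]).astype(np.int64)
    return out


def refine(records: pd.DataFrame, region: QtlInterval,
           ladder: RefineLadder = RefineLadder(),
           criteria: CandidateCriteria = CandidateCriteria(),
           alpha: float = 0.01) -> RefinementTrace:
    """Run the window ladder over a region and extract a candidate per rung.

    ``records`` should already be restricted to significant SNPs
    (:func:`select_significant`); the retention rule keeps windows with at
    least one significant member SNP. Rungs wider than the region are
    skipped with a warning.
    """
    sub = records[(records["CHROM"] == region.chrom)
                  & (records["POS"] >= region.start)
                  & (records["POS"] <= region.end)].reset_index(drop=True)
    trace = RefinementTrace(region=region)
    region_len = region.end - region.start + 1
    for w, s in ladder.rungs:
        spec = WindowSpec(w, s)
        if w > region_len:
            logger.warning("rung %d/%d wider than region (%d bp); skipped",
                           w, s, region_len)
            continue
        stats = _aggregate_region(sub, _region_windows(region, spec), alpha)
        retained = stats[stats["N_SIG"] >= 1].reset_index(drop=True)
        trace.rungs.append((spec, retained))
        if retained.empty:
            trace.candidates.append(None)
        else:
            trace.candidates.append(
                extract_candidate(retained, criteria, step=s, level=alpha))
    return trace


def extract_candidate(retained: pd.DataFrame,
                      criteria: CandidateCriteria = CandidateCriteria(),
                      step: int | None = None,
                      level: float = 0.01) -> QtlInterval:
    """Longest run of strong windows among the retained set.

    Strong = mean delta >= the ``tau``-quantile of retained-window means
    (signed: the rule targets donor-positive signals; for a negative QTL
    pass the mirrored records). Runs may bridge gaps of up to ``gap_steps``
    missing grid positions; ties go to the run with the higher mean of
    window means, then to the leftmost.
    """
    if retained.empty:
        raise ValueError("no retained windows to extract a candidate from")
    md = retained["MEAN_DELTA"].to_numpy(dtype=float)
    starts = retained["START"].to_numpy(dtype=np.int64)
    if step is None:
        step = int(np.min(np.diff(np.unique(starts)))) if len(starts) > 1 else 1
    thr = np.quantile(md, criteria.tau)
    strong = np.flatnonzero(md >= thr)
    # chain strong windows whose grid distance allows <= gap_steps missing slots
    runs: list[list[int]] = [[int(strong[0])]]
    for j in strong[1:]:
        gap = (starts[j] - starts[runs[-1][-1]]) // step - 1
        if gap <= criteria.gap_steps:
            runs[-1].append(int(j))
        else:
            runs.append([int(j)])

    def run_key(r: list[int]) -> tuple:
        span = starts[r[-1]] - starts[r[0]]
        return (span, float(np.mean(md[r])), -starts[r[0]])

    best = max(runs, key=run_key)
    sub = retained.iloc[best]
    peak = sub.iloc[int(np.argmax(sub["MEAN_DELTA"].to_numpy()))]
    return QtlInterval(
        chrom=str(retained.iloc[0]["CHROM"]),
        start=int(sub["START"].iloc[0]),
        end=int(sub["END"].iloc[-1]),
        level=level,
        peak_start=int(peak["START"]),
        peak_end=int(peak["END"]),
        peak_delta=float(peak["MEAN_DELTA"]),
        allele_effect="HP3" if peak["MEAN_DELTA"] > 0 else "M23",
    )
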