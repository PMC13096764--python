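"""Per-bulk SNP indices, delta-SNP index, and simulation-based significance.

The SNP index of a bulk at a site is the fraction of its reads carrying the
donor (Hapcheonaengmi3) allele; the delta-SNP index is high bulk minus low
bulk. Significance is empirical: the null distribution of delta is built by
re-simulating the whole sampling chain — bulk members' genotypes at a
neutral locus under the population model, the bulk allele frequency, and
binomial read counts at a given depth — and p-values are two-sided tail
fractions of |delta| with a +1 pseudo-count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import parse_pop_type

logger = logging.getLogger(__name__)

COUNT_COLS = ["HIGH_REF", "HIGH_ALT", "LOW_REF", "LOW_ALT"]

#: depth grid the null is tabulated on; per-record depths are interpolated
DEFAULT_DEPTH_GRID = tuple(range(5, 101, 5))


@dataclass(frozen=True)
class SnpFilters:
    """Row filters applied before index computation."""

    min_depth: int = 10
    max_depth: int | None = None
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def genotype_class_probs(pop_model: str) -> np.ndarray:
    """P(donor dosage = 0, 1, 2) at a neutral locus under the population model.

    F2 segregates 1:2:1; RIL(g) retains residual heterozygosity 2^-(g-1)
    with the remainder split equally between the homozygote classes; BC1F(g)
    starts from 1:1 recurrent-homozygote:heterozygote and halves the
    heterozygosity with each selfing generation.
    """
    kind, gen = parse_pop_type(pop_model)
    if kind == "F2":
        return np.array([0.25, 0.5, 0.25])
    if kind == "RIL":
        h = 2.0 ** -(gen - 1)
        return np.array([(1 - h) / 2, h, (1 - h) / 2])
    # BC1F(g): no donor homozygotes arise from the backcross itself; selfing
    # converts half the lost heterozygosity into each homozygote class
    h = 0.5 * 2.0 ** -(gen - 1)
    lost = 0.5 - h
    return np.array([0.5 + lost / 2, h, lost / 2])


@dataclass
class NullDistribution:
    """Depth-indexed empirical null of the delta-SNP index.

    ``deltas`` holds, for each tabulated depth, ``n_reps`` signed null draws
    of delta; ``abs_sorted`` the same draws as sorted absolute values for
    fast tail counting.
    """

    pop_model: str
    n_high: int
    n_low: int
    depths: np.ndarray
    deltas: np.ndarray  # (n_depths, n_reps) signed
    n_reps: int
    seed: int
    abs_sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.abs_sorted = np.sort(np.abs(self.deltas), axis=1)

    def _depth_index(self, depth: float) -> int:
        return int(np.argmin(np.abs(self.depths - depth)))

    def quantile(self, depth: float, q: float) -> float:
        """q-quantile of |delta| at the given depth (nearest-depth, linear
        interpolation between the two bracketing grid depths)."""
        lo, hi, w = self._bracket(depth)
        qlo = float(np.quantile(self.abs_sorted[lo], q))
        qhi = float(np.quantile(self.abs_sorted[hi], q))
        return (1 - w) * qlo + w * qhi

    def _bracket(self, depth: float) -> tuple[int, int, float]:
        d = self.depths
        if depth <= d[0]:
            if depth < d[0]:
                logger.warning("depth %.0f below simulated grid; using depth %d",
                               depth, d[0])
            return 0, 0, 0.0
        if depth >= d[-1]:
            return len(d) - 1, len(d) - 1, 0.0
        hi = int(np.searchsorted(d, depth))
        lo = hi - 1
        w = (depth - d[lo]) / (d[hi] - d[lo])
        return lo, hi, float(w)

    def p_value(self, delta: np.ndarray, depth: np.ndarray) -> np.ndarray:
        """Two-sided empirical p with +1 pseudo-count, interpolated in depth."""
        delta = np.atleast_1d(np.abs(np.asarray(delta, dtype=float)))
        depth = np.atleast_1d(np.asarray(depth, dtype=float))
        p = np.empty_like(delta)
        for i, (dl, dp) in enumerate(zip(delta, depth)):
            lo, hi, w = self._bracket(dp)
            ps = []
            for j in (lo, hi):
                n_ge = self.n_reps - np.searchsorted(self.abs_sorted[j], dl,
                                                     side="left")
                ps.append((1.0 + n_ge) / (self.n_reps + 1.0))
            p[i] = (1 - w) * ps[0] + w * ps[1]
        return p


def simulate_null(pop_model: str, n_high: int, n_low: int,
                  depths=DEFAULT_DEPTH_GRID, n_reps: int = 10_000,
                  seed: int = 0) -> NullDistribution:
    """Monte-Carlo null of delta at a neutral locus, per depth.

    Each replicate draws the two bulks' member genotypes independently from
    the population model's dosage distribution, forms each bulk's donor
    frequency, then draws donor read counts Binomial(depth, frequency) for
    both bulks at the same depth.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000 for stable tail quantiles")
    depths = np.asarray(sorted(depths), dtype=np.int64)
    if depths[0] < 1:
        raise ValueError("depths must be >= 1")
    probs = genotype_class_probs(pop_model)
    rng = np.random.default_rng(seed)
    # bulk donor frequencies are redrawn per depth so the per-depth samples
    # are mutually independent
    deltas = np.empty((len(depths), n_reps))
    for k, depth in enumerate(depths):
        fh = _bulk_freqs(probs, n_high, n_reps, rng)
        fl = _bulk_freqs(probs, n_low, n_reps, rng)
        dh = rng.binomial(depth, fh) / depth
        dl = rng.binomial(depth, fl) / depth
        deltas[k] = dh - dl
    return NullDistribution(pop_model=pop_model, n_high=n_high, n_low=n_low,
                            depths=depths, deltas=deltas, n_reps=n_reps,
                            seed=seed)


def _bulk_freqs(probs: np.ndarray, n_members: int, n_reps: int,
                rng: np.random.Generator) -> np.ndarray:
    counts = rng.multinomial(n_members, probs, size=n_reps)
    return (counts[:, 1] + 2 * counts[:, 2]) / (2.0 * n_members)


# ---------------------------------------------------------------------------
# observed-data path


def _validate_counts(table: pd.DataFrame) -> None:
    missing = [c for c in ["CHROM", "POS", *COUNT_COLS] if c not in table.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    counts = table[COUNT_COLS].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative read counts in SNP table")
    if table.duplicated(subset=["CHROM", "POS"]).any():
        dup = table[table.duplicated(subset=["CHROM", "POS"], keep=False)]
        raise ValueError(
            f"duplicate (CHROM, POS) rows, e.g. {dup.iloc[0]['CHROM']}:"
            f"{dup.iloc[0]['POS']}"
        )


def compute_indices(table: pd.DataFrame,
                    filters: SnpFilters = SnpFilters()) -> pd.DataFrame:
    """SNP index per bulk and delta-SNP index, after row filtering.

    Adds ``SNP_INDEX1`` (high bulk), ``SNP_INDEX2`` (low bulk) and ``DELTA``
    columns; rows failing the depth/monomorphic filters are removed before
    any index is computed. Output is sorted by (CHROM, POS).
    """
    _validate_counts(table)
    df = table.sort_values(["CHROM", "POS"], kind="stable").reset_index(drop=True)
    dh = df["HIGH_REF"] + df["HIGH_ALT"]
    dl = df["LOW_REF"] + df["LOW_ALT"]
    keep = (dh >= filters.min_depth) & (dl >= filters.min_depth)
    if filters.max_depth is not None:
        keep &= (dh <= filters.max_depth) & (dl <= filters.max_depth)
    if filters.drop_monomorphic:
        alt_total = df["HIGH_ALT"] + df["LOW_ALT"]
        ref_total = df["HIGH_REF"] + df["LOW_REF"]
        keep &= (alt_total > 0) & (ref_total > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filters removed %d of %d sites", n_dropped, len(df))
    df = df[keep].reset_index(drop=True)
    dh = df["HIGH_REF"] + df["HIGH_ALT"]
    dl = df["LOW_REF"] + df["LOW_ALT"]
    df["SNP_INDEX1"] = df["HIGH_ALT"] / dh
    df["SNP_INDEX2"] = df["LOW_ALT"] / dl
    df["DELTA"] = df["SNP_INDEX1"] - df["SNP_INDEX2"]
    return df


def effective_depth(table: pd.DataFrame) -> np.ndarray:
    """Harmonic mean of the two bulk depths — the single-depth null whose
    read-noise variance matches the observed pair of depths."""
    dh = (table["HIGH_REF"] + table["HIGH_ALT"]).to_numpy(dtype=float)
    dl = (table["LOW_REF"] + table["LOW_ALT"]).to_numpy(dtype=float)
    return 2.0 / (1.0 / dh + 1.0 / dl)


def assign_pvalues(table: pd.DataFrame, null: NullDistribution) -> pd.DataFrame:
    """Empirical two-sided p-value per SNP from the depth-matched null."""
    if "DELTA" not in table.columns:
        raise ValueError("run compute_indices before assign_pvalues")
    df = table.copy()
    df["PVAL"] = null.p_value(df["DELTA"].to_numpy(), effective_depth(df))
    return df
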