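"""Model/results façade over the pipeline.

Two fitted-model pairs, in the style of statistical modelling packages:

* :class:`QtlSeqScan` — built from a two-bulk SNP allele-depth table;
  ``fit()`` computes SNP indices, empirical p-values, the sliding-window
  genome scan, and QTL interval calls, returning :class:`QtlSeqResults`
  (which also exposes the iterative window refinement).
* :class:`IntervalMapper` — built from an F2 marker-genotype matrix and
  phenotype scores; ``fit()`` builds the Kosambi linkage map, runs the
  HK/ICIM scan and the permutation threshold, returning
  :class:`F2ScanResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import linkage as lk
from .refine import CandidateCriteria, RefineLadder, RefinementTrace, refine, \
    select_significant
from .snpindex import NullDistribution, SnpFilters, assign_pvalues, \
    compute_indices, simulate_null
from .windows import QtlInterval, WindowSpec, aggregate, call_intervals, \
    make_windows


@dataclass
class QtlSeqScan:
    """QTL-seq model: delta-SNP-index scan of a two-bulk experiment.

    Parameters
    ----------
    snp_table
        Allele-depth table (see :mod:`tillerqtl.io` for the dialect).
    pop_model
        Population code for the null ("RIL9", "F2", ...).
    n_high, n_low
        Bulk sizes (the study design is 8 high-tillering vs 12 normal
        recombinant inbred lines).
    chrom_lengths
        Optional; inferred from the last SNP per chromosome if omitted.
    """

    snp_table: pd.DataFrame
    pop_model: str = "RIL9"
    n_high: int = 8
    n_low: int = 12
    chrom_lengths: list[tuple[str, int]] | None = None
    filters: SnpFilters = field(default_factory=SnpFilters)
    window: WindowSpec = field(default_factory=WindowSpec)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "QtlSeqScan":
        return cls(snp_table=tio.read_snp_table(path), **kwargs)

    @classmethod
    def from_vcf_pair(cls, vcf_high: str | Path, vcf_low: str | Path,
                      **kwargs) -> "QtlSeqScan":
        return cls(snp_table=tio.import_vcf_pair(vcf_high, vcf_low), **kwargs)

    def _lengths(self) -> list[tuple[str, int]]:
        if self.chrom_lengths is not None:
            return self.chrom_lengths
        ends = self.snp_table.groupby("CHROM", sort=False)["POS"].max()
        return [(str(c), int(p)) for c, p in ends.items()]

    def fit(self, alpha: float = 0.05, n_reps: int = 10_000,
            window_reps: int = 1000, seed: int = 0,
            null: NullDistribution | None = None) -> "QtlSeqResults":
        """Run the full scan: indices, p-values, windows, interval calls."""
        if null is None:
            null = simulate_null(self.pop_model, self.n_high, self.n_low,
                                 n_reps=n_reps, seed=seed)
        records = assign_pvalues(compute_indices(self.snp_table, self.filters),
                                 null)
        stats = aggregate(records, make_windows(self._lengths(), self.window),
                          sig_level=alpha, null=null,
                          window_reps=window_reps, seed=seed + 1)
        intervals = call_intervals(stats, alpha=alpha)
        # annotate intervals that also clear the stricter 0.01 criteria
        strict = call_intervals(stats, alpha=0.01) if alpha > 0.01 else []
        return QtlSeqResults(model=self, null=null, records=records,
                             window_stats=stats, intervals=intervals,
                             intervals_strict=strict, alpha=alpha, seed=seed)


@dataclass
class QtlSeqResults:
    """Fitted QTL-seq scan: per-SNP statistics, window table, intervals."""

    model: QtlSeqScan
    null: NullDistribution
    records: pd.DataFrame
    window_stats: pd.DataFrame
    intervals: list[QtlInterval]
    intervals_strict: list[QtlInterval]
    alpha: float
    seed: int

    def refine_interval(self, region: QtlInterval,
                        ladder: RefineLadder = RefineLadder(),
                        criteria: CandidateCriteria = CandidateCriteria(),
                        alpha: float = 0.01) -> RefinementTrace:
        """Progressive fine-mapping of one called interval using SNPs with
        individually significant delta (p < alpha)."""
        sig = select_significant(self.records, alpha=alpha)
        return refine(sig, region, ladder=ladder, criteria=criteria,
                      alpha=alpha)

    def interval_table(self) -> pd.DataFrame:
        strict = {(iv.chrom, iv.peak_start) for iv in self.intervals_strict}
        rows = []
        for k, iv in enumerate(self.intervals, 1):
            level = 0.01 if (iv.chrom, iv.peak_start) in strict or any(
                s.chrom == iv.chrom and s.start >= iv.start and s.end <= iv.end
                for s in self.intervals_strict) else iv.level
            rows.append({"QTL": f"q{k}", "Chromosome": iv.chrom,
                         "Start": iv.start, "End": iv.end,
                         "Size_Mb": round(iv.size_mb, 4),
                         "p_value": f"<{level:g}",
                         "Allele_effect": iv.allele_effect})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n = len(self.records)
        n_sig = int((self.records["PVAL"] < 0.05).sum())
        lines = [
            "QTL-seq delta-SNP-index scan",
            f"population model: {self.model.pop_model}, bulks "
            f"{self.model.n_high}/{self.model.n_low}",
            f"SNPs analysed: {n} ({n_sig} with p<0.05)",
            f"window: {self.model.window.size / 1e6:g} Mb / "
            f"{self.model.window.step / 1e3:g} kb, alpha={self.alpha:g}",
            f"QTL intervals called: {len(self.intervals)}",
        ]
        if self.intervals:
            lines.append(self.interval_table().to_string(index=False))
        return "\n".join(lines)

    def plot(self, path: str | Path | None = None):
        """Per-chromosome SNP-index and delta tracks with the null band."""
        from . import plotting

        return plotting.plot_genome_scan(self, path)


@dataclass
class IntervalMapper:
    """F2 interval-mapping model over an ordinal trait score."""

    genotypes: pd.DataFrame  # individuals x markers, codes A/H/B/-
    marker_info: pd.DataFrame  # MARKER, CHROM, POS
    phenotypes: np.ndarray
    map_function: str = "kosambi"

    def __post_init__(self) -> None:
        self.marker_info = self.marker_info.reset_index(drop=True)
        order = [m for m in self.genotypes.columns]
        if list(self.marker_info["MARKER"]) != order:
            info = self.marker_info.set_index("MARKER").loc[order]
            self.marker_info = info.reset_index()
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.phenotypes.size != len(self.genotypes):
            raise ValueError("phenotype length != number of individuals")
        self.dosage = lk.encode_genotypes(self.genotypes)

    @classmethod
    def from_files(cls, genotype_csv: str | Path, phenotype_csv: str | Path,
                   marker_tsv: str | Path, **kwargs) -> "IntervalMapper":
        geno = tio.read_genotype_csv(genotype_csv)
        pheno = tio.read_phenotype_csv(phenotype_csv)
        pheno = pheno.reindex(geno.index.astype(str))
        if pheno.isna().any():
            missing = pheno.index[pheno.isna()][:3].tolist()
            raise ValueError(f"phenotypes missing for individuals {missing}")
        info = tio.read_marker_positions(marker_tsv)
        return cls(genotypes=geno, marker_info=info,
                   phenotypes=pheno.to_numpy(), **kwargs)

    def build_map(self) -> lk.GeneticMap:
        return lk.build_map(self.dosage, self.marker_info, self.map_function)

    def fit(self, method: str = "icim",
            config: lk.LinkageConfig | None = None,
            permutations: int | None = None) -> "F2ScanResults":
        config = config or lk.LinkageConfig()
        if permutations is not None:
            config.n_permutations = permutations
        gmap = self.build_map()
        scan_fn = {"icim": lk.icim_scan, "hk": lk.hk_scan}.get(method)
        if scan_fn is None:
            raise ValueError(f"unknown scan method {method!r}")
        scan = scan_fn(self.dosage, self.marker_info, gmap, self.phenotypes,
                       config)
        thr = lk.permutation_threshold(self.dosage, self.marker_info, gmap,
                                       self.phenotypes, config)
        scan.threshold = thr
        return F2ScanResults(model=self, gmap=gmap, scan=scan, config=config)


@dataclass
class F2ScanResults:
    """Fitted F2 scan: map, LOD profile, threshold, QTL report."""

    model: IntervalMapper
    gmap: lk.GeneticMap
    scan: lk.ScanResult
    config: lk.LinkageConfig

    @property
    def threshold(self) -> float:
        return self.scan.threshold

    def qtl_report(self) -> pd.DataFrame:
        """Table-style QTL report: flanking markers, LOD, PVE, Add, Dom."""
        pk = self.scan.peaks()
        rows = []
        for k, (_, p) in enumerate(pk.iterrows(), 1):
            rows.append({"QTL": f"q{k}", "Chr": p["GROUP"],
                         "Left_marker": p["LEFT"], "Right_marker": p["RIGHT"],
                         "Pos_cM": round(p["CM"], 1),
                         "LOD": round(p["LOD"], 2),
                         "PVE_pct": round(p["PVE"], 2),
                         "Add": round(p["ADD"], 2), "Dom": round(p["DOM"], 2)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"F2 interval mapping ({self.scan.method.upper()}, "
            f"step {self.config.step_cm:g} cM, PIN {self.config.pin:g})",
            "linkage map: " + ", ".join(
                f"{g}: {len(self.gmap.markers[g])} markers / "
                f"{self.gmap.length(g):.1f} cM" for g in self.gmap.groups),
            f"LOD threshold ({self.config.n_permutations} permutations, "
            f"alpha={self.config.alpha:g}): {self.threshold:.4f}",
        ]
        rep = self.qtl_report()
        lines.append(rep.to_string(index=False) if not rep.empty
                     else "No QTL above threshold.")
        return "\n".join(lines)

    def plot(self, path: str | Path | None = None):
        from . import plotting

        return plotting.plot_lod_profile(self, path)
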