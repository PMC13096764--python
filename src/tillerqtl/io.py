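"""File formats: SNP allele-depth tables, genotype/phenotype CSVs, interval
reports, VCF import, and run manifests.

The SNP table dialect is TSV with header columns CHROM, POS (1-based), REF,
ALT, HIGH_REF, HIGH_ALT, LOW_REF, LOW_ALT, optionally followed by computed
SNP_INDEX1, SNP_INDEX2, DELTA, PVAL; lines starting with '#' are comments.
ALT is always polarized to the donor (Hapcheonaengmi3) allele — the sign of
the delta-SNP index depends on it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import QtlInterval

logger = logging.getLogger(__name__)

REQUIRED_COLS = ["CHROM", "POS", "REF", "ALT",
                 "HIGH_REF", "HIGH_ALT", "LOW_REF", "LOW_ALT"]
COUNT_COLS = ["POS", "HIGH_REF", "HIGH_ALT", "LOW_REF", "LOW_ALT"]


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Parse and validate a SNP table file.

    Malformed rows (non-integer counts, negative counts, duplicate or
    non-increasing positions) raise with the offending 1-based line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    # map frame rows back to file lines for error messages
    with open(path) as fh:
        data_lines = [i + 1 for i, line in enumerate(fh)
                      if not line.startswith("#") and line.strip()]
    header_line = data_lines[0]
    row_lines = data_lines[1:]
    for col in COUNT_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            ln = row_lines[int(np.flatnonzero(bad)[0])]
            raise ValueError(f"{path}:{ln}: non-integer {col} value "
                             f"{df[col][bad].iloc[0]!r}")
        if (vals < 0).any():
            ln = row_lines[int(np.flatnonzero(vals < 0)[0])]
            raise ValueError(f"{path}:{ln}: negative {col}")
        df[col] = vals.astype(np.int64)
    for col in df.columns:
        if col not in REQUIRED_COLS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    dup = df.duplicated(subset=["CHROM", "POS"])
    if dup.any():
        ln = row_lines[int(np.flatnonzero(dup)[0])]
        raise ValueError(f"{path}:{ln}: duplicate (CHROM, POS)")
    for chrom, grp in df.groupby("CHROM", sort=False):
        if np.any(np.diff(grp["POS"].to_numpy()) <= 0):
            raise ValueError(f"{path}: POS not strictly increasing on {chrom}"
                             f" (header at line {header_line})")
    return df.reset_index(drop=True)


def write_snp_table(df: pd.DataFrame, path: str | Path,
                    float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_genotype_csv(path: str | Path) -> pd.DataFrame:
    """Individuals x markers genotype codes (A/H/B/-); first column is the
    individual id."""
    df = pd.read_csv(path, dtype=str)
    return df.set_index(df.columns[0])


def read_phenotype_csv(path: str | Path) -> pd.Series:
    """Two columns: individual id, numeric HT score."""
    df = pd.read_csv(path)
    return pd.Series(pd.to_numeric(df.iloc[:, 1]).to_numpy(),
                     index=df.iloc[:, 0].astype(str), name="score")


def read_marker_positions(path: str | Path) -> pd.DataFrame:
    """TSV with MARKER, CHROM, POS columns."""
    df = pd.read_csv(path, sep="\t", dtype={"MARKER": str, "CHROM": str})
    need = {"MARKER", "CHROM", "POS"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    df["POS"] = df["POS"].astype(np.int64)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# VCF import


def import_vcf_pair(vcf_high: str | Path, vcf_low: str | Path,
                    donor_alleles: dict[tuple[str, int], str] | None = None,
                    ) -> pd.DataFrame:
    """Merge two single-bulk VCFs (with AD) into a SNP table.

    Only biallelic SNPs present in both files are kept; multi-allelic or
    indel sites are dropped (counted in the log). Polarization: by default
    ALT is taken as the donor allele ("donor vs reference" calls); a
    ``{(chrom, pos): donor_base}`` table flips sites where the donor allele
    is the reference base.
    """
    from cyvcf2 import VCF

    def load(path):
        sites = {}
        n_multi = 0
        for var in VCF(str(path)):
            if len(var.ALT) != 1 or not var.is_snp:
                n_multi += 1
                continue
            ad = var.format("AD")
            if ad is None:
                raise ValueError(f"{path}: missing AD (allelic depth) field")
            ref_d, alt_d = int(ad[0][0]), int(ad[0][1])
            sites[(var.CHROM, var.POS)] = (var.REF, var.ALT[0],
                                           max(ref_d, 0), max(alt_d, 0))
        return sites, n_multi

    high, n_multi_h = load(vcf_high)
    low, n_multi_l = load(vcf_low)
    logger.info("dropped %d multi-allelic/non-SNP sites (high) and %d (low)",
                n_multi_h, n_multi_l)
    shared = sorted(set(high) & set(low))
    if not shared:
        logger.warning("no shared biallelic sites between the two VCFs")
    rows = []
    for key in shared:
        chrom, pos = key
        ref, alt, h_ref, h_alt = high[key]
        _, _, l_ref, l_alt = low[key]
        if donor_alleles is not None and donor_alleles.get(key) == ref:
            ref, alt = alt, ref
            h_ref, h_alt = h_alt, h_ref
            l_ref, l_alt = l_alt, l_ref
        rows.append((chrom, pos, ref, alt, h_ref, h_alt, l_ref, l_alt))
    return pd.DataFrame(rows, columns=REQUIRED_COLS)


# ---------------------------------------------------------------------------
# interval reports


def write_intervals(intervals: list[QtlInterval], path: str | Path,
                    fmt: str = "tsv") -> None:
    """BED (0-based half-open) or TSV (1-based inclusive, Table-style)."""
    path = Path(path)
    if fmt == "bed":
        with open(path, "w") as fh:
            for k, iv in enumerate(intervals, 1):
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                         f"QTL{k}\t{iv.peak_delta:.4f}\t"
                         f"{'+' if iv.allele_effect == 'HP3' else '-'}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("# coordinates 1-based inclusive; Size_Mb = "
                     "(End - Start + 1) / 1e6\n")
            fh.write("Chromosome\tStart\tEnd\tSize_Mb\tp_level\tAllele_effect\n")
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{iv.size_mb:.4g}\t<{iv.level:g}\t{iv.allele_effect}\n")
    else:
        raise ValueError(f"unknown interval format {fmt!r}")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """BED -> list of (chrom, start_1based, end_1based)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# manifest


def write_manifest(path: str | Path, config: dict,
                   inputs: list[str | Path] = (), seed: int | None = None) -> None:
    """Reproducibility manifest: config, seed, package versions, and input
    checksums."""
    import tillerqtl

    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "tillerqtl": tillerqtl.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_sha256": checksums,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
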