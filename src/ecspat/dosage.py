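"""Copy-number-normalised transcription statistics.

Three complementary readouts of whether per-copy transcription differs
between ecDNA and the chromosomal locus:

* **Focus ratios** — per nucleus, RNA:DNA = RNA foci / DNA foci and the
  ecDNA proportion = (DNA foci − CEN7 foci)/DNA foci (CEN7 counts proxy
  the chromosomal copy number).  If ecDNA copies were transcribed more
  efficiently per copy, the RNA:DNA ratio would rise with the ecDNA
  proportion; Spearman correlation across nuclei tests this.
* **Exon groups** — RNA-seq read counts normalised to WGS read counts
  per exon, compared (Mann-Whitney) between exons present only on the
  chromosome and exons carried predominantly on ecDNA (exploiting an
  exon 2-7 deletion on the ecDNA species).
* **Allele-frequency ratios** — at heterozygous SNPs (control allele
  frequency 40-60%) on the amplicon, the ratio of RNA-seq to WGS tumour
  allele frequency; ≈1 when per-copy transcription is equal between
  compartments.

Tables are plain DataFrames with documented columns (see the readers in
:mod:`ecspat.io`); negative ecDNA proportions (CEN7 miscounts) are kept
and flagged, never clamped, so anomalies stay visible.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rna_dna_ratio",
    "ecdna_proportion",
    "annotate_nucleus_counts",
    "ratio_proportion_correlation",
    "compare_exon_groups",
    "select_heterozygous_snps",
    "af_ratio_analysis",
]


def rna_dna_ratio(rna_foci, dna_foci):
    """RNA:DNA focus ratio; NaN (nucleus excluded) when DNA foci = 0."""
    rna = np.asarray(rna_foci, dtype=float)
    dna = np.asarray(dna_foci, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dna > 0, rna / np.where(dna > 0, dna, 1.0), np.nan)
    return out if out.ndim else float(out)


def ecdna_proportion(dna_foci, cen7_foci):
    """(DNA foci − CEN7 foci)/DNA foci; may be negative (flagged
    downstream, not clamped); NaN when DNA foci = 0."""
    dna = np.asarray(dna_foci, dtype=float)
    cen7 = np.asarray(cen7_foci, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dna > 0, (dna - cen7) / np.where(dna > 0, dna, 1.0), np.nan)
    return out if out.ndim else float(out)


def annotate_nucleus_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns to a per-nucleus count table.

    Input columns: ``nucleus_id, rna_foci, dna_foci, cen7_foci``.
    Adds ``rna_dna_ratio``, ``ecdna_proportion``, ``excluded`` (DNA
    foci = 0) and ``anomalous`` (CEN7 exceeding DNA foci).
    """
    required = {"nucleus_id", "rna_foci", "dna_foci", "cen7_foci"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table is missing column(s): {sorted(missing)}")
    out = counts.copy()
    out["rna_dna_ratio"] = rna_dna_ratio(out["rna_foci"], out["dna_foci"])
    out["ecdna_proportion"] = ecdna_proportion(out["dna_foci"], out["cen7_foci"])
    out["excluded"] = out["dna_foci"] <= 0
    out["anomalous"] = out["cen7_foci"] > out["dna_foci"]
    return out


def ratio_proportion_correlation(counts: pd.DataFrame):
    """Spearman rho between RNA:DNA ratio and ecDNA proportion across
    nuclei, with two-sided p; returns (rho, p, n_used).

    Nuclei with zero DNA foci are excluded; a constant column yields
    (nan, nan, n) rather than an error.
    """
    df = annotate_nucleus_counts(counts)
    df = df[~df["excluded"]]
    if len(df) < 5:
        raise ValueError(f"need at least 5 valid nuclei, got {len(df)}")
    x = df["rna_dna_ratio"].to_numpy()
    y = df["ecdna_proportion"].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan, len(df)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), len(df)


def compare_exon_groups(exons: pd.DataFrame):
    """Two-sided Mann-Whitney U on per-exon RNA/WGS-normalised counts,
    chromosomal vs ecDNA groups; returns (U, p).

    Input columns: ``exon_id, group, wgs_count, rna_count`` with group
    labels ``chromosomal`` / ``ecDNA``; a ``normalized`` column is
    computed as rna_count/wgs_count (wgs_count must be positive).
    """
    df = exons.copy()
    if (df["wgs_count"] <= 0).any():
        bad = df.loc[df["wgs_count"] <= 0, "exon_id"].tolist()
        raise ValueError(f"non-positive WGS count for exon(s) {bad}")
    df["normalized"] = df["rna_count"] / df["wgs_count"]
    groups = {g: sub["normalized"].to_numpy() for g, sub in df.groupby("group")}
    for g in ("chromosomal", "ecDNA"):
        if g not in groups or len(groups[g]) < 2:
            raise ValueError(f"need at least 2 exons in group {g!r}")
    a, b = groups["chromosomal"], groups["ecDNA"]
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def select_heterozygous_snps(snps: pd.DataFrame, lo: float = 0.40,
                             hi: float = 0.60) -> pd.DataFrame:
    """Keep SNPs heterozygous in the control sample: lo ≤ control
    allele frequency ≤ hi (bounds inclusive)."""
    if "af_control" not in snps.columns:
        raise ValueError("SNP table is missing column 'af_control'")
    keep = (snps["af_control"] >= lo) & (snps["af_control"] <= hi)
    return snps[keep].reset_index(drop=True)


def af_ratio_analysis(snps: pd.DataFrame, min_rna_depth: int = 20):
    """Per-SNP RNA/WGS allele-frequency ratios and per-gene medians.

    Keeps SNPs with ``rna_depth ≥ min_rna_depth`` and a positive tumour
    WGS allele frequency; returns (per-SNP DataFrame with ``af_ratio``,
    per-gene median Series).  Genes left without any qualifying SNP are
    simply absent from the medians (their count is in ``attrs``).
    """
    required = {"snp_id", "gene", "af_wgs_tumour", "af_rna_tumour", "rna_depth"}
    missing = required - set(snps.columns)
    if missing:
        raise ValueError(f"SNP table is missing column(s): {sorted(missing)}")
    all_genes = set(snps["gene"])
    df = snps[(snps["rna_depth"] >= min_rna_depth) & (snps["af_wgs_tumour"] > 0)].copy()
    df["af_ratio"] = df["af_rna_tumour"] / df["af_wgs_tumour"]
    medians = df.groupby("gene")["af_ratio"].median()
    df.attrs["genes_omitted"] = sorted(all_genes - set(medians.index))
    return df.reset_index(drop=True), medians
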