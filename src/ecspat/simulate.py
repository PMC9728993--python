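"""Synthetic microscopy and sequencing data generators.

Every downstream analysis in this package (nearest-neighbour distances,
Ripley's K clustering tests, erosion-shell profiling, dosage statistics)
is testable against data produced here, with the statistical structure
those analyses assume:

* complete spatial randomness (CSR) — foci uniform in a bounding ball,
  the null model of the clustering test;
* Thomas cluster processes — Poisson numbers of Gaussian-scattered
  children around uniform parents, emulating hypothetical "ecDNA hubs";
* doublets at a fixed separation, emulating double-minute pairs;
* dual-channel patterns with a colocalized subset, emulating two ecDNA
  species that sometimes share a molecule;
* single-slice nuclear images with a controllable radial intensity bias
  for the erosion-shell analysis;
* per-nucleus focus counts, per-exon read counts and amplicon SNP
  allele-frequency tables generated from an explicit copy-number model
  of transcription with an optional per-copy efficiency boost on ecDNA.

All lengths are µm.  Every generator is deterministic given its seed;
cohort generators split one master seed into independent per-nucleus
streams so each nucleus is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .foci import FociSet

__all__ = [
    "SimulationConfig",
    "DosageSimConfig",
    "simulate_csr_nucleus",
    "simulate_thomas_nucleus",
    "simulate_doublets",
    "simulate_dual_channel",
    "simulate_cohort",
    "simulate_radial_image",
    "simulate_dosage_tables",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in the closed ball of the given radius.

    Isotropic directions from normalised Gaussian vectors; radii from the
    inverse-CDF r = R·u^(1/3) so the radial CDF is (r/R)^3.
    """
    if n == 0:
        return np.empty((0, 3))
    v = rng.normal(size=(n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # a Gaussian triple is never numerically zero in practice, but guard
    norm[norm == 0] = 1.0
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v / norm * r


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def _make_fociset(nucleus_id, coords, channel, bounding_radius, parent_id=None, extra=None):
    table = pd.DataFrame(
        {
            "channel": np.repeat(channel, len(coords)) if isinstance(channel, str) else channel,
            "x_um": coords[:, 0] if len(coords) else np.array([]),
            "y_um": coords[:, 1] if len(coords) else np.array([]),
            "z_um": coords[:, 2] if len(coords) else np.array([]),
        }
    )
    if parent_id is not None:
        table["parent_id"] = parent_id
    return FociSet(nucleus_id=nucleus_id, table=table, bounding_radius=bounding_radius,
                   metadata=extra or {})


def simulate_csr_nucleus(n: int, bounding_radius: float = 5.0, seed=None, *,
                         channel: str = "EGFR", nucleus_id: str = "csr") -> FociSet:
    """Uniformly distributed foci in a ball — the CSR null pattern."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if bounding_radius <= 0:
        raise ValueError("bounding_radius must be positive")
    rng = _rng(seed)
    coords = _uniform_ball(rng, int(n), bounding_radius)
    return _make_fociset(nucleus_id, coords, channel, bounding_radius)


def simulate_thomas_nucleus(n_parents: int, mean_children: float, sigma: float,
                            bounding_radius: float = 5.0, seed=None, *,
                            channel: str = "EGFR", nucleus_id: str = "thomas") -> FociSet:
    """Thomas cluster process inside a ball.

    Parents are uniform in the ball but are *not* emitted as foci (the
    standard Thomas process); each parent receives a Poisson(mean_children)
    number of children placed isotropically Gaussian (sd ``sigma`` per
    axis) around it, resampled until inside the ball so that pairwise
    distances are not distorted by clipping.  True parent labels are
    recorded in a ``parent_id`` column for diagnostics.
    """
    if n_parents <= 0 or mean_children <= 0:
        raise ValueError("n_parents and mean_children must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if bounding_radius <= 0:
        raise ValueError("bounding_radius must be positive")
    rng = _rng(seed)
    parents = _uniform_ball(rng, int(n_parents), bounding_radius)
    counts = rng.poisson(mean_children, size=int(n_parents))
    coords, labels = [], []
    for pid, (parent, k) in enumerate(zip(parents, counts)):
        for _ in range(k):
            while True:
                child = parent + rng.normal(scale=sigma, size=3)
                if np.linalg.norm(child) <= bounding_radius:
                    break
            coords.append(child)
            labels.append(pid)
    coords = np.asarray(coords) if coords else np.empty((0, 3))
    return _make_fociset(nucleus_id, coords, channel, bounding_radius,
                         parent_id=np.asarray(labels, dtype=int))


def simulate_doublets(n_pairs: int, separation: float, bounding_radius: float = 5.0,
                      seed=None, *, channel: str = "CDK4",
                      nucleus_id: str = "doublets") -> FociSet:
    """Pairs of foci at an exact separation — the double-minute pattern.

    Each pair has a uniform anchor and a partner at exactly ``separation``
    in a uniformly random direction, with direction (and, if necessary,
    anchor) resampled until the partner lies inside the ball.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if separation > 2 * bounding_radius:
        raise ValueError("separation exceeds the ball diameter; pair cannot fit")
    rng = _rng(seed)
    coords = []
    pair_ids = []
    for pid in range(int(n_pairs)):
        while True:
            anchor = _uniform_ball(rng, 1, bounding_radius)[0]
            partner = None
            for _ in range(200):
                cand = anchor + separation * _unit_vectors(rng, 1)[0]
                if np.linalg.norm(cand) <= bounding_radius:
                    partner = cand
                    break
            if partner is not None:
                break
        coords.extend([anchor, partner])
        pair_ids.extend([pid, pid])
    coords = np.asarray(coords) if coords else np.empty((0, 3))
    return _make_fociset(nucleus_id, coords, channel, bounding_radius,
                         parent_id=np.asarray(pair_ids, dtype=int))


def simulate_dual_channel(n_a: int, n_b: int, coloc_fraction: float,
                          coloc_separation: float, bounding_radius: float = 5.0,
                          seed=None, *, channel_a: str = "CDK4", channel_b: str = "PDGFRA",
                          nucleus_id: str = "dual") -> FociSet:
    """Two channels with a colocalized subset at a fixed separation.

    ``coloc_fraction · min(n_a, n_b)`` cross-channel pairs sit exactly
    ``coloc_separation`` apart; the remaining foci of each channel are
    independent CSR.
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must be in [0, 1]")
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    n_pairs_f = coloc_fraction * min(n_a, n_b)
    n_pairs = int(round(n_pairs_f))
    if abs(n_pairs_f - n_pairs) > 1e-9:
        raise ValueError(
            f"coloc_fraction*min(n_a,n_b) = {n_pairs_f} does not round to an integer"
        )
    rng = _rng(seed)
    rows_coords, rows_channel = [], []
    pairs = simulate_doublets(n_pairs, coloc_separation, bounding_radius, rng,
                              nucleus_id=nucleus_id)
    pc = pairs.coords()
    for i in range(n_pairs):
        rows_coords.extend([pc[2 * i], pc[2 * i + 1]])
        rows_channel.extend([channel_a, channel_b])
    free_a = _uniform_ball(rng, n_a - n_pairs, bounding_radius)
    free_b = _uniform_ball(rng, n_b - n_pairs, bounding_radius)
    rows_coords.extend(free_a)
    rows_channel.extend([channel_a] * len(free_a))
    rows_coords.extend(free_b)
    rows_channel.extend([channel_b] * len(free_b))
    coords = np.asarray(rows_coords) if rows_coords else np.empty((0, 3))
    return _make_fociset(nucleus_id, coords, np.asarray(rows_channel, dtype=object),
                         bounding_radius)


@dataclass
class SimulationConfig:
    """Cohort-level point-pattern simulation settings.

    ``process`` selects one of ``csr``, ``thomas``, ``doublets`` or
    ``dual``; ``foci_per_nucleus`` may be an integer, a ``("poisson",
    mean)`` tuple or a callable ``f(rng) -> int``.  The ball radius
    default of 5 µm matches the null geometry of the clustering test.
    """

    seed: int = 0
    bounding_radius: float = 5.0
    n_nuclei: int = 10
    foci_per_nucleus: int | tuple | Callable = 40
    process: str = "csr"
    channel: str = "EGFR"
    thomas_parents: int = 5
    thomas_mean_children: float = 8.0
    thomas_sigma: float = 0.05
    doublet_separation: float = 0.2
    n_b: int = 0
    coloc_fraction: float = 0.0
    coloc_separation: float = 0.15

    def __post_init__(self) -> None:
        if self.bounding_radius <= 0:
            raise ValueError("bounding_radius must be positive")
        if self.process not in {"csr", "thomas", "doublets", "dual"}:
            raise ValueError(f"unknown process {self.process!r}")
        if self.process == "thomas" and self.thomas_sigma <= 0:
            raise ValueError("thomas_sigma must be positive")
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must be in [0, 1]")

    def _draw_n(self, rng: np.random.Generator) -> int:
        f = self.foci_per_nucleus
        if callable(f):
            return int(f(rng))
        if isinstance(f, tuple):
            kind, mean = f
            if kind != "poisson":
                raise ValueError(f"unknown count distribution {kind!r}")
            return int(rng.poisson(mean))
        return int(f)


def simulate_cohort(config: SimulationConfig) -> list[FociSet]:
    """One FociSet per nucleus, each from an independent stream split
    off the master seed, so nuclei are reproducible in isolation."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_nuclei)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        nid = f"sim{i:04d}"
        if config.process == "csr":
            fs = simulate_csr_nucleus(config._draw_n(rng), config.bounding_radius, rng,
                                      channel=config.channel, nucleus_id=nid)
        elif config.process == "thomas":
            fs = simulate_thomas_nucleus(config.thomas_parents, config.thomas_mean_children,
                                         config.thomas_sigma, config.bounding_radius, rng,
                                         channel=config.channel, nucleus_id=nid)
        elif config.process == "doublets":
            fs = simulate_doublets(config._draw_n(rng) // 2, config.doublet_separation,
                                   config.bounding_radius, rng,
                                   channel=config.channel, nucleus_id=nid)
        else:  # dual
            fs = simulate_dual_channel(config._draw_n(rng), config.n_b,
                                       config.coloc_fraction, config.coloc_separation,
                                       config.bounding_radius, rng, nucleus_id=nid)
        out.append(fs)
    return out


def simulate_radial_image(image_size: int, nucleus_radius: float, radial_bias: float = 0.0,
                          noise_sd: float = 0.0, seed=None, *, ellipticity: float = 1.0):
    """Single-slice probe/DAPI images with a controllable radial bias.

    Returns ``(probe, dapi, mask)``: a circular (optionally elliptical)
    nucleus mask centred in the image, a flat DAPI signal inside the
    mask, and a probe signal proportional to ``(r/R)**radial_bias``
    (peripherally biased for positive exponents, flat for zero) plus
    optional Gaussian noise, zero outside the mask.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    c = (image_size - 1) / 2.0
    if nucleus_radius <= 0 or nucleus_radius * max(1.0, ellipticity) > c:
        raise ValueError("nucleus must be positive-sized and fit inside the image")
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot((xx - c) / ellipticity, yy - c)
    mask = r <= nucleus_radius
    rel = np.clip(r / nucleus_radius, 0.0, 1.0)
    probe = np.where(mask, rel ** radial_bias if radial_bias != 0 else 1.0, 0.0)
    dapi = mask.astype(float)
    if noise_sd > 0:
        rng = _rng(seed)
        probe = probe + np.where(mask, rng.normal(scale=noise_sd, size=probe.shape), 0.0)
    return probe.astype(float), dapi, mask.astype(np.uint8)


# --------------------------------------------------------------------------
# dosage / sequencing tables

# EGFR-201 exon grouping for an ecDNA species carrying an exon 2-7
# deletion: exons 2-7 remain chromosomal-only, exons 1 and 8-28 sit
# predominantly on ecDNA.
E26_EXON_GROUPS: dict[int, str] = {
    e: ("chromosomal" if 2 <= e <= 7 else "ecDNA") for e in range(1, 29)
}


@dataclass
class DosageSimConfig:
    """Copy-number model of transcription for dosage analyses.

    Each nucleus has ``chr7_copies`` chromosomal gene copies and a
    negative-binomially distributed number of ecDNA copies (mean
    ``ec_copies_mean``, shape ``ec_copies_shape``; heavy overdispersion
    mirrors the strong per-cell copy-number heterogeneity of ecDNA).
    Each copy transcribes independently with the compartment-appropriate
    probability, so ``p_transcribe_ec == p_transcribe_chr`` is the
    copy-number-only null and a larger ecDNA value models a per-copy
    efficiency boost.
    """

    seed: int = 0
    n_nuclei: int = 40
    chr7_copies: int = 3
    ec_copies_mean: float = 30.0
    ec_copies_shape: float = 3.0
    p_transcribe_chr: float = 0.5
    p_transcribe_ec: float = 0.5
    rna_depth_scale: float = 100.0
    wgs_depth_scale: float = 100.0
    snp_control_af_range: tuple[float, float] = (0.4, 0.6)
    n_snps: int = 50
    gene: str = "EGFR"
    exon_groups: dict[int, str] = field(default_factory=lambda: dict(E26_EXON_GROUPS))

    def __post_init__(self) -> None:
        for p in (self.p_transcribe_chr, self.p_transcribe_ec):
            if not 0 <= p <= 1:
                raise ValueError("transcription probabilities must be in [0, 1]")
        if self.rna_depth_scale <= 0 or self.wgs_depth_scale <= 0:
            raise ValueError("depth scales must be positive")
        lo, hi = self.snp_control_af_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("snp_control_af_range must be an interval within [0, 1]")


def _draw_ec_copies(rng: np.random.Generator, cfg: DosageSimConfig, size: int) -> np.ndarray:
    if cfg.ec_copies_mean == 0:
        return np.zeros(size, dtype=int)
    # gamma-Poisson mixture = negative binomial with mean m, shape k
    lam = rng.gamma(cfg.ec_copies_shape, cfg.ec_copies_mean / cfg.ec_copies_shape, size=size)
    return rng.poisson(lam)


def simulate_dosage_tables(config: DosageSimConfig):
    """Generate (per-nucleus counts, per-exon counts, SNP table).

    * Per nucleus: DNA foci = chromosomal + ecDNA copies, CEN7 foci =
      chromosomal copies, RNA foci = Binomial per copy with the
      compartment-appropriate transcription probability.
    * Per exon: WGS reads Poisson around depth_scale × copy number of
      the compartment(s) carrying the exon; RNA reads Poisson around
      depth_scale × summed per-copy transcription rate.  Bulk copy
      numbers are the cohort means.
    * Per SNP: heterozygous control allele frequency uniform in the
      configured range; the amplified allele sits on every ecDNA copy
      plus one chromosomal copy, fixing the true tumour WGS and RNA
      allele frequencies, which are then binomially sampled at Poisson
      read depths.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nuclei
    chrom = np.full(n, config.chr7_copies, dtype=int)
    ec = _draw_ec_copies(rng, config, n)
    rna = rng.binomial(chrom, config.p_transcribe_chr) + rng.binomial(ec, config.p_transcribe_ec)
    nuclei = pd.DataFrame(
        {
            "nucleus_id": [f"n{i:04d}" for i in range(n)],
            "rna_foci": rna,
            "dna_foci": chrom + ec,
            "cen7_foci": chrom,
        }
    )

    # bulk (cohort-mean) copy numbers drive the sequencing tables
    chr_bulk = float(np.mean(chrom))
    ec_bulk = float(np.mean(ec))
    p_chr, p_ec = config.p_transcribe_chr, config.p_transcribe_ec
    exon_rows = []
    for exon, group in sorted(config.exon_groups.items()):
        if group == "chromosomal":
            copies = chr_bulk
            rate = chr_bulk * p_chr
        else:
            copies = chr_bulk + ec_bulk
            rate = chr_bulk * p_chr + ec_bulk * p_ec
        wgs = rng.poisson(config.wgs_depth_scale * max(copies, 0.0))
        rna_ct = rng.poisson(config.rna_depth_scale * max(rate, 0.0))
        exon_rows.append(
            {"exon_id": f"exon{exon}", "group": group, "wgs_count": wgs, "rna_count": rna_ct}
        )
    exons = pd.DataFrame(exon_rows)

    lo, hi = config.snp_control_af_range
    af_control = rng.uniform(lo, hi, size=config.n_snps)
    # amplified allele: all ec copies + one chromosomal copy
    amp_dna = ec_bulk + 1.0
    tot_dna = ec_bulk + chr_bulk
    af_wgs_true = amp_dna / tot_dna if tot_dna > 0 else np.nan
    amp_rna = ec_bulk * p_ec + 1.0 * p_chr
    tot_rna = ec_bulk * p_ec + chr_bulk * p_chr
    af_rna_true = amp_rna / tot_rna if tot_rna > 0 else np.nan
    wgs_depth = rng.poisson(config.wgs_depth_scale * max(tot_dna, 1e-9), size=config.n_snps)
    rna_depth = rng.poisson(config.rna_depth_scale * max(tot_rna, 1e-9), size=config.n_snps)
    wgs_depth = np.maximum(wgs_depth, 1)
    af_wgs = rng.binomial(wgs_depth, af_wgs_true) / wgs_depth if np.isfinite(af_wgs_true) else np.full(config.n_snps, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        af_rna = np.where(
            rna_depth > 0,
            rng.binomial(rna_depth, af_rna_true if np.isfinite(af_rna_true) else 0.0) / np.maximum(rna_depth, 1),
            np.nan,
        )
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:04d}" for i in range(config.n_snps)],
            "gene": config.gene,
            "af_control": af_control,
            "af_wgs_tumour": af_wgs,
            "af_rna_tumour": af_rna,
            "rna_depth": rna_depth,
        }
    )
    return nuclei, exons, snps
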