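"""Reproducible multi-stage pipeline over the analysis modules.

A run is described by a plain mapping (usually loaded from YAML):

    seed: 7
    stages: [simulate, cluster]
    outdir: results/
    simulate: {process: csr, n_nuclei: 10, foci_per_nucleus: 40}
    cluster:  {channel: EGFR, n_null: 1000, fdr: 0.05}
    distances: {source: EGFR, target: EGFR, threshold_um: 0.2}
    dosage:   {counts: nuclei.csv, exons: exons.csv, snps: snps.csv}
    radial:   {probe: probe.tif, dapi: dapi.tif, mask: mask.tif, n_shells: 5}

Every stage writes tidy CSV; a ``manifest.json`` records the effective
configuration, the master seed, package version, stage outputs and
every excluded nucleus with a machine-readable reason, so a rerun with
the same seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dosage, erosion, io as eio
from .distances import proximity_fraction, shortest_distances, summaries_frame
from .ripley import RipleyConfig, cluster_cohort, cohort_summary, results_frame
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["run_pipeline"]

STAGES = ("simulate", "distances", "cluster", "radial", "dosage")


def _dump_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False)
    return path.name


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run the selected stages and return the manifest (also written to
    ``outdir/manifest.json``).  Fails before writing anything when the
    configuration is invalid."""
    stages = list(config.get("stages", []))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; available: {STAGES}")
    if not stages:
        raise ValueError("no stages selected")
    outdir = Path(outdir or config.get("outdir", "."))
    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "seed": seed, "stages": stages,
                "config": {k: v for k, v in config.items() if k != "outdir"},
                "outputs": {}, "exclusions": []}

    foci_sets = None
    if "simulate" in stages:
        sim_cfg = SimulationConfig(seed=seed, **config.get("simulate", {}))
        foci_sets = simulate_cohort(sim_cfg)
        manifest["config"]["simulate"] = asdict(sim_cfg)
    if foci_sets is None and config.get("foci"):
        foci_sets = eio.read_foci_table(config["foci"],
                                        config.get("bounding_radius", 5.0))
    outdir.mkdir(parents=True, exist_ok=True)
    if "simulate" in stages:
        manifest["outputs"]["simulate"] = _dump_csv(
            _foci_frame(foci_sets), outdir / "foci.csv")

    if "distances" in stages:
        opts = config.get("distances", {})
        if foci_sets is None:
            raise ValueError("distances stage needs simulated or loaded foci")
        src = opts.get("source", "EGFR")
        tgt = opts.get("target", src)
        thr = float(opts.get("threshold_um", 0.2))
        sums = [shortest_distances(fs, src, tgt) for fs in foci_sets]
        frame = summaries_frame(sums)
        pooled_count = sum(s.n_below(thr) for s in sums if not s.empty)
        pooled_total = sum(s.per_focus_shortest.size for s in sums)
        _, _, pct = proximity_fraction_pool(pooled_count, pooled_total)
        frame[f"n_below_{thr}um"] = [s.n_below(thr) if not s.empty else 0 for s in sums]
        manifest["outputs"]["distances"] = _dump_csv(frame, outdir / "distances.csv")
        manifest["outputs"]["distances_pooled_pct_below_threshold"] = pct
        for s in sums:
            if s.empty:
                manifest["exclusions"].append(
                    {"nucleus_id": s.nucleus_id, "stage": "distances",
                     "reason": "too_few_foci"})

    if "cluster" in stages:
        opts = dict(config.get("cluster", {}))
        if foci_sets is None:
            raise ValueError("cluster stage needs simulated or loaded foci")
        channel = opts.pop("channel", None)
        rip_cfg = RipleyConfig(seed=seed, **opts)
        results = cluster_cohort(foci_sets, channel, rip_cfg)
        manifest["outputs"]["cluster"] = _dump_csv(
            results_frame(results), outdir / "ripley.csv")
        summary = cohort_summary(results)
        manifest["outputs"]["cluster_summary"] = _dump_csv(
            summary, outdir / "ripley_summary.csv")
        manifest["cluster"] = {
            "n_null": rip_cfg.n_null,
            "bounding_radius_um": rip_cfg.bounding_radius,
            "min_foci": rip_cfg.min_foci,
            "fdr": rip_cfg.fdr,
            "n_significant_nuclei": int(sum(r.any_significant() for r in results
                                            if not r.excluded)),
            "n_tested": int(summary["n_tested"].iloc[0]),
        }
        for r in results:
            if r.excluded:
                manifest["exclusions"].append(
                    {"nucleus_id": r.nucleus_id, "stage": "cluster",
                     "reason": "min_foci", "detail": r.reason})

    if "radial" in stages:
        opts = config.get("radial", {})
        probe = eio.read_image(opts["probe"])
        dapi = eio.read_image(opts["dapi"])
        mask = eio.read_mask(opts["mask"])
        shells = erosion.equal_area_shells(mask, int(opts.get("n_shells", 5)))
        prof = erosion.shell_profile({"probe": probe}, dapi, shells,
                                     nucleus_id=opts.get("nucleus_id", "img0"))
        manifest["outputs"]["radial"] = _dump_csv(
            erosion.profiles_frame([prof]), outdir / "erosion.csv")

    if "dosage" in stages:
        opts = config.get("dosage", {})
        counts = pd.read_csv(opts["counts"])
        annotated = dosage.annotate_nucleus_counts(counts)
        rho, p, n_used = dosage.ratio_proportion_correlation(counts)
        stats = {"spearman_rho": rho, "spearman_p": p, "n_nuclei": n_used}
        if opts.get("exons"):
            u, pu = dosage.compare_exon_groups(pd.read_csv(opts["exons"]))
            stats["exon_mannwhitney_u"] = u
            stats["exon_mannwhitney_p"] = pu
        if opts.get("snps"):
            snps = dosage.select_heterozygous_snps(pd.read_csv(opts["snps"]))
            per_snp, medians = dosage.af_ratio_analysis(snps)
            _dump_csv(per_snp, outdir / "snp_af_ratios.csv")
            stats["af_ratio_median_per_gene"] = medians.to_dict()
        manifest["outputs"]["dosage"] = _dump_csv(annotated, outdir / "dosage_counts.csv")
        manifest["dosage"] = stats
        for _, row in annotated[annotated["excluded"]].iterrows():
            manifest["exclusions"].append(
                {"nucleus_id": str(row["nucleus_id"]), "stage": "dosage",
                 "reason": "zero_dna_foci"})

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def proximity_fraction_pool(count: int, total: int):
    from .distances import truncate_percent
    if total == 0:
        return 0, 0, None
    return count, total, truncate_percent(count, total)


def _foci_frame(foci_sets) -> pd.DataFrame:
    frames = []
    for fs in foci_sets:
        t = fs.table.copy()
        t.insert(0, "nucleus_id", fs.nucleus_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
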