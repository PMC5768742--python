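"""End-to-end orchestration: matrix -> balance -> call -> enrich -> predict -> classify -> interactions.

A single :class:`RunConfig` drives every stage; all stochastic stages
take explicit seeds so a re-run with the same config reproduces the
report bit-for-bit on one platform. The report collects the headline
statistics of the analysis (domain counts and sizes, contiguity,
border/protein co-localization in both directions, prediction AUCs,
type-localization and interaction summaries).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import caller as tc
from . import chromstate as cs
from . import insulator as ins
from . import interactions as ti
from . import prediction as pred
from . import synthetic as syn
from .genome import write_fragment_map
from .matrix import (
    ContactMatrix,
    bin_matrix,
    estimate_map_resolution,
    ice_normalize,
    replicate_correlation,
    save_matrix,
)

log = logging.getLogger("tadscape")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: str = "tadscape_run"
    seed: int = 0
    design: syn.SyntheticDesign | None = None  # synthetic mode when set
    # caller
    gamma: float = 0.9
    gamma_fallback: float = 0.6
    min_domain_bins: int = 2
    max_domain_bins: int | None = 900
    binsize_super: int = 20_000
    ice_tol: float = 1e-5
    ice_max_iter: int = 200
    # insulator enrichment
    flank: int = 4000
    window: int = 80
    coloc_tol: int = 2000
    n_shuffles: int = 50
    pair_max_gap: int = 200
    # prediction
    split_seed: int = 1
    balance: bool = True
    # chromatin state
    kmeans_k: int = 8
    kmeans_restarts: int = 10
    tau: float = 0.5
    inclusion: float = 0.75
    # interactions
    distance_bin: int = 200
    max_dist: int = 150_000
    size_min: int = 5000
    size_max: int = 20_000
    # QC
    resolution_candidates: tuple[int, ...] = (200, 500, 1000, 2000, 5000)
    qc_replicate: bool = False
    replicate_binsize: int = 20_000
    save_fragment_matrix: bool = False

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.design is not None:
            d["design"] = dataclasses.asdict(self.design)
            d["design"]["genome"] = list(self.design.genome.chromosomes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _caller_config(config: RunConfig, level: str, max_bins=None) -> tc.CallerConfig:
    return tc.CallerConfig(
        gamma=config.gamma,
        gamma_fallback=config.gamma_fallback,
        min_domain_bins=config.min_domain_bins,
        max_domain_bins=config.max_domain_bins if max_bins is None else max_bins,
        level=level,
    )


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if not np.isfinite(v) else v
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _jsonable(x.tolist())
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the run report.

    Synthetic mode (``config.design`` set) generates and persists the
    inputs first; the planted ground truth adds recovery statistics to
    the report.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"stages": {}, "seed": config.seed}
    t_all = time.time()

    if config.design is None:
        raise ValueError("only synthetic mode is wired through run_pipeline; "
                         "use the library functions for external data")
    design = dataclasses.replace(config.design, seed=config.seed)

    # -- stage: inputs ---------------------------------------------------------
    t = time.time()
    fragments = syn.make_fragment_map(design)
    truth = syn.build_ground_truth(design, fragments)
    matrix = syn.simulate_contact_matrix(design, fragments, truth)
    peaks, tracks = syn.simulate_peak_track(design, truth)
    marks = syn.simulate_mark_signals(design, truth)
    write_fragment_map(fragments, out / "fragments.bed")
    tc.write_domains(truth.tads, out / "truth_tads.bed")
    tc.write_domains(truth.supertads, out / "truth_supertads.bed")
    for p, ps in peaks.items():
        ps.to_narrowpeak(out / f"peaks_{p}.narrowPeak")
    log.info("inputs: %d fragments, %.0f contacts", fragments.n, matrix.total())
    report["stages"]["inputs"] = {
        "n_fragments": fragments.n,
        "total_contacts": matrix.total(),
        "median_fragment_bp": fragments.median_fragment_length(),
        "n_planted_tads": len(truth.tads),
        "n_planted_supertads": len(truth.supertads),
        "time_s": time.time() - t,
    }

    # -- stage: balance + QC ---------------------------------------------------
    t = time.time()
    matrix = ice_normalize(matrix, tol=config.ice_tol, max_iter=config.ice_max_iter)
    res = estimate_map_resolution(matrix, list(config.resolution_candidates))
    rep_corr = None
    if config.qc_replicate:
        rep = syn.simulate_contact_matrix(design, fragments, truth, replicate=1)
        rep_corr = replicate_correlation(matrix, rep, config.replicate_binsize)
    if config.save_fragment_matrix:
        save_matrix(matrix, out / "matrix.coo.txt", out / "matrix.json")
    report["stages"]["qc"] = {
        "ice_converged": bool(matrix.converged),
        "map_resolution_bp": res.binsize,
        "map_resolution_qualified": res.qualified,
        "replicate_correlation": rep_corr,
        "total_valid_pairs": matrix.total(),
        "n_masked_fragments": int(matrix.mask.sum()),
        "time_s": time.time() - t,
    }

    # -- stage: TAD calling ----------------------------------------------------
    t = time.time()
    cfg = _caller_config(config, "TAD")
    tads = tc.call_domains_dp(matrix, cfg)
    tads, deserts = tc.readdesert_fallback(matrix, tads, cfg)
    centers = tc.boundary_centers(tads)
    contig, _ = tc.contiguity_fraction(tads, fragments)
    stats = tc.domain_size_stats(tads)
    tc.write_domains(tads, out / "tads.bed")
    with open(out / "boundaries.bed", "w") as fh:
        for chrom, pos in centers.centers:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
    recovery = None
    if truth is not None:
        recovery = boundary_recovery(truth, tads)
    report["stages"]["tads"] = {
        "n_domains": len(tads),
        "median_size_bp": stats["median_bp"],
        "coverage": stats.get("coverage"),
        "contiguity_fraction": contig,
        "n_desert_triggers": len(deserts),
        "planted_boundary_recovery": recovery,
        "time_s": time.time() - t,
    }
    log.info("tads: %d domains, contiguity %.3f", len(tads), contig)

    # -- stage: super-TADs + nesting ------------------------------------------
    t = time.time()
    binned = ice_normalize(bin_matrix(matrix, config.binsize_super),
                           tol=config.ice_tol, max_iter=config.ice_max_iter)
    super_cfg = _caller_config(config, "super-TAD", max_bins=None)
    supertads = tc.call_domains_dp(binned, super_cfg)
    nesting = tc.nest_domains(tads, supertads, inclusion=config.inclusion)
    tc.write_domains(supertads, out / "supertads.bed")
    sstats = tc.domain_size_stats(supertads)
    report["stages"]["supertads"] = {
        "n_domains": len(supertads),
        "median_size_bp": sstats["median_bp"],
        "n_tads_in_super": int((nesting.assignment["region"] == "super-TAD").sum()),
        "n_tads_in_inter": int((nesting.assignment["region"] == "inter-super-TAD").sum()),
        "n_tads_unassigned": int(nesting.assignment["region"].isna().sum()),
        "time_s": time.time() - t,
    }

    # -- stage: insulator enrichment ------------------------------------------
    t = time.time()
    genome = design.genome
    enr = {}
    for p, track in tracks.items():
        e = ins.boundary_enrichment(
            track, centers, genome,
            flank=config.flank, window=config.window,
            n_shuffles=config.n_shuffles, seed=config.seed + 11,
        )
        e.to_frame().to_csv(out / f"enrichment_{p}.tsv", sep="\t", index=False)
        enr[p] = e.central_ratio()
    pairs = {
        "BEAF-32/CP190": ins.pair_sites(peaks["BEAF-32"], peaks["CP190"], config.pair_max_gap),
        "BEAF-32/Chromator": ins.pair_sites(peaks["BEAF-32"], peaks["Chromator"], config.pair_max_gap),
    }
    site_sets: dict[str, object] = dict(peaks)
    coloc = {name: ins.colocalize(s, centers, config.coloc_tol) for name, s in {**site_sets, **pairs}.items()}
    venn = ins.venn_partition(site_sets, centers, config.coloc_tol)
    borders_any = sum(venn.values())
    # expected hit rate for any protein, from shuffled centers
    rng = np.random.default_rng(config.seed + 13)
    per = {c: len(x) for c, x in centers.per_chrom().items()}
    sh_hits, sh_total = 0, 0
    for _ in range(20):
        fake = tc.BoundarySet(
            [(c, int(p_)) for c, k in per.items() for p_ in rng.integers(0, genome.length(c), k)]
        )
        vp = ins.venn_partition(site_sets, fake, config.coloc_tol)
        sh_hits += sum(vp.values())
        sh_total += len(fake)
    fisher_p, _ = ins.border_enrichment_test(borders_any, len(centers), sh_hits / sh_total)
    # union of pair sites: fraction of borders at a pair site and vice versa
    import pandas as pd

    union_sites = ins.PairSiteSet(
        ("BEAF-32", "CP190|Chromator"),
        pd.concat([pairs[k].sites for k in pairs]).drop_duplicates().reset_index(drop=True),
    )
    coloc_union = ins.colocalize(union_sites, centers, config.coloc_tol)
    report["stages"]["insulators"] = {
        "central_enrichment": enr,
        "borders_with_any_protein_prop": borders_any / len(centers),
        "fisher_p_any_protein": fisher_p,
        "borders_at_pair_sites_prop": coloc_union.borders_hit_prop,
        "pair_sites_at_borders_prop": coloc_union.sites_at_borders_prop,
        "per_set": {
            name: {
                "borders_hit_prop": c.borders_hit_prop,
                "sites_at_borders_prop": c.sites_at_borders_prop,
                "n_sites": c.n_sites,
            }
            for name, c in coloc.items()
        },
        "venn": venn,
        "time_s": time.time() - t,
    }

    # -- stage: border prediction ---------------------------------------------
    t = time.time()
    labels = pred.label_fragments(fragments, centers)
    pair_track = {}
    for name, psites in pairs.items():
        vals = {}
        for chrom, length in genome.chromosomes:
            nbins = -(-length // 500)
            v = np.zeros(nbins)
            for pos in psites.positions(chrom):
                v[int(pos // 500)] += 1.0
            vals[chrom] = v
        pair_track[name] = syn.SignalTrack.from_dense(genome, 500, vals)
    pair_feats = pred.ztransform(pred.fragment_signal(pair_track, fragments))
    active_marks = {m: marks[m] for m in cs.DEFAULT_MARK_GROUPS["active"] if m in marks}
    mark_feats = pred.ztransform(pred.fragment_signal(active_marks, fragments))
    auc_table = {}
    for name, feats in [("pair_sites", pair_feats), ("active_marks", mark_feats)]:
        model = pred.fit_border_model(
            feats, labels, split_seed=config.split_seed, balance=config.balance
        )
        auc_table[name] = model.auc
    report["stages"]["prediction"] = {"auc": auc_table, "n_border_fragments": int(labels.sum()),
                                      "time_s": time.time() - t}

    # -- stage: chromatin state ------------------------------------------------
    t = time.time()
    mark_matrix = cs.tad_mark_enrichment(marks, tads)
    mark_matrix.to_csv(out / "mark_matrix.tsv", sep="\t")
    km = cs.kmeans_types(mark_matrix, k=config.kmeans_k, seed=config.seed + 17,
                         n_restarts=config.kmeans_restarts)
    classes = cs.assign_major_types(km, list(mark_matrix.columns), tau=config.tau)
    loc = cs.type_localization_test(classes, nesting)
    typing_accuracy = None
    if truth is not None:
        called_types = _match_called_types(truth, tads, classes)
        typing_accuracy = called_types
    report["stages"]["chromatin"] = {
        "cluster_sizes": _jsonable(classes["cluster"].value_counts().sort_index().to_dict()),
        "type_counts": _jsonable(classes["major_type"].value_counts().to_dict()),
        "localization_p": None if loc is None else loc.p,
        "prop_inactive_in_super": None if loc is None else loc.prop_inactive_in_super,
        "prop_active_in_inter": None if loc is None else loc.prop_active_in_inter,
        "major_type_accuracy_vs_planted": typing_accuracy,
        "time_s": time.time() - t,
    }

    # -- stage: interactions ---------------------------------------------------
    t = time.time()
    expected = ti.expected_by_distance(matrix, binwidth=config.distance_bin,
                                       max_dist=config.max_dist)
    cond = ti.condensation(matrix, tads, (config.size_min, config.size_max))
    cond.to_csv(out / "condensation.tsv", sep="\t", index=False)
    pair_enr = ti.tad_pair_enrichments(matrix, tads, expected)
    pair_enr.to_csv(out / "tad_pair_enrichment.tsv", sep="\t", index=False)
    type_summary = ti.neighbor_type_summary(pair_enr, classes, seed=config.seed + 19)
    type_summary.to_csv(out / "type_pair_summary.tsv", sep="\t")
    contrast = ti.supertad_contact_contrast(pair_enr, nesting)
    parity_p = ti.condensation_type_test(cond, classes, seed=config.seed + 23)
    report["stages"]["interactions"] = {
        "condensation_median_included": float(cond.loc[cond["included"], "condensation"].median()),
        "n_size_matched_tads": int(cond["included"].sum()),
        "condensation_parity_p": parity_p,
        "type_pair_means": _jsonable(type_summary["mean_ratio"].to_dict()),
        "supertad_contrast": None if contrast is None else {
            "within_mean": contrast.within_mean,
            "across_mean": contrast.across_mean,
            "ratio": contrast.ratio,
        },
        "time_s": time.time() - t,
    }

    report["total_time_s"] = time.time() - t_all
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return _jsonable(report)


def boundary_recovery(truth: syn.GroundTruth, called: tc.DomainSet, tol_bins: int = 1) -> float:
    """Fraction of planted TAD junctions with a called domain edge within
    ``tol_bins`` fragments."""
    hits = total = 0
    per_called = called.per_chrom()
    for chrom in truth.fragments.genome.names:
        planted = truth.boundary_bins(chrom)
        if planted.size == 0:
            continue
        edges = np.array(
            sorted({d.start_bin for d in per_called.get(chrom, [])}
                   | {d.end_bin + 1 for d in per_called.get(chrom, [])}),
            dtype=np.int64,
        )
        total += planted.size
        if edges.size == 0:
            continue
        idx = np.searchsorted(edges, planted)
        left = np.abs(planted - edges[np.clip(idx - 1, 0, edges.size - 1)])
        right = np.abs(edges[np.clip(idx, 0, edges.size - 1)] - planted)
        hits += int(np.sum(np.minimum(left, right) <= tol_bins))
    return hits / total if total else float("nan")


def _match_called_types(truth: syn.GroundTruth, called: tc.DomainSet, classes) -> float:
    """Accuracy of called major types against planted types, matching each
    called TAD to the planted TAD with the largest overlap."""
    planted = list(truth.tads)
    hits = total = 0
    for i, d in enumerate(called):
        best_ov, best_t = 0, None
        for t, p in zip(truth.tad_types, planted):
            if p.chrom != d.chrom:
                continue
            ov = min(d.end_bp, p.end_bp) - max(d.start_bp, p.start_bp)
            if ov > best_ov:
                best_ov, best_t = ov, t
        if best_t is None:
            continue
        total += 1
        if classes.loc[i, "major_type"] == best_t:
            hits += 1
    return hits / total if total else float("nan")
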