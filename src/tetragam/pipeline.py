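"""End-to-end analysis pipeline and report bundle writer.

Stages: (optional dose calling from signals) -> QC filtering -> dedupe ->
gamete inference -> inheritance estimation -> segregation tests ->
recombination profiling -> linkage mapping -> neighbor-joining tree.
All outputs are plain text (TSV/CSV/JSON/newick) in the output directory;
given a fixed seed the summary is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import calling, diversity, inheritance, linkage, recomb, segregation, sim
from .data import (
    DataError,
    DoseMatrix,
    doses_to_gametes,
    filter_matrix,
    dedupe,
    read_dose_matrix,
    write_dose_matrix,
    write_gamete_matrix,
    write_marker_metadata,
)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "simulate": False,
    "max_marker_missing": 0.10,
    "max_sample_missing": 0.10,
    "dedupe": True,
    "lod_threshold": 5.0,
    "grouping_score": "independence",
    "alpha": 0.05,
    "min_intensity_frac": 0.10,
}


class PipelineError(RuntimeError):
    pass


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s: failed: %s", name, exc)
                raise PipelineError(f"stage {name} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return run

    return wrap


def validate_config(config: dict) -> dict:
    cfg = {**DEFAULTS, **config}
    if not cfg["simulate"]:
        if "signals" in cfg:
            if "controls" not in cfg or "markers" not in cfg:
                raise DataError("signal input requires 'controls' and 'markers' paths")
        elif "dose_matrix" not in cfg or "markers" not in cfg:
            raise DataError(
                "config must set simulate:true or provide 'dose_matrix' and 'markers'"
            )
    for key in ("max_marker_missing", "max_sample_missing"):
        if not 0.0 <= float(cfg[key]) <= 1.0:
            raise DataError(f"{key} outside [0, 1]")
    return cfg


@_stage("load")
def _load(cfg: dict, seed: int) -> DoseMatrix:
    if cfg["simulate"]:
        sim_payload = dict(cfg.get("sim", {"preset": "giant_key"}))
        sim_payload.setdefault("seed", seed)
        scfg = sim.config_from_dict(sim_payload)
        gm = sim.simulate(scfg)
        return sim.make_triploid_doses(gm)
    if "signals" in cfg:
        signals = pd.read_csv(cfg["signals"])
        controls = pd.read_csv(cfg["controls"])
        from .data import read_marker_metadata

        meta = read_marker_metadata(cfg["markers"])
        marker_ids = list(dict.fromkeys(signals["marker_id"]))
        anchors = calling.calibrate_anchors(
            controls, marker_ids, cfg["min_intensity_frac"]
        )
        return calling.call_doses(signals, anchors, meta)
    return read_dose_matrix(cfg["dose_matrix"], cfg["markers"])


def run_pipeline(
    config: dict, out_dir: str | Path, seed: int = 0
) -> dict:
    """Execute the full pipeline; returns the JSON-able summary dict."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    doses = _load(cfg, seed)

    @_stage("filter")
    def do_filter(m):
        return filter_matrix(m, cfg["max_marker_missing"], cfg["max_sample_missing"])

    doses, qc = do_filter(doses)
    if cfg["dedupe"]:

        @_stage("dedupe")
        def do_dedupe(m):
            return dedupe(m)

        doses, qc2 = do_dedupe(doses)
        qc = qc.merged(qc2)

    @_stage("infer")
    def do_infer(m):
        return doses_to_gametes(m)

    gametes = do_infer(doses)

    @_stage("inherit")
    def do_inherit(g):
        return inheritance.estimate_all(g), inheritance.phr_summary(g)

    estimates, phr = do_inherit(gametes)

    @_stage("segtest")
    def do_segtest(g):
        return segregation.distortion_table(g, cfg["alpha"])

    dist_markers, dist_chroms = do_segtest(gametes)

    @_stage("recomb")
    def do_recomb(g):
        return recomb.genome_composition(g), recomb.graphical_genotypes(g)

    composition, ggs = do_recomb(gametes)

    @_stage("map")
    def do_map(g):
        gmap, pw = linkage.build_map(
            g, cfg["lod_threshold"], grouping_score=cfg["grouping_score"]
        )
        meta = {m.marker_id: m for m in g.markers}
        per_lg, synteny, marey = linkage.marey_diagnostics(gmap, meta)
        return gmap, pw, per_lg, synteny, marey

    gmap, pairwise, per_lg, synteny_pct, marey = do_map(gametes)

    @_stage("nj")
    def do_nj(m):
        ids, d = diversity.euclidean_distances(m)
        _, newick = diversity.nj_tree(ids, d)
        return newick

    newick = do_nj(doses)

    @_stage("write")
    def do_write():
        write_dose_matrix(doses, out / "dose_matrix.tsv")
        write_marker_metadata(doses.markers, out / "markers.tsv")
        write_gamete_matrix(gametes, out / "gametes.tsv")
        (out / "qc_report.json").write_text(
            json.dumps(qc.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        phr.per_marker.to_csv(out / "phr_markers.tsv", sep="\t", index=False)
        phr.per_chromosome.to_csv(out / "phr_chromosomes.tsv", sep="\t", index=False)
        inheritance.estimates_table(estimates).to_csv(
            out / "inheritance.tsv", sep="\t", index=False
        )
        dist_markers.to_csv(out / "distortion_markers.tsv", sep="\t", index=False)
        dist_chroms.to_csv(out / "distortion_chromosomes.tsv", sep="\t", index=False)
        composition.per_gamete.to_csv(out / "crossovers.tsv", sep="\t", index=False)
        composition.crossover_distribution.to_csv(
            out / "crossover_distribution.tsv", sep="\t", index=False
        )
        recomb.runs_table(ggs).to_csv(out / "runs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "marker_i": p.marker_i,
                    "marker_j": p.marker_j,
                    "r_hat": p.r_hat,
                    "lod": p.lod,
                    "lod_independence": p.lod_independence,
                    "n_informative": p.n_informative,
                }
                for p in pairwise
            ]
        ).to_csv(out / "pairwise.tsv", sep="\t", index=False)
        meta = {m.marker_id: m for m in gametes.markers}
        gmap.to_frame(meta).to_csv(out / "map.tsv", sep="\t", index=False)
        per_lg.to_csv(out / "map_groups.tsv", sep="\t", index=False)
        marey.to_csv(out / "marey.csv", index=False)
        (out / "tree.nwk").write_text(newick + "\n")

    do_write()

    summary = {
        "seed": seed,
        "n_samples": doses.n_samples,
        "n_markers": doses.n_markers,
        "n_removed_markers": len(qc.removed_markers),
        "n_removed_samples": len(qc.removed_samples),
        "thresholds": qc.thresholds,
        "phr_genome_mean": round(phr.genome_mean, 6),
        "inheritance": [
            {
                "chromosome": e.chromosome,
                "PP": round(e.PP, 6),
                "tau": round(e.tau, 6),
                "beta": None if pd.isna(e.beta) else round(e.beta, 6),
            }
            for e in estimates
        ],
        "distortion": {
            "n_significant_hom_excess": int(
                dist_chroms[["excess_M", "excess_A"]].to_numpy().sum()
            )
            if len(dist_chroms)
            else 0,
        },
        "mean_crossovers_per_gamete": round(composition.mean_crossovers, 6),
        "genome_fractions": {
            "het": round(composition.mean_frac_het, 6),
            "M_hom": round(composition.mean_frac_M_hom, 6),
            "A_hom": round(composition.mean_frac_A_hom, 6),
        },
        "map": {
            "n_linkage_groups": len(gmap.groups),
            "n_unassigned": len(gmap.unassigned),
            "total_length_cM": round(gmap.total_length_cm, 6),
            "synteny_pct": round(synteny_pct, 6),
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
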