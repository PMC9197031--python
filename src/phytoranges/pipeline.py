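"""End-to-end orchestration of the survey analysis.

``run_pipeline`` executes the full workflow: load (or simulate) the survey,
filter rare species, build the presence matrix, cluster, impute the site
table (both strategies run as parallel model tracks by default), select the
group count by the OOB-kappa rule, train the final forest per track, check
the holdout fraction, cross-validate, and extract discriminative ranges,
PDP curves and the substrate table.  Every stage appends a JSON-lines log
entry with its seed and row counts, and all randomness fans out from one
master seed, so any stage can be replayed in isolation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, evaluation, grouping, imputation, ranges, synthetic
from .data_io import ValidationError
from .forest import ForestParams, train_forest

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a run needs; either file paths or a synthetic spec."""

    outdir: str = "phytoranges_out"
    seed: int = 0
    # inputs: paths, or synthetic simulation
    sites_path: str | None = None
    occurrences_path: str | None = None
    synthetic: bool = True
    n_sites: int = 400
    n_species: int = 24
    # filtering; the rarity cutoff scales with survey size (25 of ~1,900
    # sites at full scale; 10 of 400 at the desk default)
    min_sites: int = 10
    aquatic_only: bool = False
    # imputation tracks to run
    imputation_methods: tuple[str, ...] = ("median", "forest")
    imputation_ntree: int = 50
    # model
    ntree: int = 500
    mtry: int = 1
    nodesize: int = 50
    kappa_min: float = 0.3
    train_frac: float = 0.8
    n_folds: int = 10
    k_max: int | None = None
    n_grid: int = 25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if not self.synthetic and (self.sites_path is None or self.occurrences_path is None):
            raise ValidationError("provide sites/occurrences paths or set synthetic=true")
        for m in self.imputation_methods:
            if m not in ("median", "forest"):
                raise ValidationError(f"unknown imputation method {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "imputation_methods" in raw:
            raw["imputation_methods"] = tuple(raw["imputation_methods"])
        return cls(**raw)


class _Log:
    def __init__(self, path: Path):
        self.path = path
        path.write_text("")

    def stage(self, name: str, **info) -> None:
        entry = {"stage": name, "time": time.time(), **info}
        with self.path.open("a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def _child_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "split", "forest", "cv", "imputation", "selection"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and serialise all report files into ``cfg.outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run_log.jsonl")
    seeds = _child_seeds(cfg.seed)
    result: dict = {"seeds": seeds, "outdir": str(out)}

    # ---- load or simulate -------------------------------------------------
    if cfg.synthetic:
        bundle = synthetic.make_survey_bundle(
            seeds["simulate"], n_sites=cfg.n_sites, n_species=cfg.n_species
        )
        sites, occ = bundle.sites, bundle.occurrences
        data_io.write_site_table(sites, out / "sites.csv")
        data_io.write_occurrences(occ, out / "occurrences.csv")
        bundle.truth.save(out / "truth.json")
        log.stage("simulate", seed=seeds["simulate"], n_sites=sites.n_sites,
                  n_records=occ.n_records)
    else:
        sites = data_io.read_site_table(cfg.sites_path)
        occ = data_io.read_occurrences(cfg.occurrences_path)
        occ.validate_sites(sites)
        log.stage("load", n_sites=sites.n_sites, n_records=occ.n_records)

    # ---- filter + presence matrix -----------------------------------------
    pm = data_io.build_presence_matrix(occ, min_sites=cfg.min_sites, aquatic_only=cfg.aquatic_only)
    filtered = pm.to_occurrences()
    data_io.write_with_metadata(
        filtered.records, out / "occurrences_filtered.csv",
        {"min_sites": cfg.min_sites, "aquatic_only": cfg.aquatic_only, "seed": cfg.seed},
    )
    log.stage("filter", n_species=pm.n_species, n_records=pm.n_records)

    # ---- clustering --------------------------------------------------------
    dmat = grouping.jaccard_distances(pm)
    pd.DataFrame(dmat.values, index=dmat.species_ids, columns=dmat.species_ids).to_csv(
        out / "distances.csv"
    )
    dend = grouping.ward_linkage(dmat)
    (out / "dendrogram.json").write_text(
        json.dumps({"species_ids": dend.species_ids, "merges": dend.merges.tolist()})
    )
    log.stage("cluster", n_species=pm.n_species)

    # ---- imputation tracks --------------------------------------------------
    tracks: dict[str, data_io.SiteTable] = {}
    reports = {}
    for method in cfg.imputation_methods:
        if method == "median":
            complete, rep = imputation.impute_median_mode(sites)
        else:
            complete, rep = imputation.impute_iterative_forest(
                sites, ntree=cfg.imputation_ntree, seed=seeds["imputation"]
            )
        tracks[method] = complete
        reports[method] = rep.to_dict()
        log.stage("impute", method=method, imputed=rep.total_imputed(),
                  iterations=rep.iterations, seed=seeds["imputation"])
    (out / "imputation_report.json").write_text(json.dumps(reports, indent=2))

    params = ForestParams(ntree=cfg.ntree, mtry=cfg.mtry, nodesize=cfg.nodesize,
                          seed=seeds["forest"])

    result["tracks"] = {}
    for method, complete in tracks.items():
        track: dict = {}
        suffix = f"_{method}"

        # ---- group-count selection ----------------------------------------
        trace = evaluation.select_n_groups(
            pm, complete, params, kappa_min=cfg.kappa_min, k_max=cfg.k_max,
            train_frac=cfg.train_frac, seed=seeds["selection"],
        )
        trace.to_frame().to_csv(out / f"selection_trace{suffix}.csv", index=False)
        log.stage("select_k", method=method, selected_k=trace.selected_k,
                  reason=trace.reason, seed=seeds["selection"])
        track["selected_k"] = trace.selected_k
        track["selection_reason"] = trace.reason
        if trace.selected_k is None:
            result["tracks"][method] = track
            continue
        k = trace.selected_k

        # ---- final model ----------------------------------------------------
        ga = grouping.cut_dendrogram(dend, k)
        pd.DataFrame(
            sorted(ga.mapping.items()), columns=["species_id", "label"]
        ).to_csv(out / f"groups_k{k}{suffix}.csv", index=False)
        ds = data_io.assemble_model_dataset(pm, complete, ga.mapping)
        train, holdout = evaluation.train_holdout_split(
            ds, train_frac=cfg.train_frac, seed=seeds["split"]
        )
        forest = train_forest(train, params)
        oob = evaluation.evaluate_forest_oob(forest, train)
        ho = evaluation.evaluate_predictions(
            holdout.y, forest.predict(holdout.X), labels=forest.classes
        )
        passed, deltas = evaluation.holdout_check(oob, ho)
        log.stage("train", method=method, k=k, oob=oob, holdout=ho,
                  holdout_check=passed, seed=seeds["forest"])
        track.update(oob=oob, holdout=ho, holdout_check=passed, holdout_deltas=deltas)

        # ---- cross-validation ------------------------------------------------
        cv = evaluation.kfold_cv(ds, params, n_folds=cfg.n_folds, seed=seeds["cv"])
        track["cv"] = {k_: v for k_, v in cv.items() if k_ not in ("folds", "fold_of")}
        log.stage("cv", method=method, **track["cv"])

        # ---- ranges, PDPs, substrate table ----------------------------------
        summary = ranges.discriminative_ranges(forest)
        summary.to_frame().to_csv(out / f"ranges{suffix}.csv")
        pdps = {
            var: ranges.partial_dependence(forest, ds, var, n_grid=cfg.n_grid)
            for var in forest.schema.continuous_names()
        }
        for var, curve in pdps.items():
            curve.to_frame().to_csv(out / f"pdp_{var}{suffix}.csv", index=False)
        sub = ranges.substrate_top_group(forest, ds)
        sub.to_csv(out / f"substrate_groups{suffix}.csv", index=False)
        report = ranges.range_overlay_report(summary, pdps)
        track["ranges"] = summary.to_frame()
        track["substrate_groups"] = sub
        track["overlay_report_vars"] = sorted(report)
        log.stage("ranges", method=method,
                  root_counts={v: int(c) for v, c in summary.table["count"].items()})
        result["tracks"][method] = track

    metrics = {
        m: {k_: v for k_, v in t.items()
            if k_ in ("selected_k", "selection_reason", "oob", "holdout",
                      "holdout_check", "holdout_deltas", "cv")}
        for m, t in result["tracks"].items()
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=str))
    return result
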