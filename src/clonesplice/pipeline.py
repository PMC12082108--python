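"""End-to-end pipeline driver: simulate -> dynamics -> phylo -> splice.

Given a :class:`PipelineConfig`, runs the selected stages in order on a
synthetic dual-clone dataset, writes every intermediate file in the
package's formats, and emits a JSON report with per-stage outputs, library
versions, the seed and runtimes.  Identical inputs and seed give
byte-identical analytic outputs (the report's runtimes are the only
non-deterministic values).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .dynamics import colony_enrichment_test, detect_inversion, fit_competition_model
from .errors import CloneSpliceError, InputError
from .phylo import build_clone_tree, cluster_colonies, date_acquisition, estimate_mutation_rate
from .splice import dpsi_table, events_from_junctions, filter_events, psi_table, \
    pseudobulk_by_genotype, annotate_consequence
from .synth import SimulationConfig, simulate_clonal_trajectories, simulate_colonies, \
    simulate_junction_counts

ALL_STAGES = ("simulate", "dynamics", "phylo", "splice")


@dataclass
class PipelineConfig:
    """Paths, seed and per-module parameter blocks for one pipeline run."""

    outdir: str
    seed: int
    stages: tuple = ALL_STAGES
    sim: dict = field(default_factory=dict)       # SimulationConfig overrides
    n_boot: int = 50
    min_coverage: int = 10
    common_threshold: float = 2.0
    bias_threshold: float = 2.0
    colony_month: float = 23.0                    # visit matched to colony assays
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return (and write) the JSON report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    sim_cfg = SimulationConfig.from_mapping({"seed": seed, **config.sim})
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise InputError(f"unknown stages: {sorted(unknown)}")

    report: dict = {
        "versions": {"clonesplice": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    state: dict = {}

    def stage(name):
        return name in config.stages

    if stage("simulate"):
        t0 = time.perf_counter()
        series, traj_truth = simulate_clonal_trajectories(sim_cfg)
        meta, matrix, colony_truth = simulate_colonies(sim_cfg)
        table, annotation, event_truth = simulate_junction_counts(sim_cfg)
        cio.write_vaf_csv(series, outdir / "vaf.csv", seed=seed)
        cio.write_colony_table(meta, outdir / "colonies.tsv", seed=seed)
        cio.write_mutation_matrix(matrix, outdir / "mutation_matrix.tsv", seed=seed)
        cio.write_junction_counts(table, outdir / "junctions", seed=seed)
        cio.write_gtf(annotation, outdir / "annotation.gtf", seed=seed)
        traj_truth.colony_clones = colony_truth.colony_clones
        traj_truth.acquisition_times = colony_truth.acquisition_times
        traj_truth.trunk_mutations = colony_truth.trunk_mutations
        traj_truth.events = event_truth.events
        traj_truth.event_defs = event_truth.event_defs
        traj_truth.to_json(outdir / "truth.json")
        state.update(series=series, meta=meta, matrix=matrix, table=table,
                     annotation=annotation, truth=traj_truth)
        report["stages"]["simulate"] = {
            "runtime_s": round(time.perf_counter() - t0, 3),
            "outputs": ["vaf.csv", "colonies.tsv", "mutation_matrix.tsv",
                        "junctions.mtx", "annotation.gtf", "truth.json"],
            "n_series": len(series), "n_colonies": len(meta),
            "n_cells": len(table.counts),
        }
    else:
        state["series"] = cio.read_vaf_csv(outdir / "vaf.csv")
        state["meta"] = cio.read_colony_table(outdir / "colonies.tsv")
        state["matrix"] = cio.read_mutation_matrix(outdir / "mutation_matrix.tsv")
        state["table"] = cio.read_junction_counts(outdir / "junctions")
        state["annotation"] = cio.read_gtf(outdir / "annotation.gtf")

    if stage("dynamics"):
        t0 = time.perf_counter()
        series = state["series"]
        fit = fit_competition_model(series, detection_limit=sim_cfg.detection_limit,
                                    n_boot=config.n_boot, seed=seed)
        inversion = detect_inversion(series[0], series[1]) if len(series) >= 2 else None
        # colony enrichment: null = 2 x bulk VAF at the matched visit
        enrich = []
        meta = state["meta"]
        for comp, sub in meta.groupby("compartment"):
            for s in series:
                idx = int(np.argmin(np.abs(s.times - config.colony_month)))
                p0 = min(1.0, 2.0 * s.vaf[idx])
                k = int((sub["clone"] == s.variant_id).sum()) if "clone" in sub else \
                    int(sub[s.variant_id].sum())
                res = colony_enrichment_test(k, len(sub), p0, "two-sided", compartment=comp)
                enrich.append({"compartment": comp, "variant": s.variant_id,
                               "k": res.k_clone, "n": res.n_total,
                               "expected_fraction": res.expected_fraction,
                               "p_value": res.p_value})
        dyn = {
            "variants": list(fit.variants),
            "selection_coeffs": fit.selection_coeffs,
            "selection_stderr": fit.selection_stderr,
            "initial_fractions": fit.initial_fractions,
            "residual_rms_vaf": fit.residual,
            "inversion_month": inversion,
            "colony_enrichment": enrich,
        }
        cio.write_json_report(dyn, outdir / "dynamics.json", seed=seed)
        state["fit"] = fit
        report["stages"]["dynamics"] = {
            "runtime_s": round(time.perf_counter() - t0, 3),
            "outputs": ["dynamics.json"],
            "selection_coeffs": {v: float(s) for v, s in
                                 zip(fit.variants, fit.selection_coeffs)},
            "inversion_month": inversion,
        }

    if stage("phylo"):
        t0 = time.perf_counter()
        matrix = state["matrix"]
        clusters = cluster_colonies(matrix)
        tree = build_clone_tree(matrix)
        cio.write_newick(tree, outdir / "clone_tree.nwk")
        burdens = matrix.burdens()
        ages = matrix.age_years
        rate = estimate_mutation_rate(burdens.to_numpy(), ages.to_numpy())
        drivers = [v for v in sim_cfg.variant_ids if v in matrix.matrix.columns]
        intervals = [
            date_acquisition(tree, rate.rate_per_year, d, float(ages.max()))
            for d in drivers
        ]
        cio.write_age_intervals(intervals, outdir / "age_intervals.json", seed=seed)
        state.update(tree=tree, clusters=clusters, rate=rate, intervals=intervals)
        summary = {
            "runtime_s": round(time.perf_counter() - t0, 3),
            "outputs": ["clone_tree.nwk", "age_intervals.json"],
            "n_clones_found": len(clusters.trunks),
            "mutation_rate_per_year": rate.rate_per_year,
            "rate_ci": [rate.ci_low, rate.ci_high],
            "age_intervals": {iv.mutation_id: [iv.lower_bound_years, iv.upper_bound_years]
                              for iv in intervals},
        }
        if "truth" in state and state["truth"].colony_clones:
            truth_lab = pd.Series(state["truth"].colony_clones)
            # map found clone labels to truth variants by majority vote
            correct = 0
            for label, trunk in clusters.trunks.items():
                members = clusters.assignments[clusters.assignments == label].index
                if len(members) == 0:
                    continue
                majority = truth_lab[members].mode()[0]
                correct += int((truth_lab[members] == majority).sum())
            correct += int((truth_lab[clusters.assignments[
                clusters.assignments == "WT"].index] == "WT").sum())
            summary["clone_assignment_accuracy"] = correct / len(clusters.assignments)
        report["stages"]["phylo"] = summary

    if stage("splice"):
        t0 = time.perf_counter()
        table, annotation = state["table"], state["annotation"]
        grouped = pseudobulk_by_genotype(table)
        events = events_from_junctions(grouped, annotation)
        psis = psi_table(events, grouped, min_coverage=config.min_coverage)
        records = dpsi_table(psis)
        records = filter_events(records, config.common_threshold, config.bias_threshold)
        cons = {e.event_id: annotate_consequence(e, annotation) for e in events}
        records["consequence"] = [cons[e] for e in records.index]
        with open(outdir / "psi.tsv", "w") as fh:
            fh.write(cio._header("psi", seed))
            psis.psi.round(6).to_csv(fh, sep="\t")
        with open(outdir / "dpsi.tsv", "w") as fh:
            fh.write(cio._header("dpsi", seed))
            records.round(6).to_csv(fh, sep="\t")
        summary = {
            "runtime_s": round(time.perf_counter() - t0, 3),
            "outputs": ["psi.tsv", "dpsi.tsv"],
            "n_events": len(events),
            "classification_counts": records["classification"].value_counts().to_dict(),
        }
        if "truth" in state and state["truth"].event_defs:
            defs = state["truth"].event_defs
            truth_by_key = {tuple(sorted(d["inclusion"])): d["truth_label"]
                            for d in defs.values()}
            hits = biased_total = biased_found = common_total = common_as_biased = 0
            for e in events:
                lab = truth_by_key.get(tuple(sorted(e.inclusion)))
                if lab is None:
                    continue
                call = records.at[e.event_id, "classification"]
                if lab in ("A-biased", "B-biased"):
                    biased_total += 1
                    biased_found += int(call == lab)
                elif lab == "common":
                    common_total += 1
                    common_as_biased += int(call in ("A-biased", "B-biased"))
                hits += int(call == lab)
            summary["truth_recovery"] = {
                "matched_events": len(events),
                "label_accuracy": hits / max(1, len(events)),
                "biased_sensitivity": biased_found / max(1, biased_total),
                "common_mislabel_rate": common_as_biased / max(1, common_total),
            }
        report["stages"]["splice"] = summary

    cio.write_json_report(report, outdir / "report.json", seed=seed)
    return report
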