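"""End-to-end orchestration from a single YAML config.

``run_all`` executes atlas -> trajectories -> gene_link -> binding in order,
entirely from plain-text inputs (peak BEDs, bedGraph tracks, expression TSV,
annotation TSV, factor list, site BEDs, GMT gene sets). A synthetic section
lets one command generate the whole study first and then analyse it, which is
the standard smoke run. All randomness is seeded from ``seed``; re-running
with the same config yields byte-identical outputs apart from the report
timestamp.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import json
import time
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import atlas as atlas_mod
from . import binding as binding_mod
from . import core_io
from . import gene_link
from . import synthetic_data
from . import trajectories as traj_mod

DEFAULT_CONFIG: dict[str, Any] = {
    "stages": list(synthetic_data.DEFAULT_STAGES),
    "conditions": list(synthetic_data.DEFAULT_CONDITIONS),
    "baseline_stage": "hiF-T",
    "seed": 42,
    "out_dir": "chromtraj_out",
    "run_stages": {"atlas": True, "trajectories": True, "genes": True,
                   "binding": True},
    "synthetic": {"enabled": True, "overrides": {}},
    "inputs": {"peaks_dir": None, "tracks_dir": None, "chrom_sizes": None,
               "library_totals": None, "annotation": None, "expression": None,
               "factors": None, "gene_sets": None, "sites_dir": None},
    "threshold": {"mode": "calibrate", "value": None, "fpr": 0.01},
    "atlas": {"gap_bp": 100},
    "quantify": {"log_base": 2, "pseudocount": 1.0},
    "cluster": {"c": 10, "m": 2.0, "tol": 1e-6, "max_iter": 500,
                "funnel_cluster": "C1"},
    "criteria": {
        "up": {"min_fold": 5.0, "max_p": 1e-4, "min_fpkm": 5.0},
        "de": {"min_fold": 2.0, "max_q": 0.05},
    },
    "genes": {"max_dist_bp": 10_000, "condition": "naive"},
    "binding": {"max_dist_bp": 10_000, "min_fpkm": 1.0, "method": "pearson",
                "condition": "naive",
                "isoform_genes": {"alpha": "ISO_alpha", "beta": "ISO_beta"},
                "nominations": [
                    {"isoform": "alpha", "sign": "positive",
                     "gene_set": "EMT_LIKE"},
                    {"isoform": "beta", "sign": "negative",
                     "gene_set": "PROLIFERATION_NEG"},
                ]},
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _merge(defaults: Any, user: Any, path: str, errors: list[str],
           open_keys: bool = False) -> Any:
    """Fill defaults, reject unknown keys (with a suggestion), recurse."""
    if isinstance(defaults, dict) and isinstance(user, dict):
        out = {}
        free = open_keys or path in ("synthetic.overrides",
                                     "binding.isoform_genes")
        for key in user:
            if key not in defaults and not free:
                hint = difflib.get_close_matches(key, list(defaults), n=1)
                msg = f"unknown key {path + '.' if path else ''}{key}"
                if hint:
                    msg += f" (did you mean {hint[0]!r}?)"
                errors.append(msg)
        keys = list(defaults) + [k for k in user if k not in defaults and free]
        for key in keys:
            sub_path = f"{path}.{key}" if path else key
            if key in user and key in defaults:
                out[key] = _merge(defaults[key], user[key], sub_path, errors,
                                  open_keys=free)
            elif key in user:
                out[key] = copy.deepcopy(user[key])
            else:
                out[key] = copy.deepcopy(defaults[key])
        return out
    return copy.deepcopy(user)


def validate_config(source: str | Path | dict[str, Any]) -> dict[str, Any]:
    """Normalise a config (YAML path or dict); raise ConfigError on problems."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = source
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, user, "", errors)
    # nominations is a free-form list
    if cfg["baseline_stage"] not in cfg["stages"]:
        errors.append("baseline_stage: must be one of stages")
    elif cfg["stages"][0] != cfg["baseline_stage"]:
        errors.append("stages: the baseline stage must come first")
    fpr = cfg["threshold"]["fpr"]
    if not (isinstance(fpr, (int, float)) and 0 < fpr < 1):
        errors.append("threshold.fpr: must lie in (0, 1)")
    if cfg["threshold"]["mode"] not in ("calibrate", "fixed"):
        errors.append("threshold.mode: must be 'calibrate' or 'fixed'")
    if cfg["threshold"]["mode"] == "fixed" and cfg["threshold"]["value"] is None:
        errors.append("threshold.value: required when mode is 'fixed'")
    if cfg["cluster"]["c"] < 1:
        errors.append("cluster.c: must be >= 1")
    if not cfg["synthetic"]["enabled"]:
        for key in ("peaks_dir", "tracks_dir", "chrom_sizes", "annotation",
                    "expression", "factors"):
            if cfg["inputs"][key] is None:
                errors.append(f"inputs.{key}: required when synthetic.enabled "
                              "is false")
    if errors:
        raise ConfigError(errors)
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable digest of the analysis parameters (output location excluded)."""
    payload = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _read_library_totals(path: Path | None) -> dict[str, float]:
    if path is None or not Path(path).exists():
        return {}
    out = {}
    with open(path) as fh:
        for line in fh:
            name, total = line.split("\t")
            out[name] = float(total)
    return out


def run_all(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    """Run the configured stages end to end; returns the run report."""
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    conditions = list(cfg["conditions"])
    rng = np.random.default_rng(cfg["seed"])
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages_run": [],
        "counts": {},
        "warnings": [],
        "outputs": [],
        "skipped": [],
        "error": None,
    }
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def emit(name: str) -> Path:
        path = out_dir / name
        report["outputs"].append(str(path))
        return path

    def record_warnings(caught) -> None:
        for w in caught:
            report["warnings"].append(str(w.message))

    current = "setup"
    try:
        inputs = dict(cfg["inputs"])
        if cfg["synthetic"]["enabled"]:
            current = "simulate"
            overrides = dict(cfg["synthetic"]["overrides"])
            study_cfg = synthetic_data.StudyConfig(
                stages=tuple(stages), conditions=tuple(conditions),
                seed=cfg["seed"], **overrides)
            study = synthetic_data.simulate_study(study_cfg)
            sim_dir = out_dir / "sim"
            synthetic_data.write_study(study, sim_dir)
            inputs = {
                "peaks_dir": sim_dir / "peaks",
                "tracks_dir": sim_dir / "tracks",
                "chrom_sizes": sim_dir / "chrom.sizes",
                "library_totals": sim_dir / "tracks" / "library_totals.tsv",
                "annotation": sim_dir / "annotation.tsv",
                "expression": sim_dir / "expression.tsv",
                "factors": sim_dir / "factors.txt",
                "gene_sets": sim_dir / "gene_sets.gmt",
                "sites_dir": sim_dir / "sites",
            }
            report["stages_run"].append("simulate")
            log(f"simulated study with {len(study.atlas)} regions -> "
                f"{sim_dir.name}/")

        # ---------------- atlas ----------------
        threshold = None
        matrices: dict[str, atlas_mod.SignalMatrix] = {}
        region_atlas = None
        if cfg["run_stages"]["atlas"]:
            current = "atlas"
            peak_sets, sources = [], []
            for cond in conditions:
                for stage in stages:
                    p = Path(inputs["peaks_dir"]) / f"{cond}_{stage}.bed"
                    if p.exists():
                        peak_sets.append(core_io.parse_bed(p))
                        sources.append(str(p))
            region_atlas = atlas_mod.build_atlas(
                peak_sets, gap_bp=cfg["atlas"]["gap_bp"], sources=sources)
            core_io.write_bed(region_atlas.regions, emit("atlas.bed"))
            chrom_sizes = {}
            with open(inputs["chrom_sizes"]) as fh:
                for line in fh:
                    chrom, size = line.split("\t")
                    chrom_sizes[chrom] = int(size)
            pseudo_regions = atlas_mod.make_pseudo_input(
                region_atlas, chrom_sizes, rng)
            lib_totals = _read_library_totals(inputs.get("library_totals"))
            pseudo_values: list[np.ndarray] = []
            for cond in conditions:
                tracks = {}
                for stage in stages:
                    name = f"{cond}_{stage}"
                    tracks[stage] = core_io.parse_bedgraph(
                        Path(inputs["tracks_dir"]) / f"{name}.bedGraph",
                        library_total=lib_totals.get(name))
                matrices[cond] = atlas_mod.quantify_matrix(
                    region_atlas, tracks, cond, stages,
                    pseudocount=cfg["quantify"]["pseudocount"],
                    log_base=cfg["quantify"]["log_base"])
                matrices[cond].values.to_csv(emit(f"signal_{cond}.tsv"),
                                             sep="\t", float_format="%.5f")
                for stage in stages:
                    pseudo_values.append(atlas_mod.quantify(
                        pseudo_regions, tracks[stage],
                        pseudocount=cfg["quantify"]["pseudocount"],
                        log_base=cfg["quantify"]["log_base"]))
            pooled = np.concatenate(pseudo_values)
            if cfg["threshold"]["mode"] == "fixed":
                threshold = atlas_mod.OpenThreshold(
                    value=float(cfg["threshold"]["value"]),
                    target_fpr=cfg["threshold"]["fpr"], source="fixed",
                    log_base=cfg["quantify"]["log_base"])
            else:
                threshold = atlas_mod.calibrate_threshold(
                    pooled, target_fpr=cfg["threshold"]["fpr"],
                    log_base=cfg["quantify"]["log_base"])
            exceed = float((pooled > threshold.value).mean())
            with open(emit("threshold.json"), "w") as fh:
                json.dump({"value": threshold.value, "target_fpr":
                           threshold.target_fpr, "source": threshold.source,
                           "pseudo_n": int(pooled.size),
                           "pseudo_exceedance": exceed}, fh, indent=1)
            report["counts"]["atlas_size"] = len(region_atlas)
            report["counts"]["pseudo_exceedance"] = exceed
            report["stages_run"].append("atlas")
            log(f"atlas: {len(region_atlas)} regions; threshold "
                f"{threshold.value:.3f} ({threshold.source})")
        else:
            report["skipped"].append("atlas")

        # ---------------- trajectories ----------------
        traj: dict[str, pd.DataFrame] = {}
        clusters = None
        if cfg["run_stages"]["trajectories"] and matrices:
            current = "trajectories"
            call_frames = []
            for cond in conditions:
                calls = traj_mod.binarize(matrices[cond], threshold)
                traj[cond] = traj_mod.classify_matrix(calls, cond)
                call_frames.append(traj[cond].reset_index())
                report["counts"][f"classes_{cond}"] = traj_mod.class_counts(
                    traj[cond])
                traj_mod.stage_counts(traj[cond], stages).to_csv(
                    emit(f"stage_counts_{cond}.tsv"), sep="\t")
            pd.concat(call_frames).to_csv(emit("trajectory_calls.tsv"),
                                          sep="\t", index=False)
            if len(conditions) >= 2:
                a, b = conditions[0], conditions[1]
                venn = {}
                for klass in ("PO", "CO", "OC"):
                    iv_a = [region_atlas.regions[i] for i, rid in
                            enumerate(traj[a].index) if traj[a]["class"][rid] == klass]
                    iv_b = [region_atlas.regions[i] for i, rid in
                            enumerate(traj[b].index) if traj[b]["class"][rid] == klass]
                    if iv_a and iv_b:
                        v = core_io.intersect_counts(iv_a, iv_b)
                        venn[klass] = asdict(v)
                    else:
                        venn[klass] = {"a_only": len(iv_a), "b_only": len(iv_b),
                                       "shared_a": 0, "shared_b": 0}
                with open(emit("venn_conditions.json"), "w") as fh:
                    json.dump(venn, fh, indent=1)
                report["counts"]["condition_venn"] = venn
                for klass in ("CO", "OC"):
                    mat, excl = traj_mod.co_occurrence(traj[a], traj[b],
                                                       klass, stages)
                    mat.to_csv(emit(f"co_occurrence_{klass}.tsv"), sep="\t")
                    report["counts"][f"co_occurrence_{klass}_total"] = int(
                        mat.to_numpy().sum())
                    if excl:
                        report["warnings"].append(
                            f"co-occurrence {klass}: {excl} regions lacked a "
                            "switch stage and were excluded")
            transient_ids = sorted(
                set().union(*[traj[c].index[traj[c]["class"] == "TRANSIENT"]
                              for c in conditions]))
            if len(transient_ids) >= cfg["cluster"]["c"]:
                sig = {c: matrices[c].values.loc[transient_ids]
                       for c in conditions}
                clusters = traj_mod.cluster_transient(
                    sig, c=cfg["cluster"]["c"], m=cfg["cluster"]["m"],
                    seed=rng, tol=cfg["cluster"]["tol"],
                    max_iter=cfg["cluster"]["max_iter"])
                clusters.membership.to_csv(emit("cluster_membership.tsv"),
                                           sep="\t", float_format="%.12g")
                categories = traj_mod.categorize_clusters(clusters)
                with open(emit("cluster_categories.json"), "w") as fh:
                    json.dump(categories, fh, indent=1)
                report["counts"]["n_transient_clustered"] = len(transient_ids)
                report["counts"]["cluster_categories"] = categories
            else:
                report["warnings"].append(
                    f"only {len(transient_ids)} transient regions; "
                    "clustering skipped")
            report["stages_run"].append("trajectories")
            log("trajectories classified")
        else:
            report["skipped"].append("trajectories")

        # ---------------- genes ----------------
        expression = None
        annotation = None
        upregulated: list[str] = []
        if cfg["run_stages"]["genes"] and traj:
            current = "genes"
            annotation = core_io.read_annotation(inputs["annotation"])
            expression = gene_link.ExpressionTable.from_tsv(inputs["expression"])
            factors = gene_link.read_factor_list(inputs["factors"])
            cond = cfg["genes"]["condition"]
            links = {ln.region.region_id: ln.gene_id for ln in
                     core_io.nearest_tss(region_atlas.regions, annotation,
                                         cfg["genes"]["max_dist_bp"])}
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                stats_df = gene_link.class_expression_stats(
                    links, traj[cond]["class"], expression, cond,
                    baseline=cfg["baseline_stage"])
                stats_df.to_csv(emit("class_expression_stats.tsv"), sep="\t",
                                index=False)
                crit = cfg["criteria"]["up"]
                upregulated = gene_link.upregulated_genes(
                    expression,
                    gene_link.UpregulationCriteria(
                        min_fold_vs_baseline=crit["min_fold"],
                        max_p=crit["max_p"], min_fpkm=crit["min_fpkm"],
                        baseline_stage=cfg["baseline_stage"]),
                    condition=cond)
            record_warnings(caught)
            with open(emit("upregulated.txt"), "w") as fh:
                fh.write("\n".join(upregulated) + "\n")
            co_ids = set(traj[cond].index[traj[cond]["class"] == "CO"])
            if clusters is not None and cfg["cluster"]["funnel_cluster"]:
                want = cfg["cluster"]["funnel_cluster"]
                if want in clusters.membership.columns:
                    hard = clusters.hard_assignment()
                    ci = list(clusters.membership.columns).index(want)
                    co_ids |= set(hard.index[hard == ci])
            funnel_regions = [region_atlas.regions[i] for i, rid in
                              enumerate(region_atlas.region_ids)
                              if rid in co_ids]
            switch_map = traj[cond]["switch_stage"].to_dict()
            funnel = gene_link.candidate_funnel(
                funnel_regions, annotation, upregulated, factors,
                switch_stage_by_region=switch_map,
                max_dist_bp=cfg["genes"]["max_dist_bp"])
            funnel.candidates.to_csv(emit("candidates.tsv"), sep="\t",
                                     index=False)
            groups = gene_link.group_patterns(
                list(funnel.candidates["gene_id"]), expression, cond,
                baseline=cfg["baseline_stage"])
            with open(emit("funnel.json"), "w") as fh:
                json.dump({"n_linked": funnel.n_linked,
                           "n_upregulated_linked": funnel.n_upregulated_linked,
                           "n_candidates": funnel.n_candidates,
                           "groups": groups}, fh, indent=1)
            report["counts"]["funnel"] = {
                "n_linked": funnel.n_linked,
                "n_upregulated_linked": funnel.n_upregulated_linked,
                "n_candidates": funnel.n_candidates}
            report["stages_run"].append("genes")
            log(f"funnel: {funnel.n_linked} linked -> "
                f"{funnel.n_upregulated_linked} upregulated -> "
                f"{funnel.n_candidates} candidates")
        else:
            report["skipped"].append("genes")

        # ---------------- binding ----------------
        if cfg["run_stages"]["binding"] and inputs.get("sites_dir") and \
                expression is not None:
            current = "binding"
            site_sets = {}
            for iso, iso_gene in cfg["binding"]["isoform_genes"].items():
                p = Path(inputs["sites_dir"]) / f"{iso}.bed"
                if not p.exists():
                    continue
                raw = core_io.parse_bed(p)
                scores = np.array([iv.score if iv.score is not None else
                                   np.inf for iv in raw])
                site_sets[iso] = binding_mod.call_sites(
                    raw, scores, threshold, iso)
            if len(site_sets) == 2:
                iso_a, iso_b = sorted(site_sets)
                venn = binding_mod.binding_venn(site_sets[iso_a],
                                                site_sets[iso_b])
                with open(emit("binding_venn.json"), "w") as fh:
                    json.dump(asdict(venn), fh, indent=1)
                report["counts"]["binding_venn"] = asdict(venn)
            gene_sets = (binding_mod.read_gmt(inputs["gene_sets"])
                         if inputs.get("gene_sets") else {})
            nominations = {}
            for iso, sites in site_sets.items():
                targets = binding_mod.assign_targets(
                    sites, annotation, expression,
                    max_dist_bp=cfg["binding"]["max_dist_bp"],
                    min_fpkm=cfg["binding"]["min_fpkm"])
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    summary = binding_mod.classify_correlation(
                        targets, cfg["binding"]["isoform_genes"][iso],
                        expression, condition=cfg["binding"]["condition"],
                        method=cfg["binding"]["method"])
                record_warnings(caught)
                summary.targets.to_csv(emit(f"targets_{iso}.tsv"), sep="\t",
                                       index=False, float_format="%.4f")
                report["counts"][f"targets_{iso}"] = {
                    "n": len(summary.targets),
                    "positive_fraction": summary.positive_fraction,
                    "n_excluded": summary.n_excluded}
                for nom in cfg["binding"]["nominations"]:
                    if nom["isoform"] != iso or nom["gene_set"] not in gene_sets:
                        continue
                    nominations[f"{iso}:{nom['sign']}:{nom['gene_set']}"] = \
                        binding_mod.nominate(summary, nom["sign"],
                                             gene_sets[nom["gene_set"]])
            with open(emit("nominations.json"), "w") as fh:
                json.dump(nominations, fh, indent=1)
            report["counts"]["nominations"] = nominations
            report["stages_run"].append("binding")
            log("binding analysed")
        else:
            report["skipped"].append("binding")

    except Exception as exc:  # partial progress is still reported
        report["error"] = {"stage": current, "message": str(exc)}
        _write_report(report, log_lines, out_dir)
        raise StageFailure(current, exc) from exc

    _write_report(report, log_lines, out_dir)
    return report


def _write_report(report: dict[str, Any], log_lines: list[str],
                  out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
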