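"""Synthetic reprogramming study with machine-readable planted ground truth.

Emulates the design of a two-condition (naive, primed) seven-stage
reprogramming time course: a region atlas with planted PO/CO/OC/NEVER/
TRANSIENT accessibility trajectories on a log2 Gaussian signal model, a
matched pseudo-input background sample, replicate-level FPKM expression
coupled to nearby-region accessibility, a curated factor list with planted
upregulated candidates, and two isoform binding-site sets with planted
positively/negatively correlated target genes. Every planted fact is recorded
in a GroundTruth object so each downstream stage can be scored exactly.

Defaults follow the study design: stages hiF-T, d6, d8, d14, d20, d24, iPSC;
three expression replicates per (condition, stage); open/closed log2 signal
means 6.0/2.0 with sd 0.7, which puts the 1%-FPR calibrated cutoff near 4.2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, SignalMatrix
from .binding import BindingSiteSet, write_gmt
from .core_io import (
    GeneAnnotation,
    GenomicInterval,
    SignalTrack,
    write_annotation,
    write_bed,
    write_bedgraph,
)
from .gene_link import ExpressionTable

DEFAULT_STAGES = ("hiF-T", "d6", "d8", "d14", "d20", "d24", "iPSC")
DEFAULT_CONDITIONS = ("naive", "primed")


@dataclass
class StudyConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    stages: tuple[str, ...] = DEFAULT_STAGES
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_per_class: dict[str, int] = field(default_factory=lambda: {
        "PO": 400, "CO": 400, "OC": 400, "NEVER": 400, "TRANSIENT": 400})
    # log2 signal model
    open_mean: float = 6.0
    open_sd: float = 0.7
    closed_mean: float = 2.0
    closed_sd: float = 0.7
    n_pseudo: int = 10_000
    # geometry
    region_length: int = 500
    region_spacing: int = 1500
    # expression
    n_linked_genes: int = 300       # one gene per region, first n regions
    n_unlinked_genes: int = 50
    replicates: int = 3
    expr_baseline_log2: float = 3.0
    expr_baseline_sd: float = 1.0
    expr_noise_sd: float = 0.5
    coupling: float = 1.0
    # forced-upregulated plants (the funnel's true positives)
    n_forced_up: int = 10
    forced_fold: float = 50.0
    forced_baseline_fpkm: float = 2.0
    forced_noise_sd: float = 0.01
    n_factor_decoys: int = 20
    # binding
    n_targets: dict[str, int] = field(default_factory=lambda: {
        "alpha": 150, "beta": 60})
    n_shared_sites: int = 20
    positive_fraction: dict[str, float] = field(default_factory=lambda: {
        "alpha": 0.8, "beta": 0.2})
    low_fpkm_fraction: float = 0.05
    corr_amplitude: float = 2.0
    corr_noise_sd: float = 0.1
    site_length: int = 400
    binding_gene_spacing: int = 30_000
    seed: int = 42

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if all(v == 0 for v in self.n_per_class.values()):
            raise ValueError("at least one trajectory class count must be > 0")
        if self.open_mean <= self.closed_mean:
            raise ValueError("open-state mean must exceed closed-state mean")
        for k, f in self.positive_fraction.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"positive_fraction[{k}] must lie in [0, 1]")
        if not (0.0 <= self.low_fpkm_fraction <= 1.0):
            raise ValueError("low_fpkm_fraction must lie in [0, 1]")
        if len(self.stages) < 3:
            raise ValueError("need >= 3 stages")

    @property
    def n_regions(self) -> int:
        return sum(self.n_per_class.values())

    @property
    def chrom_sizes(self) -> dict[str, int]:
        n_bind = sum(self.n_targets.values()) + self.n_shared_sites
        return {
            "chr1": 10_000 + self.n_regions * self.region_spacing + 100_000,
            "chrU": 10_000 + self.n_unlinked_genes * 5_000 + 50_000,
            "chrB": 100_000 + (n_bind + 2) * self.binding_gene_spacing + 50_000,
        }


@dataclass
class GroundTruth:
    """Everything planted, keyed the way downstream calls report it."""

    region_class: dict[str, dict[str, str]]            # condition -> region_id -> class
    switch_stage: dict[str, dict[str, str | None]]     # condition -> region_id -> stage
    upregulated: list[str]
    pattern_group: dict[str, int]
    target_sign: dict[str, dict[str, str]]             # isoform -> gene -> sign
    low_expression_targets: dict[str, list[str]]       # isoform -> genes below FPKM 1

    def class_counts(self, condition: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for klass in self.region_class[condition].values():
            out[klass] = out.get(klass, 0) + 1
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticStudy:
    config: StudyConfig
    atlas: RegionAtlas
    signals: dict[str, SignalMatrix]                   # condition -> matrix
    true_states: dict[str, pd.DataFrame]               # condition -> bool frame
    pseudo_values: np.ndarray
    annotation: list[GeneAnnotation]
    links: dict[str, str]                              # region_id -> gene_id
    expression: ExpressionTable
    factor_list: list[str]
    gene_sets: dict[str, list[str]]
    binding: dict[str, BindingSiteSet]                 # isoform -> sites
    isoform_genes: dict[str, str]                      # isoform -> gene_id
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# trajectory plants


def _planted_states(klass: str, n_stages: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean open/closed trajectory for one region of one class."""
    if klass == "PO":
        return np.ones(n_stages, dtype=bool)
    if klass == "NEVER":
        return np.zeros(n_stages, dtype=bool)
    if klass == "CO":
        s = int(rng.integers(1, n_stages))
        return np.arange(n_stages) >= s
    if klass == "OC":
        s = int(rng.integers(1, n_stages))
        return np.arange(n_stages) < s
    if klass == "TRANSIENT":
        s1 = int(rng.integers(1, n_stages - 1))
        s2 = int(rng.integers(s1 + 1, n_stages))
        inner = (np.arange(n_stages) >= s1) & (np.arange(n_stages) < s2)
        # open-closed-open or closed-open-closed, equally likely
        return ~inner if rng.random() < 0.5 else inner
    raise ValueError(f"unknown class {klass!r}")


def generate_atlas_signals(config: StudyConfig,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[RegionAtlas, dict[str, SignalMatrix],
                                      dict[str, pd.DataFrame],
                                      np.ndarray, GroundTruth]:
    """Region atlas, per-condition signal matrices and pseudo-input sample.

    Each region's per-stage log2 signal is drawn from the open or closed
    Gaussian according to its planted trajectory; the same class is planted in
    both conditions with independently drawn switch stages. Pseudo-input
    values are drawn from the closed distribution.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_stages = len(config.stages)
    classes: list[str] = []
    for klass in ("PO", "CO", "OC", "NEVER", "TRANSIENT"):
        classes += [klass] * config.n_per_class.get(klass, 0)
    classes_arr = np.array(classes)
    rng.shuffle(classes_arr)

    regions = [
        GenomicInterval("chr1", 10_000 + i * config.region_spacing,
                        10_000 + i * config.region_spacing + config.region_length)
        for i in range(config.n_regions)
    ]
    atlas = RegionAtlas(regions=regions, gap_bp=100, sources=["synthetic"])
    rids = atlas.region_ids

    signals: dict[str, SignalMatrix] = {}
    true_states: dict[str, pd.DataFrame] = {}
    region_class: dict[str, dict[str, str]] = {}
    switch_stage: dict[str, dict[str, str | None]] = {}
    for cond in config.conditions:
        states = np.vstack([
            _planted_states(k, n_stages, rng) for k in classes_arr])
        noise_open = rng.normal(config.open_mean, config.open_sd,
                                size=states.shape)
        noise_closed = rng.normal(config.closed_mean, config.closed_sd,
                                  size=states.shape)
        # log2(CPM+1) signals are nonnegative by construction
        values = np.maximum(np.where(states, noise_open, noise_closed), 0.0)
        signals[cond] = SignalMatrix(
            values=pd.DataFrame(values, index=rids, columns=list(config.stages)),
            condition=cond)
        true_states[cond] = pd.DataFrame(states, index=rids,
                                         columns=list(config.stages))
        region_class[cond] = dict(zip(rids, classes_arr))
        sw: dict[str, str | None] = {}
        for rid, klass, st in zip(rids, classes_arr, states):
            if klass == "CO":
                sw[rid] = config.stages[int(np.argmax(st))]
            elif klass == "OC":
                sw[rid] = config.stages[int(np.argmin(st))]
            else:
                sw[rid] = None
        switch_stage[cond] = sw

    pseudo = np.maximum(
        rng.normal(config.closed_mean, config.closed_sd, size=config.n_pseudo), 0.0)
    gt = GroundTruth(region_class=region_class, switch_stage=switch_stage,
                     upregulated=[], pattern_group={}, target_sign={},
                     low_expression_targets={})
    return atlas, signals, true_states, pseudo, gt


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: StudyConfig, atlas: RegionAtlas,
                        ) -> tuple[list[GeneAnnotation], dict[str, str]]:
    """One gene 300 bp upstream of each of the first n_linked_genes regions,
    plus unlinked decoy genes on a region-free chromosome and the binding
    genes on their own chromosome (targets then the two isoform genes)."""
    genes: list[GeneAnnotation] = []
    links: dict[str, str] = {}
    n_linked = min(config.n_linked_genes, len(atlas))
    for i in range(n_linked):
        region = atlas.regions[i]
        tss = region.start - 300
        gid = f"G{i:04d}"
        genes.append(GeneAnnotation(
            gid, "chr1", "+", tss, GenomicInterval("chr1", tss, tss + 2000),
            features={"5utr": [(tss, tss + 100)],
                      "exon": [(tss, tss + 200), (tss + 1500, tss + 2000)]}))
        links[region.region_id] = gid
    for i in range(config.n_unlinked_genes):
        tss = 10_000 + i * 5_000
        genes.append(GeneAnnotation(
            f"U{i:03d}", "chrU", "+", tss,
            GenomicInterval("chrU", tss, tss + 2000),
            features={"exon": [(tss, tss + 2000)]}))
    # binding target genes and the two isoform genes live on chrB
    k = 0
    for iso in sorted(config.n_targets):
        for j in range(config.n_targets[iso]):
            tss = 100_000 + k * config.binding_gene_spacing
            genes.append(GeneAnnotation(
                f"T{iso[0].upper()}{j:03d}", "chrB", "+", tss,
                GenomicInterval("chrB", tss, tss + 2000),
                features={"exon": [(tss, tss + 2000)]}))
            k += 1
    for j in range(config.n_shared_sites):
        tss = 100_000 + k * config.binding_gene_spacing
        genes.append(GeneAnnotation(
            f"TS{j:03d}", "chrB", "+", tss,
            GenomicInterval("chrB", tss, tss + 2000),
            features={"exon": [(tss, tss + 2000)]}))
        k += 1
    for iso in sorted(config.n_targets):
        tss = 100_000 + k * config.binding_gene_spacing
        genes.append(GeneAnnotation(
            f"ISO_{iso}", "chrB", "+", tss,
            GenomicInterval("chrB", tss, tss + 2000),
            features={"exon": [(tss, tss + 2000)]}))
        k += 1
    return genes, links


# ---------------------------------------------------------------------------
# expression


def generate_expression(config: StudyConfig, ground_truth: GroundTruth,
                        links: Mapping[str, str],
                        signals: Mapping[str, SignalMatrix],
                        annotation: Sequence[GeneAnnotation],
                        rng: np.random.Generator | None = None,
                        ) -> ExpressionTable:
    """Replicate-level FPKM coupled to linked-region accessibility.

    A linked gene's per-stage mean log2 FPKM is its baseline plus
    ``coupling`` times the z-standardised accessibility of its region at that
    stage; replicates add Gaussian noise. ``n_forced_up`` genes linked to CO
    regions are forced to satisfy the upregulation criterion (large fold,
    FPKM above threshold, tiny replicate noise) and flagged in GroundTruth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    gene_ids = [g.gene_id for g in annotation]
    gene_to_region = {g: r for r, g in links.items()}
    columns: list[str] = []
    replicate_map: dict[str, tuple[str, str]] = {}
    for cond in config.conditions:
        for stage in config.stages:
            for r in range(config.replicates):
                col = f"{cond}_{stage}_r{r + 1}"
                columns.append(col)
                replicate_map[col] = (cond, stage)

    baseline = rng.normal(config.expr_baseline_log2, config.expr_baseline_sd,
                          size=len(gene_ids))
    # pick forced-upregulated plants among genes linked to CO regions (naive)
    cond0 = config.conditions[0]
    co_genes = [links[r] for r, k in ground_truth.region_class[cond0].items()
                if k == "CO" and r in links]
    forced = sorted(co_genes)[:config.n_forced_up]
    forced_set = set(forced)

    z_by_cond = {
        cond: _zscore(signals[cond].values) for cond in config.conditions}

    log2 = np.empty((len(gene_ids), len(columns)))
    for gi, gid in enumerate(gene_ids):
        region = gene_to_region.get(gid)
        for ci, col in enumerate(columns):
            cond, stage = replicate_map[col]
            if gid in forced_set:
                level = (config.forced_baseline_fpkm if stage == config.stages[0]
                         else config.forced_baseline_fpkm * config.forced_fold)
                mean = np.log2(level)
                noise_sd = config.forced_noise_sd
            else:
                mean = baseline[gi]
                if region is not None:
                    mean += config.coupling * float(
                        z_by_cond[cond].loc[region, stage])
                noise_sd = config.expr_noise_sd
            log2[gi, ci] = mean + rng.normal(0.0, noise_sd)
    fpkm = pd.DataFrame(np.power(2.0, log2), index=gene_ids, columns=columns)
    ground_truth.upregulated = forced
    ground_truth.pattern_group = {g: 1 for g in forced}
    return ExpressionTable(fpkm=fpkm, replicate_map=replicate_map)


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# binding


def generate_binding(config: StudyConfig, annotation: Sequence[GeneAnnotation],
                     expression: ExpressionTable, ground_truth: GroundTruth,
                     rng: np.random.Generator | None = None,
                     ) -> dict[str, BindingSiteSet]:
    """Two isoform site sets with planted targets and correlation signs.

    The isoform genes get opposite monotone expression profiles (alpha rises,
    beta falls across stages). Each target gene's stage profile is regenerated
    as a line of planted slope sign plus small stage noise, so its Pearson r
    with the isoform profile carries the planted sign at |r| near 1. Shared
    sites (identical intervals in both sets) sit near dedicated shared target
    genes; a configured fraction of targets is written at FPKM < 1 to
    exercise the expression filter.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    total_targets = sum(config.n_targets.values()) + config.n_shared_sites
    if total_targets > len(annotation):
        raise ValueError("requested binding targets exceed available genes")
    by_id = {g.gene_id: g for g in annotation}
    stages = list(config.stages)
    t = np.linspace(-1.0, 1.0, len(stages))
    direction = {"alpha": 1.0, "beta": -1.0}
    isoforms = sorted(config.n_targets)

    def set_profile(gid: str, profile_log2: np.ndarray, noise_sd: float) -> None:
        for cond in config.conditions:
            for si, stage in enumerate(stages):
                for col in expression.replicates(cond, stage):
                    expression.fpkm.loc[gid, col] = float(
                        2.0 ** (profile_log2[si] + rng.normal(0.0, noise_sd)))

    # isoform expression: opposite monotone ramps
    for iso in isoforms:
        gid = f"ISO_{iso}"
        set_profile(gid, config.expr_baseline_log2
                    + direction.get(iso, 1.0) * config.corr_amplitude * t, 0.02)

    sets: dict[str, BindingSiteSet] = {}
    target_sign: dict[str, dict[str, str]] = {iso: {} for iso in isoforms}
    low_expr: dict[str, list[str]] = {iso: [] for iso in isoforms}

    def make_site(gene_id: str) -> GenomicInterval:
        g = by_id[gene_id]
        return GenomicInterval(g.chrom, g.tss + 2000,
                               g.tss + 2000 + config.site_length,
                               name=gene_id)

    shared_genes = [f"TS{j:03d}" for j in range(config.n_shared_sites)]
    shared_sites = [make_site(g) for g in shared_genes]
    # shared targets: slope sign assigned against alpha's direction
    for g in shared_genes:
        pos_for_alpha = rng.random() < config.positive_fraction.get("alpha", 0.5)
        slope = config.corr_amplitude * (1.0 if pos_for_alpha else -1.0)
        set_profile(g, config.expr_baseline_log2 + slope * t, config.corr_noise_sd)
        for iso in isoforms:
            r_sign = slope * direction.get(iso, 1.0)
            target_sign[iso][g] = "positive" if r_sign > 0 else "negative"

    for iso in isoforms:
        own = [f"T{iso[0].upper()}{j:03d}" for j in range(config.n_targets[iso])]
        n_low = int(round(config.low_fpkm_fraction * len(own)))
        low = own[:n_low]
        for g in own:
            if g in set(low):
                # constant weak expression, below the FPKM >= 1 filter
                set_profile(g, np.full(len(stages), np.log2(0.3)), 0.02)
                low_expr[iso].append(g)
                continue
            positive = rng.random() < config.positive_fraction.get(iso, 0.5)
            slope = (config.corr_amplitude * direction.get(iso, 1.0)
                     * (1.0 if positive else -1.0))
            set_profile(g, config.expr_baseline_log2 + slope * t,
                        config.corr_noise_sd)
            target_sign[iso][g] = "positive" if positive else "negative"
        sites = [make_site(g) for g in own] + list(shared_sites)
        scored = [GenomicInterval(s.chrom, s.start, s.end, name=s.name,
                                  score=float(rng.normal(config.open_mean,
                                                         config.open_sd)))
                  for s in sites]
        sets[iso] = BindingSiteSet(isoform=iso, sites=scored)
    ground_truth.target_sign = target_sign
    ground_truth.low_expression_targets = low_expr
    return sets


# ---------------------------------------------------------------------------
# orchestration and file output


def simulate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study, deterministically from config.seed."""
    config = config if config is not None else StudyConfig()
    root = np.random.SeedSequence(config.seed)
    rng_sig, rng_expr, rng_bind = (
        np.random.default_rng(s) for s in root.spawn(3))
    atlas, signals, true_states, pseudo, gt = generate_atlas_signals(config, rng_sig)
    annotation, links = generate_annotation(config, atlas)
    expression = generate_expression(config, gt, links, signals, annotation,
                                     rng_expr)
    binding = generate_binding(config, annotation, expression, gt, rng_bind)

    factor_list = list(gt.upregulated)
    unlinked = [g.gene_id for g in annotation if g.chrom == "chrU"]
    factor_list += unlinked[:config.n_factor_decoys]
    factor_list += [f"ABSENT{i:02d}" for i in range(10)]

    gene_sets: dict[str, list[str]] = {}
    alpha_pos = sorted(g for g, s in gt.target_sign.get("alpha", {}).items()
                       if s == "positive" and not g.startswith("TS"))
    beta_neg = sorted(g for g, s in gt.target_sign.get("beta", {}).items()
                      if s == "negative" and not g.startswith("TS"))
    if alpha_pos:
        gene_sets["EMT_LIKE"] = [alpha_pos[0], "NOTAGENE01", "NOTAGENE02"]
    if beta_neg:
        gene_sets["PROLIFERATION_NEG"] = beta_neg[:6] + ["NOTAGENE03"]

    isoform_genes = {iso: f"ISO_{iso}" for iso in sorted(config.n_targets)}
    return SyntheticStudy(config=config, atlas=atlas, signals=signals,
                          true_states=true_states,
                          pseudo_values=pseudo, annotation=annotation,
                          links=links, expression=expression,
                          factor_list=factor_list, gene_sets=gene_sets,
                          binding=binding, isoform_genes=isoform_genes,
                          ground_truth=gt)


def write_study(study: SyntheticStudy, outdir: str | Path,
                background_block_bp: int = 2000) -> None:
    """Materialise the study as plain-text files a real pipeline would read.

    Per (condition, stage): a peak BED of truly open regions and a 25-bp
    bedGraph track storing already-normalised signal (library totals written
    alongside as 1e6, i.e. the counts-per-million scaling is pre-applied, so
    region quantification reproduces the planted log2 values exactly).
    Background is block-constant at closed-distribution level so pseudo-input
    regions measure a closed-like null.
    """
    outdir = Path(outdir)
    for sub in ("peaks", "tracks", "sites"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    config = study.config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])

    chrom_sizes = config.chrom_sizes
    with open(outdir / "chrom.sizes", "w") as fh:
        fh.write(f"chr1\t{chrom_sizes['chr1']}\n")

    bin_w = 25
    n_bins = chrom_sizes["chr1"] // bin_w
    lib_totals: dict[str, float] = {}
    for cond in config.conditions:
        states = study.true_states[cond]
        values = study.signals[cond].values
        for stage in config.stages:
            name = f"{cond}_{stage}"
            open_now = [GenomicInterval("chr1", *map(int, rid.split(":")[1].split("-")))
                        for rid, isopen in states[stage].items() if isopen]
            write_bed(open_now, outdir / "peaks" / f"{name}.bed")
            # block-constant closed-level background, regions overwritten
            arr = np.empty(n_bins, dtype=float)
            n_blocks = (n_bins * bin_w + background_block_bp - 1) // background_block_bp
            block_vals = 2.0 ** rng.normal(config.closed_mean, config.closed_sd,
                                           size=n_blocks) - 1.0
            block_vals = np.clip(block_vals, 0.0, None)
            bpb = background_block_bp // bin_w
            arr[:] = np.repeat(block_vals, bpb)[:n_bins]
            for rid, v in values[stage].items():
                _, span = rid.split(":")
                s, e = map(int, span.split("-"))
                arr[s // bin_w:(e + bin_w - 1) // bin_w] = max(0.0, 2.0 ** v - 1.0)
            track = SignalTrack(data={"chr1": arr}, bin_width=bin_w,
                                library_total=1e6)
            write_bedgraph(track, outdir / "tracks" / f"{name}.bedGraph")
            lib_totals[name] = 1e6
    with open(outdir / "tracks" / "library_totals.tsv", "w") as fh:
        for name in sorted(lib_totals):
            fh.write(f"{name}\t{lib_totals[name]:g}\n")

    write_annotation(study.annotation, outdir / "annotation.tsv")
    study.expression.to_tsv(outdir / "expression.tsv")
    with open(outdir / "factors.txt", "w") as fh:
        fh.write("\n".join(study.factor_list) + "\n")
    write_gmt(study.gene_sets, outdir / "gene_sets.gmt")
    for iso, sites in study.binding.items():
        write_bed(sites.sites, outdir / "sites" / f"{iso}.bed")
    study.ground_truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "study_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
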