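"""Isoform binding-site analysis: calling, overlap, targets, correlation sign.

Two tagged isoforms of one transcription factor (e.g. PRDM1α and PRDM1β) each
yield a set of candidate binding intervals with a per-site signal. Sites are
called with the same FPR-calibrated threshold machinery as open-chromatin
calling. Target genes are those with a TSS near any site, excluding weakly
expressed genes (mean FPKM < 1), and each target is classed by the sign of
the correlation between its temporal expression and the isoform's. Candidate
functional targets are then nominated by intersecting a sign-filtered target
set with a curated gene set (GMT entry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import OpenThreshold
from .core_io import GeneAnnotation, GenomicInterval, VennCounts, intersect_counts, tss_distance
from .gene_link import ExpressionTable


@dataclass
class BindingSiteSet:
    isoform: str
    sites: list[GenomicInterval]          # non-overlapping, with per-site score
    threshold: OpenThreshold | None = None

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.sites:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"{self.isoform}: overlapping sites "
                                     f"{a.region_id} / {b.region_id}")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class TargetGene:
    gene_id: str
    isoform: str
    nearest_site: str
    distance_bp: int
    mean_fpkm: float
    r: float | None = None
    sign: str | None = None


def call_sites(candidates: Sequence[GenomicInterval], signals: np.ndarray,
               threshold: OpenThreshold, isoform: str) -> BindingSiteSet:
    """Keep candidate regions whose signal is strictly above the threshold."""
    signals = np.asarray(signals, dtype=float)
    if signals.shape[0] != len(candidates):
        raise ValueError("one signal per candidate region required")
    sites = [GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name, score=float(v))
             for iv, v in zip(candidates, signals) if v > threshold.value]
    return BindingSiteSet(isoform=isoform, sites=sites, threshold=threshold)


def binding_venn(set_a: BindingSiteSet, set_b: BindingSiteSet,
                 min_overlap_bp: int = 1) -> VennCounts:
    return intersect_counts(set_a.sites, set_b.sites, min_overlap_bp=min_overlap_bp)


def assign_targets(sites: BindingSiteSet, annotation: Sequence[GeneAnnotation],
                   expression: ExpressionTable, max_dist_bp: int = 10_000,
                   min_fpkm: float = 1.0) -> list[TargetGene]:
    """Genes with a TSS within max_dist_bp of any site, filtered on expression.

    Genes whose overall mean FPKM is below ``min_fpkm`` are excluded. One
    record per gene, carrying the nearest site.
    """
    overall = expression.overall_mean()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sites.sites:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[TargetGene] = []
    for gene in annotation:
        best: tuple[int, GenomicInterval] | None = None
        for iv in by_chrom.get(gene.chrom, ()):
            d = tss_distance(iv, gene.tss)
            if best is None or d < best[0]:
                best = (d, iv)
        if best is None or best[0] > max_dist_bp:
            continue
        if gene.gene_id not in overall.index:
            continue
        fpkm = float(overall.loc[gene.gene_id])
        if fpkm < min_fpkm:
            continue
        out.append(TargetGene(gene_id=gene.gene_id, isoform=sites.isoform,
                              nearest_site=best[1].region_id,
                              distance_bp=best[0], mean_fpkm=fpkm))
    return out


@dataclass
class CorrelationSummary:
    targets: pd.DataFrame          # gene_id, isoform, r, sign, distance, fpkm
    positive_fraction: float
    n_positive: int
    n_negative: int
    n_excluded: int                # zero or undefined correlation


def classify_correlation(targets: Sequence[TargetGene], isoform_gene: str,
                         expression: ExpressionTable, condition: str = "naive",
                         method: str = "pearson") -> CorrelationSummary:
    """Correlate each target's stage profile with the isoform's and take signs.

    Profiles are per-stage mean log2(FPKM+1) across the stages of one
    condition. Targets with an exactly zero or undefined correlation (e.g. a
    constant profile) are excluded from the positive fraction, with a warning
    and a logged count.
    """
    stages = expression.stages(condition)
    if len(stages) < 3:
        raise ValueError("need >= 3 stages to correlate profiles")
    means = np.log2(expression.stage_means(condition, stages) + 1.0)
    if isoform_gene not in means.index:
        raise ValueError(f"isoform gene {isoform_gene!r} absent from expression")
    iso = means.loc[isoform_gene].to_numpy(dtype=float)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    n_pos = n_neg = n_excl = 0
    for t in targets:
        y = means.loc[t.gene_id].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(iso) == 0:
            r = float("nan")
        else:
            r = float(corr(y, iso).statistic)
        if np.isnan(r) or r == 0.0:
            sign = "excluded"
            n_excl += 1
        elif r > 0:
            sign, n_pos = "positive", n_pos + 1
        else:
            sign, n_neg = "negative", n_neg + 1
        rows.append((t.gene_id, t.isoform, r, sign, t.distance_bp, t.mean_fpkm))
    if n_excl:
        warnings.warn(f"{sites_label(targets)}: {n_excl} targets with "
                      "zero/undefined correlation excluded from the fraction")
    frac = n_pos / (n_pos + n_neg) if (n_pos + n_neg) else float("nan")
    df = pd.DataFrame(rows, columns=["gene_id", "isoform", "r", "sign",
                                     "distance_bp", "mean_fpkm"])
    return CorrelationSummary(targets=df, positive_fraction=frac,
                              n_positive=n_pos, n_negative=n_neg,
                              n_excluded=n_excl)


def sites_label(targets: Sequence[TargetGene]) -> str:
    return targets[0].isoform if targets else "binding"


def nominate(summary: CorrelationSummary, sign: str,
             gene_set: Sequence[str]) -> list[str]:
    """Sign-filtered targets intersected with a curated gene set, sorted."""
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    kept = set(summary.targets.loc[summary.targets["sign"] == sign, "gene_id"])
    return sorted(kept & set(gene_set))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: name <tab> description <tab> member genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
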