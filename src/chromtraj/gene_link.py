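"""Region-gene linking, expression statistics and the candidate-factor funnel.

Genes are linked to accessibility regions through their TSS (within 10 kb by
default). Class-wise expression is summarised per stage with a Mann-Whitney U
test against the fibroblast baseline. Upregulated genes must clear, at every
post-baseline stage, a 5-fold change versus baseline, p < 1e-4 (Welch t on
log2(FPKM+1) replicates) and FPKM > 5. The candidate funnel intersects
TSS-linked genes with the upregulated set and a curated epigenetic-factor
list, then groups candidates by temporal expression pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneAnnotation, GenomicInterval, tss_distance


@dataclass
class ExpressionTable:
    """Gene x replicate FPKM with a replicate -> (condition, stage) map."""

    fpkm: pd.DataFrame
    replicate_map: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be >= 0")
        missing = set(self.fpkm.columns) - set(self.replicate_map)
        if missing:
            raise ValueError(f"replicates without mapping: {sorted(missing)}")

    def replicates(self, condition: str, stage: str) -> list[str]:
        return [r for r, (c, s) in self.replicate_map.items()
                if c == condition and s == stage and r in self.fpkm.columns]

    def stages(self, condition: str) -> list[str]:
        seen: list[str] = []
        for _, (c, s) in self.replicate_map.items():
            if c == condition and s not in seen:
                seen.append(s)
        return seen

    def stage_values(self, condition: str, stage: str) -> pd.DataFrame:
        return self.fpkm[self.replicates(condition, stage)]

    def stage_means(self, condition: str, stages: Sequence[str] | None = None) -> pd.DataFrame:
        stages = list(stages) if stages is not None else self.stages(condition)
        return pd.DataFrame(
            {s: self.stage_values(condition, s).mean(axis=1) for s in stages},
            index=self.fpkm.index, columns=stages)

    def overall_mean(self) -> pd.Series:
        return self.fpkm.mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        header = pd.DataFrame(
            {r: [c, s] for r, (c, s) in self.replicate_map.items()},
            index=["condition", "stage"])[self.fpkm.columns]
        with open(path, "w") as fh:
            fh.write("#condition\t" + "\t".join(header.loc["condition"]) + "\n")
            fh.write("#stage\t" + "\t".join(header.loc["stage"]) + "\n")
        self.fpkm.to_csv(path, sep="\t", mode="a", index_label="gene_id",
                         float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        with open(path) as fh:
            cond_line = fh.readline().rstrip("\n").split("\t")
            stage_line = fh.readline().rstrip("\n").split("\t")
        if cond_line[0] != "#condition" or stage_line[0] != "#stage":
            raise ValueError(f"{path}: missing #condition/#stage header lines")
        fpkm = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        reps = list(fpkm.columns)
        replicate_map = {r: (c, s) for r, c, s in
                         zip(reps, cond_line[1:], stage_line[1:])}
        return cls(fpkm=fpkm, replicate_map=replicate_map)


@dataclass(frozen=True)
class UpregulationCriteria:
    """Stage-wise upregulation gates versus the course baseline."""

    min_fold_vs_baseline: float = 5.0
    max_p: float = 1e-4
    min_fpkm: float = 5.0
    baseline_stage: str = "hiF-T"


@dataclass(frozen=True)
class DECriteria:
    min_fold: float = 2.0
    max_q: float = 0.05


def _welch_log_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t p-value on log2(x+1); degenerate equal groups -> 1."""
    la, lb = np.log2(np.asarray(a, float) + 1), np.log2(np.asarray(b, float) + 1)
    if la.std() == 0 and lb.std() == 0:
        return 1.0 if la.mean() == lb.mean() else 0.0
    res = stats.ttest_ind(la, lb, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def class_expression_stats(links: Mapping[str, str], classes: pd.Series,
                           expression: ExpressionTable, condition: str,
                           baseline: str = "hiF-T",
                           log_base: int = 2) -> pd.DataFrame:
    """Median log FPKM and Mann-Whitney p versus baseline, per (class, stage).

    ``links`` maps region_id -> gene_id; ``classes`` maps region_id -> class.
    For each class the linked genes' per-gene stage-mean FPKM is pooled and
    compared two-sided against the same genes' baseline means. The exact null
    is used for pooled n <= 20 without ties, the tie-corrected normal
    approximation otherwise.
    """
    stages = expression.stages(condition)
    means = expression.stage_means(condition, stages)
    rows = []
    for klass in sorted(set(classes)):
        region_ids = classes.index[classes == klass]
        genes = sorted({links[r] for r in region_ids if r in links})
        genes = [g for g in genes if g in means.index]
        if not genes:
            warnings.warn(f"class {klass}: no linked genes; stats omitted")
            continue
        base_vals = means.loc[genes, baseline].to_numpy()
        for stage in stages:
            vals = means.loc[genes, stage].to_numpy()
            logged = np.log(vals + 1) / np.log(log_base)
            if stage == baseline:
                p = 1.0
            else:
                pooled = np.concatenate([vals, base_vals])
                method = ("exact" if pooled.size <= 20
                          and np.unique(pooled).size == pooled.size
                          else "asymptotic")
                p = float(stats.mannwhitneyu(vals, base_vals,
                                             alternative="two-sided",
                                             method=method).pvalue)
            rows.append((klass, stage, len(genes), float(np.median(logged)), p))
    return pd.DataFrame(rows, columns=["class", "stage", "n_genes",
                                       "median_log_fpkm", "mwu_p"])


def upregulated_genes(expression: ExpressionTable,
                      criteria: UpregulationCriteria = UpregulationCriteria(),
                      condition: str = "naive") -> list[str]:
    """Genes clearing fold, p and level gates at every post-baseline stage."""
    stages = expression.stages(condition)
    if criteria.baseline_stage not in stages:
        raise ValueError(f"baseline stage {criteria.baseline_stage!r} absent")
    base_reps = expression.stage_values(condition, criteria.baseline_stage)
    test_p = all(len(expression.replicates(condition, s)) >= 2 for s in stages)
    if not test_p:
        warnings.warn(
            "some stages have a single replicate: the p-value criterion is "
            "SKIPPED and upregulation rests on fold/level gates only",
            stacklevel=2)
    base_mean = base_reps.mean(axis=1)
    keep = pd.Series(True, index=expression.fpkm.index)
    for stage in stages:
        if stage == criteria.baseline_stage:
            continue
        reps = expression.stage_values(condition, stage)
        mean = reps.mean(axis=1)
        fold_ok = mean > criteria.min_fold_vs_baseline * base_mean
        level_ok = mean > criteria.min_fpkm
        keep &= fold_ok & level_ok
        if test_p:
            cand = keep[keep].index
            pvals = pd.Series(
                [_welch_log_t(reps.loc[g].to_numpy(), base_reps.loc[g].to_numpy())
                 for g in cand], index=cand)
            keep.loc[cand] = pvals < criteria.max_p
    return sorted(keep[keep].index)


def differential_genes(expression: ExpressionTable,
                       group_a: Sequence[str], group_b: Sequence[str],
                       criteria: DECriteria = DECriteria()) -> pd.DataFrame:
    """Welch-t / BH differential expression between two replicate groups.

    Fold change is the ratio of group means on the larger side (so a 2-fold
    change in either direction qualifies). Returns one row per gene with
    fold, p, q and the DE flag.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = expression.fpkm[list(group_a)].to_numpy(dtype=float)
    b = expression.fpkm[list(group_b)].to_numpy(dtype=float)
    la, lb = np.log2(a + 1), np.log2(b + 1)
    res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (la.std(axis=1) == 0) & (lb.std(axis=1) == 0)
    p[degenerate & (la.mean(axis=1) == lb.mean(axis=1))] = 1.0
    p[degenerate & (la.mean(axis=1) != lb.mean(axis=1))] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    eps = 1e-9
    ratio = (a.mean(axis=1) + eps) / (b.mean(axis=1) + eps)
    fold = np.maximum(ratio, 1.0 / ratio)
    out = pd.DataFrame({"fold": fold, "p": p, "q": q},
                       index=expression.fpkm.index)
    out["de"] = (out["fold"] > criteria.min_fold) & (out["q"] < criteria.max_q)
    return out


@dataclass
class FunnelResult:
    """Candidate epigenetic factors with per-gene evidence and funnel counts."""

    candidates: pd.DataFrame   # gene_id, nearest region, distance, switch stage
    n_linked: int              # genes with a TSS within range of any region
    n_upregulated_linked: int
    n_candidates: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_candidates = len(self.candidates)


def candidate_funnel(regions: Sequence[GenomicInterval],
                     annotation: Sequence[GeneAnnotation],
                     upregulated: Sequence[str], factor_list: Sequence[str],
                     switch_stage_by_region: Mapping[str, str | None] | None = None,
                     max_dist_bp: int = 10_000) -> FunnelResult:
    """TSS-within-range genes ∩ upregulated ∩ curated factor list.

    A gene enters the funnel when its TSS lies within ``max_dist_bp`` of ANY
    input region (the gained-accessibility regions plus any selected transient
    cluster's regions). Evidence records the nearest such region, its distance
    and, where known, that region's switch stage.
    """
    if not factor_list:
        raise ValueError("factor list must be non-empty")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    linked: dict[str, tuple[GenomicInterval, int]] = {}
    for gene in annotation:
        best: tuple[int, GenomicInterval] | None = None
        for iv in by_chrom.get(gene.chrom, ()):  # fine at funnel scale
            d = tss_distance(iv, gene.tss)
            if best is None or d < best[0]:
                best = (d, iv)
        if best is not None and best[0] <= max_dist_bp:
            linked[gene.gene_id] = (best[1], best[0])
    up = set(upregulated)
    up_linked = sorted(g for g in linked if g in up)
    factors = set(factor_list)
    cand_genes = sorted(g for g in up_linked if g in factors)
    rows = []
    for g in cand_genes:
        region, dist = linked[g]
        switch = None
        if switch_stage_by_region is not None:
            switch = switch_stage_by_region.get(region.region_id)
        rows.append((g, region.region_id, dist, switch))
    candidates = pd.DataFrame(rows, columns=["gene_id", "nearest_region",
                                             "distance_bp", "switch_stage"])
    return FunnelResult(candidates=candidates, n_linked=len(linked),
                        n_upregulated_linked=len(up_linked))


def group_patterns(genes: Sequence[str], expression: ExpressionTable,
                   condition: str = "naive", baseline: str = "hiF-T",
                   spearman_min: float = 0.7, min_final_fold: float = 2.0,
                   surge_fold: float = 2.0, low_fpkm: float = 5.0,
                   flat_fold: float = 2.0) -> dict[str, int]:
    """Assign each gene a temporal expression-pattern group.

    1 progressive-up: monotone rise (Spearman >= spearman_min) ending at
      >= min_final_fold x baseline; 3 late-surge: the last two stages' mean is
      >= surge_fold x the earlier maximum while earlier stages stay below
      low_fpkm; 4 low-stable: all stage means < low_fpkm with a fold span
      < flat_fold; 2 otherwise (expressed without a strong trend).
    """
    stages = expression.stages(condition)
    if stages[0] != baseline:
        stages = [baseline] + [s for s in stages if s != baseline]
    means = expression.stage_means(condition, stages)
    idx = np.arange(len(stages))
    out: dict[str, int] = {}
    eps = 1e-9
    for g in genes:
        y = means.loc[g].to_numpy(dtype=float)
        rho = (float("nan") if np.all(y == y[0])
               else stats.spearmanr(y, idx).statistic)
        final_fold = (y[-1] + eps) / (y[0] + eps)
        span_fold = (y.max() + eps) / (y.min() + eps)
        late = y[-2:].mean()
        early_max = y[:-2].max()
        # late-surge precedes progressive-up: a step in the last two stages
        # also produces a high tie-corrected Spearman and would be captured
        # by the monotone rule otherwise
        if late >= surge_fold * early_max and early_max < low_fpkm:
            out[g] = 3
        elif not np.isnan(rho) and rho >= spearman_min and final_fold >= min_final_fold:
            out[g] = 1
        elif (y < low_fpkm).all() and span_fold < flat_fold:
            out[g] = 4
        else:
            out[g] = 2
    return out


def read_factor_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and # comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out
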