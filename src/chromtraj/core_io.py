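"""Genomic-interval algebra and plain-text readers/writers.

All coordinates are 0-based, half-open (BED convention). The operations here
(merge with a gap, overlap counting, nearest-TSS linking, midpoint feature
annotation) are the interval primitives every downstream stage of the
chromatin-trajectory analysis consumes.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

FEATURE_PRECEDENCE = ("promoter", "5utr", "3utr", "exon", "intron", "tts", "intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GeneAnnotation:
    """One gene: TSS, transcript span and optional labelled sub-features.

    ``features`` maps labels in {"5utr", "3utr", "exon", "intron"} to lists of
    half-open (start, end) pairs lying within the span. The TSS sits at
    span.start for + strand genes and at span.end - 1 for - strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: GenomicInterval
    features: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        expected = self.span.start if self.strand == "+" else self.span.end - 1
        if self.tss != expected:
            raise ValueError(
                f"{self.gene_id}: tss {self.tss} inconsistent with {self.strand} "
                f"strand span [{self.span.start}, {self.span.end})"
            )
        for label, blocks in self.features.items():
            for s, e in blocks:
                if s < self.span.start or e > self.span.end:
                    raise ValueError(f"{self.gene_id}: {label} block [{s},{e}) outside span")

    @property
    def transcript_end(self) -> int:
        """Position of the last transcribed base (transcription termination)."""
        return self.span.end - 1 if self.strand == "+" else self.span.start


@dataclass
class SignalTrack:
    """Genome-wide signal in fixed-width bins (default 25 bp).

    ``data`` maps chromosome -> float array of bin values starting at bin 0;
    ``library_total`` is the normalisation denominator (defaults to the sum of
    all bin values, a fragment-count surrogate).
    """

    data: dict[str, np.ndarray]
    bin_width: int = 25
    library_total: float | None = None

    def __post_init__(self) -> None:
        for chrom, values in self.data.items():
            arr = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{chrom}: track values must be finite and >= 0")
            self.data[chrom] = arr
        if self.library_total is None:
            self.library_total = float(sum(a.sum() for a in self.data.values()))
        if self.library_total <= 0:
            raise ValueError("library_total must be positive")


# ---------------------------------------------------------------------------
# readers / writers


def parse_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, in file order.

    ``track``/``browser``/comment lines are skipped. A record with end <= start
    is rejected with its line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            intervals.append(GenomicInterval(chrom, start, end, name=name, score=score))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def parse_bedgraph(path: str | Path, bin_width: int = 25,
                   library_total: float | None = None) -> SignalTrack:
    """Read a bedGraph whose records are aligned to fixed ``bin_width`` bins.

    Records whose start is not a bin multiple, or whose length is not a bin
    multiple, are rejected: the quantification contract assumes exact bins.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64,
                            "value": float})
    if ((df["start"] % bin_width != 0) | ((df["end"] - df["start"]) % bin_width != 0)).any():
        bad = df[(df["start"] % bin_width != 0)
                 | ((df["end"] - df["start"]) % bin_width != 0)].index[0]
        raise ValueError(f"{path}: record {bad} not aligned to {bin_width}-bp bins")
    data: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        n_bins = int(sub["end"].max()) // bin_width
        arr = np.zeros(n_bins, dtype=float)
        b0 = (sub["start"].to_numpy() // bin_width)
        b1 = (sub["end"].to_numpy() // bin_width)
        vals = sub["value"].to_numpy()
        for s, e, v in zip(b0, b1, vals):
            arr[s:e] = v
        data[str(chrom)] = arr
    return SignalTrack(data=data, bin_width=bin_width, library_total=library_total)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write non-zero bins, run-length collapsed, as bedGraph."""
    with open(path, "w") as fh:
        w = track.bin_width
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s * w}\t{e * w}\t{v:.6g}\n")


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the gene-annotation table.

    Tab-separated columns: gene_id, chrom, strand, tss, span_start, span_end,
    optional features column with ``label:start-end,start-end;label:...``
    block syntax (labels among 5utr/3utr/exon/intron).
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns")
            gene_id, chrom, strand = parts[0], parts[1], parts[2]
            tss, s0, s1 = int(parts[3]), int(parts[4]), int(parts[5])
            features: dict[str, list[tuple[int, int]]] = {}
            if len(parts) > 6 and parts[6]:
                for block in parts[6].split(";"):
                    label, _, spans = block.partition(":")
                    pairs = []
                    for pair in spans.split(","):
                        a, _, b = pair.partition("-")
                        pairs.append((int(a), int(b)))
                    features[label] = pairs
            genes.append(GeneAnnotation(gene_id, chrom, strand, tss,
                                        GenomicInterval(chrom, s0, s1), features))
    return genes


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tspan_start\tspan_end\tfeatures\n")
        for g in genes:
            feats = ";".join(
                f"{label}:" + ",".join(f"{s}-{e}" for s, e in blocks)
                for label, blocks in g.features.items()
            )
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                     f"{g.span.start}\t{g.span.end}\t{feats}\n")


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(intervals: Sequence[GenomicInterval], gap_bp: int = 0) -> list[GenomicInterval]:
    """Merge intervals whose separation is <= gap_bp (``bedtools merge -d``).

    Output is sorted and pairwise non-overlapping. Two intervals on the same
    chromosome merge iff ``next.start - prev.end <= gap_bp`` after sorting,
    which bit-matches bedtools: abutting or overlapping intervals always merge,
    and a separation of exactly gap_bp merges while gap_bp + 1 does not.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    if not intervals:
        return []
    merged: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap_bp:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def _assert_non_overlapping(intervals: Sequence[GenomicInterval], label: str) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{label} contains overlapping intervals on {chrom} "
                    f"({a.region_id} / {b.region_id}); merge first"
                )


@dataclass(frozen=True)
class VennCounts:
    """Overlap census between two internally non-overlapping interval sets."""

    a_only: int
    b_only: int
    shared_a: int  # A intervals overlapping >=1 B interval
    shared_b: int  # B intervals overlapping >=1 A interval

    @property
    def n_a(self) -> int:
        return self.a_only + self.shared_a

    @property
    def n_b(self) -> int:
        return self.b_only + self.shared_b


def intersect_counts(set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval],
                     min_overlap_bp: int = 1) -> VennCounts:
    """Count intervals of each set overlapping the other by >= min_overlap_bp."""
    _assert_non_overlapping(set_a, "set A")
    _assert_non_overlapping(set_b, "set B")

    def overlapping(query: Sequence[GenomicInterval],
                    subject: Sequence[GenomicInterval]) -> int:
        subj: dict[str, tuple[list[int], list[int]]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
        for iv in subject:
            by_chrom[iv.chrom].append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            subj[chrom] = ([iv.start for iv in ivs], [iv.end for iv in ivs])
        hits = 0
        for iv in query:
            if iv.chrom not in subj:
                continue
            starts, ends = subj[iv.chrom]
            i = bisect.bisect_left(ends, iv.start + min_overlap_bp)
            while i < len(starts) and starts[i] + min_overlap_bp <= iv.end:
                if min(iv.end, ends[i]) - max(iv.start, starts[i]) >= min_overlap_bp:
                    hits += 1
                    break
                i += 1
        return hits

    shared_a = overlapping(set_a, set_b)
    shared_b = overlapping(set_b, set_a)
    return VennCounts(a_only=len(set_a) - shared_a, b_only=len(set_b) - shared_b,
                      shared_a=shared_a, shared_b=shared_b)


@dataclass(frozen=True)
class TssLink:
    region: GenomicInterval
    gene_id: str
    distance: int


def tss_distance(region: GenomicInterval, tss: int) -> int:
    """0 when the TSS lies inside the region, else bp to the nearest edge base."""
    if region.start <= tss < region.end:
        return 0
    if tss < region.start:
        return region.start - tss
    return tss - (region.end - 1)


def nearest_tss(regions: Sequence[GenomicInterval], annotation: Sequence[GeneAnnotation],
                max_dist_bp: int = 10_000) -> list[TssLink]:
    """Link each region to its single nearest TSS within max_dist_bp.

    Regions with no TSS in range are omitted. Distance ties break toward the
    lexicographically smaller gene_id.
    """
    if not annotation:
        raise ValueError("annotation must contain at least one gene")
    by_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for g in annotation:
        by_chrom[g.chrom].append((g.tss, g.gene_id))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    links: list[TssLink] = []
    for region in regions:
        cands = by_chrom.get(region.chrom)
        if not cands:
            continue
        positions = [t for t, _ in cands]
        i = bisect.bisect_left(positions, region.start)
        best: tuple[int, str] | None = None
        # scan outward from the insertion point; distances grow monotonically
        lo, hi = i - 1, i
        while lo >= 0 or hi < len(cands):
            for j in (lo, hi):
                if 0 <= j < len(cands):
                    d = tss_distance(region, cands[j][0])
                    key = (d, cands[j][1])
                    if best is None or key < best:
                        best = key
            # stop once both frontiers are provably farther than the best
            if best is not None:
                left_d = tss_distance(region, cands[lo][0]) if lo >= 0 else None
                right_d = tss_distance(region, cands[hi][0]) if hi < len(cands) else None
                if (left_d is None or left_d > best[0]) and \
                   (right_d is None or right_d > best[0]):
                    break
            lo -= 1
            hi += 1
        if best is not None and best[0] <= max_dist_bp:
            links.append(TssLink(region=region, gene_id=best[1], distance=best[0]))
    return links


class FeatureIndex:
    """Point-query index over promoter/UTR/exon/intron/TTS windows.

    Promoter windows default to 2000 bp upstream and 500 bp downstream of the
    TSS (strand-aware); the TTS window is +/- 500 bp of the transcript end.
    Both are configurable since annotation pipelines differ on them.
    """

    def __init__(self, annotation: Sequence[GeneAnnotation],
                 promoter_upstream: int = 2000, promoter_downstream: int = 500,
                 tts_window: int = 500) -> None:
        self.trees: dict[str, dict[str, IntervalTree]] = defaultdict(dict)

        def add(label: str, chrom: str, start: int, end: int) -> None:
            if end > start:
                tree = self.trees[label].setdefault(chrom, IntervalTree())
                tree.addi(start, end)

        for g in annotation:
            if g.strand == "+":
                add("promoter", g.chrom, g.tss - promoter_upstream, g.tss + promoter_downstream)
            else:
                add("promoter", g.chrom, g.tss - promoter_downstream + 1,
                    g.tss + promoter_upstream + 1)
            t = g.transcript_end
            add("tts", g.chrom, t - tts_window, t + tts_window + 1)
            for label, blocks in g.features.items():
                for s, e in blocks:
                    add(label, g.chrom, s, e)
            if "intron" not in g.features:
                # infer intron as gene body not covered by any declared block
                covered = IntervalTree()
                for blocks in g.features.values():
                    for s, e in blocks:
                        covered.addi(s, e)
                body = IntervalTree([])
                body.addi(g.span.start, g.span.end)
                for iv in covered:
                    body.chop(iv.begin, iv.end)
                for iv in body:
                    add("intron", g.chrom, iv.begin, iv.end)

    def labels_at(self, chrom: str, pos: int) -> set[str]:
        out = set()
        for label, per_chrom in self.trees.items():
            tree = per_chrom.get(chrom)
            if tree is not None and tree.overlaps_point(pos):
                out.add(label)
        return out


def annotate_feature(region: GenomicInterval,
                     annotation: Sequence[GeneAnnotation] | FeatureIndex) -> str:
    """Label a region by its midpoint with promoter > 5'UTR > 3'UTR > exon >
    intron > TTS > intergenic precedence."""
    index = annotation if isinstance(annotation, FeatureIndex) else FeatureIndex(annotation)
    hits = index.labels_at(region.chrom, region.midpoint)
    for label in FEATURE_PRECEDENCE[:-1]:
        if label in hits:
            return label
    return "intergenic"


def annotate_features(regions: Sequence[GenomicInterval],
                      annotation: Sequence[GeneAnnotation] | FeatureIndex) -> Counter:
    """Feature-label counts over a region set; counts sum to len(regions)."""
    index = annotation if isinstance(annotation, FeatureIndex) else FeatureIndex(annotation)
    return Counter(annotate_feature(r, index) for r in regions)
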