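"""Brute-force reference implementations used to check the interval algebra.

These deliberately work base-by-base (or by exhaustive scan) and share no
code with the package implementations they verify.
"""

from __future__ import annotations

from collections import defaultdict

from chromtraj.core_io import GeneAnnotation, GenomicInterval


def merge_oracle(intervals: list[GenomicInterval], gap_bp: int) -> list[GenomicInterval]:
    """Per-base merge: mark covered bases, then chain coverage runs whose
    separation is <= gap_bp."""
    by_chrom: dict[str, set[int]] = defaultdict(set)
    for iv in intervals:
        by_chrom[iv.chrom].update(range(iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        bases = sorted(by_chrom[chrom])
        runs: list[list[int]] = [[bases[0], bases[0] + 1]]
        for b in bases[1:]:
            if b == runs[-1][1]:
                runs[-1][1] = b + 1
            else:
                runs.append([b, b + 1])
        chained: list[list[int]] = [runs[0]]
        for s, e in runs[1:]:
            if s - chained[-1][1] <= gap_bp:
                chained[-1][1] = e
            else:
                chained.append([s, e])
        out.extend(GenomicInterval(chrom, s, e) for s, e in chained)
    return out


def intersect_oracle(set_a: list[GenomicInterval], set_b: list[GenomicInterval],
                     min_overlap_bp: int = 1) -> tuple[int, int]:
    """Pairwise per-base overlap counts: (#A hitting B, #B hitting A)."""

    def hits(query, subject):
        n = 0
        for q in query:
            qb = set(range(q.start, q.end))
            for s in subject:
                if s.chrom == q.chrom and len(qb & set(range(s.start, s.end))) >= min_overlap_bp:
                    n += 1
                    break
        return n

    return hits(set_a, set_b), hits(set_b, set_a)


def nearest_oracle(region: GenomicInterval, genes: list[GeneAnnotation],
                   max_dist_bp: int) -> tuple[str, int] | None:
    """Exhaustive nearest TSS with (distance, gene_id) tie order."""
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        if region.start <= g.tss < region.end:
            d = 0
        elif g.tss < region.start:
            d = region.start - g.tss
        else:
            d = g.tss - (region.end - 1)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best is None or best[0] > max_dist_bp:
        return None
    return best[1], best[0]


def classify_oracle(pattern: tuple[bool, ...]) -> str:
    """Trajectory class via string-shape matching (independent of the
    transition-counting implementation)."""
    import re

    s = "".join("1" if p else "0" for p in pattern)
    if re.fullmatch("1+", s):
        return "PO"
    if re.fullmatch("0+", s):
        return "NEVER"
    if re.fullmatch("0+1+", s):
        return "CO"
    if re.fullmatch("1+0+", s):
        return "OC"
    return "TRANSIENT"
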