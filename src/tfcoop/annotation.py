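"""Peak-to-gene annotation, differential peak calls and meta-gene profiles.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A gene's transcription start site (TSS) is ``start`` on
the '+' strand and ``end - 1`` on the '-' strand; the promoter is the
1 kb window immediately upstream of the TSS (strand-adjusted), i.e.
``[TSS - promoter_bp, TSS)`` for '+' genes and ``[end, end + promoter_bp)``
for '-' genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

REGION_PROMOTER = "promoter"
REGION_GENE_BODY = "gene_body"
REGION_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED-style)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter_window(self, promoter_bp: int = 1000) -> tuple[int, int]:
        """Half-open genomic window upstream of the TSS."""
        if self.strand == "+":
            return (max(0, self.start - promoter_bp), self.start)
        return (self.end, self.end + promoter_bp)


@dataclass(frozen=True)
class PeakAnnotation:
    interval: GenomicInterval
    gene: str | None
    region_class: str


def _tss_distance(peak: GenomicInterval, tss: int) -> int:
    """Distance from an interval to a point (0 when the point is inside)."""
    if peak.start <= tss < peak.end:
        return 0
    return min(abs(peak.start - tss), abs(peak.end - 1 - tss))


def annotate_peaks(
    peaks: Iterable[GenomicInterval],
    gene_models: Sequence[GeneModel],
    promoter_bp: int = 1000,
) -> list[PeakAnnotation]:
    """Assign each peak to promoter, gene body or intergenic space.

    A peak overlapping any strand-adjusted promoter window is a promoter
    peak (promoter precedence applies when a peak straddles the TSS);
    otherwise a peak overlapping a gene body ``[start, end)`` is a gene-body
    peak; everything else is intergenic.  Multi-gene conflicts are resolved
    by nearest TSS, then by lexicographic gene symbol.  Peaks on
    chromosomes absent from the gene models are classified intergenic with
    a logged note.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    annotations: list[PeakAnnotation] = []
    for peak in peaks:
        genes = by_chrom.get(peak.chrom)
        if genes is None:
            logger.info(
                "peak %s:%d-%d on chromosome absent from gene models; "
                "classified intergenic", peak.chrom, peak.start, peak.end,
            )
            annotations.append(PeakAnnotation(peak, None, REGION_INTERGENIC))
            continue

        def pick(candidates: list[GeneModel]) -> GeneModel:
            return min(candidates, key=lambda g: (_tss_distance(peak, g.tss), g.gene))

        prom = [
            g for g in genes
            if _spans_overlap(peak.start, peak.end, *g.promoter_window(promoter_bp))
        ]
        if prom:
            annotations.append(PeakAnnotation(peak, pick(prom).gene, REGION_PROMOTER))
            continue
        body = [g for g in genes if _spans_overlap(peak.start, peak.end, g.start, g.end)]
        if body:
            annotations.append(PeakAnnotation(peak, pick(body).gene, REGION_GENE_BODY))
            continue
        annotations.append(PeakAnnotation(peak, None, REGION_INTERGENIC))
    return annotations


def _spans_overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return max(a0, b0) < min(a1, b1)


def peaks_to_genes(
    annotations: Iterable[PeakAnnotation], include_gene_body: bool = False
) -> set[str]:
    """Unique genes whose promoters (optionally bodies) carry a peak."""
    wanted = {REGION_PROMOTER}
    if include_gene_body:
        wanted.add(REGION_GENE_BODY)
    return {a.gene for a in annotations if a.region_class in wanted and a.gene}


def differential_peaks(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    min_overlap_fraction: float = 0.5,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Presence/absence differential peak call between two conditions.

    Two peaks are the "same" peak when their overlap covers at least
    ``min_overlap_fraction`` of the shorter of the two intervals (boundary
    counts as overlapping).  Returns ``(gained_in_a, lost_in_a)`` where
    gained peaks are in A with no match in B and lost peaks are in B with
    no match in A.
    """
    if not (0 < min_overlap_fraction <= 1):
        raise ValueError("min_overlap_fraction must be in (0, 1]")

    def unmatched(src: Sequence[GenomicInterval], other: Sequence[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for p in other:
            by_chrom.setdefault(p.chrom, []).append(p)
        out = []
        for p in src:
            matched = False
            for q in by_chrom.get(p.chrom, ()):
                ov = p.overlap(q)
                if ov >= min_overlap_fraction * min(len(p), len(q)):
                    matched = True
                    break
            if not matched:
                out.append(p)
        return out

    return unmatched(peaks_a, peaks_b), unmatched(peaks_b, peaks_a)


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _covered_fraction(merged: list[tuple[int, int]], lo: float, hi: float) -> float:
    if hi <= lo:
        return 0.0
    cov = 0.0
    for s, e in merged:
        cov += max(0.0, min(e, hi) - max(s, lo))
        if s >= hi:
            break
    return cov / (hi - lo)


def metagene_profile(
    peaks: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    upstream_bp: int = 3000,
    downstream_bp: int = 3000,
    body_bins: int = 40,
    flank_bin_bp: int = 100,
) -> np.ndarray:
    """Average peak coverage on meta-gene coordinates.

    Each gene is mapped onto (upstream flank bins of ``flank_bin_bp``,
    ``body_bins`` equal-width bins over the scaled gene body, downstream
    flank bins), strand-adjusted so that bin 0 is the farthest upstream
    position.  Each bin holds the mean (over genes) fraction of its span
    covered by the merged peak set.
    """
    if upstream_bp % flank_bin_bp or downstream_bp % flank_bin_bp:
        raise ValueError("flank sizes must be multiples of flank_bin_bp")
    n_up = upstream_bp // flank_bin_bp
    n_down = downstream_bp // flank_bin_bp
    n_bins = n_up + body_bins + n_down

    merged_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        merged_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged_by_chrom = {c: _merge_spans(v) for c, v in merged_by_chrom.items()}

    total = np.zeros(n_bins)
    n_genes = 0
    for g in gene_models:
        if g.end - g.start <= 1:
            raise ValueError(f"gene {g.gene}: body must be longer than 1 bp")
        merged = merged_by_chrom.get(g.chrom, [])
        edges: list[tuple[float, float]] = []
        if g.strand == "+":
            for k in range(n_up):
                lo = g.start - upstream_bp + k * flank_bin_bp
                edges.append((lo, lo + flank_bin_bp))
            bw = (g.end - g.start) / body_bins
            for k in range(body_bins):
                edges.append((g.start + k * bw, g.start + (k + 1) * bw))
            for k in range(n_down):
                lo = g.end + k * flank_bin_bp
                edges.append((lo, lo + flank_bin_bp))
        else:
            for k in range(n_up):
                hi = g.end + upstream_bp - k * flank_bin_bp
                edges.append((hi - flank_bin_bp, hi))
            bw = (g.end - g.start) / body_bins
            for k in range(body_bins):
                edges.append((g.end - (k + 1) * bw, g.end - k * bw))
            for k in range(n_down):
                hi = g.start - k * flank_bin_bp
                edges.append((hi - flank_bin_bp, hi))
        total += [_covered_fraction(merged, lo, hi) for lo, hi in edges]
        n_genes += 1
    if n_genes == 0:
        return total
    return total / n_genes
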