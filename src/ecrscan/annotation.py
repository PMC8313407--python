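"""Interval services on the gene annotation.

Introns are derived per gene by merging the exons of all principal
(APPRIS-flagged) transcripts — coalescing overlapping or abutting exons —
and subtracting them from the union span of those transcripts.  Queries are
assigned to genic features with the fixed priority
CDS > 3'UTR > 5'UTR > exon > intron > gene > intergenic, ties broken by
larger overlap and then lexicographic gene id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    Annotation,
    GenomicInterval,
    ValidationError,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

FEATURE_PRIORITY = ["CDS", "UTR3", "UTR5", "exon", "intron", "gene"]
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class IntronRegion:
    interval: GenomicInterval
    gene_id: str
    ordinal: int  # 5'->3' in transcript orientation

    @property
    def name(self) -> str:
        return f"{self.gene_id}_intron{self.ordinal}"


@dataclass(frozen=True)
class FeatureLabel:
    category: str  # one of FEATURE_PRIORITY + ["intergenic"]
    gene_id: str | None

    def __post_init__(self):
        if self.category not in FEATURE_PRIORITY + [INTERGENIC]:
            raise ValidationError(f"unknown feature category {self.category!r}")
        if (self.gene_id is None) != (self.category == INTERGENIC):
            raise ValidationError("gene_id must be None iff intergenic")


def derive_introns(annotation: Annotation) -> list[IntronRegion]:
    """Merge principal exons per gene and subtract from the principal span.

    Genes without a principal transcript are skipped with a warning.
    Ordinals follow transcript orientation: the first intron of a (−)-strand
    gene is the genomically rightmost one.
    """
    introns: list[IntronRegion] = []
    for gene in annotation:
        principal = gene.principal_transcripts()
        if not principal:
            warnings.warn(
                f"gene {gene.gene_id} has no principal transcript; skipped",
                stacklevel=2,
            )
            continue
        span = gene.principal_span()
        exons = [e for tx in principal for e in tx.exons]
        merged = merge_intervals(exons, min_overlap=0)  # coalesce abutting exons
        gaps = subtract_intervals(span, merged)
        if gene.strand == "-":
            gaps = list(reversed(gaps))
        for ordinal, gap in enumerate(gaps, start=1):
            introns.append(IntronRegion(gap, gene.gene_id, ordinal))
    introns.sort(key=lambda i: (i.interval.chrom, i.interval.start, i.interval.end))
    return introns


@dataclass
class FeatureTracks:
    """Per-category interval tracks, each a list of (interval, gene_id)."""

    tracks: dict[str, list[tuple[GenomicInterval, str]]]

    @classmethod
    def from_annotation(
        cls, annotation: Annotation, introns: Sequence[IntronRegion] | None = None
    ) -> "FeatureTracks":
        if introns is None:
            introns = derive_introns(annotation)
        tracks: dict[str, list[tuple[GenomicInterval, str]]] = {
            c: [] for c in FEATURE_PRIORITY
        }
        for gene in annotation:
            tracks["gene"].append((gene.span, gene.gene_id))
            for tx in gene.transcripts:
                for ex in tx.exons:
                    tracks["exon"].append((ex, gene.gene_id))
                for c in tx.cds:
                    tracks["CDS"].append((c, gene.gene_id))
                for u in tx.utr3():
                    tracks["UTR3"].append((u, gene.gene_id))
                for u in tx.utr5():
                    tracks["UTR5"].append((u, gene.gene_id))
        for ir in introns:
            tracks["intron"].append((ir.interval, ir.gene_id))
        for c in tracks:
            tracks[c].sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))
        return cls(tracks)


def map_to_features(
    queries: Iterable[GenomicInterval], tracks: FeatureTracks
) -> list[FeatureLabel]:
    """Label each query with the highest-priority overlapping feature.

    Within a category, ties between genes are broken by larger overlap
    length, then lexicographic gene id, so output does not depend on track
    record order.
    """
    labels = []
    for q in queries:
        label = FeatureLabel(INTERGENIC, None)
        for category in FEATURE_PRIORITY:
            hits = [
                (q.overlap_length(iv), gid)
                for iv, gid in tracks.tracks[category]
                if q.overlaps(iv)
            ]
            if hits:
                hits.sort(key=lambda h: (-h[0], h[1]))
                label = FeatureLabel(category, hits[0][1])
                break
        labels.append(label)
    return labels


def distance_to_upstream_utr3(
    query: GenomicInterval,
    utr3_track: Sequence[GenomicInterval],
    tracks: FeatureTracks | None = None,
) -> int | None:
    """Distance from an intergenic query to the nearest upstream 3' UTR.

    "Upstream" is taken in each UTR's own transcription direction: a
    (+)-strand UTR qualifies when it ends at or before the query start, a
    (−)-strand UTR when it starts at or after the query end.  The nearer of
    the best candidate on each strand is returned; abutting intervals have
    distance 0; None when no candidate exists.
    """
    if tracks is not None:
        if map_to_features([query], tracks)[0].category != INTERGENIC:
            raise ValidationError("query is not intergenic")
    best: int | None = None
    for utr in utr3_track:
        if utr.chrom != query.chrom:
            continue
        if utr.strand == "+" and utr.end <= query.start:
            d = query.start - utr.end
        elif utr.strand == "-" and utr.start >= query.end:
            d = utr.start - query.end
        else:
            continue
        if best is None or d < best:
            best = d
    return best


def classify_repeat_overlap(
    group: Sequence[GenomicInterval], repeats: pd.DataFrame
) -> str:
    """Classify an interval group against a repeat track.

    Returns "Alu" if any member overlaps a repeat whose family name begins
    with "Alu", else "non-Alu RE" if any member overlaps any repeat, else
    "no RE".  ``repeats`` is a BED-like DataFrame with a ``name`` column
    carrying the family.
    """
    any_repeat = False
    for iv in group:
        sub = repeats[
            (repeats["chrom"] == iv.chrom)
            & (repeats["start"] < iv.end)
            & (repeats["end"] > iv.start)
        ]
        if len(sub):
            any_repeat = True
            if sub["name"].astype(str).str.startswith("Alu").any():
                return "Alu"
    return "non-Alu RE" if any_repeat else "no RE"
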