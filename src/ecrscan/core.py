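"""Core domain types: stranded genomic intervals, annotation models, parameters.

All internal coordinates are 0-based half-open ([start, end)), the BED
convention.  GTF's 1-based inclusive coordinates are converted at the I/O
boundary.  Interval "overlap" means at least one shared base; the distance
between disjoint intervals is ``start(downstream) - end(upstream)``, so
abutting intervals have distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open stranded interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> int:
        """Distance between disjoint intervals; 0 when they overlap or abut."""
        if self.chrom != other.chrom:
            raise ValidationError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_overlap: int = 1
) -> list[GenomicInterval]:
    """Merge intervals sharing >= ``min_overlap`` bases (per chrom; strand-blind).

    With the default ``min_overlap=1`` abutting intervals are NOT merged,
    matching a merge step that requires at least 1-bp overlap.  Pass
    ``min_overlap=0`` to coalesce book-ended intervals as well (used when
    merging exons before intron subtraction).
    """
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            # overlap of candidate with current run
            if cur_end - iv.start >= min_overlap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def subtract_intervals(
    span: GenomicInterval, blocks: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Return the parts of ``span`` not covered by ``blocks`` (same chrom)."""
    gaps: list[GenomicInterval] = []
    pos = span.start
    for b in sorted(
        (b for b in blocks if b.chrom == span.chrom and b.overlaps(span)),
        key=lambda i: i.start,
    ):
        if b.start > pos:
            gaps.append(GenomicInterval(span.chrom, pos, b.start, span.strand))
        pos = max(pos, b.end)
    if pos < span.end:
        gaps.append(GenomicInterval(span.chrom, pos, span.end, span.strand))
    return gaps


@dataclass(frozen=True)
class PipelineParams:
    """Every numeric threshold used by the pipeline, with its default.

    Units are noted per field; all values must be strictly positive and the
    three frequency bounds must satisfy freq_min < freq_high < freq_max.
    """

    max_gap: int = 50  # nt, max distance between editing sites in a cluster
    min_cluster_sites: int = 5  # sites, minimum final cluster size
    ecr_pad: int = 1000  # nt added on both sides of a cluster
    ecr_group_gap: int = 2000  # nt, clusters closer than this share an ECR
    freq_min: float = 0.05  # minimum editing frequency
    freq_max: float = 0.95  # maximum editing frequency
    freq_high: float = 0.10  # "high" editing frequency (secondary filter)
    min_coverage: int = 10  # reads, any nucleotide
    min_caller_score: float = 0.5  # upstream caller confidence
    logcpm_cutoff_gene: float = 0.5  # mean log2-cpm filter, genes
    logcpm_cutoff_intron: float = 1.0  # mean log2-cpm filter, introns
    logcpm_cutoff_ecr: float = 4.5  # mean log2-cpm filter, ECRs
    de_abs_log2fc: float = 1.0  # |log2FC| for "regulated"
    de_fdr: float = 0.05  # BH-adjusted p for "regulated"
    splice_p_strict: float = 0.001  # strict splice-cluster significance
    splice_p_loose: float = 0.01  # loose splice-cluster significance
    clip_max_gap: int = 50  # nt, CLIP-peak proximity window
    ligand_min_len: int = 300  # nt, dsRNA stretch length criterion (>)
    ligand_max_mismatch_frac: float = 0.2  # mismatch fraction criterion (<)
    ligand_min_helix: int = 37  # bp, longest-helix criterion (>=)
    ecr_min_rpkm: float = 4.0  # rpkm, "expressed ECR" predicate

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValidationError(f"parameter {f.name} must be positive, got {v}")
        if not (self.freq_min < self.freq_high < self.freq_max):
            raise ValidationError(
                "frequency bounds must satisfy freq_min < freq_high < freq_max"
            )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def override(self, **kwargs) -> "PipelineParams":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)


# --- transcript / gene models -------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utrs: list[GenomicInterval] = field(default_factory=list)
    principal: bool = False

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def validate(self) -> None:
        for ex in self.exons:
            if not (self.start <= ex.start and ex.end <= self.end):
                raise ValidationError(
                    f"exon [{ex.start}, {ex.end}) outside transcript "
                    f"{self.transcript_id} span [{self.start}, {self.end})"
                )

    def utr3(self) -> list[GenomicInterval]:
        """UTR intervals 3' of the CDS in transcript orientation."""
        return self._utr_side(three_prime=True)

    def utr5(self) -> list[GenomicInterval]:
        return self._utr_side(three_prime=False)

    def _utr_side(self, three_prime: bool) -> list[GenomicInterval]:
        if not self.cds:
            return []
        cds_start = min(c.start for c in self.cds)
        cds_end = max(c.end for c in self.cds)
        out = []
        for u in self.utrs:
            downstream = u.start >= cds_end  # genomically right of CDS
            upstream = u.end <= cds_start
            if self.strand == "+":
                is3 = downstream
                is5 = upstream
            else:
                is3 = upstream
                is5 = downstream
            if (three_prime and is3) or (not three_prime and is5):
                out.append(u)
        return out


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        """Union span of all transcripts."""
        return GenomicInterval(
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )

    def principal_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.principal]

    def principal_span(self) -> GenomicInterval | None:
        pts = self.principal_transcripts()
        if not pts:
            return None
        return GenomicInterval(
            self.chrom,
            min(t.start for t in pts),
            max(t.end for t in pts),
            self.strand,
        )


@dataclass
class Annotation:
    """Transcript models grouped by gene, plus the repeat/CLIP/SNP tracks."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)
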