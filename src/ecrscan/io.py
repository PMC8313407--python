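"""File formats: GTF, BED6/BED3, pileup/count TSVs, dot-bracket text.

GTF is read and written with its native 1-based inclusive coordinates and
converted to the internal 0-based half-open convention at this boundary.
BED files are native 0-based half-open.  All numeric TSV output is formatted
to 6 significant digits so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import Annotation, Gene, GenomicInterval, Transcript, ValidationError


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


def _parse_attributes(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_annotation(gtf_path: str | Path) -> Annotation:
    """Read a GTF into transcript models grouped by gene.

    Transcripts whose attribute field mentions "appris" anywhere (e.g.
    ``tag "appris_principal_1"``) are flagged as principal isoforms.  The
    1-based inclusive GTF coordinates become 0-based half-open internally.
    """
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    deferred: list[tuple[str, str, GenomicInterval, int]] = []

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(parts)}"
                )
            seqname, _source, feature, start_s, end_s, _score, strand, _frame, attr = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if strand not in ("+", "-", "."):
                raise ParseError(f"{gtf_path}: line {lineno}: bad strand {strand!r}")
            start, end = start1 - 1, end1  # to 0-based half-open
            if end <= start:
                raise ParseError(
                    f"{gtf_path}: line {lineno}: empty interval {start1}-{end1}"
                )
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{gtf_path}: line {lineno}: missing gene_id")

            if feature == "gene":
                genes.setdefault(gene_id, Gene(gene_id, seqname, strand))
            elif feature == "transcript":
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise ParseError(
                        f"{gtf_path}: line {lineno}: transcript without transcript_id"
                    )
                tx = Transcript(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=seqname,
                    strand=strand,
                    start=start,
                    end=end,
                    principal="appris" in attr,
                )
                transcripts[tid] = tx
                genes.setdefault(gene_id, Gene(gene_id, seqname, strand))
                genes[gene_id].transcripts.append(tx)
            elif feature in ("exon", "CDS", "UTR"):
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise ParseError(
                        f"{gtf_path}: line {lineno}: {feature} without transcript_id"
                    )
                deferred.append(
                    (feature, tid, GenomicInterval(seqname, start, end, strand), lineno)
                )
            # other feature types are ignored

    for feature, tid, iv, lineno in deferred:
        tx = transcripts.get(tid)
        if tx is None:
            raise ParseError(
                f"{gtf_path}: line {lineno}: {feature} references unknown "
                f"transcript {tid!r}"
            )
        if feature == "exon":
            tx.exons.append(iv)
        elif feature == "CDS":
            tx.cds.append(iv)
        else:
            tx.utrs.append(iv)

    for tx in transcripts.values():
        tx.exons.sort(key=lambda e: e.start)
        tx.cds.sort(key=lambda e: e.start)
        tx.utrs.sort(key=lambda e: e.start)
        tx.validate()
    return Annotation(genes=dict(sorted(genes.items())))


def write_annotation(annotation: Annotation, gtf_path: str | Path) -> None:
    """Write transcript models back to GTF (1-based inclusive)."""

    def line(chrom, feature, iv_start, iv_end, strand, attrs):
        attr = " ".join(f'{k} "{v}";' for k, v in attrs)
        return (
            f"{chrom}\tecrscan\t{feature}\t{iv_start + 1}\t{iv_end}\t.\t"
            f"{strand}\t.\t{attr}\n"
        )

    with open(gtf_path, "w") as fh:
        for gene in annotation:
            span = gene.span
            fh.write(
                line(gene.chrom, "gene", span.start, span.end, gene.strand,
                     [("gene_id", gene.gene_id)])
            )
            for tx in gene.transcripts:
                attrs = [("gene_id", gene.gene_id), ("transcript_id", tx.transcript_id)]
                if tx.principal:
                    attrs.append(("tag", "appris_principal_1"))
                fh.write(line(tx.chrom, "transcript", tx.start, tx.end, tx.strand, attrs))
                for feature, ivs in (("exon", tx.exons), ("CDS", tx.cds), ("UTR", tx.utrs)):
                    for iv in ivs:
                        fh.write(line(tx.chrom, feature, iv.start, iv.end, tx.strand, attrs))


# --- BED ---------------------------------------------------------------------


def read_bed(path: str | Path, min_fields: int = 3) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame (chrom, start, end[, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    use = min(6, _n_bed_cols(path))
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=names[:use], usecols=range(use),
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:min_fields])
    if df.shape[1] < min_fields:
        raise ParseError(f"{path}: expected >= {min_fields} BED fields")
    if "strand" not in df.columns:
        df["strand"] = "."
    if "name" not in df.columns:
        df["name"] = "."
    return df


def _n_bed_cols(path: str | Path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 3


def write_bed(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    with open(path, "w") as fh:
        if header:
            for hline in header.rstrip("\n").split("\n"):
                fh.write(f"# {hline}\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=cols)


def bed_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), getattr(r, "strand", "."))
        for r in df.itertuples(index=False)
    ]


# --- generic TSV with reproducible formatting --------------------------------


def format_sig(x, sig: int = 6) -> str:
    """Format a number to 6 significant digits; '.' for missing values."""
    if x is None or (isinstance(x, float) and x != x):
        return "."
    if isinstance(x, (int,)) or (isinstance(x, float) and float(x).is_integer() and abs(x) < 1e15):
        return str(int(x))
    return f"{x:.{sig}g}"


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a TSV with optional '# ' comment header, 6-sig-digit floats,
    and '.' for missing values."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind in "fc":
            out[col] = out[col].map(format_sig)
        else:
            out[col] = out[col].map(lambda v: "." if v is None or v != v else v)
    with open(path, "w") as fh:
        if header_comment:
            for hline in header_comment.rstrip("\n").split("\n"):
                fh.write(f"# {hline}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["."])


# --- pileups -----------------------------------------------------------------

PILEUP_COLUMNS = [
    "chrom", "pos", "strand", "A", "C", "G", "T", "caller_score", "caller_pass",
]


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read a per-sample pileup TSV of strand-resolved base counts."""
    df = read_tsv(path)
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: pileup missing columns {missing}")
    df["caller_pass"] = df["caller_pass"].astype(bool)
    return df


def write_pileup(df: pd.DataFrame, path: str | Path, header_comment=None) -> None:
    out = df[PILEUP_COLUMNS].copy()
    out["caller_pass"] = out["caller_pass"].astype(bool)
    write_tsv(out, path, header_comment)


# --- count matrices ----------------------------------------------------------


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample count matrix; first column is the feature id."""
    df = read_tsv(path)
    return df.set_index(df.columns[0])


def write_counts(df: pd.DataFrame, path: str | Path, header_comment=None) -> None:
    out = df.reset_index()
    out.columns = ["feature_id", *df.columns]
    write_tsv(out, path, header_comment)


# --- LeafCutter-layout splice cluster counts ---------------------------------

_ROWKEY_RE = re.compile(r"^([^:]+):(\d+):(\d+):(\S+)$")


def parse_splice_rowkey(key: str) -> tuple[str, int, int, str]:
    """Parse a 'chrom:start:end:cluster_id' row key."""
    m = _ROWKEY_RE.match(key)
    if m is None:
        raise ParseError(f"malformed splice-count row key {key!r}")
    chrom, start, end, clu = m.groups()
    return chrom, int(start), int(end), clu


def read_splice_counts(path: str | Path) -> pd.DataFrame:
    """Read intron excision counts keyed 'chrom:start:end:cluster_id'.

    Returns a DataFrame with chrom/start/end/cluster_id columns followed by
    one count column per sample.
    """
    raw = pd.read_csv(path, sep=r"\s+", comment="#")
    first = raw.columns[0]
    if raw.index.name is None and not raw[first].map(
        lambda v: isinstance(v, str) and ":" in v
    ).all():
        raise ParseError(f"{path}: first column does not look like row keys")
    keys = raw[first].map(parse_splice_rowkey)
    meta = pd.DataFrame(
        keys.tolist(), columns=["chrom", "start", "end", "cluster_id"]
    )
    counts = raw.drop(columns=[first]).reset_index(drop=True)
    return pd.concat([meta, counts], axis=1)


def write_splice_counts(df: pd.DataFrame, path: str | Path, header_comment=None) -> None:
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end", "cluster_id")]
    out = pd.DataFrame(
        {
            "intron": [
                f"{r.chrom}:{int(r.start)}:{int(r.end)}:{r.cluster_id}"
                for r in df.itertuples(index=False)
            ]
        }
    )
    for c in sample_cols:
        out[c] = df[c].to_numpy()
    with open(path, "w") as fh:
        if header_comment:
            for hline in header_comment.rstrip("\n").split("\n"):
                fh.write(f"# {hline}\n")
        out.to_csv(fh, sep=" ", index=False)


# --- dot-bracket structures --------------------------------------------------


def read_structures(path: str | Path) -> list[tuple[str, str]]:
    """Read multi-record dot-bracket text.

    Records are '>id' lines followed by an optional sequence line and a
    structure line over the alphabet ``( ) .``.  Returns (id, structure)
    pairs.
    """
    records: list[tuple[str, str]] = []
    current_id = None
    structure = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    if structure is None:
                        raise ParseError(f"{path}: record {current_id!r} has no structure")
                    records.append((current_id, structure))
                current_id, structure = line[1:].strip(), None
            elif set(line) <= {"(", ")", "."}:
                structure = line
            elif set(line.upper()) <= set("ACGUTN"):
                continue  # optional sequence line
            else:
                raise ParseError(f"{path}: line {lineno}: unrecognized content")
    if current_id is not None:
        if structure is None:
            raise ParseError(f"{path}: record {current_id!r} has no structure")
        records.append((current_id, structure))
    return records


def write_structures(
    records: Iterable[tuple[str, str]] | Iterable[tuple[str, str, str]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 3:
                rid, seq, struct = rec
                fh.write(f">{rid}\n{seq}\n{struct}\n")
            else:
                rid, struct = rec
                fh.write(f">{rid}\n{struct}\n")
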