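"""Seedable synthetic-data generator with planted ground truth.

Emulates every input the pipeline consumes on a toy annotation-only genome
(no FASTA; sequence is only emitted for structure records): a GTF with one
principal transcript per gene, Alu-like repeats in introns and intergenic
space (a fraction as inverted pairs), CLIP peaks near known splice sites,
genomic SNPs, per-sample strand-resolved pileups at planted editing sites,
negative-binomial count matrices with planted per-feature log2 fold
changes, intron-excision count tables with planted cryptic-splice-site
usage shifts, hairpin dot-bracket structures with planted mismatch
geometry, and repeat-family eCLIP count tables.

The experimental design mirrors the study conditions: four genotypes
(CTRL, hnRNPC, ADAR, DKO) × harvest days {3, 4, 5} × 3 replicates.
Identical spec + seed always produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Annotation,
    Gene,
    GenomicInterval,
    PipelineParams,
    Transcript,
    ValidationError,
)
from .editing import EditingCluster, build_ecrs
from . import io as pio

CONDITIONS = ("CTRL", "hnRNPC", "ADAR", "DKO")
GENOTYPE = {
    "CTRL": ("WT", "WT"),
    "hnRNPC": ("KO", "WT"),
    "ADAR": ("WT", "KO"),
    "DKO": ("KO", "KO"),
}
DAYS = (3, 4, 5)
N_REPLICATES = 3
ERROR_RATE = 0.005  # per-base sequencing-error rate folded into references


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_genes: int = 60
    gene_length: int = 10000
    exons_per_gene: int = 4
    exon_length: int = 300
    intergenic_gap: int = 20000
    repeat_density: float = 0.3  # fraction of intronic bases under repeats
    inverted_pair_fraction: float = 0.3
    non_alu_repeat_fraction: float = 0.2
    n_editing_clusters: int = 30
    sites_per_cluster: tuple[int, int] = (5, 12)
    cluster_region_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # intron, UTR3, intergenic
    edit_freq_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"CTRL": 0.30, "hnRNPC": 0.30, "ADAR": 0.05, "DKO": 0.05}
    )
    site_coverage: float = 100.0  # mean reads per site per sample
    n_decoy_singletons: int = 15
    n_decoy_lowfreq: int = 15
    n_decoy_callerfail: int = 15
    n_snps: int = 40
    intron_effect: float = 3.0  # log2FC planted on decoupled introns
    gene_effect: float = 2.0  # log2FC planted on transcription-driven genes
    isg_main_effect: float = 1.0  # per-factor ISG main-effect log2FC
    isg_interaction: float = 2.0  # extra log2FC in the double knockout only
    n_isg: int = 15
    n_transcription_driven: int = 10
    n_decoupled: int = 15
    nb_dispersion: float = 0.05
    gene_base_mean: float = 300.0
    intron_base_fraction: float = 0.05  # intron mean relative to its gene
    ecr_base_mean: float = 60.0
    library_size_sigma: float = 0.15  # log-normal per-sample depth jitter
    n_splice_clusters: int = 120
    n_shifted_splice_clusters: int = 30
    splice_cluster_depth: float = 150.0
    null_intron_props: tuple[float, float] = (0.75, 0.25)
    shifted_props_wt: tuple[float, float] = (0.8, 0.2)
    shifted_props_ko: tuple[float, float] = (0.4, 0.6)
    n_structures: int = 30
    n_eclip_families: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "repeat_density", "inverted_pair_fraction", "non_alu_repeat_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_genes", "gene_length", "exons_per_gene", "exon_length",
            "n_editing_clusters",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for cond, f in self.edit_freq_by_condition.items():
            if not 0 <= f <= 1:
                raise ValidationError(f"editing frequency for {cond} not in [0, 1]")
        if set(self.edit_freq_by_condition) != set(CONDITIONS):
            raise ValidationError(
                f"edit_freq_by_condition must cover the 2x2 design {CONDITIONS}"
            )
        lo, hi = self.sites_per_cluster
        if not (0 < lo <= hi):
            raise ValidationError("invalid sites_per_cluster range")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


def sample_table() -> pd.DataFrame:
    """The 36-sample design: genotype × day × replicate."""
    rows = []
    for cond in CONDITIONS:
        hn, ad = GENOTYPE[cond]
        for day in DAYS:
            for rep in range(1, N_REPLICATES + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_d{day}_r{rep}",
                        "condition": cond,
                        "hnRNPC": hn,
                        "ADAR": ad,
                        "day": day,
                        "replicate": rep,
                        "treatment": f"{cond}_d{day}",
                    }
                )
    return pd.DataFrame(rows)


def negative_binomial(
    rng: np.random.Generator, mean, dispersion: float, size=None
):
    """Gamma-Poisson draw with Var = m + dispersion·m²; dispersion 0 → Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size if size is not None else mean.shape)
    return rng.poisson(lam)


# --- annotation --------------------------------------------------------------


@dataclass
class SimAnnotation:
    annotation: Annotation
    repeats: pd.DataFrame  # BED6-like with family names
    clip_peaks: pd.DataFrame  # BED6-like
    snps: pd.DataFrame  # BED3-like
    sites: pd.DataFrame  # planted editing-site truth
    clusters: pd.DataFrame  # planted cluster truth
    ecrs: pd.DataFrame  # planted ECR truth (default padding/merge rules)
    chrom: str = "chr1"


def _gene_geometry(spec: SimSpec, idx: int) -> tuple[int, int, str]:
    start = spec.intergenic_gap + idx * (spec.gene_length + spec.intergenic_gap)
    strand = "+" if idx % 2 == 0 else "-"
    return start, start + spec.gene_length, strand


def generate_annotation(spec: SimSpec) -> SimAnnotation:
    """Build the toy annotation plus repeat/CLIP/SNP tracks and the planted
    editing-cluster coordinates."""
    rng = spec.rng(1)
    chrom = "chr1"
    n_exons = spec.exons_per_gene
    exon_len = spec.exon_length
    if n_exons * exon_len >= spec.gene_length:
        raise ValidationError("exons do not fit in gene_length")

    genes: dict[str, Gene] = {}
    intron_regions: list[tuple[str, GenomicInterval]] = []
    for i in range(spec.n_genes):
        g0, g1, strand = _gene_geometry(spec, i)
        gid = f"G{i:04d}"
        spacing = (spec.gene_length - exon_len) / max(1, n_exons - 1)
        exons = [
            GenomicInterval(
                chrom, g0 + round(k * spacing), g0 + round(k * spacing) + exon_len, strand
            )
            for k in range(n_exons)
        ]
        # UTRs at the gene ends; sizes fixed so CDS/UTR tracks are nontrivial
        left_utr = 150 if strand == "-" else 100
        right_utr = 100 if strand == "-" else 150
        utrs = [
            GenomicInterval(chrom, exons[0].start, exons[0].start + left_utr, strand),
            GenomicInterval(chrom, exons[-1].end - right_utr, exons[-1].end, strand),
        ]
        cds = [
            GenomicInterval(chrom, exons[0].start + left_utr, exons[0].end, strand),
            *[GenomicInterval(chrom, e.start, e.end, strand) for e in exons[1:-1]],
            GenomicInterval(chrom, exons[-1].start, exons[-1].end - right_utr, strand),
        ]
        tx = Transcript(
            transcript_id=f"{gid}.T1",
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            start=g0,
            end=g1,
            exons=exons,
            cds=cds,
            utrs=utrs,
            principal=True,
        )
        genes[gid] = Gene(gid, chrom, strand, [tx])
        for a, b in zip(exons[:-1], exons[1:]):
            intron_regions.append((gid, GenomicInterval(chrom, a.end, b.start, strand)))

    # repeats: intronic, away from intron edges so canonical splice sites
    # stay repeat-free; a fraction as inverted (opposite-strand) pairs
    rep_len = 300
    margin = 350
    repeat_rows = []
    rep_idx = 0
    for gid, intron in intron_regions:
        usable = intron.length - 2 * margin
        if usable < rep_len:
            continue
        n_rep = int(np.floor(intron.length * spec.repeat_density / rep_len))
        n_rep = min(n_rep, usable // (rep_len + 50))
        if n_rep <= 0:
            continue
        slot = usable / n_rep
        for k in range(n_rep):
            if slot - rep_len > 1:
                jitter = int(rng.integers(0, int(slot - rep_len)))
            else:
                jitter = 0
            start = intron.start + margin + int(k * slot) + jitter
            alu = rng.random() >= spec.non_alu_repeat_fraction
            family = (
                str(rng.choice(["AluSx", "AluY", "AluJb"]))
                if alu
                else str(rng.choice(["L1M", "MIR"]))
            )
            inverted = rng.random() < spec.inverted_pair_fraction
            strand = "-" if inverted else "+"
            repeat_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + rep_len,
                    "name": family,
                    "score": 0,
                    "strand": strand,
                }
            )
            rep_idx += 1
    # a couple of intergenic repeats per gap, clear of cluster placement zones
    for i in range(spec.n_genes):
        _, g1, _ = _gene_geometry(spec, i)
        for off in (6000, 8000):
            if rng.random() < spec.repeat_density:
                repeat_rows.append(
                    {
                        "chrom": chrom,
                        "start": g1 + off,
                        "end": g1 + off + rep_len,
                        "name": "AluSx",
                        "score": 0,
                        "strand": "+",
                    }
                )
    repeats = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    if spec.repeat_density == 0:
        repeats = repeats.iloc[0:0]

    # CLIP peaks within clip_max_gap of half of the intron-start splice sites
    clip_rows = []
    for gid, intron in intron_regions[::2]:
        offset = int(rng.integers(5, 46))
        clip_rows.append(
            {
                "chrom": chrom,
                "start": intron.start + offset,
                "end": intron.start + offset + 30,
                "name": f"clip_{gid}_{intron.start}",
                "score": 0,
                "strand": ".",
            }
        )
    clip_peaks = pd.DataFrame(
        clip_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # planted editing clusters: intronic, 3'UTR or intergenic
    lo, hi = spec.sites_per_cluster
    site_rows = []
    cluster_rows = []
    gene_ids = sorted(genes)
    regions = rng.choice(
        ["intron", "UTR3", "intergenic"],
        size=spec.n_editing_clusters,
        p=np.asarray(spec.cluster_region_probs) / np.sum(spec.cluster_region_probs),
    )
    used_introns: set[int] = set()
    for ci, region in enumerate(regions):
        cid = f"cluster{ci:03d}"
        n_sites = int(rng.integers(lo, hi + 1))
        gaps = rng.integers(5, 46, size=n_sites - 1)
        span = int(gaps.sum()) + 1
        if region == "intron":
            choices = [
                k for k in range(len(intron_regions)) if k not in used_introns
            ]
            k = int(rng.choice(choices))
            used_introns.add(k)
            gid, intron = intron_regions[k]
            strand = genes[gid].strand
            start = intron.start + 30 + int(
                rng.integers(0, max(1, intron.length - span - 60))
            )
        elif region == "UTR3":
            gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
            gene = genes[gid]
            tx = gene.transcripts[0]
            utr = tx.utr3()[0]
            strand = gene.strand
            start = utr.start + 5
            # shrink gaps so the full cluster fits inside the UTR
            budget = utr.length - 10
            n_sites = min(n_sites, 1 + budget // 6)
            gap_hi = max(6, min(46, budget // max(1, n_sites - 1)))
            gaps = rng.integers(5, gap_hi, size=n_sites - 1)
        else:  # intergenic: downstream of a gene's 3' end in its direction
            gi = int(rng.integers(0, spec.n_genes))
            g0, g1, gstrand = _gene_geometry(spec, gi)
            offset = int(rng.integers(500, 4500))
            strand = gstrand
            start = g1 + offset if gstrand == "+" else max(0, g0 - offset - span)
            gid = ""
        positions = [start]
        for g in gaps:
            positions.append(positions[-1] + int(g))
        for p in positions:
            site_rows.append(
                {
                    "site_id": f"{cid}_s{p}",
                    "chrom": chrom,
                    "pos": p,
                    "strand": strand,
                    "region": region,
                    "cluster_id": cid,
                    "decoy": "",
                }
            )
        cluster_rows.append(
            {
                "cluster_id": cid,
                "chrom": chrom,
                "start": positions[0],
                "end": positions[-1] + 1,
                "strand": strand,
                "region": region,
                "n_sites": len(positions),
                "gene_id": gid,
            }
        )

    # decoys: quality-passing singletons, low-frequency sites, caller-fail sites
    genome_end = spec.intergenic_gap + spec.n_genes * (
        spec.gene_length + spec.intergenic_gap
    )
    taken = {r["pos"] for r in site_rows}

    def isolated_position() -> int:
        while True:
            p = int(rng.integers(0, genome_end))
            if all(abs(p - q) > 3000 for q in taken):
                taken.add(p)
                return p

    for kind, n in (
        ("singleton", spec.n_decoy_singletons),
        ("lowfreq", spec.n_decoy_lowfreq),
        ("callerfail", spec.n_decoy_callerfail),
    ):
        for j in range(n):
            p = isolated_position()
            site_rows.append(
                {
                    "site_id": f"decoy_{kind}_{j}",
                    "chrom": chrom,
                    "pos": p,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "region": "decoy",
                    "cluster_id": "",
                    "decoy": kind,
                }
            )

    sites = pd.DataFrame(site_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    if sites["pos"].duplicated().any():
        sites = sites.drop_duplicates("pos").reset_index(drop=True)
    clusters = pd.DataFrame(cluster_rows)

    # SNP positions disjoint from every planted site
    snp_pos = []
    site_pos = set(sites["pos"])
    while len(snp_pos) < spec.n_snps:
        p = int(rng.integers(0, genome_end))
        if p not in site_pos and p not in snp_pos:
            snp_pos.append(p)
    snps = pd.DataFrame(
        {"chrom": chrom, "start": sorted(snp_pos), "end": [p + 1 for p in sorted(snp_pos)]}
    )

    # truth ECRs from the planted clusters under the default padding rules
    params = PipelineParams()
    truth_clusters = [
        EditingCluster(
            r.chrom,
            r.strand,
            tuple(
                sorted(
                    sites.loc[sites["cluster_id"] == r.cluster_id, "pos"].astype(int)
                )
            ),
        )
        for r in clusters.itertuples(index=False)
    ]
    ecr_list = build_ecrs(truth_clusters, params)
    pos_to_cluster = {
        (c.chrom, tuple(sorted(sites.loc[sites["cluster_id"] == c_id, "pos"]))): c_id
        for c_id, c in zip(clusters["cluster_id"], truth_clusters)
    }
    ecr_rows = []
    for e in ecr_list:
        members = [
            pos_to_cluster[(c.chrom, c.positions)] for c in e.clusters
        ]
        ecr_rows.append(
            {
                "ecr_id": e.name,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "n_clusters": e.n_clusters,
                "members": ",".join(members),
            }
        )
    ecrs = pd.DataFrame(ecr_rows)

    return SimAnnotation(
        annotation=Annotation(genes=genes),
        repeats=repeats,
        clip_peaks=clip_peaks,
        snps=snps,
        sites=sites,
        clusters=clusters,
        ecrs=ecrs,
        chrom=chrom,
    )


# --- pileups -----------------------------------------------------------------


def generate_pileups(
    spec: SimSpec, sim: SimAnnotation
) -> dict[str, pd.DataFrame]:
    """Per-sample pileup TSV frames at every planted site.

    Coverage is Poisson around ``site_coverage``; the edited-base count is
    binomial at the condition's planted frequency; each of the two
    non-participating bases receives a small uniform error count that the
    frequency computation folds into the reference.
    """
    rng = spec.rng(2)
    design = sample_table()
    sites = sim.sites
    n = len(sites)
    freq_by_cond = dict(spec.edit_freq_by_condition)
    out: dict[str, pd.DataFrame] = {}
    for r in design.itertuples(index=False):
        cond_freq = freq_by_cond[r.condition]
        freqs = np.where(
            sites["decoy"] == "", cond_freq,
            np.where(sites["decoy"] == "lowfreq", 0.02, cond_freq),
        ).astype(float)
        cov = rng.poisson(spec.site_coverage, size=n)
        edited = rng.binomial(cov, freqs)
        err1 = rng.binomial(cov, ERROR_RATE)
        err2 = rng.binomial(cov, ERROR_RATE)
        plus = sites["strand"].to_numpy() == "+"
        a = np.where(plus, cov - edited, err1)
        g = np.where(plus, edited, err2)
        t = np.where(plus, err1, cov - edited)
        c = np.where(plus, err2, edited)
        fail = sites["decoy"].to_numpy() == "callerfail"
        score = np.where(fail, rng.uniform(0.0, 0.45, n), rng.uniform(0.6, 1.0, n))
        passed = ~fail
        out[r.sample_id] = pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "pos": sites["pos"],
                "strand": sites["strand"],
                "A": a,
                "C": c,
                "G": g,
                "T": t,
                "caller_score": np.round(score, 4),
                "caller_pass": passed,
            }
        )
    return out


# --- count matrices ----------------------------------------------------------


@dataclass
class SimCounts:
    design: pd.DataFrame
    gene_counts: pd.DataFrame
    intron_counts: pd.DataFrame
    ecr_counts: pd.DataFrame
    ecr_lengths: pd.Series
    splice_counts: pd.DataFrame  # long layout: chrom/start/end/cluster_id + samples
    truth_genes: pd.DataFrame
    truth_introns: pd.DataFrame
    truth_ecrs: pd.DataFrame
    truth_splice: pd.DataFrame
    intron_to_gene: dict[str, str]


def _condition_lfc(
    cond: str, hn_effect: float, ad_effect: float, interaction: float
) -> float:
    hn, ad = GENOTYPE[cond]
    lfc = 0.0
    if hn == "KO":
        lfc += hn_effect
    if ad == "KO":
        lfc += ad_effect
    if hn == "KO" and ad == "KO":
        lfc += interaction
    return lfc


def generate_counts(spec: SimSpec, sim: SimAnnotation) -> SimCounts:
    """Negative-binomial count matrices with planted per-feature log2FCs.

    Decoupled introns carry ``intron_effect`` in hnRNPC-deficient conditions
    with zero effect on their genes; transcription-driven genes carry
    ``gene_effect`` on both the gene and its introns; planted ISGs carry
    the two main effects plus the interaction term in the double knockout
    only.  Splice-cluster tables shift relative intron usage toward the
    cryptic site in hnRNPC-deficient conditions for the planted subset.
    """
    rng = spec.rng(3)
    design = sample_table()
    samples = design["sample_id"].tolist()

    gene_ids = sorted(sim.annotation.genes)
    n_genes = len(gene_ids)
    base = rng.lognormal(np.log(spec.gene_base_mean), 0.8, size=n_genes)
    perm = rng.permutation(n_genes)
    isg_idx = set(perm[: spec.n_isg])
    trans_idx = set(perm[spec.n_isg : spec.n_isg + spec.n_transcription_driven])
    dec_idx = set(
        perm[
            spec.n_isg
            + spec.n_transcription_driven : spec.n_isg
            + spec.n_transcription_driven
            + spec.n_decoupled
        ]
    )
    lib_mult = {
        s: float(m)
        for s, m in zip(samples, rng.lognormal(0.0, spec.library_size_sigma, len(samples)))
    }

    gene_truth_rows = []
    gene_lfc = np.zeros((n_genes, len(CONDITIONS)))
    for i, gid in enumerate(gene_ids):
        for j, cond in enumerate(CONDITIONS):
            lfc = 0.0
            if i in isg_idx:
                lfc = _condition_lfc(
                    cond, spec.isg_main_effect, spec.isg_main_effect, spec.isg_interaction
                )
            elif i in trans_idx and GENOTYPE[cond][0] == "KO":
                lfc = spec.gene_effect
            gene_lfc[i, j] = lfc
        klass = (
            "ISG" if i in isg_idx
            else "transcription" if i in trans_idx
            else "decoupled_host" if i in dec_idx
            else "null"
        )
        gene_truth_rows.append(
            {
                "feature_id": gid,
                "class": klass,
                **{f"lfc_{c}": gene_lfc[i, j] for j, c in enumerate(CONDITIONS)},
                "interaction": spec.isg_interaction if i in isg_idx else 0.0,
            }
        )
    cond_index = {c: j for j, c in enumerate(CONDITIONS)}
    gene_counts = pd.DataFrame(index=gene_ids, columns=samples, dtype=int)
    for s in samples:
        cond = s.split("_")[0]
        mean = base * (2.0 ** gene_lfc[:, cond_index[cond]]) * lib_mult[s]
        gene_counts[s] = negative_binomial(rng, mean, spec.nb_dispersion)

    # introns: ordinals 1..n_exons-1 per gene; decoupled genes plant the
    # effect on their middle intron
    intron_ids = []
    intron_to_gene = {}
    intron_lfc_rows = []
    n_introns_per_gene = spec.exons_per_gene - 1
    intron_means = []
    intron_lfc = []
    for i, gid in enumerate(gene_ids):
        for k in range(1, n_introns_per_gene + 1):
            iid = f"{gid}_intron{k}"
            intron_ids.append(iid)
            intron_to_gene[iid] = gid
            decoupled = i in dec_idx and k == min(2, n_introns_per_gene)
            lfcs = {}
            for cond in CONDITIONS:
                lfc = float(gene_lfc[i, cond_index[cond]])  # follow the gene
                if decoupled and GENOTYPE[cond][0] == "KO":
                    lfc += spec.intron_effect
                lfcs[cond] = lfc
            intron_lfc.append(lfcs)
            intron_means.append(base[i] * spec.intron_base_fraction)
            intron_lfc_rows.append(
                {
                    "feature_id": iid,
                    "gene_id": gid,
                    "class": "decoupled" if decoupled else "coupled",
                    **{f"lfc_{c}": lfcs[c] for c in CONDITIONS},
                    "delta_hnRNPC": (
                        spec.intron_effect if decoupled else 0.0
                    ),
                }
            )
    intron_means = np.asarray(intron_means)
    intron_counts = pd.DataFrame(index=intron_ids, columns=samples, dtype=int)
    for s in samples:
        cond = s.split("_")[0]
        mean = intron_means * np.array([2.0 ** d[cond] for d in intron_lfc]) * lib_mult[s]
        intron_counts[s] = negative_binomial(rng, mean, spec.nb_dispersion)

    # ECRs: planted half up-regulated in hnRNPC-deficient conditions
    ecr_ids = sim.ecrs["ecr_id"].tolist()
    ecr_lengths = pd.Series(
        (sim.ecrs["end"] - sim.ecrs["start"]).to_numpy(), index=ecr_ids, dtype=float
    )
    up = rng.random(len(ecr_ids)) < 0.5
    ecr_truth_rows = []
    ecr_counts = pd.DataFrame(index=ecr_ids, columns=samples, dtype=int)
    ecr_base = rng.lognormal(np.log(spec.ecr_base_mean), 0.5, size=len(ecr_ids))
    for j, (eid, is_up) in enumerate(zip(ecr_ids, up)):
        ecr_truth_rows.append(
            {
                "feature_id": eid,
                "class": "hnRNPC_up" if is_up else "null",
                "lfc_hnRNPC": spec.intron_effect if is_up else 0.0,
            }
        )
    for s in samples:
        cond = s.split("_")[0]
        lfc = np.where(up & (GENOTYPE[cond][0] == "KO"), spec.intron_effect, 0.0)
        mean = ecr_base * (2.0 ** lfc) * lib_mult[s]
        ecr_counts[s] = negative_binomial(rng, mean, spec.nb_dispersion)

    # splice clusters: two introns sharing a start; the second intron uses a
    # cryptic end inside an intronic repeat for the shifted subset
    n_total = spec.n_splice_clusters
    n_shift = min(spec.n_shifted_splice_clusters, n_total)
    intron_geoms = []
    for gid in gene_ids:
        gene = sim.annotation.genes[gid]
        tx = gene.transcripts[0]
        for a, b in zip(tx.exons[:-1], tx.exons[1:]):
            intron_geoms.append((gid, a.end, b.start))
    if n_total > len(intron_geoms):
        n_total = len(intron_geoms)
        n_shift = min(n_shift, n_total)
    pick = rng.choice(len(intron_geoms), size=n_total, replace=False)
    splice_rows = []
    splice_truth = []
    for t, gi in enumerate(pick):
        gid, istart, iend = intron_geoms[gi]
        clu = f"clu_{t}"
        shifted = t < n_shift
        if shifted:
            # cryptic 3' end inside an intronic repeat, if one is available
            reps = sim.repeats[
                (sim.repeats["start"] > istart) & (sim.repeats["end"] < iend)
                & (sim.repeats["name"].str.startswith("Alu"))
            ]
            cryptic = (
                int(reps.iloc[0]["start"]) + 50 if len(reps) else istart + 700
            )
        else:
            # within the repeat-free margin at the intron 5' edge
            cryptic = istart + 250
        introns = [(istart, iend), (istart, cryptic)]
        props = {}
        for cond in CONDITIONS:
            ko = GENOTYPE[cond][0] == "KO"
            if shifted:
                props[cond] = spec.shifted_props_ko if ko else spec.shifted_props_wt
            else:
                props[cond] = spec.null_intron_props
        counts_by_sample = {}
        for s in samples:
            cond = s.split("_")[0]
            total = rng.poisson(spec.splice_cluster_depth)
            counts_by_sample[s] = rng.multinomial(total, props[cond])
        for k, (s0, e0) in enumerate(introns):
            row = {"chrom": sim.chrom, "start": s0, "end": e0, "cluster_id": clu}
            for s in samples:
                row[s] = int(counts_by_sample[s][k])
            splice_rows.append(row)
        splice_truth.append(
            {
                "cluster_id": clu,
                "gene_id": gid,
                "shifted": shifted,
                "cryptic_end": cryptic if shifted else np.nan,
            }
        )
    splice_counts = pd.DataFrame(splice_rows)

    return SimCounts(
        design=design,
        gene_counts=gene_counts,
        intron_counts=intron_counts,
        ecr_counts=ecr_counts,
        ecr_lengths=ecr_lengths,
        splice_counts=splice_counts,
        truth_genes=pd.DataFrame(gene_truth_rows),
        truth_introns=pd.DataFrame(intron_lfc_rows),
        truth_ecrs=pd.DataFrame(ecr_truth_rows),
        truth_splice=pd.DataFrame(splice_truth),
        intron_to_gene=intron_to_gene,
    )


# --- structures --------------------------------------------------------------


def assemble_hairpin(
    helices: Sequence[int], loops: Sequence[int], terminal_loop: int
) -> tuple[str, dict]:
    """Assemble a hairpin from helix runs interleaved with symmetric
    interior loops and a terminal loop; return (dot-bracket, truth).

    ``loops[i]`` dots are placed on *each* strand between helices i and
    i+1.  Truth metrics follow by arithmetic: total length
    2·(Σh + Σl) + terminal, mismatch fraction (2·Σl + terminal)/total,
    longest helix max(h).
    """
    helices = [int(h) for h in helices]
    loops = [int(l) for l in loops]
    if len(loops) != len(helices) - 1:
        raise ValidationError("need exactly len(helices)-1 interior loops")
    if any(h <= 0 for h in helices) or any(l <= 0 for l in loops):
        raise ValidationError("helix and loop sizes must be positive")
    if terminal_loop < 0:
        raise ValidationError("terminal loop must be >= 0")
    left = []
    right = []
    for i, h in enumerate(helices):
        left.append("(" * h)
        right.append(")" * h)
        if i < len(loops):
            left.append("." * loops[i])
            right.append("." * loops[i])
    structure = "".join(left) + "." * terminal_loop + "".join(reversed(right))
    total = 2 * (sum(helices) + sum(loops)) + terminal_loop
    truth = {
        "total_length": total,
        "mismatch_fraction": (2 * sum(loops) + terminal_loop) / total,
        "longest_helix": max(helices),
    }
    return structure, truth


def make_hairpin(total_length: int, mismatch_fraction: float) -> tuple[str, dict]:
    """Build a hairpin with a requested length and mismatch fraction.

    The unpaired budget round(length·fraction) is split between a terminal
    loop and symmetric interior loops; errors on geometrically inconsistent
    requests (odd pairing budget, no room for helices).
    """
    unpaired = round(total_length * mismatch_fraction)
    paired = total_length - unpaired
    if paired < 2 or paired % 2 != 0:
        raise ValidationError(
            f"inconsistent geometry: {paired} paired positions at length "
            f"{total_length}, fraction {mismatch_fraction}"
        )
    n_pairs = paired // 2
    if unpaired == 0:
        return assemble_hairpin([n_pairs], [], 0)
    terminal = unpaired if unpaired <= 4 else (4 if unpaired % 2 == 0 else 3)
    rem = unpaired - terminal  # even; split across the two strands
    per_side = rem // 2
    n_loops = int(np.ceil(per_side / 3)) if per_side else 0
    if n_pairs < n_loops + 1:
        raise ValidationError("inconsistent geometry: too many mismatches for stem")
    loops = [3] * (n_loops - 1) + [per_side - 3 * (n_loops - 1)] if n_loops else []
    n_helices = n_loops + 1
    base = n_pairs // n_helices
    helices = [base] * n_helices
    helices[0] += n_pairs - base * n_helices
    return assemble_hairpin(helices, loops, terminal)


def generate_structures(spec: SimSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Random hairpin records plus exact truth metrics.

    Half are ligand-like by construction (long, low-mismatch, with one
    helix at or above the seed length); the rest are short or mismatch-rich.
    """
    rng = spec.rng(4)
    records = []
    truth_rows = []
    for i in range(spec.n_structures):
        ligand_like = i < spec.n_structures // 2
        if ligand_like:
            n_helices = int(rng.integers(3, 7))
            helices = list(rng.integers(10, 30, size=n_helices))
            helices[int(rng.integers(0, n_helices))] = int(rng.integers(37, 60))
            loops = list(rng.integers(1, 4, size=n_helices - 1))
            terminal = int(rng.integers(3, 7))
        else:
            n_helices = int(rng.integers(2, 5))
            helices = list(rng.integers(4, 12, size=n_helices))
            loops = list(rng.integers(4, 9, size=n_helices - 1))
            terminal = int(rng.integers(4, 9))
        structure, truth = assemble_hairpin(helices, loops, terminal)
        rid = f"hairpin{i:03d}"
        records.append((rid, structure))
        truth_rows.append({"structure_id": rid, **truth, "planted_ligand_like": ligand_like})
    return records, pd.DataFrame(truth_rows)


# --- eCLIP family counts -----------------------------------------------------


def generate_family_counts(
    spec: SimSpec,
    planted: Mapping[str, float] | None = None,
    total_reads: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat-family eCLIP/input count tables with planted fold enrichments.

    ``planted`` maps "family:strand" to a true fold enrichment (default:
    Alu antisense 4-fold, Alu sense 2-fold).  Returns (counts, truth).
    """
    rng = spec.rng(5)
    if planted is None:
        planted = {"Alu:antisense": 4.0, "Alu:sense": 2.0}
    families = ["Alu", "L1", "MIR", "rRNA", "tRNA"] + [
        f"FAM{i:03d}" for i in range(spec.n_eclip_families - 5)
    ]
    rows = []
    truth_rows = []
    for strand in ("sense", "antisense"):
        w = rng.dirichlet(np.ones(len(families)) * 5.0)
        fe = np.array([planted.get(f"{f}:{strand}", 1.0) for f in families])
        p_input = w
        p_eclip = w * fe / np.sum(w * fe)
        eclip = rng.multinomial(total_reads, p_eclip)
        inp = rng.multinomial(total_reads, p_input)
        for f, e, i0 in zip(families, eclip, inp):
            rows.append(
                {
                    "family": f,
                    "strand": strand,
                    "eclip_reads": int(e),
                    "input_reads": int(i0),
                    "eclip_total": total_reads,
                    "input_total": total_reads,
                }
            )
        for f, x in zip(families, p_eclip / p_input):
            truth_rows.append({"family": f, "strand": strand, "true_fe": float(x)})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# --- standalone calibration simulations --------------------------------------


def simulate_de_counts(
    seed: int,
    n_features: int = 2000,
    n_per_group: int = 3,
    n_planted: int = 0,
    log2fc: float = 0.0,
    dispersion: float = 0.05,
    base_mean: float = 300.0,
    base_sigma: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    """Two-group count matrix for DE calibration/recovery studies.

    Base means are log-normal around ``base_mean`` (clipped at 100 so every
    feature resembles an expression-filtered one); the first ``n_planted``
    features carry ``log2fc`` in group B.  Returns (counts, design,
    planted feature index).
    """
    rng = np.random.default_rng([seed, 10])
    base = rng.lognormal(np.log(base_mean), base_sigma, n_features).clip(100, None)
    samples = [f"s{j}" for j in range(2 * n_per_group)]
    design = pd.DataFrame(
        {"sample_id": samples,
         "treatment": ["A"] * n_per_group + ["B"] * n_per_group}
    )
    lfc = np.zeros(n_features)
    lfc[:n_planted] = log2fc
    mean = np.tile(base[:, None], (1, 2 * n_per_group)).astype(float)
    mean[:, n_per_group:] *= 2.0 ** lfc[:, None]
    counts = pd.DataFrame(
        negative_binomial(rng, mean, dispersion),
        index=pd.Index([f"f{i}" for i in range(n_features)], name="feature_id"),
        columns=samples,
    )
    return counts, design, counts.index[:n_planted]


def simulate_factorial_counts(
    seed: int,
    n_isg: int = 500,
    n_synergistic: int = 100,
    n_background: int = 1500,
    main_effect: float = 1.0,
    interaction: float = 2.0,
    n_per_group: int = 3,
    dispersion: float = 0.05,
    base_mean: float = 300.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index, pd.Index]:
    """Single-day 2×2 factorial count matrix for interaction recovery.

    The matrix holds ``n_isg`` interferon-responsive features — all carry
    the two main effects, the first ``n_synergistic`` additionally carry
    ``interaction`` in the double knockout only — plus ``n_background``
    unresponsive features so library sizes behave like a transcriptome's.
    Returns (counts, design, isg index, synergistic index).
    """
    rng = np.random.default_rng([seed, 11])
    n_features = n_isg + n_background
    base = rng.lognormal(np.log(base_mean), 0.5, n_features).clip(100, None)
    rows = []
    for cond in CONDITIONS:
        hn, ad = GENOTYPE[cond]
        for rep in range(1, n_per_group + 1):
            rows.append(
                {
                    "sample_id": f"{cond}_r{rep}",
                    "condition": cond,
                    "hnRNPC": hn,
                    "ADAR": ad,
                    "day": 5,
                    "replicate": rep,
                    "treatment": f"{cond}_d5",
                }
            )
    design = pd.DataFrame(rows)
    ids = [f"isg{i}" for i in range(n_isg)] + [f"bg{i}" for i in range(n_background)]
    counts = pd.DataFrame(
        index=pd.Index(ids, name="feature_id"),
        columns=design["sample_id"], dtype=int,
    )
    responsive = np.zeros(n_features)
    responsive[:n_isg] = 1.0
    synergy = np.zeros(n_features)
    synergy[:n_synergistic] = interaction
    for r in design.itertuples(index=False):
        lfc = np.zeros(n_features)
        if r.hnRNPC == "KO":
            lfc += main_effect * responsive
        if r.ADAR == "KO":
            lfc += main_effect * responsive
        if r.hnRNPC == "KO" and r.ADAR == "KO":
            lfc += synergy
        counts[r.sample_id] = negative_binomial(
            rng, base * 2.0 ** lfc, dispersion
        )
    return counts, design, counts.index[:n_isg], counts.index[:n_synergistic]


# --- full bundle to disk -----------------------------------------------------


def simulate_run(spec: SimSpec, outdir: str | Path) -> Path:
    """Write every pipeline input (plus truth tables) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = f"ecrscan synthetic inputs; seed={spec.seed}"
    sim = generate_annotation(spec)
    pio.write_annotation(sim.annotation, outdir / "annotation.gtf")
    pio.write_bed(sim.repeats, outdir / "repeats.bed", header=hdr)
    pio.write_bed(sim.clip_peaks, outdir / "clip_peaks.bed", header=hdr)
    pio.write_bed(sim.snps, outdir / "snps.bed", header=hdr)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    pio.write_tsv(sim.sites, truth_dir / "sites.tsv", hdr)
    pio.write_tsv(sim.clusters, truth_dir / "clusters.tsv", hdr)
    pio.write_tsv(sim.ecrs, truth_dir / "ecrs.tsv", hdr)

    pileup_dir = outdir / "pileups"
    pileup_dir.mkdir(exist_ok=True)
    for sample, df in generate_pileups(spec, sim).items():
        pio.write_pileup(df, pileup_dir / f"{sample}.tsv", hdr)

    counts = generate_counts(spec, sim)
    pio.write_tsv(counts.design, outdir / "design.tsv", hdr)
    pio.write_counts(counts.gene_counts, outdir / "gene_counts.tsv", hdr)
    pio.write_counts(counts.intron_counts, outdir / "intron_counts.tsv", hdr)
    pio.write_counts(counts.ecr_counts, outdir / "ecr_counts.tsv", hdr)
    lengths = counts.ecr_lengths.rename("length").reset_index()
    lengths.columns = ["feature_id", "length"]
    pio.write_tsv(lengths, outdir / "ecr_lengths.tsv", hdr)
    pio.write_splice_counts(
        counts.splice_counts, outdir / "splice_perind_numers.counts", hdr
    )
    isgs = counts.truth_genes.loc[
        counts.truth_genes["class"] == "ISG", ["feature_id"]
    ]
    pio.write_tsv(isgs, outdir / "isgs.tsv", hdr)
    pio.write_tsv(counts.truth_genes, truth_dir / "gene_lfc.tsv", hdr)
    pio.write_tsv(counts.truth_introns, truth_dir / "intron_lfc.tsv", hdr)
    pio.write_tsv(counts.truth_ecrs, truth_dir / "ecr_lfc.tsv", hdr)
    pio.write_tsv(counts.truth_splice, truth_dir / "splice_shifts.tsv", hdr)

    records, struct_truth = generate_structures(spec)
    pio.write_structures(records, outdir / "structures.dbn")
    pio.write_tsv(struct_truth, truth_dir / "structures.tsv", hdr)

    fam_counts, fam_truth = generate_family_counts(spec)
    pio.write_tsv(fam_counts, outdir / "eclip_family_counts.tsv", hdr)
    pio.write_tsv(fam_truth, truth_dir / "eclip_fe.tsv", hdr)
    return outdir
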