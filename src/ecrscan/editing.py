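"""Post-caller A-to-I editing machinery.

A-to-I editing appears as A→G on the sense strand and T→C on the antisense
strand of the genome.  Counts of the two non-participating bases are treated
as sequencing errors and folded into the reference count, so the editing
frequency at a site is edit/(reference+edit) = edit/total.

The discovery cascade is: per-site frequency computation → primary filter
(caller confidence, coverage and frequency bounds in at least one ADAR-WT
sample, SNP exclusion) → gap-clustering (max gap 50 nt) → re-extraction of
counts across all samples → secondary filter (per-treatment triplet rule) →
re-clustering and retention of clusters with ≥5 sites → ECR construction
(pad ±1,000 nt, merge on ≥1-bp overlap, equivalent to grouping clusters
<2,000 bp apart).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, PipelineParams, ValidationError


def compute_site_frequency(
    base_counts: Mapping[str, int], strand: str
) -> tuple[int, int, float]:
    """Return (reference_count, edit_count, frequency) for one site.

    Sense: edit = G, reference = A plus the error bases T and C.
    Antisense: edit = C, reference = T plus the error bases A and G.
    All-zero counts give frequency 0.
    """
    if strand not in ("+", "-"):
        raise ValidationError("editing sites require an explicit strand")
    a, c, g, t = (int(base_counts[b]) for b in "ACGT")
    if min(a, c, g, t) < 0:
        raise ValidationError("negative base count")
    if strand == "+":
        edit, ref = g, a + t + c
    else:
        edit, ref = c, t + a + g
    total = ref + edit
    freq = edit / total if total > 0 else 0.0
    return ref, edit, freq


@dataclass
class SiteTable:
    """Editing-site candidates with per-sample folded counts.

    ``sites`` has columns chrom, pos, strand, snp (bool).  ``edit``, ``ref``,
    ``score`` and ``passed`` are aligned DataFrames with one column per
    sample.  Missing (site, sample) observations are zeros, reproducing the
    convention that unobserved read counts and frequencies are set to 0.
    """

    sites: pd.DataFrame
    edit: pd.DataFrame
    ref: pd.DataFrame
    score: pd.DataFrame
    passed: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.sites)
        for name in ("edit", "ref", "score", "passed"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} table not aligned with sites")

    @property
    def samples(self) -> list[str]:
        return list(self.edit.columns)

    @property
    def total(self) -> pd.DataFrame:
        return self.edit + self.ref

    @property
    def frequency(self) -> pd.DataFrame:
        total = self.total
        return (self.edit / total.where(total > 0)).fillna(0.0)

    def subset(self, mask) -> "SiteTable":
        idx = self.sites.index[mask]
        return SiteTable(
            self.sites.loc[idx],
            self.edit.loc[idx],
            self.ref.loc[idx],
            self.score.loc[idx],
            self.passed.loc[idx],
        )

    @classmethod
    def from_pileups(
        cls,
        pileups: Mapping[str, pd.DataFrame],
        snp_positions: pd.DataFrame | None = None,
    ) -> "SiteTable":
        """Assemble the per-sample pileup TSVs into one aligned table.

        ``pileups`` maps sample id → pileup DataFrame (chrom, pos, strand,
        A, C, G, T, caller_score, caller_pass).  ``snp_positions`` is a
        BED3-like frame of genomic SNPs; any candidate site at a SNP
        position is flagged.
        """
        keys: dict[tuple[str, int, str], None] = {}
        for df in pileups.values():
            for r in df.itertuples(index=False):
                keys.setdefault((r.chrom, int(r.pos), r.strand), None)
        site_keys = sorted(keys)
        index = pd.MultiIndex.from_tuples(site_keys, names=["chrom", "pos", "strand"])
        samples = list(pileups)
        edit = pd.DataFrame(0, index=index, columns=samples, dtype=int)
        ref = pd.DataFrame(0, index=index, columns=samples, dtype=int)
        score = pd.DataFrame(0.0, index=index, columns=samples)
        passed = pd.DataFrame(False, index=index, columns=samples)
        for sample, df in pileups.items():
            for r in df.itertuples(index=False):
                key = (r.chrom, int(r.pos), r.strand)
                rc, ec, _ = compute_site_frequency(
                    {"A": r.A, "C": r.C, "G": r.G, "T": r.T}, r.strand
                )
                edit.at[key, sample] = ec
                ref.at[key, sample] = rc
                score.at[key, sample] = float(r.caller_score)
                passed.at[key, sample] = bool(r.caller_pass)
        sites = pd.DataFrame(
            {
                "chrom": [k[0] for k in site_keys],
                "pos": [k[1] for k in site_keys],
                "strand": [k[2] for k in site_keys],
            }
        )
        snp = np.zeros(len(sites), dtype=bool)
        if snp_positions is not None and len(snp_positions):
            snp_set = {
                (r.chrom, int(r.start))
                for r in snp_positions.itertuples(index=False)
            }
            snp = np.array(
                [(r.chrom, r.pos) in snp_set for r in sites.itertuples(index=False)]
            )
        sites["snp"] = snp
        for frame in (edit, ref, score, passed):
            frame.reset_index(drop=True, inplace=True)
        return cls(sites, edit, ref, score, passed)


def primary_site_filter(
    table: SiteTable, wt_sample_ids: Sequence[str], params: PipelineParams
) -> SiteTable:
    """Keep non-SNP sites with caller pass, score ≥ min_caller_score,
    coverage ≥ min_coverage and frequency within [freq_min, freq_max] in at
    least one ADAR-WT sample."""
    if not len(wt_sample_ids):
        raise ValidationError("wt_sample_ids must be non-empty")
    wt = list(wt_sample_ids)
    freq = table.frequency[wt]
    total = table.total[wt]
    ok = (
        table.passed[wt]
        & (table.score[wt] >= params.min_caller_score)
        & (total >= params.min_coverage)
        & (freq >= params.freq_min)
        & (freq <= params.freq_max)
    )
    keep = ok.any(axis=1).to_numpy() & ~table.sites["snp"].to_numpy()
    return table.subset(keep)


def cluster_sites(positions: Sequence[int], max_gap: int) -> list[list[int]]:
    """Group sorted positions into clusters with adjacent gaps ≤ max_gap.

    The gap between two sites is the difference of their 1-bp positions, so
    sites at 100 and 150 (gap 50) share a cluster at max_gap 50.  The result
    equals the transitive closure of the pairwise gap-≤-max_gap relation.
    """
    pos = sorted(int(p) for p in positions)
    if not pos:
        return []
    clusters: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


@dataclass(frozen=True)
class EditingCluster:
    chrom: str
    strand: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValidationError("empty cluster")
        if list(self.positions) != sorted(self.positions):
            raise ValidationError("cluster positions must be sorted")

    @property
    def interval(self) -> GenomicInterval:
        """Canonical cluster interval [first site, last site + 1)."""
        return GenomicInterval(
            self.chrom, self.positions[0], self.positions[-1] + 1, self.strand
        )

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def cluster_site_table(table: SiteTable, max_gap: int) -> list[EditingCluster]:
    """Cluster a SiteTable per (chrom, strand)."""
    clusters: list[EditingCluster] = []
    for (chrom, strand), grp in table.sites.groupby(["chrom", "strand"], sort=True):
        for positions in cluster_sites(grp["pos"].tolist(), max_gap):
            clusters.append(EditingCluster(chrom, strand, tuple(positions)))
    clusters.sort(key=lambda c: (c.chrom, c.positions[0], c.strand))
    return clusters


def secondary_site_filter(
    table: SiteTable,
    treatments: Mapping[str, Sequence[str]],
    params: PipelineParams,
) -> SiteTable:
    """Keep sites where the 3 samples of at least one treatment satisfy:
    all frequencies ≥ freq_min, ≥2 frequencies ≥ freq_high, all read counts
    ≥ min_coverage."""
    for name, samples in treatments.items():
        if len(samples) != 3:
            raise ValidationError(
                f"treatment {name!r} has {len(samples)} samples, expected 3"
            )
    freq = table.frequency
    total = table.total
    keep = np.zeros(len(table.sites), dtype=bool)
    for samples in treatments.values():
        f = freq[list(samples)]
        t = total[list(samples)]
        ok = (
            (f.min(axis=1) >= params.freq_min)
            & ((f >= params.freq_high).sum(axis=1) >= 2)
            & (t.min(axis=1) >= params.min_coverage)
        )
        keep |= ok.to_numpy()
    return table.subset(keep)


def finalize_clusters(
    table: SiteTable, params: PipelineParams
) -> tuple[SiteTable, list[EditingCluster]]:
    """Re-cluster the retained sites and drop clusters with < min_cluster_sites.

    Returns the final site selection (sites of surviving clusters only) and
    the surviving clusters.
    """
    clusters = [
        c
        for c in cluster_site_table(table, params.max_gap)
        if c.n_sites >= params.min_cluster_sites
    ]
    kept = {
        (c.chrom, p, c.strand) for c in clusters for p in c.positions
    }
    mask = np.array(
        [
            (r.chrom, r.pos, r.strand) in kept
            for r in table.sites.itertuples(index=False)
        ],
        dtype=bool,
    )
    return table.subset(mask), clusters


@dataclass(frozen=True)
class ECR:
    """Editing-cluster-rich region: padded, merged cluster-group interval."""

    interval: GenomicInterval
    clusters: tuple[EditingCluster, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def name(self) -> str:
        return f"ECR_{self.interval.chrom}_{self.interval.start}_{self.interval.end}"


def build_ecrs(clusters: Sequence[EditingCluster], params: PipelineParams) -> list[ECR]:
    """Pad each cluster by ecr_pad on both sides (clamped at 0) and merge
    padded intervals overlapping by ≥1 bp.

    Two clusters share an ECR iff they are connected by a chain of
    inter-cluster gaps strictly below 2·ecr_pad; a gap of exactly 2·ecr_pad
    leaves the padded intervals abutting, which does not merge.
    """
    by_chrom: dict[str, list[EditingCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    ecrs: list[ECR] = []
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: (c.positions[0], c.positions[-1]))
        cur: list[EditingCluster] = [cs[0]]
        cur_start = max(0, cs[0].interval.start - params.ecr_pad)
        cur_end = cs[0].interval.end + params.ecr_pad
        for c in cs[1:]:
            pad_start = max(0, c.interval.start - params.ecr_pad)
            pad_end = c.interval.end + params.ecr_pad
            if pad_start < cur_end:  # >= 1-bp overlap
                cur.append(c)
                cur_end = max(cur_end, pad_end)
            else:
                ecrs.append(ECR(GenomicInterval(chrom, cur_start, cur_end), tuple(cur)))
                cur = [c]
                cur_start, cur_end = pad_start, pad_end
        ecrs.append(ECR(GenomicInterval(chrom, cur_start, cur_end), tuple(cur)))
    ecrs.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return ecrs


def average_editing(
    table: SiteTable,
    groups: Mapping[str, Sequence[tuple[int, str]]],
) -> pd.DataFrame:
    """Pooled editing fraction Σedit/Σreads per group.

    ``groups`` maps a group name to (site row position, sample id) pairs;
    every (site, sample) pair may appear in at most one group.  Groups with
    zero pooled reads get fraction 0 and a ``no_reads`` flag.
    """
    seen: set[tuple[int, str]] = set()
    rows = []
    total = table.total
    for name, pairs in groups.items():
        e = r = 0
        for site_idx, sample in pairs:
            if (site_idx, sample) in seen:
                raise ValidationError(
                    f"(site {site_idx}, sample {sample}) assigned to multiple groups"
                )
            seen.add((site_idx, sample))
            e += int(table.edit.iloc[site_idx][sample])
            r += int(total.iloc[site_idx][sample])
        rows.append(
            {
                "group": name,
                "edit_reads": e,
                "total_reads": r,
                "editing": e / r if r > 0 else 0.0,
                "no_reads": r == 0,
            }
        )
    return pd.DataFrame(rows)


def pooled_site_editing(
    table: SiteTable, treatments: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-site, per-treatment pooled editing Σedit/Σreads across the
    treatment's samples (pooling all days)."""
    out = table.sites[["chrom", "pos", "strand"]].copy()
    total = table.total
    for name, samples in treatments.items():
        e = table.edit[list(samples)].sum(axis=1)
        t = total[list(samples)].sum(axis=1)
        out[name] = (e / t.where(t > 0)).fillna(0.0).to_numpy()
        out[f"{name}_reads"] = t.to_numpy()
    return out


def ecr_editing_by_day(
    table: SiteTable,
    ecrs: Sequence[ECR],
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Day-wise pooled editing per ECR per genotype.

    ``design`` needs sample_id, condition and day columns.  For each ECR,
    genotype and day, the pooled fraction is Σedit/Σreads over all member
    editing sites and the three samples of that treatment.
    """
    rows = []
    total = table.total
    pos_index = {
        (r.chrom, r.pos, r.strand): i
        for i, r in enumerate(table.sites.itertuples(index=False))
    }
    for ecr in ecrs:
        site_rows = [
            pos_index[(c.chrom, p, c.strand)]
            for c in ecr.clusters
            for p in c.positions
            if (c.chrom, p, c.strand) in pos_index
        ]
        for (condition, day), grp in design.groupby(["condition", "day"], sort=True):
            samples = grp["sample_id"].tolist()
            e = int(table.edit.iloc[site_rows][samples].to_numpy().sum())
            t = int(total.iloc[site_rows][samples].to_numpy().sum())
            rows.append(
                {
                    "ecr": ecr.name,
                    "condition": condition,
                    "day": day,
                    "edit_reads": e,
                    "total_reads": t,
                    "editing": e / t if t > 0 else 0.0,
                    "no_reads": t == 0,
                }
            )
    return pd.DataFrame(rows)


def reporting_site_mask(
    table: SiteTable, comparison_samples: Sequence[str], min_reads: int = 10
) -> np.ndarray:
    """Display filter for plots: sites with ≥ min_reads in every sample of a
    comparison.  This never alters the retained-site set, only which sites
    are shown."""
    total = table.total[list(comparison_samples)]
    return (total >= min_reads).all(axis=1).to_numpy()
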