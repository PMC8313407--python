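"""Splicing-cluster statistics downstream of an external intron-excision
counter.

Input follows the "_perind_numers.counts" layout: rows keyed
``chrom:start:end:cluster_id`` with one excision-count column per sample.
Relative splice-site use aggregates intron counts sharing a start or end
coordinate and normalizes by the cluster total; a likelihood-ratio G-test
on pooled intron-proportion vectors serves as a self-contained stand-in for
the external differential-splicing model (externally supplied per-cluster
significance always takes precedence when present).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, ValidationError
from .annotation import classify_repeat_overlap
from . import io as pio


@dataclass
class SpliceClusterCounts:
    """Per-cluster intron excision counts with optional significance."""

    cluster_id: str
    chrom: str
    introns: pd.DataFrame  # columns: start, end, + one count column per sample
    p: float | None = None
    p_adj: float | None = None

    @property
    def samples(self) -> list[str]:
        return [c for c in self.introns.columns if c not in ("start", "end")]

    @property
    def span(self) -> GenomicInterval:
        """Region from the most 5' to the most 3' intron end in the cluster."""
        return GenomicInterval(
            self.chrom,
            int(self.introns["start"].min()),
            int(self.introns["end"].max()),
        )

    def splice_sites(self) -> list[int]:
        """All distinct intron start/end coordinates (boundary coordinates)."""
        return sorted(
            set(self.introns["start"].astype(int)) | set(self.introns["end"].astype(int))
        )


def read_splice_tables(
    counts_path,
    significance_path=None,
) -> list[SpliceClusterCounts]:
    """Read intron excision counts and join per-cluster significance.

    The significance table needs ``cluster`` and ``p`` columns
    (``p.adjust`` optional).  Clusters absent from it keep p = None.
    """
    df = pio.read_splice_counts(counts_path)
    sig: dict[str, tuple[float, float | None]] = {}
    if significance_path is not None:
        sdf = pd.read_csv(significance_path, sep="\t", comment="#")
        pcol = "p" if "p" in sdf.columns else "p.value"
        acol = "p.adjust" if "p.adjust" in sdf.columns else None
        for _, r in sdf.iterrows():
            # cluster ids may be written "chrom:clu_x"; accept both forms
            clu = str(r["cluster"]).split(":")[-1]
            sig[clu] = (float(r[pcol]), float(r[acol]) if acol else None)
    clusters = []
    for (chrom, clu), grp in df.groupby(["chrom", "cluster_id"], sort=True):
        introns = grp.drop(columns=["chrom", "cluster_id"]).reset_index(drop=True)
        p, padj = sig.get(clu, (None, None))
        clusters.append(SpliceClusterCounts(clu, chrom, introns, p, padj))
    return clusters


def relative_splice_site_use(
    cluster: SpliceClusterCounts,
    conditions: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Relative use of each splice site per condition, with fold change.

    Replicate counts are summed within each condition before normalizing.
    A site's use is (Σ counts of introns touching it) / (Σ all intron counts
    in the cluster), so within a condition the start-site uses sum to 1 and
    the end-site uses sum to 1.  With exactly two conditions (A, B) a
    ``fold_change`` column reports use(B)/use(A).
    """
    rows = []
    pooled = {
        cond: cluster.introns[list(samples)].sum(axis=1).to_numpy(dtype=float)
        for cond, samples in conditions.items()
    }
    starts = cluster.introns["start"].astype(int).to_numpy()
    ends = cluster.introns["end"].astype(int).to_numpy()
    for side, coords in (("start", starts), ("end", ends)):
        for site in sorted(set(coords)):
            row = {"cluster_id": cluster.cluster_id, "site": site, "side": side}
            for cond, counts in pooled.items():
                total = counts.sum()
                row[cond] = counts[coords == site].sum() / total if total > 0 else np.nan
            rows.append(row)
    out = pd.DataFrame(rows)
    conds = list(conditions)
    if len(conds) == 2:
        a, b = conds
        with np.errstate(divide="ignore", invalid="ignore"):
            out["fold_change"] = out[b] / out[a]
    return out


def clip_proximity(
    sites: Sequence[tuple[str, int]],
    clip_peaks: pd.DataFrame,
    max_gap: int,
) -> pd.DataFrame:
    """Distance of each splice-site coordinate to the nearest CLIP peak.

    Splice sites are boundary coordinates: a site inside a peak has
    distance 0, otherwise distance = bases to the nearest peak edge.
    Proximal iff distance ≤ max_gap.
    """
    rows = []
    by_chrom = {c: g for c, g in clip_peaks.groupby("chrom")}
    for chrom, pos in sites:
        dist = None
        g = by_chrom.get(chrom)
        if g is not None and len(g):
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            d = np.maximum.reduce([starts - pos, pos - ends, np.zeros(len(g), dtype=int)])
            dist = int(d.min())
        rows.append(
            {
                "chrom": chrom,
                "site": pos,
                "distance": dist,
                "proximal": dist is not None and dist <= max_gap,
            }
        )
    return pd.DataFrame(rows)


def g_test(observed: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio G-test of independence on a groups × introns table.

    G = 2 Σ O·ln(O/E) over cells with O > 0; df = (#groups−1)(#introns−1).
    """
    observed = np.asarray(observed, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    if total == 0 or (row == 0).any():
        raise ValidationError("zero-total group in G-test")
    expected = row * col / total
    mask = observed > 0
    g = 2.0 * float((observed[mask] * np.log(observed[mask] / expected[mask])).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
    return g, p


def differential_splice_clusters(
    clusters: Sequence[SpliceClusterCounts],
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-cluster G-test comparing pooled intron proportions between two
    condition groups, with BH adjustment across clusters.

    Single-intron clusters are excluded; clusters with zero total counts in
    a group get p = NaN and do not enter the BH adjustment.
    """
    if len(groups) != 2:
        raise ValidationError("exactly two condition groups required")
    rows = []
    for cl in clusters:
        if len(cl.introns) < 2:
            continue
        table = np.array(
            [cl.introns[list(samples)].sum(axis=1).to_numpy() for samples in groups.values()],
            dtype=float,
        )
        if (table.sum(axis=1) == 0).any():
            g, p = np.nan, np.nan
        else:
            g, p = g_test(table)
        rows.append(
            {"cluster_id": cl.cluster_id, "chrom": cl.chrom, "g": g, "p": p}
        )
    out = pd.DataFrame(rows, columns=["cluster_id", "chrom", "g", "p"])
    out["p_adj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def stratify_clusters(
    clusters: Sequence[SpliceClusterCounts],
    repeats: pd.DataFrame,
    p_adj: Mapping[str, float] | None = None,
    cutoffs: Sequence[float] = (0.001, 0.01, 0.05, 0.1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each cluster by the repeat content of its splice sites and
    report, per class and adjusted-p cutoff, the fraction of clusters below
    the cutoff.

    Splice sites are width-1 query intervals at intron boundary coordinates.
    Returns (per-cluster table, per-class/per-cutoff fraction table).
    """
    per_cluster = []
    for cl in clusters:
        sites = [
            GenomicInterval(cl.chrom, max(0, s - 1), s + 1) for s in cl.splice_sites()
        ]
        klass = classify_repeat_overlap(sites, repeats)
        padj = (
            p_adj.get(cl.cluster_id)
            if p_adj is not None
            else (cl.p_adj if cl.p_adj is not None else np.nan)
        )
        per_cluster.append(
            {"cluster_id": cl.cluster_id, "repeat_class": klass, "p_adj": padj}
        )
    per_cluster = pd.DataFrame(per_cluster)
    rows = []
    scored = per_cluster[per_cluster["p_adj"].notna()]
    for klass, grp in scored.groupby("repeat_class"):
        for cutoff in cutoffs:
            rows.append(
                {
                    "repeat_class": klass,
                    "cutoff": cutoff,
                    "n_clusters": len(grp),
                    "n_differential": int((grp["p_adj"] <= cutoff).sum()),
                    "fraction": (grp["p_adj"] <= cutoff).mean() if len(grp) else np.nan,
                }
            )
    return per_cluster, pd.DataFrame(rows)


def gene_splice_overlap(
    gene_spans: Mapping[str, GenomicInterval],
    clusters: Sequence[SpliceClusterCounts],
    p_adj: Mapping[str, float],
    p_cutoff: float,
) -> tuple[pd.DataFrame, float]:
    """Flag each expressed gene whose span overlaps a differentially
    regulated splice cluster (adjusted p ≤ cutoff); return the flagged
    fraction."""
    significant = [
        cl.span
        for cl in clusters
        if p_adj.get(cl.cluster_id) is not None
        and not np.isnan(p_adj[cl.cluster_id])
        and p_adj[cl.cluster_id] <= p_cutoff
    ]
    rows = []
    for gid, span in gene_spans.items():
        hit = any(span.overlaps(s) for s in significant)
        rows.append({"gene_id": gid, "overlaps_differential_cluster": hit})
    out = pd.DataFrame(rows)
    frac = float(out["overlaps_differential_cluster"].mean()) if len(out) else 0.0
    return out, frac
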