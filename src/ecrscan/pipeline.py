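"""Staged orchestration: annotate → editing → ecr → splicing → diffexp →
structure → report.

Stages are stateless: each reads its declared inputs plus the table files
earlier stages wrote under the output directory, so single stages can be
re-run from the CLI.  Every output table carries the parameter set and seed
in a header comment; re-running with identical config and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import diffexp as de
from . import editing as ed
from . import io as pio
from . import splicing as sp
from . import structure as st
from .config import STAGES, RunConfig
from .core import GenomicInterval, ValidationError


class PipelineError(RuntimeError):
    """A stage cannot run; the message names the stage."""


_REQUIRED_INPUTS = {
    "annotate": ["gtf"],
    "editing": ["pileup_dir", "snps", "design"],
    "ecr": ["gtf", "design"],
    "splicing": ["splice_counts", "repeats", "clip_peaks", "design", "gene_counts"],
    "diffexp": [
        "gene_counts", "intron_counts", "ecr_counts", "ecr_lengths", "design",
    ],
    "structure": ["structures"],
    "report": [],
}

_UPSTREAM = {
    "annotate": [],
    "editing": [],
    "ecr": ["editing"],
    "splicing": ["annotate"],
    "diffexp": [],
    "structure": [],
    "report": [],
}


def _header(cfg: RunConfig, stage: str) -> str:
    params = " ".join(f"{k}={v}" for k, v in cfg.params.as_dict().items())
    return f"ecrscan stage={stage} seed={cfg.seed}\nparams: {params}"


def _read_design(cfg: RunConfig) -> pd.DataFrame:
    return de.check_design(pio.read_tsv(cfg.inputs["design"]))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the requested stages in dependency order; return the report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("ecrscan.run")
    logger.setLevel(logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        logger.info("resolved configuration:\n%s", cfg.echo())
        ordered = [s for s in STAGES if s in cfg.stages]
        for stage in ordered:
            missing = [k for k in _REQUIRED_INPUTS[stage] if k not in cfg.inputs]
            if missing:
                raise PipelineError(
                    f"stage {stage!r} requires missing input(s): {missing}"
                )
            for up in _UPSTREAM[stage]:
                if up not in ordered[: ordered.index(stage)] and not _stage_done(
                    outdir, up
                ):
                    raise PipelineError(
                        f"stage {stage!r} needs output of stage {up!r}, which has "
                        "not been run"
                    )
        report: dict = {}
        for stage in ordered:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](cfg, outdir, report, logger)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage_done(outdir: Path, stage: str) -> bool:
    markers = {
        "annotate": "introns.bed",
        "editing": "editing_sites.tsv",
        "ecr": "ecrs.bed",
        "splicing": "splice_cluster_tests.tsv",
        "diffexp": "de_genes.tsv",
        "structure": "structure_metrics.tsv",
    }
    return (outdir / markers.get(stage, "")).exists()


# --- stages ------------------------------------------------------------------


def _stage_annotate(cfg, outdir, report, logger):
    annot = pio.read_annotation(cfg.inputs["gtf"])
    introns = ann.derive_introns(annot)
    bed = pd.DataFrame(
        {
            "chrom": [i.interval.chrom for i in introns],
            "start": [i.interval.start for i in introns],
            "end": [i.interval.end for i in introns],
            "name": [i.name for i in introns],
            "score": 0,
            "strand": [i.interval.strand for i in introns],
        }
    )
    pio.write_bed(bed, outdir / "introns.bed", _header(cfg, "annotate"))
    genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in annot],
            "chrom": [g.chrom for g in annot],
            "start": [g.span.start for g in annot],
            "end": [g.span.end for g in annot],
            "strand": [g.strand for g in annot],
        }
    )
    pio.write_tsv(genes, outdir / "genes.tsv", _header(cfg, "annotate"))
    report["n_genes"] = len(genes)
    report["n_introns"] = len(introns)


def _stage_editing(cfg, outdir, report, logger):
    pdir = Path(cfg.inputs["pileup_dir"])
    pileups = {
        p.stem: pio.read_pileup(p) for p in sorted(pdir.glob("*.tsv"))
    }
    if not pileups:
        raise PipelineError("stage 'editing': no pileup TSVs found")
    snps = pio.read_bed(cfg.inputs["snps"])
    design = _read_design(cfg)
    table = ed.SiteTable.from_pileups(pileups, snps)
    wt = design.loc[design["ADAR"] == "WT", "sample_id"].tolist()
    table = ed.primary_site_filter(table, wt, cfg.params)
    treatments = {
        t: g["sample_id"].tolist() for t, g in design.groupby("treatment")
    }
    table = ed.secondary_site_filter(table, treatments, cfg.params)
    table, clusters = ed.finalize_clusters(table, cfg.params)
    sites_out = table.sites[["chrom", "pos", "strand"]].copy()
    cluster_of = {}
    for ci, c in enumerate(clusters):
        for p in c.positions:
            cluster_of[(c.chrom, p, c.strand)] = f"cluster{ci:03d}"
    sites_out["cluster_id"] = [
        cluster_of[(r.chrom, r.pos, r.strand)]
        for r in sites_out.itertuples(index=False)
    ]
    for s in table.samples:
        sites_out[f"edit_{s}"] = table.edit[s].to_numpy()
        sites_out[f"total_{s}"] = table.total[s].to_numpy()
    pio.write_tsv(sites_out, outdir / "editing_sites.tsv", _header(cfg, "editing"))
    cbed = pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.interval.start for c in clusters],
            "end": [c.interval.end for c in clusters],
            "name": [f"cluster{ci:03d}" for ci in range(len(clusters))],
            "score": [c.n_sites for c in clusters],
            "strand": [c.strand for c in clusters],
        }
    )
    pio.write_bed(cbed, outdir / "editing_clusters.bed", _header(cfg, "editing"))
    cond_samples = {
        c: g["sample_id"].tolist() for c, g in design.groupby("condition")
    }
    pooled = ed.pooled_site_editing(table, cond_samples)
    pio.write_tsv(pooled, outdir / "editing_summary.tsv", _header(cfg, "editing"))
    report["n_editing_sites"] = len(sites_out)
    report["n_editing_clusters"] = len(clusters)
    for cond in sorted(cond_samples):
        e = sum(
            int(table.edit.iloc[i][s])
            for i in range(len(table.sites))
            for s in cond_samples[cond]
        )
        t = sum(
            int(table.total.iloc[i][s])
            for i in range(len(table.sites))
            for s in cond_samples[cond]
        )
        report[f"pooled_editing_{cond}"] = e / t if t else 0.0


def _load_final_sites(cfg, outdir) -> tuple[ed.SiteTable, list[ed.EditingCluster]]:
    df = pio.read_tsv(outdir / "editing_sites.tsv")
    samples = sorted(
        c[len("edit_"):] for c in df.columns if c.startswith("edit_")
    )
    sites = df[["chrom", "pos", "strand"]].copy()
    sites["snp"] = False
    edit = pd.DataFrame({s: df[f"edit_{s}"].to_numpy() for s in samples})
    total = pd.DataFrame({s: df[f"total_{s}"].to_numpy() for s in samples})
    ref = total - edit
    zeros = pd.DataFrame(0.0, index=edit.index, columns=samples)
    table = ed.SiteTable(sites, edit, ref, zeros, zeros.astype(bool) | True)
    clusters = ed.cluster_site_table(table, cfg.params.max_gap)
    return table, clusters


def _stage_ecr(cfg, outdir, report, logger):
    if not (outdir / "editing_sites.tsv").exists():
        raise PipelineError("stage 'ecr': missing editing stage output")
    table, clusters = _load_final_sites(cfg, outdir)
    ecrs = ed.build_ecrs(clusters, cfg.params)
    annot = pio.read_annotation(cfg.inputs["gtf"])
    introns = ann.derive_introns(annot)
    tracks = ann.FeatureTracks.from_annotation(annot, introns)
    # label each cluster, then each ECR by its member clusters
    cluster_labels = ann.map_to_features([c.interval for c in clusters], tracks)
    label_by_cluster = dict(zip((id(c) for c in clusters), cluster_labels))
    ebed = []
    utr3_track = [iv for iv, _ in tracks.tracks["UTR3"]]
    dist_rows = []
    for e in ecrs:
        member_labels = [label_by_cluster[id(c)].category for c in e.clusters]
        # ECR label: highest-priority member-cluster category
        order = ann.FEATURE_PRIORITY + [ann.INTERGENIC]
        label = min(member_labels, key=order.index)
        ebed.append(
            {
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "name": e.name,
                "score": e.n_clusters,
                "strand": ".",
                "feature": label,
            }
        )
        for c in e.clusters:
            if label_by_cluster[id(c)].category == ann.INTERGENIC:
                d = ann.distance_to_upstream_utr3(c.interval, utr3_track)
                dist_rows.append(
                    {
                        "chrom": c.chrom,
                        "start": c.interval.start,
                        "end": c.interval.end,
                        "distance_to_upstream_utr3": np.nan if d is None else d,
                    }
                )
    ebed = pd.DataFrame(ebed)
    pio.write_bed(
        ebed[["chrom", "start", "end", "name", "score", "strand"]],
        outdir / "ecrs.bed",
        _header(cfg, "ecr"),
    )
    pio.write_tsv(
        ebed[["name", "chrom", "start", "end", "feature"]],
        outdir / "ecr_features.tsv",
        _header(cfg, "ecr"),
    )
    pio.write_tsv(
        pd.DataFrame(dist_rows, columns=[
            "chrom", "start", "end", "distance_to_upstream_utr3",
        ]),
        outdir / "intergenic_cluster_utr3_distance.tsv",
        _header(cfg, "ecr"),
    )
    design = _read_design(cfg)
    day_editing = ed.ecr_editing_by_day(table, ecrs, design)
    pio.write_tsv(day_editing, outdir / "ecr_editing_by_day.tsv", _header(cfg, "ecr"))
    report["n_ecrs"] = len(ecrs)
    counts = ebed["feature"].value_counts()
    labels = ann.map_to_features([c.interval for c in clusters], tracks)
    cl_counts = pd.Series([l.category for l in labels]).value_counts()
    for cat in ["intron", "UTR3", "intergenic"]:
        report[f"cluster_fraction_{cat}"] = float(
            cl_counts.get(cat, 0) / max(1, len(clusters))
        )
    dists = pd.DataFrame(dist_rows)
    if len(dists):
        d = dists["distance_to_upstream_utr3"].dropna()
        report["intergenic_within_5kb_of_utr3"] = float((d <= 5000).mean())


def _stage_splicing(cfg, outdir, report, logger):
    if not (outdir / "genes.tsv").exists():
        raise PipelineError("stage 'splicing': missing annotate stage output")
    clusters = sp.read_splice_tables(
        cfg.inputs["splice_counts"], cfg.inputs.get("splice_significance")
    )
    design = _read_design(cfg)
    repeats = pio.read_bed(cfg.inputs["repeats"])
    clip = pio.read_bed(cfg.inputs["clip_peaks"])
    groups = {
        "CTRL": design.loc[design["condition"] == "CTRL", "sample_id"].tolist(),
        "hnRNPC": design.loc[design["condition"] == "hnRNPC", "sample_id"].tolist(),
    }
    tests = sp.differential_splice_clusters(clusters, groups)
    # externally supplied significance takes precedence
    p_adj = {
        cl.cluster_id: (cl.p_adj if cl.p_adj is not None else np.nan)
        for cl in clusters
    }
    if all(np.isnan(v) for v in p_adj.values()):
        p_adj = dict(zip(tests["cluster_id"], tests["p_adj"]))
    pio.write_tsv(tests, outdir / "splice_cluster_tests.tsv", _header(cfg, "splicing"))

    usage_rows = []
    for cl in clusters:
        pa = p_adj.get(cl.cluster_id, np.nan)
        if pa is None or np.isnan(pa) or pa > cfg.params.splice_p_strict:
            continue
        usage_rows.append(sp.relative_splice_site_use(cl, groups))
    usage = (
        pd.concat(usage_rows, ignore_index=True)
        if usage_rows
        else pd.DataFrame(columns=["cluster_id", "site", "side", "CTRL", "hnRNPC"])
    )
    pio.write_tsv(usage, outdir / "splice_site_usage.tsv", _header(cfg, "splicing"))

    all_sites = sorted(
        {(cl.chrom, s) for cl in clusters for s in cl.splice_sites()}
    )
    prox = sp.clip_proximity(all_sites, clip, cfg.params.clip_max_gap)
    pio.write_tsv(prox, outdir / "splice_clip_proximity.tsv", _header(cfg, "splicing"))

    per_cluster, fractions = sp.stratify_clusters(clusters, repeats, p_adj)
    pio.write_tsv(per_cluster, outdir / "splice_cluster_classes.tsv", _header(cfg, "splicing"))
    pio.write_tsv(fractions, outdir / "splice_class_fractions.tsv", _header(cfg, "splicing"))

    gene_counts = pio.read_counts(cfg.inputs["gene_counts"])
    lib = de.library_sizes(gene_counts)
    nf = de.normalization_factors(gene_counts)
    expressed = de.filter_features(gene_counts, "gene", cfg.params, lib, nf)
    genes = pio.read_tsv(outdir / "genes.tsv")
    spans = {
        r.gene_id: GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in genes.itertuples(index=False)
        if r.gene_id in expressed.index
    }
    overlap, frac = sp.gene_splice_overlap(
        spans, clusters, p_adj, cfg.params.splice_p_loose
    )
    pio.write_tsv(overlap, outdir / "gene_splice_overlap.tsv", _header(cfg, "splicing"))
    report["n_splice_clusters"] = len(clusters)
    sig = [v for v in p_adj.values() if v is not None and not np.isnan(v)]
    report["splice_clusters_differential"] = int(
        sum(v <= cfg.params.splice_p_loose for v in sig)
    )
    report["gene_splice_overlap_fraction"] = frac
    report["clip_proximal_fraction"] = float(prox["proximal"].mean()) if len(prox) else 0.0


def _stage_diffexp(cfg, outdir, report, logger):
    design = _read_design(cfg)
    gene_counts = pio.read_counts(cfg.inputs["gene_counts"])
    intron_counts = pio.read_counts(cfg.inputs["intron_counts"])
    ecr_counts = pio.read_counts(cfg.inputs["ecr_counts"])
    lengths = pio.read_tsv(cfg.inputs["ecr_lengths"]).set_index("feature_id")["length"]
    lib = de.library_sizes(gene_counts)
    nf = de.normalization_factors(gene_counts)
    nf_out = nf.rename("norm_factor").reset_index()
    nf_out.columns = ["sample_id", "norm_factor"]
    pio.write_tsv(nf_out, outdir / "norm_factors.tsv", _header(cfg, "diffexp"))

    results = {}
    for klass, counts in (
        ("gene", gene_counts), ("intron", intron_counts), ("ECR", ecr_counts)
    ):
        kept = de.filter_features(counts, klass, cfg.params, lib, nf)
        per_day = []
        for day in sorted(design["day"].unique()):
            res = de.differential_expression(
                kept, design, (f"CTRL_d{day}", f"hnRNPC_d{day}"), cfg.params,
                lib=lib, norm_factor=nf,
            )
            res.insert(0, "day", day)
            per_day.append(res)
        allres = pd.concat(per_day).reset_index()
        pio.write_tsv(allres, outdir / f"de_{klass.lower()}s.tsv", _header(cfg, "diffexp"))
        results[klass] = per_day
        report[f"n_{klass.lower()}_tested"] = len(kept)
        report[f"n_{klass.lower()}_regulated"] = int(
            pd.concat(per_day)["regulated"].sum()
        )

    # intron-vs-gene decoupling on the middle day
    day = sorted(design["day"].unique())[1]
    gene_day = results["gene"][1]
    intron_day = results["intron"][1]
    mapping = {iid: iid.split("_intron")[0] for iid in intron_day.index}
    mapping = {
        i: g for i, g in mapping.items() if g in gene_day.index
    }
    dec = de.intron_gene_decoupling(
        intron_day.loc[list(mapping)], gene_day, mapping
    )
    dec.insert(0, "day", day)
    pio.write_tsv(dec.reset_index(), outdir / "intron_gene_decoupling.tsv",
                  _header(cfg, "diffexp"))
    report["decoupled_intron_fraction"] = float(
        ((dec["delta"].abs() >= 1.0) & (dec["intron_log2fc"].abs() >= 1.0)).mean()
    )

    # rpkm expressed predicate for ECRs
    common = ecr_counts.index.intersection(lengths.index)
    rp = de.rpkm(ecr_counts.loc[common], lengths.loc[common], lib, nf)
    expressed = de.expressed_features(rp, design, cfg.params.ecr_min_rpkm)
    exp_out = expressed.rename("expressed").reset_index()
    exp_out.columns = ["feature_id", "expressed"]
    pio.write_tsv(exp_out, outdir / "ecr_expressed.tsv", _header(cfg, "diffexp"))
    report["n_ecr_expressed"] = int(expressed.sum())

    # 2x2 factorial interaction on the last day, across the ISG set
    if "isgs" in cfg.inputs:
        isgs = pio.read_tsv(cfg.inputs["isgs"])["feature_id"].tolist()
        last = sorted(design["day"].unique())[-1]
        sub = design[design["day"] == last]
        inter = de.interaction_test(gene_counts, sub, isgs, cfg.params, lib=lib,
                                    norm_factor=nf)
        pio.write_tsv(inter.reset_index(), outdir / "isg_interaction.tsv",
                      _header(cfg, "diffexp"))
        report["n_isg_tested"] = len(inter)
        report["n_isg_interaction_significant"] = int(inter["significant"].sum())
        report["mean_isg_interaction"] = float(inter["interaction"].mean())


def _stage_structure(cfg, outdir, report, logger):
    records = pio.read_structures(cfg.inputs["structures"])
    rows = []
    for rid, db in records:
        m = st.structure_metrics(db)
        flags = st.classify_ligand(m, cfg.params)
        rows.append(
            {
                "structure_id": rid,
                "total_length": m.total_length,
                "mismatch_fraction": m.mismatch_fraction,
                "longest_helix": m.longest_helix,
                "long_enough": flags.long_enough,
                "low_mismatch": flags.low_mismatch,
                "long_helix": flags.long_helix,
                "ligand_like": flags.ligand_like,
                "combinator": "any",
            }
        )
    out = pd.DataFrame(rows)
    pio.write_tsv(out, outdir / "structure_metrics.tsv", _header(cfg, "structure"))
    report["n_structures"] = len(out)
    report["n_ligand_like"] = int(out["ligand_like"].sum()) if len(out) else 0


def _stage_report(cfg, outdir, report, logger):
    rows = [{"metric": k, "value": v} for k, v in sorted(report.items())]
    pio.write_tsv(pd.DataFrame(rows), outdir / "report.tsv", _header(cfg, "report"))
    with open(outdir / "report.json", "w") as fh:
        json.dump({k: report[k] for k in sorted(report)}, fh, indent=2, default=float)
        fh.write("\n")


_STAGE_FUNCS = {
    "annotate": _stage_annotate,
    "editing": _stage_editing,
    "ecr": _stage_ecr,
    "splicing": _stage_splicing,
    "diffexp": _stage_diffexp,
    "structure": _stage_structure,
    "report": _stage_report,
}
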