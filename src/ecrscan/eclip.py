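"""Repeat-family eCLIP enrichment: the screen-selection statistic.

For each RNA family (Alu, L1, ...) and strand orientation, fold enrichment
compares the family's share of eCLIP reads with its share of size-matched
input reads; relative information content (RIC) weights the log2 fold
enrichment by the family's eCLIP read fraction, so abundant *and* enriched
families rank highest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ValidationError

REQUIRED = ["family", "strand", "eclip_reads", "input_reads"]


def family_enrichment(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-family fold enrichment and relative information content.

    ``counts`` columns: family, strand, eclip_reads, input_reads (and
    optionally eclip_total / input_total; otherwise library totals are the
    per-strand sums of family reads).  With a Laplace pseudocount on both
    libraries, p_eclip = (reads+pc)/(total+pc·n_families) and analogously
    for input; FE = p_eclip/p_input; RIC = p_eclip·log2(FE).  Families are
    ranked by RIC within each strand.
    """
    missing = [c for c in REQUIRED if c not in counts.columns]
    if missing:
        raise ValidationError(f"family counts missing columns {missing}")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    out = []
    for strand, grp in counts.groupby("strand", sort=True):
        grp = grp.copy()
        n_fam = len(grp)
        eclip_total = (
            float(grp["eclip_total"].iloc[0])
            if "eclip_total" in grp.columns
            else float(grp["eclip_reads"].sum())
        )
        input_total = (
            float(grp["input_total"].iloc[0])
            if "input_total" in grp.columns
            else float(grp["input_reads"].sum())
        )
        if eclip_total <= 0 or input_total <= 0:
            raise ValidationError(f"all-zero library for strand {strand!r}")
        p_eclip = (grp["eclip_reads"] + pseudocount) / (
            eclip_total + pseudocount * n_fam
        )
        p_input = (grp["input_reads"] + pseudocount) / (
            input_total + pseudocount * n_fam
        )
        if pseudocount == 0 and (p_input == 0).any():
            raise ValidationError(
                "zero input fraction without pseudocount; enrichment undefined"
            )
        fe = p_eclip / p_input
        grp["p_eclip"] = p_eclip
        grp["p_input"] = p_input
        grp["fold_enrichment"] = fe
        grp["ric"] = p_eclip * np.log2(fe)
        grp = grp.sort_values("ric", ascending=False)
        grp["rank"] = np.arange(1, len(grp) + 1)
        out.append(grp)
    return pd.concat(out, ignore_index=True)
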