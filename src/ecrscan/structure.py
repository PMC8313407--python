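"""Score dsRNA stretches from dot-bracket secondary structures.

A putative MDA5 ligand resembles the stimulatory inverted-repeat Alu
hairpins: total stretch length > 300 nt, mismatched-nucleotide fraction
(count of '.' over string length, terminal loop included) < 0.2, and/or a
longest uninterrupted helix ≥ 37 bp.  "Uninterrupted" requires contiguity
on both strands: a single-nucleotide bulge on either strand ends the run.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import PipelineParams, ValidationError


@dataclass(frozen=True)
class StretchMetrics:
    total_length: int
    mismatch_fraction: float
    longest_helix: int


@dataclass(frozen=True)
class LigandFlags:
    long_enough: bool  # length > 300 nt
    low_mismatch: bool  # mismatch fraction < 0.2
    long_helix: bool  # longest helix >= 37 bp
    ligand_like: bool  # combined per combinator


def pairing_table(dot_bracket: str) -> list[int | None]:
    """Partner index per position (None if unpaired); errors on unbalanced
    brackets."""
    bad = set(dot_bracket) - {"(", ")", "."}
    if bad:
        raise ValidationError(f"invalid dot-bracket characters {sorted(bad)}")
    partner: list[int | None] = [None] * len(dot_bracket)
    stack: list[int] = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValidationError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise ValidationError(f"unbalanced '(' at position {stack[-1]}")
    return partner


def longest_helix(dot_bracket: str) -> int:
    """Longest run of stacked base pairs contiguous on both strands.

    Position i extends the current helix iff both i and i−1 are paired and
    partner(i) == partner(i−1) − 1.
    """
    partner = pairing_table(dot_bracket)
    best = run = 0
    for i, p in enumerate(partner):
        if p is None:
            run = 0
            continue
        if i > 0 and partner[i - 1] is not None and p == partner[i - 1] - 1:
            run += 1
        else:
            run = 1
        best = max(best, run)
    return best


def structure_metrics(dot_bracket: str) -> StretchMetrics:
    """Length, mismatch fraction and longest uninterrupted helix of one
    structure record."""
    partner = pairing_table(dot_bracket)  # validates
    n = len(dot_bracket)
    if n == 0:
        raise ValidationError("empty structure")
    dots = dot_bracket.count(".")
    return StretchMetrics(
        total_length=n,
        mismatch_fraction=dots / n,
        longest_helix=longest_helix(dot_bracket),
    )


def classify_ligand(
    metrics: StretchMetrics,
    params: PipelineParams,
    combinator: str = "any",
) -> LigandFlags:
    """Evaluate the three irAlu-reference criteria and combine them.

    The default combinator "any" reflects the inclusive reading of the
    criteria; "all" requires every criterion.
    """
    if combinator not in ("any", "all"):
        raise ValidationError(f"combinator must be 'any' or 'all', got {combinator!r}")
    flags = (
        metrics.total_length > params.ligand_min_len,
        metrics.mismatch_fraction < params.ligand_max_mismatch_frac,
        metrics.longest_helix >= params.ligand_min_helix,
    )
    combined = any(flags) if combinator == "any" else all(flags)
    return LigandFlags(*flags, ligand_like=combined)
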