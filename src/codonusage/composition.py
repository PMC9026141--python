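"""Nucleotide composition statistics, CodonW-style.

Overall base fractions are computed on whole sequences; positional GC
(GC1, GC2, GC3 and their first/second-position mean GC12) on codon
count tables over all sense codons, stops excluded.  The "3s"
quantities (A3s, C3s, G3s, U3s and the synonymous GC3s variant) are
restricted to codons of synonymously degenerate families, i.e. AUG,
UGG and stops never contribute — the convention of CodonW, whose
output these statistics mirror.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codon_stats import CodonCountTable
from .errors import UndefinedCompositionError
from .genetic_code import GC_BASES, RNA_BASES

__all__ = [
    "CompositionSummary",
    "PositionalGC",
    "composition_overall",
    "positional_gc",
    "third_position_syn_fractions",
    "composition_summary",
]


@dataclass(frozen=True)
class PositionalGC:
    gc1: float
    gc2: float
    gc3: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2


@dataclass(frozen=True)
class CompositionSummary:
    """Per-isolate composition report (one column of a CodonW table)."""

    overall: dict[str, float]
    third_pos_syn: dict[str, float]
    gc1: float
    gc2: float
    gc3: float
    gc_overall: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2


def composition_overall(seq: str) -> dict[str, float]:
    """Fractions of A, C, G, U over the unambiguous positions of ``seq``."""
    counts = {b: 0 for b in RNA_BASES}
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise UndefinedCompositionError("no unambiguous bases in sequence")
    return {b: counts[b] / total for b in RNA_BASES}


def positional_gc(table: CodonCountTable, synonymous_only_gc3: bool = False) -> PositionalGC:
    """G+C fractions at the three codon positions of counted sense codons.

    With ``synonymous_only_gc3`` the third position is computed over
    degenerate-family codons only (the strict "GC3s" reading); the
    default uses all sense codons, which reproduces CodonW's table
    output.
    """
    code = table._code
    gc = [0, 0, 0]
    totals = [0, 0, 0]
    for codon in code.sense_codons:
        n = table.counts[codon]
        if n == 0:
            continue
        degenerate = code.degeneracy(codon) > 1
        for pos in range(3):
            if pos == 2 and synonymous_only_gc3 and not degenerate:
                continue
            totals[pos] += n
            if codon[pos] in GC_BASES:
                gc[pos] += n
    if totals[0] == 0 or totals[2] == 0:
        raise UndefinedCompositionError("empty codon count table")
    return PositionalGC(*(g / t for g, t in zip(gc, totals)))


def third_position_syn_fractions(table: CodonCountTable) -> dict[str, float]:
    """Third-position base fractions over degenerate-family codons.

    Excludes AUG, UGG and stop codons; the four fractions sum to one.
    """
    code = table._code
    counts = {b: 0 for b in RNA_BASES}
    for codon in code.sense_codons:
        if code.degeneracy(codon) > 1:
            counts[codon[2]] += table.counts[codon]
    total = sum(counts.values())
    if total == 0:
        raise UndefinedCompositionError(
            "no synonymous-family codons in the count table"
        )
    return {b: counts[b] / total for b in RNA_BASES}


def composition_summary(
    seq: str, table: CodonCountTable, synonymous_only_gc3: bool = False
) -> CompositionSummary:
    """Combine whole-sequence and codon-positional composition.

    ``seq`` is typically a full genome (poly-A trimmed) and ``table``
    the pooled codon counts of its ORFs.
    """
    overall = composition_overall(seq)
    pos = positional_gc(table, synonymous_only_gc3=synonymous_only_gc3)
    return CompositionSummary(
        overall=overall,
        third_pos_syn=third_position_syn_fractions(table),
        gc1=pos.gc1,
        gc2=pos.gc2,
        gc3=pos.gc3,
        gc_overall=overall["G"] + overall["C"],
    )
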