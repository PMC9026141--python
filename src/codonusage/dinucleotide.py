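"""Dinucleotide odds ratios (Karlin's rho*) per genomic region.

For dinucleotide XY the odds ratio is the observed overlapping
dinucleotide frequency relative to the product of the mononucleotide
frequencies of the same region:

.. math::  \\rho_{XY} = \\frac{f_{XY}}{f_X\\, f_Y}

By a widely used convention a dinucleotide is called significantly
underrepresented at :math:`\\rho \\le 0.78` and significantly
overrepresented at :math:`\\rho \\ge 1.23`.  CpG and UpA depletion in
RNA virus genomes — the pattern these calls are designed to expose —
reflects host antiviral pressure on those dinucleotides.

Dinucleotides are counted within each contiguous piece of a region and
never across the junction between separate pieces, so no phantom pairs
arise when a region (e.g. the UTR complement of several ORFs) is split.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .errors import UndefinedCompositionError
from .genetic_code import RNA_BASES
from .sequence_io import SequenceRecord

UNDER_THRESHOLD = 0.78
OVER_THRESHOLD = 1.23

CALL_UNDER = "underrepresented"
CALL_NORMAL = "normal"
CALL_OVER = "overrepresented"

DINUCLEOTIDES = tuple(a + b for a, b in product(RNA_BASES, RNA_BASES))


@dataclass(frozen=True)
class DinucleotideProfile:
    """Sixteen odds ratios for one region, with representation calls."""

    region: str
    rho: dict[str, float | None]
    n_dinucleotides: int

    @property
    def calls(self) -> dict[str, str]:
        return {
            d: (call_value(r) if r is not None else "missing")
            for d, r in self.rho.items()
        }


def call_value(
    rho: float,
    under: float = UNDER_THRESHOLD,
    over: float = OVER_THRESHOLD,
) -> str:
    """Threshold call with inclusive boundaries on both sides."""
    if rho <= under:
        return CALL_UNDER
    if rho >= over:
        return CALL_OVER
    return CALL_NORMAL


def dinucleotide_odds(
    seqs: Iterable[str], region: str = "whole-genome"
) -> DinucleotideProfile:
    """Odds ratios over one or more contiguous sequence pieces.

    Mononucleotide frequencies come from the same pieces as the
    dinucleotide counts; pairs containing ambiguity codes are skipped.
    Ratios whose mononucleotide product is zero are reported as ``None``
    (missing), not zero.
    """
    mono = {b: 0 for b in RNA_BASES}
    di = {d: 0 for d in DINUCLEOTIDES}
    n_pairs = 0
    for seq in seqs:
        for ch in seq:
            if ch in mono:
                mono[ch] += 1
        for i in range(len(seq) - 1):
            pair = seq[i : i + 2]
            if pair in di:
                di[pair] += 1
                n_pairs += 1
    n_mono = sum(mono.values())
    if n_pairs == 0:
        raise UndefinedCompositionError("region too short to count dinucleotides")
    f_mono = {b: c / n_mono for b, c in mono.items()}
    rho: dict[str, float | None] = {}
    for d in DINUCLEOTIDES:
        denom = f_mono[d[0]] * f_mono[d[1]]
        rho[d] = (di[d] / n_pairs) / denom if denom > 0 else None
    return DinucleotideProfile(region=region, rho=rho, n_dinucleotides=n_pairs)


def call_representation(profile: DinucleotideProfile) -> dict[str, str]:
    """Per-dinucleotide representation calls for a computed profile."""
    return profile.calls


def region_profiles(record: SequenceRecord) -> dict[str, DinucleotideProfile]:
    """Whole-genome, CDS and UTR odds-ratio profiles of one record.

    The UTR is the complement of the CDS spans within the sequence; if
    that complement is empty the UTR profile is reported as ``None``.
    """
    out: dict[str, DinucleotideProfile | None] = {}
    out["whole-genome"] = dinucleotide_odds([record.seq], region="whole-genome")
    cds_pieces = [record.seq[r.start : r.end] for r in record.cds_regions()]
    out["CDS"] = (
        dinucleotide_odds(cds_pieces, region="CDS") if cds_pieces else None
    )
    utr_pieces = [record.seq[s:e] for s, e in record.utr_complement()]
    try:
        out["UTR"] = (
            dinucleotide_odds(utr_pieces, region="UTR") if utr_pieces else None
        )
    except UndefinedCompositionError:
        out["UTR"] = None
    return out


def mean_profile(
    profiles: Sequence[DinucleotideProfile], region: str
) -> DinucleotideProfile:
    """Average per-isolate odds ratios dinucleotide-by-dinucleotide.

    A ratio missing in some isolates is averaged over the isolates where
    it is defined; missing everywhere stays missing.
    """
    rho: dict[str, float | None] = {}
    for d in DINUCLEOTIDES:
        vals = [p.rho[d] for p in profiles if p.rho[d] is not None]
        rho[d] = sum(vals) / len(vals) if vals else None
    return DinucleotideProfile(
        region=region,
        rho=rho,
        n_dinucleotides=sum(p.n_dinucleotides for p in profiles),
    )
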