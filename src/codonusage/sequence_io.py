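"""FASTA input/output, alphabet normalization and CDS extraction.

The internal alphabet is RNA (``U``); DNA input is converted on read so
that positive-sense RNA virus genomes and host mRNA sets flow through
identical code paths.  Coordinates are 0-based half-open throughout.
Only the forward strand is considered when scanning for open reading
frames, which matches the mRNA / +ssRNA context this package targets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO

from .errors import FastaFormatError
from .genetic_code import GeneticCode, standard_code

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGU")
START_CODON = "AUG"


@dataclass(frozen=True)
class Region:
    """A labelled half-open span ``[start, end)`` on a sequence."""

    label: Literal["CDS", "UTR"]
    start: int
    end: int
    frame_ok: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with annotations and isolate metadata.

    ``seq`` is upper-case RNA after normalization; positions holding
    characters outside ``{A, C, G, U}`` (ambiguity codes, gaps) are
    listed in ``ambiguous_positions`` and the original characters kept.
    """

    id: str
    seq: str
    regions: tuple[Region, ...] = ()
    meta: dict = field(default_factory=dict)
    description: str = ""

    @property
    def ambiguous_positions(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.seq) if b not in _VALID_BASES)

    @property
    def is_ambiguous(self) -> bool:
        return any(b not in _VALID_BASES for b in self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def cds_regions(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.label == "CDS")

    def utr_complement(self) -> tuple[tuple[int, int], ...]:
        """Spans of the sequence not covered by any CDS region."""
        covered = sorted((r.start, r.end) for r in self.cds_regions())
        merged: list[list[int]] = []
        for s, e in covered:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out, pos = [], 0
        for s, e in merged:
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < len(self.seq):
            out.append((pos, len(self.seq)))
        return tuple(out)


@dataclass(frozen=True)
class CdsValidationReport:
    """Outcome of coding-sequence quality filtering for one record."""

    id: str
    failure_reasons: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.failure_reasons


def normalize(seq: str) -> str:
    """Upper-case and convert DNA ``T`` to RNA ``U``."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized :class:`SequenceRecord` s.

    The first whitespace-delimited token of the description line becomes
    the record id; the remainder is kept verbatim in ``description``.

    Raises
    ------
    FastaFormatError
        If sequence data precedes the first header line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}: sequence data before first FASTA header", line=lineno
                )
            break
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=entry.id,
                seq=normalize(str(entry.seq)),
                description=entry.description[len(entry.id) :].strip(),
            )
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    alphabet: Literal["rna", "dna"] = "rna",
    width: int = 70,
) -> None:
    """Write records as FASTA; ``alphabet='dna'`` converts U back to T."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            seq = to_dna(rec.seq) if alphabet == "dna" else rec.seq
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata_tsv(path: str | Path) -> dict[str, dict]:
    """Read an id/host/country/clade sidecar table keyed by record id."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rid = row.pop("id")
            out[rid] = {k: v for k, v in row.items() if v != ""}
    return out


def write_metadata_tsv(records: Iterable[SequenceRecord], path: str | Path) -> None:
    keys = ("host", "country", "clade")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(("id",) + keys)
        for rec in records:
            writer.writerow([rec.id] + [rec.meta.get(k, "") for k in keys])


def read_spans_tsv(path: str | Path) -> dict[str, list[Region]]:
    """Read a span sidecar (columns id, label, start, end) keyed by id."""
    out: dict[str, list[Region]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["id"], []).append(
                Region(row["label"], int(row["start"]), int(row["end"]))
            )
    return out


def write_spans_tsv(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(("id", "label", "start", "end"))
        for rec in records:
            for region in rec.regions:
                writer.writerow((rec.id, region.label, region.start, region.end))


def attach_annotations(
    records: Iterable[SequenceRecord],
    spans: dict[str, list[Region]] | None = None,
    metadata: dict[str, dict] | None = None,
) -> list[SequenceRecord]:
    out = []
    for rec in records:
        if spans and rec.id in spans:
            rec = replace(rec, regions=tuple(spans[rec.id]))
        if metadata and rec.id in metadata:
            rec = replace(rec, meta={**rec.meta, **metadata[rec.id]})
        out.append(rec)
    return out


def validate_cds(
    record: SequenceRecord,
    min_length: int = 30,
    code: GeneticCode | None = None,
) -> CdsValidationReport:
    """Quality-filter one putative coding sequence.

    A record passes when it starts with AUG, ends with a stop codon, has
    length divisible by three, contains no in-frame internal stop, no
    ambiguity codes, and codes for at least ``min_length`` amino acids
    between the start and stop codons.
    """
    code = code or standard_code()
    seq = record.seq
    reasons: list[str] = []
    if record.is_ambiguous:
        reasons.append("ambiguous-bases")
    if len(seq) % 3 != 0:
        reasons.append("length-not-multiple-of-3")
    if not seq.startswith(START_CODON):
        reasons.append("no-start")
    n_codons = len(seq) // 3
    terminal = seq[(n_codons - 1) * 3 : n_codons * 3] if n_codons else ""
    if len(seq) % 3 != 0 or terminal not in code.stops:
        reasons.append("no-terminal-stop")
    internal = any(
        seq[i : i + 3] in code.stops for i in range(3, (n_codons - 1) * 3, 3)
    )
    if internal:
        reasons.append("internal-stop")
    # codons strictly between start and terminal stop
    if n_codons - 2 < min_length:
        reasons.append("too-short")
    return CdsValidationReport(id=record.id, failure_reasons=tuple(reasons))


def _scan_orfs(seq: str, code: GeneticCode) -> Iterator[tuple[int, int]]:
    """Yield (start, end) of every AUG..stop ORF on the forward strand."""
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == START_CODON:
                    start = i
            elif codon in code.stops:
                yield start, i + 3
                start = None


def extract_orfs(
    record: SequenceRecord,
    strategy: Literal["annotated-spans", "longest-orf-scan"] = "annotated-spans",
    min_length: int = 1,
    code: GeneticCode | None = None,
) -> list[SequenceRecord]:
    """Extract CDS sub-records from a genome or mRNA record.

    ``annotated-spans`` cuts out each annotated CDS region, dropping (with
    a logged warning) spans that fail frame validation.  ``longest-orf-scan``
    returns the single longest forward-strand AUG->stop ORF that passes
    :func:`validate_cds` with the given ``min_length``.
    """
    code = code or standard_code()
    out: list[SequenceRecord] = []
    if strategy == "annotated-spans":
        for k, region in enumerate(record.cds_regions()):
            sub = SequenceRecord(
                id=f"{record.id}|CDS{k}",
                seq=record.seq[region.start : region.end],
                regions=(Region("CDS", 0, region.end - region.start),),
                meta=dict(record.meta),
            )
            report = validate_cds(sub, min_length=min_length, code=code)
            if report.passed:
                out.append(sub)
            else:
                logger.warning(
                    "dropping CDS span %s [%d, %d): %s",
                    record.id,
                    region.start,
                    region.end,
                    ", ".join(report.failure_reasons),
                )
        return out
    if strategy == "longest-orf-scan":
        best: tuple[int, int] | None = None
        for start, end in _scan_orfs(record.seq, code):
            if best is None or end - start > best[1] - best[0]:
                candidate = SequenceRecord(id=record.id, seq=record.seq[start:end])
                if validate_cds(candidate, min_length=min_length, code=code).passed:
                    best = (start, end)
        if best is None:
            return []
        start, end = best
        return [
            SequenceRecord(
                id=f"{record.id}|ORF",
                seq=record.seq[start:end],
                regions=(Region("CDS", 0, end - start),),
                meta=dict(record.meta),
            )
        ]
    raise ValueError(f"unknown strategy: {strategy!r}")
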