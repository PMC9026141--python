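"""Codon counting, relative synonymous codon usage (RSCU) and codon
classification.

RSCU for codon *j* of amino acid *i* with synonymous family size
:math:`n_i` is the observed count scaled to its expectation under equal
usage within the family:

.. math::  \\mathrm{RSCU}_{ij} = \\frac{x_{ij}\\, n_i}{\\sum_j x_{ij}}

so the values of an observed family always sum to the family size and a
value of 1 means no bias.  Codons with RSCU above 1.5 are conventionally
called significantly preferred and codons below 0.6 significantly
unpreferred; between those bounds a codon is preferred (>1) or
unpreferred (<1).  The two single-codon families (AUG, UGG) and stops
are excluded, leaving 59 classifiable codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CdsValidationError, InsufficientGroupsError, UndefinedStatisticError
from .genetic_code import GeneticCode, standard_code
from .sequence_io import SequenceRecord, validate_cds

CLASS_SIG_PREFERRED = "significantly-preferred"
CLASS_PREFERRED = "preferred"
CLASS_NO_BIAS = "no-bias"
CLASS_UNPREFERRED = "unpreferred"
CLASS_SIG_UNPREFERRED = "significantly-unpreferred"
CLASS_MISSING = "missing"

CLASS_ORDER = (
    CLASS_SIG_PREFERRED,
    CLASS_PREFERRED,
    CLASS_NO_BIAS,
    CLASS_UNPREFERRED,
    CLASS_SIG_UNPREFERRED,
)


@dataclass
class CodonCountTable:
    """Counts over the 64 codons, pooled from one or more CDS records."""

    counts: dict[str, int]
    source_ids: tuple[str, ...] = ()
    ambiguous_skipped: int = 0
    _code: GeneticCode = field(default_factory=standard_code, repr=False)

    def __post_init__(self) -> None:
        full = dict.fromkeys(self._code.sense_codons, 0)
        full.update(dict.fromkeys(self._code.stops, 0))
        for codon, n in self.counts.items():
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] = int(n)
        self.counts = full

    @property
    def n_codons(self) -> int:
        """Total sense-codon count (stop codons excluded)."""
        return sum(self.counts[c] for c in self._code.sense_codons)

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts[c] for c in self._code.families[aa]}

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in self.counts}
        return CodonCountTable(
            counts=merged,
            source_ids=self.source_ids + other.source_ids,
            ambiguous_skipped=self.ambiguous_skipped + other.ambiguous_skipped,
        )

    def is_empty(self) -> bool:
        return self.n_codons == 0


def count_codons(
    cds_records: Iterable[SequenceRecord],
    force: bool = False,
    min_length: int = 1,
    code: GeneticCode | None = None,
) -> CodonCountTable:
    """Count in-frame codons over a set of CDS records.

    The terminal stop codon is recorded under its stop key but excluded
    from ``n_codons``; triplets containing ambiguity codes are skipped
    and tallied in ``ambiguous_skipped``.  Records failing CDS
    validation raise unless ``force`` is set.
    """
    code = code or standard_code()
    counts: dict[str, int] = {}
    ids: list[str] = []
    skipped = 0
    for rec in cds_records:
        if not force:
            report = validate_cds(rec, min_length=min_length, code=code)
            if not report.passed:
                raise CdsValidationError(
                    f"record {rec.id!r} fails CDS validation: "
                    f"{', '.join(report.failure_reasons)}"
                )
        for i in range(0, len(rec.seq) - len(rec.seq) % 3, 3):
            codon = rec.seq[i : i + 3]
            if codon in code.table or codon in code.stops:
                counts[codon] = counts.get(codon, 0) + 1
            else:
                skipped += 1
        ids.append(rec.id)
    return CodonCountTable(
        counts=counts, source_ids=tuple(ids), ambiguous_skipped=skipped
    )


@dataclass
class RSCUTable:
    """RSCU values with per-codon bias classes.

    ``values`` holds the 59 classifiable codons (plus AUG/UGG fixed at
    1.0 when their amino acid is observed); codons of unobserved amino
    acids go to ``missing`` and never appear as zeros.
    """

    values: dict[str, float]
    missing: frozenset[str] = frozenset()
    label: str = ""
    _code: GeneticCode = field(default_factory=standard_code, repr=False)

    @property
    def classes(self) -> dict[str, str]:
        out = {c: classify_value(v) for c, v in self.values.items()
               if c in self._code.classifiable_codons}
        out.update(dict.fromkeys(self.missing, CLASS_MISSING))
        return out

    def classifiable_values(self) -> dict[str, float]:
        return {
            c: v
            for c, v in self.values.items()
            if c in self._code.classifiable_codons
        }


def classify_value(value: float) -> str:
    """Map one RSCU value to its bias class.

    Boundaries follow the conventional reading: strictly above 1.5 is
    significantly preferred, strictly below 0.6 significantly
    unpreferred, exactly 1 is no bias.
    """
    if value > 1.5:
        return CLASS_SIG_PREFERRED
    if value > 1.0:
        return CLASS_PREFERRED
    if value == 1.0:
        return CLASS_NO_BIAS
    if value >= 0.6:
        return CLASS_UNPREFERRED
    return CLASS_SIG_UNPREFERRED


def rscu(table: CodonCountTable, label: str = "") -> RSCUTable:
    """Compute RSCU from a codon count table.

    Families whose total count is zero are marked missing rather than
    set to 0, since a zero would spuriously classify every member as
    significantly unpreferred.
    """
    if table.is_empty():
        raise UndefinedStatisticError("RSCU of an empty codon count table")
    code = table._code
    values: dict[str, float] = {}
    missing: set[str] = set()
    for aa, family in code.families.items():
        total = sum(table.counts[c] for c in family)
        if total == 0:
            missing.update(family)
            continue
        n_i = len(family)
        for c in family:
            values[c] = table.counts[c] * n_i / total
    return RSCUTable(values=values, missing=frozenset(missing), label=label)


@dataclass(frozen=True)
class Classification:
    """Partition of the 59 classifiable codons into bias classes."""

    by_class: dict[str, tuple[str, ...]]
    ending_counts: dict[str, dict[str, int]]  # class -> {"AU": n, "GC": n}
    n_preferred_strict: int  # RSCU strictly > 1.0
    n_preferred_inclusive: int  # RSCU >= 1.0

    def __getitem__(self, cls: str) -> tuple[str, ...]:
        return self.by_class.get(cls, ())


def classify(rscu_table: RSCUTable) -> Classification:
    """Partition classifiable codons by bias class.

    Alongside the partition, counts of A/U-ending versus G/C-ending
    codons are reported per class, and both the strict (>1) and
    inclusive (>=1) preferred-codon counts are given: values printed as
    exactly 1.00 flip between the two readings.
    """
    by_class: dict[str, list[str]] = {c: [] for c in CLASS_ORDER}
    by_class[CLASS_MISSING] = []
    for codon, cls in rscu_table.classes.items():
        by_class[cls].append(codon)
    ending: dict[str, dict[str, int]] = {}
    for cls, codons in by_class.items():
        ending[cls] = {
            "AU": sum(1 for c in codons if c[2] in "AU"),
            "GC": sum(1 for c in codons if c[2] in "GC"),
        }
    vals = rscu_table.classifiable_values()
    return Classification(
        by_class={cls: tuple(sorted(codons)) for cls, codons in by_class.items()},
        ending_counts=ending,
        n_preferred_strict=sum(1 for v in vals.values() if v > 1.0),
        n_preferred_inclusive=sum(1 for v in vals.values() if v >= 1.0),
    )


def mean_rscu(
    tables: Sequence[RSCUTable], label: str = "", min_present: int = 1
) -> RSCUTable:
    """Arithmetic mean of per-isolate RSCU values, codon by codon.

    A codon is averaged over the isolates in which its family is
    observed; it stays missing only if absent from more than
    ``len(tables) - min_present`` isolates.
    """
    if not tables:
        raise UndefinedStatisticError("mean RSCU of zero tables")
    code = tables[0]._code
    values: dict[str, float] = {}
    missing: set[str] = set()
    all_codons = set().union(*({*t.values} | t.missing for t in tables))
    for codon in all_codons:
        present = [t.values[codon] for t in tables if codon in t.values]
        if len(present) >= min_present:
            values[codon] = sum(present) / len(present)
        else:
            missing.add(codon)
    return RSCUTable(values=values, missing=frozenset(missing), label=label, _code=code)


@dataclass(frozen=True)
class RscuRange:
    codon: str
    range: float
    argmax: str
    argmin: str


def rscu_range(group_tables: Mapping[str, RSCUTable]) -> list[RscuRange]:
    """Max-minus-min RSCU per codon across groups, sorted descending.

    Codons missing in any group are excluded.  Requires at least two
    groups.
    """
    if len(group_tables) < 2:
        raise InsufficientGroupsError(
            f"need >= 2 groups for RSCU ranges, got {len(group_tables)}"
        )
    labels = list(group_tables)
    code = next(iter(group_tables.values()))._code
    out = []
    for codon in code.classifiable_codons:
        if any(codon not in t.values for t in group_tables.values()):
            continue
        vals = {g: group_tables[g].values[codon] for g in labels}
        hi = max(labels, key=lambda g: (vals[g], g))
        lo = min(labels, key=lambda g: (vals[g], g))
        out.append(RscuRange(codon, vals[hi] - vals[lo], hi, lo))
    out.sort(key=lambda r: (-r.range, r.codon))
    return out


def rscu_from_values(values: Mapping[str, float], label: str = "") -> RSCUTable:
    """Build an :class:`RSCUTable` from externally supplied values.

    Accepts DNA or RNA codon spelling.  Codons of the standard code not
    present in ``values`` are marked missing.  Family sums are checked
    loosely (printed tables are rounded to two decimals).
    """
    code = standard_code()
    norm = {k.upper().replace("T", "U"): float(v) for k, v in values.items()}
    unknown = set(norm) - set(code.sense_codons)
    if unknown:
        raise ValueError(f"not sense codons: {sorted(unknown)}")
    missing = {
        c
        for c in code.classifiable_codons
        if c not in norm and not any(f in norm for f in code.family_of(c))
    }
    for aa, family in code.families.items():
        present = [norm[c] for c in family if c in norm]
        if present and len(family) > 1:
            if not math.isclose(sum(present), len(family), abs_tol=0.05 * len(family)):
                raise ValueError(
                    f"family {aa} RSCU values sum to {sum(present):.3f}, "
                    f"expected about {len(family)}"
                )
    return RSCUTable(values=norm, missing=frozenset(missing), label=label)
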