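"""The standard genetic code over the RNA alphabet.

Synonymous codon *families* (all codons translating to one amino acid)
are the unit of every bias statistic in this package: RSCU normalises
within families, the effective number of codons averages per-family
homozygosities by family size, and "3s" composition statistics are
restricted to degenerate families.  Under the standard nuclear code the
family sizes are 1 (Met, Trp), 2 (Phe, Tyr, His, Gln, Asn, Lys, Asp,
Glu, Cys), 3 (Ile), 4 (Val, Pro, Thr, Ala, Gly) and 6 (Leu, Ser, Arg),
covering the 61 sense codons; the 59 "classifiable" codons exclude the
single-codon families AUG and UGG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_rna_by_id

RNA_BASES = ("A", "C", "G", "U")
GC_BASES = frozenset("GC")


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid table plus family structure.

    Attributes
    ----------
    table : dict
        Sense codon -> one-letter amino acid (61 entries).
    families : dict
        Amino acid -> tuple of synonymous codons, sorted.
    stops : frozenset
        The three stop codons.
    """

    table: dict[str, str]
    families: dict[str, tuple[str, ...]]
    stops: frozenset[str]
    sense_codons: tuple[str, ...] = field(init=False)
    classifiable_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        sense = tuple(sorted(self.table))
        classifiable = tuple(c for c in sense if len(self.families[self.table[c]]) > 1)
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "classifiable_codons", classifiable)

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.table[codon]]

    def degeneracy(self, codon: str) -> int:
        return len(self.family_of(codon))

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Partition amino acids by synonymous family size."""
        classes: dict[int, list[str]] = {}
        for aa, fam in self.families.items():
            classes.setdefault(len(fam), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in classes.items()}

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI translation table 1), RNA."""
    bio = unambiguous_rna_by_id[1]
    table = dict(bio.forward_table)
    families: dict[str, list[str]] = {}
    for codon, aa in table.items():
        families.setdefault(aa, []).append(codon)
    return GeneticCode(
        table=table,
        families={aa: tuple(sorted(cods)) for aa, cods in families.items()},
        stops=frozenset(bio.stop_codons),
    )


def translate(seq: str, code: GeneticCode | None = None) -> str:
    """Translate an in-frame RNA CDS to protein; stops render as ``*``."""
    code = code or standard_code()
    prot = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        prot.append("*" if codon in code.stops else code.table.get(codon, "X"))
    return "".join(prot)
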