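"""Wright's effective number of codons (ENC) and the ENC-plot null curve.

ENC condenses codon usage bias into a single number between 20 (one
codon per amino acid, maximal bias) and 61 (all synonymous codons used
equally, no bias).  For a synonymous family with counts
:math:`x_1..x_n` and total :math:`n`, the codon homozygosity is

.. math::  F = \\frac{n \\sum_i p_i^2 - 1}{n - 1}, \\qquad p_i = x_i / n

and ENC combines the mean homozygosity :math:`\\bar F_k` of each
degeneracy class (9 two-fold, 1 three-fold, 5 four-fold and 3 six-fold
families under the standard code):

.. math::  N_c = 2 + \\frac{9}{\\bar F_2} + \\frac{1}{\\bar F_3}
               + \\frac{5}{\\bar F_4} + \\frac{3}{\\bar F_6}

Families observed fewer than twice are skipped; when the three-fold
class (Ile alone) is unobserved its mean is imputed as
:math:`(\\bar F_2 + \\bar F_4)/2`, other missing classes from the mean
of the available ones, and the result is clamped to [20, 61] — the
default behaviour of the CodonW program, which these routines mirror.

The ENC-plot null curve gives the ENC expected when codon choice is
driven purely by the third-position G+C content *s*:

.. math::  N_c^{exp}(s) = 2 + s + \\frac{29}{s^2 + (1-s)^2}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .codon_stats import CodonCountTable
from .errors import UndefinedStatisticError

ENC_MIN = 20.0
ENC_MAX = 61.0

# number of amino-acid families per degeneracy class, standard code
_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


def family_homozygosity(counts: Mapping[str, int] | Sequence[int]) -> float | None:
    """Codon homozygosity F of one synonymous family.

    Returns ``None`` (family skipped) when the family total is below 2,
    where F is undefined.
    """
    xs = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    n = sum(xs)
    if n < 2:
        return None
    s = sum((x / n) ** 2 for x in xs)
    return (n * s - 1) / (n - 1)


@dataclass(frozen=True)
class ENCResult:
    """ENC with the per-class mean homozygosities behind it."""

    enc: float
    f_bar: dict[int, float]
    per_family_f: dict[str, float]
    imputed_classes: frozenset[int] = frozenset()
    clamped: bool = False


def enc_value(table: CodonCountTable) -> ENCResult:
    """Wright's ENC of a codon count table.

    Families with F = 0 (possible at tiny counts, e.g. two codons used
    once each) are excluded from their class mean to avoid division
    blow-ups; a class lost entirely this way falls back to the
    imputation rule.
    """
    if table.is_empty():
        raise UndefinedStatisticError("ENC of an empty codon count table")
    code = table._code
    per_family: dict[str, float] = {}
    class_fs: dict[int, list[float]] = {k: [] for k in _CLASS_WEIGHTS}
    for aa, family in code.families.items():
        k = len(family)
        if k == 1:
            continue
        f = family_homozygosity(table.family_counts(aa))
        if f is None:
            continue
        per_family[aa] = f
        if f > 0:
            class_fs[k].append(f)
    f_bar = {k: sum(v) / len(v) for k, v in class_fs.items() if v}
    if len(f_bar) < 2:
        raise UndefinedStatisticError(
            "fewer than two degeneracy classes observable; ENC undefined"
        )
    imputed: set[int] = set()
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
        imputed.add(3)
    available_mean = sum(f_bar.values()) / len(f_bar)
    for k in _CLASS_WEIGHTS:
        if k not in f_bar:
            f_bar[k] = available_mean
            imputed.add(k)
    enc = 2 + sum(w / f_bar[k] for k, w in _CLASS_WEIGHTS.items())
    clamped = not (ENC_MIN <= enc <= ENC_MAX)
    enc = min(max(enc, ENC_MIN), ENC_MAX)
    return ENCResult(
        enc=enc,
        f_bar=dict(sorted(f_bar.items())),
        per_family_f=per_family,
        imputed_classes=frozenset(imputed),
        clamped=clamped,
    )


def enc_expected(s: float) -> float:
    """Null-model ENC at third-position G+C content ``s`` in (0, 1)."""
    if not 0.0 < s < 1.0:
        raise ValueError(f"GC3s must lie strictly inside (0, 1), got {s}")
    return 2 + s + 29.0 / (s * s + (1 - s) * (1 - s))


@dataclass(frozen=True)
class ENCPlotPoint:
    id: str
    gc3: float
    enc: float
    expected: float = field(compare=False)
    below_curve: bool = field(compare=False)


def enc_plot_points(
    isolates: Iterable[tuple[str, float, float]],
) -> list[ENCPlotPoint]:
    """Annotate (id, GC3s, ENC) triples with the null curve.

    ``below_curve`` is a strict inequality: a point exactly on the
    curve is not flagged.
    """
    out = []
    for iid, gc3, enc in isolates:
        exp = enc_expected(gc3)
        out.append(ENCPlotPoint(iid, gc3, enc, exp, enc < exp))
    return out
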