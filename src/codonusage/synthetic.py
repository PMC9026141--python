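"""Synthetic coding-sequence and isolate-set generator.

Every analysis stage in this package assumes data with a particular
statistical structure: codon counts drawn from per-amino-acid codon
frequencies, a linear GC12 = a + b*GC3 relationship across isolates,
and controlled CpG/UpA depletion.  This module generates datasets with
exactly that structure so each analysis can be validated as a
parameter-recovery problem.

Defaults mirror the cowpea mild mottle virus study system: per-family
codon probabilities derived from the published CpMMV RSCU vector, a
genome base composition of A 0.29 / U 0.30 / C 0.18 / G 0.23 for
untranslated regions, 33 isolates of six ORFs and roughly 2,900 codons
each, a GC12-on-GC3 slope of 0.3863, and moderate CpG/UpA suppression.

The GC structure across isolates is imposed by exponential tilting: for
isolate *i* with targets (gc3_i, gc12_i) the 61-codon distribution is
reweighted as  p(c) \\propto q(c) exp(t3 g3(c) + t12 (g1(c)+g2(c)))
where g_k(c) indicates G or C at codon position k, and (t3, t12) are
solved so the tilted expectations hit the targets.  Codon sampling then
reproduces the targets up to multinomial error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from . import data as refdata
from .codon_stats import CodonCountTable
from .errors import FeasibilityError, GeneratorSpecError
from .genetic_code import GC_BASES, GeneticCode, standard_code
from .sequence_io import Region, SequenceRecord

# Average amino-acid frequencies of well-curated protein sequence
# databases; a generic, realistic protein composition.
_RAW_AA_PROFILE = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0475,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}
DEFAULT_AA_PROFILE: dict[str, float] = {
    aa: v / sum(_RAW_AA_PROFILE.values()) for aa, v in _RAW_AA_PROFILE.items()
}

STOP_WEIGHTS = {"UAA": 0.5, "UAG": 0.2, "UGA": 0.3}


def default_codon_probs(code: GeneticCode | None = None) -> dict[str, dict[str, float]]:
    """Within-family codon probabilities from the CpMMV RSCU vector.

    RSCU divided by family size is a probability up to rounding of the
    published values; each family is renormalised to sum exactly to 1.
    """
    code = code or standard_code()
    probs: dict[str, dict[str, float]] = {}
    for aa, family in code.families.items():
        if len(family) == 1:
            probs[aa] = {family[0]: 1.0}
            continue
        raw = {c: refdata.CPMMV_RSCU[c] / len(family) for c in family}
        total = sum(raw.values())
        probs[aa] = {c: v / total for c, v in raw.items()}
    return probs


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic dataset generator.

    ``slope``/``intercept``/``noise_sd`` define the across-isolate
    structure GC12 = intercept + slope * GC3 + N(0, noise_sd), with GC3
    targets spread evenly over ``gc3_range``.  Suppression factors in
    (0, 1] multiply the sampling weight of every codon (or UTR base)
    whose choice would create a CpG / UpA dinucleotide; 1.0 disables
    suppression.
    """

    codon_probs: dict[str, dict[str, float]] = field(default_factory=default_codon_probs)
    aa_profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_PROFILE))
    n_codons: int = 2900
    n_isolates: int = 33
    n_orfs: int = 6
    slope: float = 0.3863
    intercept: float = 0.2555
    noise_sd: float = 0.005
    gc3_range: tuple[float, float] = (0.30, 0.50)
    base_composition: dict[str, float] = field(
        default_factory=lambda: dict(refdata.CPMMV_BASE_COMPOSITION)
    )
    utr_length: int = 80
    cpg_suppression: float = 1.0
    upa_suppression: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        code = standard_code()
        if set(self.aa_profile) != set(code.families):
            raise GeneratorSpecError("aa_profile must cover exactly the 20 amino acids")
        if any(p < 0 for p in self.aa_profile.values()):
            raise GeneratorSpecError("negative amino-acid probability")
        if not math.isclose(sum(self.aa_profile.values()), 1.0, abs_tol=1e-6):
            raise GeneratorSpecError("aa_profile must sum to 1")
        for aa, fam in self.codon_probs.items():
            if set(fam) != set(code.families[aa]):
                raise GeneratorSpecError(f"codon_probs for {aa} must cover its family")
            if any(p < 0 for p in fam.values()):
                raise GeneratorSpecError(f"negative codon probability for {aa}")
            if not math.isclose(sum(fam.values()), 1.0, abs_tol=1e-6):
                raise GeneratorSpecError(f"codon_probs for {aa} must sum to 1")
        for name in ("cpg_suppression", "upa_suppression"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise GeneratorSpecError(f"{name} must lie in (0, 1], got {v}")
        if self.noise_sd < 0 or self.n_codons < 1:
            raise GeneratorSpecError("noise_sd must be >= 0 and n_codons >= 1")


def cpmmv_like_spec(seed: int = 0, **overrides) -> GeneratorSpec:
    """The default study-scale fixture: a CpMMV-like isolate set.

    33 isolates, six ORFs and ~2,900 codons each, codon frequencies and
    base composition from the published virus tables, GC12-on-GC3 slope
    0.3863, and moderate CpG/UpA suppression.  The published RSCU
    vector already encodes most of the virus's codon-level CpG/UpA
    avoidance, so the extra factors are mild — enough to carry the
    depletion into the untranslated regions, where the iid background
    would otherwise show no signal.
    """
    params = dict(cpg_suppression=0.65, upa_suppression=0.6, seed=seed)
    params.update(overrides)
    return GeneratorSpec(**params)


# ---------------------------------------------------------------------------
# codon distributions and tilting


def sense_distribution(spec: GeneratorSpec, code: GeneticCode | None = None):
    """Joint 61-codon probability vector implied by the spec.

    Returns (codons, probs) with p(c) = aa_profile[aa(c)] *
    codon_probs[aa(c)][c].
    """
    code = code or standard_code()
    codons = code.sense_codons
    p = np.array([_joint_prob(spec, code, c) for c in codons], dtype=float)
    return codons, p / p.sum()


def _joint_prob(spec: GeneratorSpec, code: GeneticCode, codon: str) -> float:
    aa = code.table[codon]
    return spec.aa_profile[aa] * spec.codon_probs[aa][codon]


def _gc_indicators(codons: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    g12 = np.array([(c[0] in GC_BASES) + (c[1] in GC_BASES) for c in codons], float)
    g3 = np.array([c[2] in GC_BASES for c in codons], float)
    return g12, g3


def _stationary_codon_distribution(
    codons: Sequence[str], weights: np.ndarray, f_cpg: float, f_upa: float
) -> np.ndarray:
    """Long-run codon distribution of the suppressed sequential sampler.

    The sampler draws codon *c* after codon *b* with probability
    proportional to ``weights[c]`` times the suppression penalty of the
    CpG/UpA pairs created within *c* and at the junction; the junction
    penalty depends only on the last base of *b*, so the last base is a
    4-state Markov chain whose stationary law gives the codon mixture.
    """
    if f_cpg >= 1 and f_upa >= 1:
        return weights / weights.sum()
    from .genetic_code import RNA_BASES

    pen_in = np.array(
        [_pair_penalty("", c, f_cpg, f_upa) for c in codons]
    )
    cond = {}  # last base -> conditional codon distribution
    for b in RNA_BASES:
        junction = np.array(
            [
                f_cpg if b + c[0] == "CG" else f_upa if b + c[0] == "UA" else 1.0
                for c in codons
            ]
        )
        w = weights * pen_in * junction
        cond[b] = w / w.sum()
    third = np.array([RNA_BASES.index(c[2]) for c in codons])
    M = np.zeros((4, 4))
    for i, b in enumerate(RNA_BASES):
        for j in range(4):
            M[i, j] = cond[b][third == j].sum()
    # stationary law of the last-base chain
    eigvals, eigvecs = np.linalg.eig(M.T)
    k = int(np.argmin(np.abs(eigvals - 1)))
    pi = np.real(eigvecs[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    return sum(pi[i] * cond[b] for i, b in enumerate(RNA_BASES))


def tilt_distribution(
    codons: Sequence[str],
    q: np.ndarray,
    gc3_target: float,
    gc12_target: float,
    f_cpg: float = 1.0,
    f_upa: float = 1.0,
) -> np.ndarray:
    """Exponentially tilt ``q`` so realized GC3/GC12 hit the targets.

    When suppression factors are below 1 the targets are solved against
    the stationary distribution of the suppressed sampler, so the
    compositional structure across isolates survives suppression.
    Returns the tilted *base* distribution to feed the sampler (the
    sampler re-applies the penalties at draw time).
    """
    g12, g3 = _gc_indicators(codons)

    def expectations(t):
        w = q * np.exp(t[0] * g3 + t[1] * g12)
        p = _stationary_codon_distribution(codons, w, f_cpg, f_upa)
        return np.array([p @ g3, (p @ g12) / 2.0])

    sol = optimize.root(
        lambda t: expectations(t) - [gc3_target, gc12_target],
        x0=[0.0, 0.0],
        method="hybr",
    )
    if not sol.success or np.abs(sol.fun).max() > 1e-8:
        raise FeasibilityError(
            f"cannot tilt codon distribution to GC3={gc3_target:.3f}, "
            f"GC12={gc12_target:.3f}"
        )
    w = q * np.exp(sol.x[0] * g3 + sol.x[1] * g12)
    return w / w.sum()


def isolate_targets(spec: GeneratorSpec, rng: np.random.Generator):
    """Per-isolate (gc3, gc12) targets on the configured linear structure."""
    lo, hi = spec.gc3_range
    gc3 = np.linspace(lo, hi, spec.n_isolates)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_isolates) if spec.noise_sd else 0.0
    gc12 = spec.intercept + spec.slope * gc3 + noise
    return gc3, np.atleast_1d(gc12 + np.zeros_like(gc3))


def isolate_distributions(spec: GeneratorSpec, rng: np.random.Generator):
    """Tilted 61-codon distributions for each isolate of the set."""
    codons, q = sense_distribution(spec)
    gc3, gc12 = isolate_targets(spec, rng)
    dists = [
        tilt_distribution(
            codons, q, s, m, spec.cpg_suppression, spec.upa_suppression
        )
        for s, m in zip(gc3, gc12)
    ]
    return codons, gc3, gc12, dists


def sample_codon_counts(
    codons: Sequence[str], probs: np.ndarray, n: int, rng: np.random.Generator
) -> CodonCountTable:
    """Multinomial codon counts — the fast path for replicate studies."""
    draw = rng.multinomial(n, probs)
    return CodonCountTable(counts={c: int(k) for c, k in zip(codons, draw) if k})


# ---------------------------------------------------------------------------
# sequence-level generation


def _sample_stop(rng: np.random.Generator) -> str:
    stops = list(STOP_WEIGHTS)
    return stops[rng.choice(len(stops), p=np.array(list(STOP_WEIGHTS.values())))]


def _pair_penalty(prev: str, codon: str, f_cpg: float, f_upa: float) -> float:
    """Suppression weight for the CpG/UpA pairs a codon choice creates."""
    w = 1.0
    seq = prev + codon
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair == "CG":
            w *= f_cpg
        elif pair == "UA":
            w *= f_upa
    return w


def _sample_codons_sequential(
    codons: Sequence[str],
    probs: np.ndarray,
    n: int,
    rng: np.random.Generator,
    f_cpg: float,
    f_upa: float,
    prev: str = "",
) -> list[str]:
    """Draw codons left to right, discounting CpG/UpA-creating choices."""
    penalties = np.empty(len(codons))
    out: list[str] = []
    for _ in range(n):
        for j, c in enumerate(codons):
            penalties[j] = _pair_penalty(prev[-1:], c, f_cpg, f_upa)
        w = probs * penalties
        idx = rng.choice(len(codons), p=w / w.sum())
        out.append(codons[idx])
        prev = codons[idx]
    return out


def generate_cds(
    spec: GeneratorSpec,
    rng: np.random.Generator | None = None,
    n_codons: int | None = None,
    record_id: str = "synthetic-cds",
) -> SequenceRecord:
    """One CDS: AUG, ``n_codons`` sampled sense codons, a stop codon.

    Amino acids are drawn from ``aa_profile`` and codons within families
    from ``codon_probs`` (jointly, one categorical draw per codon);
    suppression factors below 1 switch to sequential sampling with
    CpG/UpA-creating choices down-weighted.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = n_codons if n_codons is not None else spec.n_codons
    codons, p = sense_distribution(spec)
    if spec.cpg_suppression < 1 or spec.upa_suppression < 1:
        body = _sample_codons_sequential(
            codons, p, n, rng, spec.cpg_suppression, spec.upa_suppression, prev="AUG"
        )
    else:
        body = [codons[i] for i in rng.choice(len(codons), size=n, p=p)]
    seq = "AUG" + "".join(body) + _sample_stop(rng)
    return SequenceRecord(
        id=record_id, seq=seq, regions=(Region("CDS", 0, len(seq)),)
    )


_HOST_CYCLE = ("soybean", "cowpea", "papaya")


def generate_isolate_set(spec: GeneratorSpec) -> list[SequenceRecord]:
    """A full isolate set with annotated ORFs, UTRs and metadata.

    Each isolate's codons follow its tilted distribution (imposing the
    GC12-on-GC3 structure), split into ``n_orfs`` consecutive ORFs
    separated by short untranslated segments drawn from the background
    base composition.  Suppression factors apply to coding and
    untranslated parts alike.  Hosts and clades are assigned cyclically
    so grouping code paths are exercisable.
    """
    rng = np.random.default_rng(spec.seed)
    codons, gc3, gc12, dists = isolate_distributions(spec, rng)
    records = []
    per_orf = max(spec.n_codons // spec.n_orfs, 1)
    for i, dist in enumerate(dists):
        orf_seqs = []
        for _ in range(spec.n_orfs):
            if spec.cpg_suppression < 1 or spec.upa_suppression < 1:
                body = _sample_codons_sequential(
                    codons, dist, per_orf, rng,
                    spec.cpg_suppression, spec.upa_suppression, prev="AUG",
                )
            else:
                body = [codons[j] for j in rng.choice(len(codons), size=per_orf, p=dist)]
            orf_seqs.append("AUG" + "".join(body) + _sample_stop(rng))
        pieces, regions = [], []
        pos = 0
        for k, orf in enumerate(orf_seqs):
            utr = random_sequence(
                spec.utr_length, spec.base_composition, rng,
                cpg_suppression=spec.cpg_suppression,
                upa_suppression=spec.upa_suppression,
            )
            pieces.append(utr)
            pos += len(utr)
            pieces.append(orf)
            regions.append(Region("CDS", pos, pos + len(orf)))
            pos += len(orf)
        tail = random_sequence(
            spec.utr_length, spec.base_composition, rng,
            cpg_suppression=spec.cpg_suppression,
            upa_suppression=spec.upa_suppression,
        )
        pieces.append(tail)
        records.append(
            SequenceRecord(
                id=f"ISO{i + 1:03d}",
                seq="".join(pieces),
                regions=tuple(regions),
                meta={
                    "host": _HOST_CYCLE[i % len(_HOST_CYCLE)],
                    "clade": "I" if i < (2 * spec.n_isolates) // 3 else "II",
                    "gc3_target": float(gc3[i]),
                    "gc12_target": float(gc12[i]),
                },
            )
        )
    return records


def random_sequence(
    length: int,
    base_probs: dict[str, float],
    rng: np.random.Generator,
    cpg_suppression: float = 1.0,
    upa_suppression: float = 1.0,
) -> str:
    """IID (or CpG/UpA-discounted first-order Markov) background sequence."""
    bases = list(base_probs)
    p = np.array([base_probs[b] for b in bases], float)
    p = p / p.sum()
    if cpg_suppression >= 1 and upa_suppression >= 1:
        return "".join(bases[i] for i in rng.choice(len(bases), size=length, p=p))
    out: list[str] = []
    prev = ""
    for _ in range(length):
        w = p.copy()
        for j, b in enumerate(bases):
            if prev + b == "CG":
                w[j] *= cpg_suppression
            elif prev + b == "UA":
                w[j] *= upa_suppression
        prev = bases[rng.choice(len(bases), p=w / w.sum())]
        out.append(prev)
    return "".join(out)


def suppress_dinucleotides(
    record: SequenceRecord,
    spec: GeneratorSpec,
    rng: np.random.Generator | None = None,
) -> SequenceRecord:
    """Synonymous-only resampling that depletes CpG/UpA in a CDS.

    Codons are revisited left to right; each is replaced by a draw from
    its synonymous family where every choice's weight is the spec's
    within-family probability times ``factor**(new CpG/UpA pairs)``
    counted within the codon and across the junction with the previous
    one.  The encoded protein is unchanged by construction; factors of
    1.0 make this the identity in distribution.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    code = standard_code()
    seq = record.seq
    if len(seq) % 3:
        raise GeneratorSpecError("suppress_dinucleotides requires an in-frame CDS")
    new_codons: list[str] = []
    prev = ""
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in code.stops:
            new_codons.append(codon)
            prev = codon
            continue
        aa = code.table[codon]
        family = code.families[aa]
        if len(family) == 1 or (
            spec.cpg_suppression >= 1 and spec.upa_suppression >= 1
        ):
            # nothing to suppress: exact identity
            new_codons.append(codon)
            prev = codon
            continue
        w = np.array(
            [
                spec.codon_probs[aa][c]
                * _pair_penalty(prev[-1:], c, spec.cpg_suppression, spec.upa_suppression)
                for c in family
            ]
        )
        if w.sum() == 0:
            w = np.ones(len(family))
        choice = family[rng.choice(len(family), p=w / w.sum())]
        new_codons.append(choice)
        prev = choice
    return replace(record, seq="".join(new_codons))
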