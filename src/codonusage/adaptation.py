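"""Virus-to-host codon adaptation via RSCU vector correlation.

A virus that mimics its host's synonymous codon preferences translates
more efficiently on the host's tRNA pool.  The degree of mimicry is
summarised here as the Pearson correlation between the virus's RSCU
vector and a host's RSCU vector over the shared classifiable codons;
ranking candidate hosts by that correlation points at the host whose
translational machinery the virus is best adapted to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

from scipy import stats

from .codon_stats import RSCUTable
from .errors import InsufficientOverlapError

MIN_SHARED_CODONS = 10


@dataclass(frozen=True)
class AdaptationComparison:
    virus_group: str
    host: str
    r: float
    p_value: float
    n_codons: int
    method: str = "pearson"


def rscu_correlation(
    virus: RSCUTable,
    host: RSCUTable,
    method: Literal["pearson", "spearman"] = "pearson",
) -> AdaptationComparison:
    """Correlate two RSCU vectors over shared non-missing codons.

    Codons missing in either table are excluded; fewer than
    ``MIN_SHARED_CODONS`` left raises.  Spearman is offered because
    RSCU vectors are bounded and right-skewed, but Pearson is the
    conventional choice.
    """
    v = virus.classifiable_values()
    h = host.classifiable_values()
    shared = sorted(set(v) & set(h))
    if len(shared) < MIN_SHARED_CODONS:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared codons between "
            f"{virus.label or 'virus'} and {host.label or 'host'}"
        )
    x = [v[c] for c in shared]
    y = [h[c] for c in shared]
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AdaptationComparison(
        virus_group=virus.label,
        host=host.label,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n_codons=len(shared),
        method=method,
    )


@dataclass(frozen=True)
class HostRanking:
    """Hosts of one virus group ordered by decreasing correlation."""

    virus_group: str
    order: tuple[str, ...]
    tied: tuple[tuple[str, str], ...] = ()


def rank_hosts(
    virus_groups: Mapping[str, RSCUTable],
    hosts: Mapping[str, RSCUTable],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[dict[tuple[str, str], AdaptationComparison | None], dict[str, HostRanking]]:
    """Full virus-group x host correlation matrix plus per-group rankings.

    Cells where the correlation is undefined (insufficient overlap)
    are ``None`` rather than aborting the matrix.  Within a group,
    hosts are ranked by r, ties broken by the number of shared codons
    and then label order; exact ties are reported.
    """
    if not virus_groups or len(hosts) < 2:
        raise ValueError("need >= 1 virus group and >= 2 hosts")
    matrix: dict[tuple[str, str], AdaptationComparison | None] = {}
    rankings: dict[str, HostRanking] = {}
    for vg, vtable in virus_groups.items():
        cells: dict[str, AdaptationComparison] = {}
        for hl, htable in hosts.items():
            try:
                cmp_ = rscu_correlation(vtable, htable, method=method)
            except InsufficientOverlapError:
                matrix[(vg, hl)] = None
                continue
            cmp_ = AdaptationComparison(
                virus_group=vg, host=hl, r=cmp_.r, p_value=cmp_.p_value,
                n_codons=cmp_.n_codons, method=cmp_.method,
            )
            matrix[(vg, hl)] = cmp_
            cells[hl] = cmp_
        order = sorted(
            cells, key=lambda hl: (-cells[hl].r, -cells[hl].n_codons, hl)
        )
        tied = tuple(
            (a, b)
            for i, a in enumerate(order)
            for b in order[i + 1 :]
            if cells[a].r == cells[b].r and cells[a].n_codons == cells[b].n_codons
        )
        rankings[vg] = HostRanking(virus_group=vg, order=tuple(order), tied=tied)
    return matrix, rankings
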