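"""End-to-end orchestration: composition -> RSCU -> ENC -> neutrality ->
dinucleotide -> adaptation, from a config file to a directory of reports.

All tabular outputs are TSV; figures are PNG.  A run manifest records
the configuration hash, seed, package version and per-stage record
counts so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from . import sequence_io as sio
from .adaptation import rank_hosts
from .codon_stats import (
    CodonCountTable,
    RSCUTable,
    classify,
    count_codons,
    mean_rscu,
    rscu,
    rscu_from_values,
    rscu_range,
)
from .composition import composition_summary
from .dinucleotide import mean_profile, region_profiles, call_value, DINUCLEOTIDES
from .enc import enc_expected, enc_plot_points, enc_value
from .genetic_code import standard_code
from .neutrality import interpret_slope, neutrality_regression
from .synthetic import cpmmv_like_spec, generate_isolate_set

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With no ``genomes_fasta`` a synthetic isolate set with the default
    virus-like parameters is generated from ``seed``.  Thresholds
    default to the conventional RSCU (1.5 / 0.6) and dinucleotide
    (0.78 / 1.23) significance bounds.
    """

    genomes_fasta: str | None = None
    spans_tsv: str | None = None
    metadata_tsv: str | None = None
    host_cds_fastas: dict[str, str] = field(default_factory=dict)
    host_rscu_tsvs: dict[str, str] = field(default_factory=dict)
    outdir: str = "results"
    group_by: tuple[str, ...] = ("clade", "host")
    rscu_hi: float = 1.5
    rscu_lo: float = 0.6
    dinuc_lo: float = 0.78
    dinuc_hi: float = 1.23
    pooled: bool = False
    seed: int = 0
    n_isolates: int | None = None
    n_codons: int | None = None

    def __post_init__(self) -> None:
        if not (self.rscu_lo < 1 < self.rscu_hi):
            raise ValueError("need rscu_lo < 1 < rscu_hi")
        if not (self.dinuc_lo < 1 < self.dinuc_hi):
            raise ValueError("need dinuc_lo < 1 < dinuc_hi")
        self.group_by = tuple(self.group_by)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_or_simulate(config: RunConfig) -> list[sio.SequenceRecord]:
    if config.genomes_fasta:
        records = sio.read_fasta(config.genomes_fasta)
        spans = sio.read_spans_tsv(config.spans_tsv) if config.spans_tsv else None
        meta = (
            sio.read_metadata_tsv(config.metadata_tsv)
            if config.metadata_tsv
            else None
        )
        return sio.attach_annotations(records, spans=spans, metadata=meta)
    overrides = {}
    if config.n_isolates:
        overrides["n_isolates"] = config.n_isolates
    if config.n_codons:
        overrides["n_codons"] = config.n_codons
    return generate_isolate_set(cpmmv_like_spec(seed=config.seed, **overrides))


def _isolate_tables(
    records: list[sio.SequenceRecord],
) -> tuple[list[sio.SequenceRecord], dict[str, CodonCountTable], list[str]]:
    """Pool each isolate's validated ORF codon counts; log drops."""
    tables: dict[str, CodonCountTable] = {}
    dropped: list[str] = []
    kept: list[sio.SequenceRecord] = []
    for rec in records:
        orfs = sio.extract_orfs(rec, strategy="annotated-spans")
        if not orfs:
            dropped.append(rec.id)
            logger.warning("isolate %s: no valid ORFs, dropped", rec.id)
            continue
        tables[rec.id] = count_codons(orfs)
        kept.append(rec)
    return kept, tables, dropped


def _host_tables(config: RunConfig) -> dict[str, RSCUTable]:
    hosts: dict[str, RSCUTable] = {}
    for label, path in config.host_rscu_tsvs.items():
        df = pd.read_csv(path, sep="\t", comment="#")
        hosts[label] = rscu_from_values(
            dict(zip(df["codon"], df["rscu"])), label=label
        )
    for label, path in config.host_cds_fastas.items():
        records = sio.read_fasta(path)
        valid = [r for r in records if sio.validate_cds(r).passed]
        if not valid:
            logger.warning("host %s: no valid CDS, skipped", label)
            continue
        hosts[label] = rscu(count_codons(valid), label=label)
    return hosts


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write its report; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = load_or_simulate(config)
    records, tables, dropped = _isolate_tables(records)
    if not tables:
        raise ValueError("no isolate with a valid ORF; nothing to analyse")
    code = standard_code()

    # per-isolate composition, ENC, RSCU
    summaries = {rid: composition_summary(
        next(r for r in records if r.id == rid).seq, tbl
    ) for rid, tbl in tables.items()}
    encs = {rid: enc_value(tbl) for rid, tbl in tables.items()}
    rscus = {rid: rscu(tbl, label=rid) for rid, tbl in tables.items()}

    comp_rows = []
    for rid in tables:
        s = summaries[rid]
        rec = next(r for r in records if r.id == rid)
        comp_rows.append(
            {
                "id": rid,
                "group": "",
                **{k: rec.meta.get(k, "") for k in config.group_by},
                "A": s.overall["A"], "U": s.overall["U"],
                "C": s.overall["C"], "G": s.overall["G"],
                "GC": s.gc_overall,
                "GC1": s.gc1, "GC2": s.gc2, "GC12": s.gc12, "GC3": s.gc3,
                "A3s": s.third_pos_syn["A"], "U3s": s.third_pos_syn["U"],
                "C3s": s.third_pos_syn["C"], "G3s": s.third_pos_syn["G"],
                "ENC": encs[rid].enc,
            }
        )
    comp_df = pd.DataFrame(comp_rows)
    num_cols = [c for c in comp_df.columns if c not in ("id", "group", *config.group_by)]
    group_rows = [{"id": "", "group": "Overall",
                   **{c: comp_df[c].mean() for c in num_cols}}]
    for key in config.group_by:
        if key not in comp_df.columns:
            continue
        for value, sub in comp_df.groupby(key):
            if value == "":
                continue
            group_rows.append({"id": "", "group": f"{key}={value}",
                               **{c: sub[c].mean() for c in num_cols}})
    comp_out = pd.concat([comp_df, pd.DataFrame(group_rows)], ignore_index=True)
    _write_tsv(comp_out, outdir / "composition.tsv",
               "per-isolate and per-group nucleotide composition with ENC")

    # RSCU: overall mean across isolates (or pooled counts)
    if config.pooled:
        pooled_table = sum(list(tables.values())[1:], start=list(tables.values())[0])
        overall_rscu = rscu(pooled_table, label="overall")
    else:
        overall_rscu = mean_rscu(list(rscus.values()), label="overall")
    cls = classify(overall_rscu)
    rscu_rows = [
        {
            "amino_acid": code.table[c],
            "codon": c,
            "rscu": overall_rscu.values[c],
            "class": overall_rscu.classes[c],
        }
        for c in code.classifiable_codons
        if c in overall_rscu.values
    ]
    _write_tsv(pd.DataFrame(rscu_rows), outdir / "rscu.tsv",
               "overall RSCU with bias classes")

    # per-host-group RSCU + ranges
    host_groups: dict[str, RSCUTable] = {}
    for value in sorted({r.meta.get("host", "") for r in records} - {""}):
        members = [rscus[r.id] for r in records if r.meta.get("host") == value]
        if members:
            host_groups[value] = mean_rscu(members, label=value)
    if len(host_groups) >= 2:
        ranges = rscu_range(host_groups)
        _write_tsv(
            pd.DataFrame([asdict(r) for r in ranges]),
            outdir / "rscu_ranges.tsv",
            "cross-host RSCU ranges (max - min per codon)",
        )

    # ENC plot
    points = enc_plot_points(
        [(rid, summaries[rid].gc3, encs[rid].enc) for rid in tables]
    )
    enc_df = pd.DataFrame(
        [
            {"id": p.id, "GC3s": p.gc3, "ENC": p.enc,
             "ENC_expected": p.expected, "below_curve": p.below_curve}
            for p in points
        ]
    )
    _write_tsv(enc_df, outdir / "enc_plot.tsv", "ENC vs GC3s with null curve")
    _plot_enc(enc_df, outdir / "enc_plot.png")

    # neutrality
    reg = neutrality_regression(
        [(summaries[rid].gc3, summaries[rid].gc12) for rid in tables]
    )
    neut = {
        "slope": reg.slope, "intercept": reg.intercept, "r": reg.r,
        "p_value": reg.p_value, "n": reg.n,
        "mutation_pct": reg.mutation_pct, "selection_pct": reg.selection_pct,
        "dominant_force": interpret_slope(reg),
    }
    (outdir / "neutrality.json").write_text(json.dumps(neut, indent=2))
    _plot_neutrality(
        [(summaries[rid].gc3, summaries[rid].gc12) for rid in tables],
        reg, outdir / "neutrality.png",
    )

    # dinucleotide profiles, mean over isolates per region
    per_region: dict[str, list] = {"whole-genome": [], "CDS": [], "UTR": []}
    for rec in records:
        profs = region_profiles(rec)
        for region, prof in profs.items():
            if prof is not None:
                per_region[region].append(prof)
    dinuc_rows = []
    for region, profs in per_region.items():
        if not profs:
            continue
        mean_p = mean_profile(profs, region)
        for d in DINUCLEOTIDES:
            r = mean_p.rho[d]
            dinuc_rows.append(
                {
                    "region": region, "dinucleotide": d,
                    "rho": r,
                    "call": call_value(r, config.dinuc_lo, config.dinuc_hi)
                    if r is not None else "missing",
                }
            )
    dinuc_df = pd.DataFrame(dinuc_rows)
    _write_tsv(dinuc_df, outdir / "dinucleotide.tsv",
               "mean dinucleotide odds ratios per region")
    _plot_dinucleotide(dinuc_df, outdir / "dinucleotide.png", config)

    # adaptation
    adaptation_rows = 0
    hosts = _host_tables(config)
    if len(hosts) >= 2 and host_groups:
        matrix, rankings = rank_hosts(host_groups, hosts)
        rows = []
        for (vg, hl), cell in matrix.items():
            rows.append(
                {
                    "virus_group": vg, "host": hl,
                    "r": cell.r if cell else np.nan,
                    "p_value": cell.p_value if cell else np.nan,
                    "n_codons": cell.n_codons if cell else 0,
                    "rank": rankings[vg].order.index(hl) + 1
                    if cell and hl in rankings[vg].order else "",
                }
            )
        _write_tsv(pd.DataFrame(rows), outdir / "adaptation.tsv",
                   "virus-group x host RSCU correlation matrix")
        adaptation_rows = len(rows)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_isolates": len(tables),
        "n_dropped": len(dropped),
        "dropped_ids": dropped,
        "n_orfs_total": sum(len(t.source_ids) for t in tables.values()),
        "n_codons_total": int(sum(t.n_codons for t in tables.values())),
        "adaptation_cells": adaptation_rows,
        "neutrality": neut,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _plot_enc(enc_df: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    grid = np.linspace(0.05, 0.95, 200)
    ax.plot(grid, [enc_expected(s) for s in grid], label="expected (no selection)")
    ax.scatter(enc_df["GC3s"], enc_df["ENC"], s=12, color="tab:red", label="isolates")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_neutrality(points, reg, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [p[0] for p in points]
    ax.scatter(xs, [p[1] for p in points], s=12)
    grid = np.linspace(min(xs), max(xs), 2)
    ax.plot(grid, reg.intercept + reg.slope * grid, color="tab:red",
            label=f"slope={reg.slope:.4f}, r={reg.r:.3f}")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_dinucleotide(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    regions = df["region"].unique()
    fig, axes = plt.subplots(
        len(regions), 1, figsize=(7, 2.6 * len(regions)), squeeze=False
    )
    for ax, region in zip(axes.ravel(), regions):
        sub = df[df["region"] == region]
        ax.bar(sub["dinucleotide"], sub["rho"].astype(float))
        ax.axhline(config.dinuc_lo, color="tab:red", lw=0.8, ls="--")
        ax.axhline(config.dinuc_hi, color="tab:red", lw=0.8, ls="--")
        ax.set_ylabel("odds ratio")
        ax.set_title(region, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
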