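#!/usr/bin/env python
"""Download the CpMMV GenBank records and build pipeline inputs.

Network helper, not part of the tested surface: it fetches the
accessions listed in ``codonusage.data.CPMMV_ACCESSIONS`` via NCBI
Entrez, writes a genome FASTA plus metadata/span sidecars (CDS spans
taken from the GenBank feature table), and prints a ready-to-run
pipeline invocation.  Requires internet access and an e-mail address
for Entrez.

Usage:
    python scripts/fetch_genbank.py --email you@example.org --outdir data/cpmmv
"""

from __future__ import annotations

import argparse
import csv
import time
from pathlib import Path

from Bio import Entrez, SeqIO

from codonusage.data import CPMMV_ACCESSIONS
from codonusage.sequence_io import Region, SequenceRecord, write_fasta, write_spans_tsv, write_metadata_tsv


def fetch(accession: str) -> SeqIO.SeqRecord:
    with Entrez.efetch(
        db="nucleotide", id=accession, rettype="gb", retmode="text"
    ) as handle:
        return SeqIO.read(handle, "genbank")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="Entrez contact e-mail")
    parser.add_argument("--outdir", type=Path, default=Path("data/cpmmv"))
    parser.add_argument("--delay", type=float, default=0.4,
                        help="seconds between Entrez requests")
    args = parser.parse_args()
    Entrez.email = args.email
    args.outdir.mkdir(parents=True, exist_ok=True)

    records = []
    for accession, country, host in CPMMV_ACCESSIONS:
        gb = fetch(accession)
        seq = str(gb.seq).upper().replace("T", "U").rstrip("A")  # trim poly-A
        regions = []
        for feat in gb.features:
            if feat.type == "CDS":
                start, end = int(feat.location.start), int(feat.location.end)
                if end <= len(seq):
                    regions.append(Region("CDS", start, end))
        records.append(
            SequenceRecord(
                id=accession, seq=seq, regions=tuple(regions),
                meta={"host": host, "country": country},
            )
        )
        print(f"fetched {accession}: {len(seq)} nt, {len(regions)} CDS")
        time.sleep(args.delay)

    write_fasta(records, args.outdir / "genomes.fasta")
    write_spans_tsv(records, args.outdir / "spans.tsv")
    write_metadata_tsv(records, args.outdir / "metadata.tsv")
    print(
        f"\nnow run:\n  codonusage all --genomes {args.outdir}/genomes.fasta "
        f"--spans {args.outdir}/spans.tsv --metadata {args.outdir}/metadata.tsv "
        f"--outdir results/cpmmv"
    )


if __name__ == "__main__":
    main()
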