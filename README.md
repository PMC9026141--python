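# codonusage

Synonymous codon usage bias analysis for viral genomes, built around the
study system of cowpea mild mottle virus (CpMMV) — a whitefly-transmitted
carlavirus with a +ssRNA genome of six partially overlapping ORFs — but
applicable to any set of coding sequences.

Viruses depend on host translation machinery, so their synonymous codon
choices record the forces acting on the genome: directional mutation
pressure, selection for translational efficiency (mimicry of the host
codon pool), and selection to escape dinucleotide-targeting antiviral
responses (CpG/UpA depletion). This package implements the classical
toolkit used to separate those forces:

- **RSCU** — relative synonymous codon usage,
  RSCU<sub>ij</sub> = x<sub>ij</sub>·n<sub>i</sub>/Σ<sub>j</sub>x<sub>ij</sub>
  for codon *j* of amino acid *i* with family size n<sub>i</sub>; codons
  with RSCU > 1.5 are significantly preferred, < 0.6 significantly
  unpreferred.
- **ENC** — Wright's effective number of codons,
  N<sub>c</sub> = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, ranging from 20
  (one codon per amino acid) to 61 (uniform usage), with the ENC-plot
  null curve N<sub>c</sub><sup>exp</sup>(s) = 2 + s + 29/(s² + (1−s)²)
  for third-position G+C content *s*.
- **Neutrality regression** — OLS of GC12 on GC3 across isolates; the
  slope estimates the share of compositional variation due to mutation
  pressure, its complement the share due to selection.
- **Dinucleotide odds ratios** — Karlin's ρ*<sub>XY</sub> =
  f<sub>XY</sub>/(f<sub>X</sub>f<sub>Y</sub>) per region (whole genome,
  CDS, UTR); ρ ≤ 0.78 flags significant underrepresentation, ρ ≥ 1.23
  overrepresentation.
- **Host adaptation** — Pearson correlation of virus and host RSCU
  vectors over the 59 classifiable codons, with host ranking.

A first-class synthetic-data generator produces isolate sets with the
statistical structure every stage assumes (per-family codon
frequencies, a controlled GC12 = a + b·GC3 relationship, tunable
CpG/UpA suppression), so the whole pipeline is validated as parameter
recovery without any downloads.

## Worked example

```python
from codonusage import (
    classify, count_codons, enc_value, extract_orfs, rscu,
    neutrality_regression, composition_summary, generate_isolate_set,
    cpmmv_like_spec,
)

isolates = generate_isolate_set(cpmmv_like_spec(seed=1))  # 33 virus-like genomes
points, encs = [], []
for rec in isolates:
    table = count_codons(extract_orfs(rec, strategy="annotated-spans"))
    s = composition_summary(rec.seq, table)
    points.append((s.gc3, s.gc12))
    encs.append(enc_value(table).enc)

reg = neutrality_regression(points)
print(f"slope {reg.slope:.4f}  r {reg.r:.3f}  "
      f"mutation {reg.mutation_pct:.2f}%  selection {reg.selection_pct:.2f}%")
print(f"mean ENC {sum(encs)/len(encs):.2f}")
```

Output:

```
slope 0.3858  r 0.954  mutation 38.58%  selection 61.42%
mean ENC 47.19
```

The generator imposed a GC12-on-GC3 slope of 0.3863 across the 33
isolates; the neutrality regression recovers it (0.3858), reading as
mutation pressure explaining ~39% of compositional variation and
selection ~61%. The mean ENC of ~47 reflects the moderate codon bias
encoded in the generator's codon frequencies.

The same analyses run from the shell:

```bash
codonusage simulate --seed 1 --outdir fixture
codonusage all --genomes fixture/genomes.fasta --spans fixture/spans.tsv \
    --metadata fixture/metadata.tsv --outdir results
```

which writes `composition.tsv`, `rscu.tsv`, `rscu_ranges.tsv`,
`enc_plot.tsv/png`, `neutrality.json/png`, `dinucleotide.tsv/png`, an
`adaptation.tsv` matrix when host CDS sets are supplied, and a
`manifest.json` recording seed, config hash and per-stage counts.

To analyse the real virus, `scripts/fetch_genbank.py --email you@... `
downloads the GenBank isolate sequences bundled as accession metadata in
`codonusage.data` and emits ready-to-run pipeline inputs (network
required).

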