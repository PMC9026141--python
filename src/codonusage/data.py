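"""Published reference values for cowpea mild mottle virus (CpMMV).

CpMMV is a whitefly-transmitted carlavirus (+ssRNA, six ORFs, the
central three forming the overlapping triple gene block) with a wide
legume host range.  The constants below are the published summary
statistics of its codon usage: the overall RSCU vector of the
full-genome isolate set, the overall genome base composition, and the
GenBank accessions of the isolate sequences.  They serve two purposes
in this package: as desk-scale inputs for classification and
composition routines, and as the default parameters of the synthetic
sequence generator, so that simulated datasets carry the compositional
signature of the real virus.
"""

from __future__ import annotations

# Overall RSCU of the CpMMV full-genome isolate set: the 59 codons of
# synonymously degenerate families (AUG, UGG and stops excluded).
CPMMV_RSCU: dict[str, float] = {
    # Phe
    "UUU": 1.27, "UUC": 0.73,
    # Leu
    "UUA": 1.11, "UUG": 1.81, "CUU": 1.16, "CUC": 0.53, "CUA": 0.55, "CUG": 0.83,
    # Ile
    "AUU": 1.52, "AUC": 0.67, "AUA": 0.81,
    # Val
    "GUU": 1.72, "GUC": 0.72, "GUA": 0.57, "GUG": 0.99,
    # Ser
    "UCU": 1.39, "UCC": 0.83, "UCA": 1.17, "UCG": 0.13, "AGU": 1.58, "AGC": 0.91,
    # Pro
    "CCU": 1.68, "CCC": 0.75, "CCA": 1.31, "CCG": 0.26,
    # Thr
    "ACU": 1.71, "ACC": 0.94, "ACA": 1.16, "ACG": 0.20,
    # Ala
    "GCU": 2.08, "GCC": 0.83, "GCA": 0.86, "GCG": 0.24,
    # Tyr
    "UAU": 1.04, "UAC": 0.96,
    # His
    "CAU": 1.02, "CAC": 0.98,
    # Gln
    "CAA": 1.37, "CAG": 0.63,
    # Asn
    "AAU": 1.46, "AAC": 0.54,
    # Lys
    "AAA": 1.11, "AAG": 0.89,
    # Asp
    "GAU": 1.45, "GAC": 0.55,
    # Glu
    "GAA": 1.00, "GAG": 1.00,
    # Cys
    "UGU": 1.24, "UGC": 0.76,
    # Arg
    "CGU": 0.52, "CGC": 0.29, "CGA": 0.65, "CGG": 0.17, "AGA": 2.12, "AGG": 2.25,
    # Gly
    "GGU": 1.36, "GGC": 0.79, "GGA": 0.85, "GGG": 1.00,
}

# Overall genome base composition of CpMMV (poly-A tail excluded).
CPMMV_BASE_COMPOSITION: dict[str, float] = {
    "A": 0.29, "U": 0.30, "C": 0.18, "G": 0.23,
}

# Published per-group composition and ENC summary (columns: overall,
# the two phylogenetic clades, and host-of-isolation groups).
CPMMV_COMPOSITION_TABLE: dict[str, dict[str, float]] = {
    "Overall":   {"A": 0.29, "U": 0.30, "C": 0.18, "G": 0.23, "GC": 0.41,
                  "GC1": 0.41, "GC2": 0.40, "GC12": 0.41, "GC3": 0.40,
                  "A3": 0.35, "U3": 0.41, "C3": 0.24, "G3": 0.28, "ENC": 52.23},
    "Clade-I":   {"A": 0.29, "U": 0.30, "C": 0.18, "G": 0.23, "GC": 0.41,
                  "GC1": 0.41, "GC2": 0.40, "GC12": 0.41, "GC3": 0.40,
                  "A3": 0.34, "U3": 0.41, "C3": 0.24, "G3": 0.28, "ENC": 52.28},
    "Clade-II":  {"A": 0.30, "U": 0.29, "C": 0.18, "G": 0.23, "GC": 0.41,
                  "GC1": 0.42, "GC2": 0.40, "GC12": 0.41, "GC3": 0.40,
                  "A3": 0.36, "U3": 0.40, "C3": 0.24, "G3": 0.27, "ENC": 51.91},
    "Soybean":   {"A": 0.29, "U": 0.30, "C": 0.18, "G": 0.23, "GC": 0.41,
                  "GC1": 0.42, "GC2": 0.40, "GC12": 0.41, "GC3": 0.40,
                  "A3": 0.35, "U3": 0.41, "C3": 0.24, "G3": 0.28, "ENC": 52.22},
    "Cowpea":    {"A": 0.30, "U": 0.29, "C": 0.18, "G": 0.23, "GC": 0.41,
                  "GC1": 0.41, "GC2": 0.41, "GC12": 0.41, "GC3": 0.41,
                  "A3": 0.35, "U3": 0.39, "C3": 0.24, "G3": 0.28, "ENC": 52.33},
    "FrenchBean": {"A": 0.29, "U": 0.30, "C": 0.18, "G": 0.23, "GC": 0.41,
                   "GC1": 0.42, "GC2": 0.39, "GC12": 0.41, "GC3": 0.41,
                   "A3": 0.34, "U3": 0.41, "C3": 0.25, "G3": 0.28, "ENC": 52.49},
    "MungBean":  {"A": 0.30, "U": 0.30, "C": 0.18, "G": 0.23, "GC": 0.40,
                  "GC1": 0.39, "GC2": 0.41, "GC12": 0.40, "GC3": 0.41,
                  "A3": 0.34, "U3": 0.41, "C3": 0.24, "G3": 0.29, "ENC": 51.54},
    "Papaya":    {"A": 0.30, "U": 0.31, "C": 0.17, "G": 0.22, "GC": 0.39,
                  "GC1": 0.39, "GC2": 0.39, "GC12": 0.39, "GC3": 0.39,
                  "A3": 0.36, "U3": 0.41, "C3": 0.22, "G3": 0.28, "ENC": 52.16},
}

# Published neutrality regression over the 33 full-genome isolates.
CPMMV_NEUTRALITY_SLOPE = 0.3863
CPMMV_NEUTRALITY_R = 0.715

# GenBank accessions of the CpMMV sequences (accession, country, host).
# Useful with scripts/fetch_genbank.py to rebuild the real dataset.
CPMMV_ACCESSIONS: list[tuple[str, str, str]] = [
    ("AF024628", "India", "Arachis hypogaea"),
    ("AF024629", "India", "Arachis hypogaea"),
    ("DQ444266", "Brazil", "Arachis repens"),
    ("DQ885940", "Brazil", "Glycine max"),
    ("GU191840", "Puerto Rico", "Vigna unguiculata"),
    ("HQ184471", "Ghana", "Vigna unguiculata"),
    ("JX524198", "India", "Glycine max"),
    ("KC774019", "USA", "Bemisia tabaci"),
    ("KC774020", "USA", "Desmodium tortuosum"),
    ("KC884244", "Brazil", "Glycine max"),
    ("KC884245", "Brazil", "Glycine max"),
    ("KC884246", "Brazil", "Glycine max"),
    ("KC884247", "Brazil", "Glycine max"),
    ("KC884248", "Brazil", "Glycine max"),
    ("KC884249", "Brazil", "Glycine max"),
    ("KF554101", "Brazil", "Glycine max"),
    ("KF554102", "Brazil", "Glycine max"),
    ("KF554103", "Brazil", "Glycine max"),
    ("KF554104", "Brazil", "Glycine max"),
    ("KF554105", "Brazil", "Glycine max"),
    ("KF554106", "Brazil", "Glycine max"),
    ("KF554107", "Brazil", "Glycine max"),
    ("KF554108", "Brazil", "Glycine max"),
    ("KF554109", "Brazil", "Glycine max"),
    ("KF554110", "Brazil", "Glycine max"),
    ("KF554111", "Brazil", "Glycine max"),
    ("KF554112", "Brazil", "Glycine max"),
    ("KJ534276", "India", "Vigna radiata"),
    ("KJ534277", "India", "Vigna mungo"),
    ("KP402890", "Argentina", "Salvia hispanica"),
    ("KY420906", "China", "Vigna unguiculata"),
    ("MH345698", "India", "Vigna mungo"),
    ("MK069989", "Mexico", "Phaseolus vulgaris"),
    ("MK202583", "Brazil", "Phaseolus vulgaris"),
    ("MK984605", "Kenya", "Carica papaya"),
    ("MN908944", "China", "Glycine max"),
    ("MT232837", "China", "Glycine max"),
    ("MT366555", "China", "Glycine max"),
    ("MT473963", "Brazil", "Glycine max"),
    ("MW354936", "China", "Glycine max"),
    ("MW354937", "China", "Glycine max"),
    ("MW354938", "China", "Glycine max"),
    ("MW354939", "China", "Glycine max"),
    ("MW354940", "China", "Glycine max"),
    ("MW354941", "China", "Glycine max"),
    ("MW354942", "China", "Glycine max"),
    ("MW354943", "China", "Glycine max"),
    ("MW354944", "China", "Glycine max"),
    ("MW354945", "China", "Glycine max"),
    ("MW371117", "Pakistan", "Glycine max"),
    ("MW371118", "Pakistan", "Glycine max"),
    ("MW371119", "Pakistan", "Glycine max"),
    ("MW961149", "Ghana", "Vigna unguiculata"),
    ("MZ202343", "Sudan", "Phaseolus vulgaris"),
    ("OL631603", "China", "Glycine max"),
]
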