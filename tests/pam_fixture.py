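"""Regression fixture: 19 SNPs with curated PAM gain/loss classifications.

Each entry gives a SYNTHETIC 11-bp sequence context (the SNP at 0-based
index 5), reference and alternative base, and the expected classifications.
The bases surrounding each SNP inside the matched motifs are dictated by
the curated classification table this fixture encodes; the remaining
padding bases are synthetic, chosen so that no unrelated PAM overlaps the
SNP wherever that is possible.  For three SNPs the tabulated bases
themselves force additional overlapping-placement effects (recorded in
``FORCED_EXTRAS``); the curated table reports one representative placement.

Expected rows are (enzyme, effect, strand, ref_motif, alt_motif) with
bracket notation read along the matching strand.
"""

SNP_INDEX = 5  # 0-based position of the SNP within each context

# snp_id -> (context, ref, alt, expected rows)
PAM_TABLE = {
    "SNP1": (
        "TGGGGGATTGC",
        "G",
        "C",
        [
            ("SpCas9", "loss", "positive", "GG[G]", "GG[C]"),
            ("SpCas9_VQR", "loss", "positive", "GGG[G]", "GGG[C]"),
            ("SpCas9_VQR", "loss", "positive", "G[G]AT", "G[C]AT"),
            ("SaCas9", "loss", "positive", "GGG[G]AT", "GGG[C]AT"),
        ],
    ),
    "SNP2": (
        "ACGCCCCTACG",
        "C",
        "G",
        [
            ("SpCas9", "loss", "negative", "AG[G]", "AG[C]"),
            ("SpCas9", "loss", "negative", "G[G]G", "G[C]G"),
            ("SpCas9_VQR", "loss", "negative", "G[G]GG", "G[C]GG"),
        ],
    ),
    "SNP3": (
        "TCATGGGGATC",
        "G",
        "A",
        [
            ("SpCas9", "loss", "positive", "TG[G]", "TG[A]"),
            ("SpCas9_VQR", "loss", "positive", "G[G]GG", "G[A]GG"),
            ("SpCas9_EQR", "gain", "positive", "TG[G]G", "TG[A]G"),
        ],
    ),
    "SNP4": (
        "CACAACCATGA",
        "C",
        "G",
        [("SpCas9", "loss", "negative", "TG[G]", "TG[C]")],
    ),
    "SNP5": (
        "AGCAAGCCACG",
        "G",
        "C",
        [
            ("SpCas9", "gain", "negative", "GG[C]", "GG[G]"),
            ("SpCas9", "loss", "positive", "AA[G]", "AA[C]"),
        ],
    ),
    "SNP6": (
        "GTCTACTGACG",
        "C",
        "G",
        [
            ("SpCas9", "gain", "positive", "TA[C]", "TA[G]"),
            ("SpCas9", "loss", "negative", "CA[G]", "CA[C]"),
            ("SpCas9_VQR", "gain", "positive", "A[C]TG", "A[G]TG"),
        ],
    ),
    "SNP7": (
        "AATGTCAGATG",
        "C",
        "T",
        [("SpCas9_VQR", "loss", "negative", "T[G]AC", "T[A]AC")],
    ),
    "SNP8": ("AGCTCAGAGTT", "A", "G", []),
    "SNP9": ("CGTATATCTGG", "A", "G", []),
    "SNP10": (
        "GTGAGTAGACA",
        "T",
        "C",
        [("SaCas9", "loss", "positive", "GTGAG[T]", "GTGAG[C]")],
    ),
    "SNP11": (
        "TGGTCACCGGA",
        "A",
        "G",
        [("SpCas9_VRER", "gain", "negative", "GG[T]G", "GG[C]G")],
    ),
    "SNP12": (
        "GCGGCAGGGAT",
        "A",
        "G",
        [
            ("SpCas9_VQR", "gain", "positive", "GGC[A]", "GGC[G]"),
            ("SpCas9_VRER", "gain", "positive", "GGC[A]", "GGC[G]"),
            ("SpCas9_VQR", "gain", "positive", "C[A]GG", "C[G]GG"),
        ],
    ),
    "SNP13": (
        "CATTCGGGGAC",
        "G",
        "A",
        [("SpCas9_VQR", "loss", "positive", "C[G]GG", "C[A]GG")],
    ),
    "SNP14": ("TGGTGTATGCT", "T", "C", []),
    "SNP15": (
        "ACTGCAGTTGA",
        "A",
        "G",
        [
            ("SpCas9_VQR", "gain", "positive", "TGC[A]", "TGC[G]"),
            ("SpCas9_EQR", "gain", "positive", "TGC[A]", "TGC[G]"),
        ],
    ),
    "SNP16": (
        "CGATCGAGTTG",
        "G",
        "A",
        [
            ("SpCas9_VQR", "loss", "positive", "C[G]AG", "C[A]AG"),
            ("SpCas9_EQR", "loss", "positive", "C[G]AG", "C[A]AG"),
            ("SaCas9", "loss", "positive", "TC[G]AGT", "TC[A]AGT"),
        ],
    ),
    "SNP17": (
        "GTTAAAAAGTC",
        "A",
        "G",
        [
            ("SpCas9", "gain", "positive", "AA[A]", "AA[G]"),
            ("SpCas9_VQR", "gain", "positive", "A[A]AA", "A[G]AA"),
            ("AsCpf1", "loss", "negative", "TT[T]T", "TT[C]T"),
        ],
    ),
    "SNP18": (
        "TATAGCCTGGT",
        "C",
        "T",
        [
            ("SpCas9", "loss", "negative", "AG[G]", "AG[A]"),
            ("SpCas9_VQR", "gain", "negative", "AG[G]C", "AG[A]C"),
        ],
    ),
    "SNP19": (
        "GTCCACGCCAT",
        "C",
        "T",
        [
            ("SpCas9_VQR", "loss", "negative", "GGC[G]", "GGC[A]"),
            ("SpCas9_VRER", "loss", "negative", "GGC[G]", "GGC[A]"),
            ("SpCas9_VQR", "loss", "negative", "C[G]TG", "C[A]TG"),
        ],
    ),
}

# Extra placements forced by the tabulated bases themselves (overlapping
# occurrences of the same biological PAM event): the classifier must emit
# the expected rows, and may additionally emit only these.
FORCED_EXTRAS = {
    "SNP4": 1,  # a second SpCas9 placement is unavoidable in any context
    "SNP5": 2,  # alt GG[G] creates overlapping NGNG / NNGRRT placements
    "SNP17": 2,  # poly-T: AsCpf1 TTTN matches at shifted offsets
}
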