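"""Published germline insertion-site flank pairs (zebrafish, Tol2).

Eight insertion sites cloned from F1 transgenic fish after
protein-mediated Tol2 transposition, written as the 18 bp of genomic
sequence abutting each transposon end: the left flank ends with the
duplicated target word, the right flank begins with it.  Every pair
supports a full 8-bp duplication (site 8 is typeset in its source with
only 7 bp emphasised, but the printed strings contain the 8-bp match).
"""

from __future__ import annotations

# (site label, left flank, right flank, chromosome, locus annotation)
GERMLINE_JUNCTION_FLANKS: list[tuple[str, str, str, str, str]] = [
    ("site1", "AAATATTTACCAAGCAAC", "CAAGCAACACGTTCAGTG", "8", "intron of gfra2"),
    ("site2", "ATAATTTCCTCTTATTTG", "CTTATTTGCATGTCAGAT", "13", "intergenic"),
    ("site3", "CGCATGCTAACTTATAGA", "CTTATAGAGGAGGTGCCC", "8", "exon of wu:fb79a07"),
    ("site4", "AAACGTTCCTCCTAACAC", "CCTAACACAGTTAGATGG", "3", "intergenic"),
    ("site5", "CAACACATGACTCGTTGG", "CTCGTTGGCCATATGCTA", "15", "intergenic"),
    ("site6", "GGGAATATGTGTTATTAA", "GTTATTAACTGCGTCCCA", "4", "repetitive sequence"),
    ("site7", "AGCTGTCTCTTCTGTGTC", "TCTGTGTCATTCAGTCTC", "3", "intron of LOC557901"),
    ("site8", "TGTCAGAGATCTAGGTCA", "CTAGGTCAGATGGAGGAA", "25", "intergenic"),
]


def flank_pairs() -> list[tuple[str, str]]:
    """The (left flank, right flank) pairs, uppercase."""
    return [(left, right) for _, left, right, _, _ in GERMLINE_JUNCTION_FLANKS]
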