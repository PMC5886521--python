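"""Published putative Rex operator sites of T. saccharolyticum.

The reference site table used as the scanner's acceptance suite: each
entry is (locus_tag of the nearest downstream gene, gene name or None,
operator sequence as printed on the forward genome strand, upstream
distance in bp). All but one sequence are 18-mers; the asrABC site is
printed as 19 bases and is expected to contain a matching 18-bp window
rather than to be one.

The published consensus over the adhE/adhA sites (strand-corrected) is
``TTGTTANNNNNNTAACNN``.
"""

from __future__ import annotations

__all__ = ["PUBLISHED_SITES", "PUBLISHED_CONSENSUS", "ADH_SITE_SEQS"]

#: (locus_tag, gene_name, sequence, distance)
PUBLISHED_SITES: list[tuple[str, str | None, str, int]] = [
    ("Tsac_0014", None, "TTGTAAATTTACATACTA", -65),
    ("Tsac_0416", "adhE", "TTGTTAAATGAATAACAA", -150),
    ("Tsac_0416", "adhE", "TTGTTAATAAATTAACAC", -31),
    ("Tsac_0648", None, "ATGATAATCAATAATCTT", -116),
    ("Tsac_0675", "echABCDEF-hypABFCDE", "TTGTTAAATAATAAACAA", -138),
    ("Tsac_0692", None, "TTGAAATTATTATTTCAA", -169),
    ("Tsac_0706", "asrABC", "TGGTTATTTATTTAACAAA", -56),  # printed as 19 bases
    ("Tsac_0744", None, "TTGAACTTAAAATTTCAG", -36),
    ("Tsac_0924", None, "ATGATAATAAAACATCAA", -82),
    ("Tsac_0932", None, "ATGATATAATCATATCAA", -37),
    ("Tsac_0989", None, "ATGTATATGATAATACAA", -35),
    ("Tsac_1035", None, "AAGAAAAAATTGATTCAT", -154),
    ("Tsac_1163", None, "ACGATATATGTAAATCAT", -92),
    ("Tsac_1375", "marR", "CTGAAATAATCATTTCAA", -86),
    ("Tsac_1550", "hfsABCD", "TTGTTAATAAATTAACTA", -78),
    ("Tsac_1619", None, "GTGATTTTAAATGATCAA", -10),
    ("Tsac_1753", None, "TTGATAAACTTTTATCCA", -35),
    ("Tsac_1856", None, "TTGTTTTTAGTTTAACAT", -33),
    ("Tsac_1947", None, "ATGATTCAAAAAAATCAA", -186),
    ("Tsac_1985", None, "TTGAATTGAAATTTTCTA", -82),
    ("Tsac_2078", None, "CTGATGAATTAAAATCAA", -99),
    ("Tsac_2087", "adhA", "TAGTTAAATTTATAACAA", -34),
    ("Tsac_2115", "rodA", "TAGTATTATATCATACAA", -60),
    ("Tsac_2192", None, "ATGAATTTTTGTATTCTT", -88),
    ("Tsac_2363", "hydG", "TTGTTAAATATTCAACAA", -92),
    ("Tsac_2550", None, "ATGATTTTATTCAATCCT", -74),
    ("Tsac_2619", None, "TTGATTACATAATATCCA", -44),
    ("Tsac_2652", None, "ATGAAATCTAATATTCCT", -62),
    ("Tsac_2683", None, "AAGATTATTATCTATCAT", -165),
]

#: Consensus of the two adhE operators and the strand-corrected adhA
#: operator at threshold 1.0.
PUBLISHED_CONSENSUS = "TTGTTANNNNNNTAACNN"

#: The three alcohol-dehydrogenase operator sequences entering the
#: consensus (adhE x2 as printed, adhA as printed on the forward strand
#: i.e. needing strand correction).
ADH_SITE_SEQS = {
    "adhE_upstream": "TTGTTAAATGAATAACAA",
    "adhE_proximal": "TTGTTAATAAATTAACAC",
    "adhA_forward": "TAGTTAAATTTATAACAA",
}
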