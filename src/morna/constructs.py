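"""Published reagent sequences for the moR-21 system.

These are the oligonucleotide sequences of the moR-21 sponge construct and
the Txndc5 3'UTR seed-site region, used as worked examples and fixtures
throughout the package. The full mature moR-21 sequence is not public;
``MOR21_PLACEHOLDER`` is a synthetic stand-in constrained to the two
recoverable termini (see its docstring).
"""

from __future__ import annotations

#: moR-21 sponge gBlocks fragment: seven bulged moR-21 binding sites
#: (TCCGAC + 3-nt bulge + TGGTACAG) separated by 4-nt linkers, flanked by
#: XhoI (CTCGAG) and ApaI (GGGCCC) cloning sites.
MOR21_SPONGE_GBLOCKS = (
    "actagcaCTCGAGccga"
    "TCCGACTCCTGGTACAG" "gcgt"
    "TCCGACGTATGGTACAG" "acgc"
    "TCCGACCATTGGTACAG" "tcga"
    "TCCGACGTCTGGTACAG" "accg"
    "TCCGACGCATGGTACAG" "ccgg"
    "TCCGACCGCTGGTACAG" "acga"
    "TCCGACCTCTGGTACAG"
    "acggatcgcGGGCCCtaatatc"
)

#: The seven 3-nt bulge fillers of the sponge sites, 5'->3' in construct order.
SPONGE_BULGES = ("TCC", "GTA", "CAT", "GTC", "GCA", "CGC", "CTC")

#: The six 4-nt linkers between consecutive sponge sites.
SPONGE_LINKERS = ("gcgt", "acgc", "tcga", "accg", "ccgg", "acga")

#: 5' flank of the sponge fragment (carries the XhoI site).
SPONGE_FLANK5 = "actagcaCTCGAGccga"

#: 3' flank of the sponge fragment (carries the ApaI site).
SPONGE_FLANK3 = "acggatcgcGGGCCCtaatatc"

#: 5'-terminal octamer of moR-21 (nucleotides 1-8), the reverse complement
#: of the sponge-site seed anchor TGGTACAG.
MOR21_SEED_OCTAMER = "CUGUACCA"

#: 3'-terminal hexamer of moR-21, the reverse complement of the sponge-site
#: 3'-compensatory anchor TCCGAC.
MOR21_TAIL_HEXAMER = "GUCGGA"

#: SYNTHETIC placeholder for mature moR-21: a 20-nt RNA whose first eight
#: and last six nucleotides equal the termini recoverable from the sponge
#: binding sites; the central six nucleotides are arbitrary filler and do
#: NOT represent the real sequence.
MOR21_PLACEHOLDER = "CUGUACCAAGCUGUGUCGGA"

#: Wild-type Txndc5 3'UTR segment around the moR-21 seed-match site,
#: reconstructed from the site-directed mutagenesis primers by reverting
#: their two-base substitutions. Contains one exact TGGTACA seed match.
TXNDC5_SITE_WT = "TGAAAAGAAAACTCAAGTGGTACAATTTGGTTTATACTTTCTAA"

#: Seed-match mutant 1 of the same segment (GGTACAA -> GGTTGAA).
TXNDC5_SITE_MUT1 = "TGAAAAGAAAACTCAAGTGGTTGAATTTGGTTTATACTTTCTAA"

#: Seed-match mutant 2 of the same segment (TGGTACA -> TGACACA).
TXNDC5_SITE_MUT2 = "TATGAAAAGAAAACTCAAGTGACACAATTTGGTTTATACTTTCT"
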