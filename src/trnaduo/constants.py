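"""Fixed sequence constants of the tRNA-spacer dual-guide cassette system.

All sequences are uppercase-normalised DNA. The cassette reads, 5' to 3':

    [spacer 1] [scaffold 1: WT/Mod6/Mod7] [tRNA leader] [glycine tRNA]
    [spacer 2] [imp scaffold (vector backbone, position 2)]

Position 1 carries one of three scaffolds (WT, or the Mod6/Mod7 variants
whose T->C flip in the lower stem removes the TTTT pol III terminator);
position 2 always uses the improved ("imp") scaffold with extended stem
loop, so the two scaffolds never share a primer-binding site.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


#: sgRNA scaffold variants. WT is the original S. pyogenes scaffold and
#: contains a TTTT pol III terminator near its 5' end; Mod6 removes it via a
#: T->C lower-stem flip, Mod7 additionally substitutes nexus/hairpin bases
#: while preserving secondary structure; imp is the extended-stem-loop
#: scaffold used in cassette position 2.
SCAFFOLDS: dict[str, str] = {
    "WT": "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC",
    "Mod6": "GTTTCAGAGCTAGAAATAGCAAGTTGAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC",
    "Mod7": "GTTTCAGAGCTAGAAATAGCAAGTTGAAATAAGACTAGTTCGTTATCACGCCGAAAGGCGGGCACCGAGTCGGTGC",
    "imp": "GTTTAAGAGCTATGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC",
}

#: Scaffold names allowed in cassette position 1.
POSITION1_SCAFFOLDS = ("WT", "Mod6", "Mod7")

#: Human glycine tRNA body (71 nt), cleaved at both ends by RNase P/Z.
TRNA_GLY = "GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTCCCACGCGGGAGACCCGGGTTCAATTCCCGGCCAATGCA"

#: tRNA leader sequences (taken from the native glycine tRNA transcript).
LEADERS: dict[int, str] = {
    0: "",
    6: "GCAGAG",
    30: "TGTTATCCTGCAGGCGGTTGTTACGCAGAG",
}

#: Library amplification primers (oligo-pool PCR).
LIBAMP_F = "ATCATATGCTTACCGTAACTTGAAAGTATTTCGATTTCTTGGCTTTATATATCTTGTGGAAAGGACGAAACACC"
LIBAMP_R = "TGCCACTTTTTCAAGTTGATAACGGACTAGCCTTATTTAAACTTGCTATGCTGTTTCCAGCATAGCTCTTAAAC"

#: Synthesis-oligo cloning arms: the primer-annealing regions of the
#: amplification primers. Left = 3'-terminal 25 nt of LIBAMP_F (ends in
#: ACACC so the guide's leading G completes the U6 "CACCG" junction);
#: right = reverse complement of the 3'-terminal 26 nt of LIBAMP_R, which
#: equals the first 26 nt of the imp scaffold.
OLIGO_LEFT_ARM = LIBAMP_F[-25:]
OLIGO_RIGHT_ARM = reverse_complement(LIBAMP_R[-26:])

#: Custom sequencing primers. The R1 primer ends in ...ACACCG: its trailing
#: G consumes the spacer's first base, so read 1 starts at spacer-1 base 2.
#: The R2 primer anneals in the imp scaffold, so read 2 starts at the
#: reverse complement of spacer 2.
SEQ_PRIMER_R1 = "TCTTCCGATCTCTTGTGGAAAGGACGAAACACCG"
SEQ_PRIMER_R2 = "GCTCTTCCGATCTGCTGTTTCCAGCATAGCTCTTAAAC"
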