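"""Assembly and validation of dual-guide cassettes and synthesis oligos.

A cassette concatenates spacer 1, a position-1 scaffold (WT/Mod6/Mod7), a
tRNA leader, the glycine tRNA body, and spacer 2.  With two 20-nt spacers,
the WT scaffold and the 6-nt leader the cassette is 193 nt and the distance
between the two spacer 5' ends is 173 nt — short enough that, with 51 nt of
cloning arms (244 nt total), the whole guide pair fits on one synthesis
oligo.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .constants import (
    LEADERS,
    OLIGO_LEFT_ARM,
    OLIGO_RIGHT_ARM,
    POSITION1_SCAFFOLDS,
    SCAFFOLDS,
    TRNA_GLY,
)

SPACER_MIN_LEN = 17
SPACER_MAX_LEN = 20

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SpacerSeq:
    """A validated protospacer: 17-20 nt over {A,C,G,T}, leading G.

    Stored full length including the leading guanine required for
    efficient U6 transcription.
    """

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"spacer {seq!r} contains non-ACGT character(s): {sorted(bad)}"
            )
        if not SPACER_MIN_LEN <= len(seq) <= SPACER_MAX_LEN:
            raise ValueError(
                f"spacer length {len(seq)} outside "
                f"[{SPACER_MIN_LEN}, {SPACER_MAX_LEN}]: {seq!r}"
            )
        if seq[0] != "G":
            raise ValueError(f"spacer must start with G, got {seq[0]!r}: {seq!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def validate_spacer(seq: str) -> SpacerSeq:
    """Validate a protospacer sequence, returning a :class:`SpacerSeq`.

    Raises ``ValueError`` for non-ACGT characters, length outside 17-20 nt,
    or a first base other than G.
    """
    if not seq:
        raise ValueError("empty spacer sequence")
    return SpacerSeq(seq)


@dataclass(frozen=True)
class CassetteLayout:
    """Ordered parts of one dual-guide cassette with 0-based offsets."""

    spacer1: SpacerSeq
    scaffold1_name: str
    leader_len: int
    spacer2: SpacerSeq
    full_sequence: str = field(init=False)
    part_offsets: dict = field(init=False)

    def __post_init__(self) -> None:
        scaffold = SCAFFOLDS[self.scaffold1_name]
        leader = LEADERS[self.leader_len]
        parts = [
            ("spacer1", self.spacer1.sequence),
            ("scaffold1", scaffold),
            ("leader", leader),
            ("trna", TRNA_GLY),
            ("spacer2", self.spacer2.sequence),
        ]
        offsets = {}
        pos = 0
        for name, seq in parts:
            offsets[name] = pos
            pos += len(seq)
        object.__setattr__(self, "full_sequence", "".join(s for _, s in parts))
        object.__setattr__(self, "part_offsets", offsets)

    def __len__(self) -> int:
        return len(self.full_sequence)


def assemble_cassette(
    spacer1: SpacerSeq | str,
    scaffold1: str,
    leader_len: int,
    spacer2: SpacerSeq | str,
) -> CassetteLayout:
    """Concatenate spacer1 + scaffold1 + leader + tRNA + spacer2.

    ``scaffold1`` must be one of WT, Mod6, Mod7 (the imp scaffold belongs
    to the vector backbone downstream of spacer 2, never to position 1);
    ``leader_len`` one of 0, 6, 30.  A zero-length leader is accepted but
    warned about, as it partially reduces position-1 guide activity.
    """
    if isinstance(spacer1, str):
        spacer1 = validate_spacer(spacer1)
    if isinstance(spacer2, str):
        spacer2 = validate_spacer(spacer2)
    if scaffold1 == "imp":
        raise ValueError(
            "the imp scaffold belongs to the vector backbone (position 2); "
            "position 1 takes one of " + ", ".join(POSITION1_SCAFFOLDS)
        )
    if scaffold1 not in POSITION1_SCAFFOLDS:
        raise ValueError(f"unknown scaffold {scaffold1!r}")
    if leader_len not in LEADERS:
        raise ValueError(f"leader length must be one of {sorted(LEADERS)}")
    if leader_len == 0:
        warnings.warn(
            "leaderless tRNA cassettes show partially reduced position-1 "
            "guide activity",
            UserWarning,
            stacklevel=2,
        )
    return CassetteLayout(spacer1, scaffold1, leader_len, spacer2)


def spacer_start_offset(layout: CassetteLayout) -> int:
    """Distance in nt between the 5' ends of spacer 1 and spacer 2."""
    return layout.part_offsets["spacer2"] - layout.part_offsets["spacer1"]


@dataclass(frozen=True)
class SynthesisOligo:
    """A full synthesis oligo: left cloning arm + cassette + right arm."""

    cassette: CassetteLayout
    left_arm: str = OLIGO_LEFT_ARM
    right_arm: str = OLIGO_RIGHT_ARM
    full_sequence: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "full_sequence",
            self.left_arm + self.cassette.full_sequence + self.right_arm,
        )

    def __len__(self) -> int:
        return len(self.full_sequence)


def assemble_synthesis_oligo(layout: CassetteLayout) -> SynthesisOligo:
    """Flank a cassette with the 25-nt left and 26-nt right cloning arms.

    The left arm ends in ACACC, so the spacer's leading G completes the
    canonical U6 "ACACCG" junction.
    """
    oligo = SynthesisOligo(layout)
    junction = oligo.left_arm[-5:] + layout.spacer1.sequence[0]
    if junction != "ACACCG":  # guaranteed by spacer validation
        raise ValueError(f"left junction {junction!r} != 'ACACCG'")
    return oligo


def scan_pol3_terminators(seq: str) -> list[int]:
    """0-based start positions of maximal runs of >=4 consecutive T.

    A TTTT run terminates pol III transcription; the Mod scaffolds exist to
    remove the run present in the WT scaffold.
    """
    return [m.start() for m in re.finditer("T{4,}", seq.upper())]
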