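import itertools

import numpy as np
import pytest

from trnaduo.libdesign import GuidePairRecord, LibraryManifest

BASES = "ACGT"


def random_spacer(rng: np.random.Generator, length: int = 20) -> str:
    return "G" + "".join(rng.choice(list(BASES), size=length - 1))


def unique_spacers(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        out.add(random_spacer(rng, length))
    return sorted(out)


def make_manifest(rng: np.random.Generator, n: int = 6,
                  scaffold: str = "WT") -> LibraryManifest:
    """A small random manifest of double-knockout vectors."""
    sp1 = unique_spacers(rng, n)
    sp2 = unique_spacers(rng, n)
    recs = [
        GuidePairRecord(f"v{i:03d}", f"G1_{i}", sp1[i], scaffold,
                        f"G2_{i}", sp2[i], "double_ko")
        for i in range(n)
    ]
    return LibraryManifest(recs, name="test")


def record_generator(rng: np.random.Generator, design_class: str = "double_ko",
                     prefix: str = "gen"):
    """Infinite stream of valid records with globally unique spacer pairs."""
    for i in itertools.count():
        yield GuidePairRecord(
            f"{prefix}_{i:06d}",
            f"{prefix}A{i}", random_spacer(rng), "WT",
            f"{prefix}B{i}", random_spacer(rng), design_class,
        )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
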