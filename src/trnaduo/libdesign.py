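"""Library manifest construction: anchor x library combinatorics,
orientation mirroring, class composition, and TSV manifest I/O.

A manifest is an ordered collection of guide-pair records, one per vector.
In the anchor-library design every "anchor" gene is paired combinatorially
with every "library" gene, anchors fixed in cassette position 2 and library
guides in position 1; singleton vectors pair a single targeting guide with
a control guide so its single-knockout effect can be estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .cassette import validate_spacer
from .constants import POSITION1_SCAFFOLDS

#: Allowed values of ``design_class``.
DESIGN_CLASSES = frozenset(
    {
        "double_ko",
        "singleton",
        "paralog_control",
        "essential_control",
        "nonessential_control",
        "intergenic_control",
        "nontargeting_control",
    }
)

MANIFEST_COLUMNS = [
    "vector_id",
    "gene1",
    "spacer1",
    "scaffold1",
    "gene2",
    "spacer2",
    "design_class",
]


@dataclass(frozen=True)
class GuidePairRecord:
    """One designed vector: a guide pair plus its design class."""

    vector_id: str
    gene1: str
    spacer1: str
    scaffold1: str
    gene2: str
    spacer2: str
    design_class: str

    def __post_init__(self) -> None:
        validate_spacer(self.spacer1)
        validate_spacer(self.spacer2)
        if self.scaffold1 not in POSITION1_SCAFFOLDS:
            raise ValueError(
                f"vector {self.vector_id}: scaffold1 must be one of "
                f"{POSITION1_SCAFFOLDS}, got {self.scaffold1!r}"
            )
        if self.design_class not in DESIGN_CLASSES:
            raise ValueError(
                f"vector {self.vector_id}: unknown design_class "
                f"{self.design_class!r}"
            )

    @property
    def spacer_pair(self) -> tuple[str, str]:
        return (self.spacer1, self.spacer2)


class LibraryManifest:
    """Ordered, validated collection of :class:`GuidePairRecord`."""

    def __init__(
        self,
        records: Iterable[GuidePairRecord],
        name: str = "library",
        metadata: dict | None = None,
    ) -> None:
        self.records: list[GuidePairRecord] = list(records)
        self.name = name
        self.metadata: dict = dict(metadata or {})
        self._validate()

    def _validate(self) -> None:
        seen_ids: set[str] = set()
        seen_pairs: set[tuple[str, str]] = set()
        for rec in self.records:
            if rec.vector_id in seen_ids:
                raise ValueError(f"duplicate vector_id {rec.vector_id!r}")
            seen_ids.add(rec.vector_id)
            if rec.spacer_pair in seen_pairs:
                raise ValueError(
                    f"duplicate spacer pair {rec.spacer_pair} "
                    f"(vector {rec.vector_id})"
                )
            seen_pairs.add(rec.spacer_pair)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GuidePairRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LibraryManifest):
            return NotImplemented
        return self.records == other.records

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.design_class] = counts.get(rec.design_class, 0) + 1
        return counts

    @property
    def spacer_pairs(self) -> set[tuple[str, str]]:
        return {rec.spacer_pair for rec in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "vector_id": r.vector_id,
                    "gene1": r.gene1,
                    "spacer1": r.spacer1,
                    "scaffold1": r.scaffold1,
                    "gene2": r.gene2,
                    "spacer2": r.spacer2,
                    "design_class": r.design_class,
                }
                for r in self.records
            ],
            columns=MANIFEST_COLUMNS,
        )


def build_anchor_library(
    anchor_guides: Mapping[str, Sequence[str]],
    library_guides: Mapping[str, Sequence[str]],
    control_guides: Mapping[str, Sequence[str]] | None = None,
    singleton_controls_per_guide: int | None = None,
    guides_per_gene: int = 2,
    scaffold1: str = "Mod7",
    name: str = "anchor_library",
) -> LibraryManifest:
    """Anchor x library combinatorial design with singleton controls.

    One ``double_ko`` vector is made per (library guide, anchor guide)
    combination, library guide in position 1 and anchor guide in position 2,
    using the first ``guides_per_gene`` guides of each gene.  If
    ``control_guides`` is given, each anchor guide (position 2) and each
    library guide (position 1) is additionally paired with each of the
    designated control guides (all of them by default, or the first
    ``singleton_controls_per_guide``) to form ``singleton`` vectors.
    """
    anchor_genes = set(anchor_guides)
    library_genes = set(library_guides)
    control_genes = set(control_guides or {})
    overlap = (anchor_genes & library_genes) | (anchor_genes & control_genes) | (
        library_genes & control_genes
    )
    if overlap:
        raise ValueError(f"gene roles must be disjoint; shared: {sorted(overlap)}")
    for role, guides in (("anchor", anchor_guides), ("library", library_guides)):
        for gene, spacers in guides.items():
            if not spacers:
                raise ValueError(f"{role} gene {gene!r} has no guides")

    all_spacers: dict[str, str] = {}
    for guides in (anchor_guides, library_guides, control_guides or {}):
        for gene, spacers in guides.items():
            for sp in spacers:
                prev = all_spacers.setdefault(sp, gene)
                if prev != gene:
                    raise ValueError(
                        f"spacer {sp!r} shared between genes {prev!r} and {gene!r}"
                    )

    records: list[GuidePairRecord] = []
    i = 0

    def add(gene1, sp1, gene2, sp2, cls):
        nonlocal i
        records.append(
            GuidePairRecord(f"{name}_{i:06d}", gene1, sp1, scaffold1, gene2, sp2, cls)
        )
        i += 1

    for lib_gene in sorted(library_guides):
        for anc_gene in sorted(anchor_guides):
            for lib_sp in library_guides[lib_gene][:guides_per_gene]:
                for anc_sp in anchor_guides[anc_gene][:guides_per_gene]:
                    add(lib_gene, lib_sp, anc_gene, anc_sp, "double_ko")

    if control_guides:
        ctrl = [
            (gene, sp)
            for gene in sorted(control_guides)
            for sp in control_guides[gene]
        ]
        if not ctrl:
            raise ValueError("control_guides given but contains no guides")
        if singleton_controls_per_guide is not None:
            ctrl = ctrl[:singleton_controls_per_guide]
        # anchors keep position 2 (control in position 1); library guides
        # keep position 1 (control in position 2)
        for anc_gene in sorted(anchor_guides):
            for anc_sp in anchor_guides[anc_gene]:
                for cgene, csp in ctrl:
                    add(cgene, csp, anc_gene, anc_sp, "singleton")
        for lib_gene in sorted(library_guides):
            for lib_sp in library_guides[lib_gene]:
                for cgene, csp in ctrl:
                    add(lib_gene, lib_sp, cgene, csp, "singleton")
    elif singleton_controls_per_guide:
        raise ValueError("singleton controls requested but control_guides is empty")

    return LibraryManifest(records, name=name)


def mirror_orientations(manifest: LibraryManifest) -> LibraryManifest:
    """Add the (b, a) orientation for every (a, b) guide pair.

    Self-pairs are not duplicated and already-mirrored manifests pass
    through unchanged (the operation is idempotent).  Mirrored records get
    vector ids suffixed ``_rev``.
    """
    pairs = manifest.spacer_pairs
    out = list(manifest.records)
    for rec in manifest.records:
        rev = (rec.spacer2, rec.spacer1)
        if rev in pairs:
            continue
        pairs.add(rev)
        out.append(
            replace(
                rec,
                vector_id=rec.vector_id + "_rev",
                gene1=rec.gene2,
                spacer1=rec.spacer2,
                gene2=rec.gene1,
                spacer2=rec.spacer1,
            )
        )
    return LibraryManifest(out, name=manifest.name, metadata=manifest.metadata)


def compose_pilot_classes(
    class_specs: Mapping[str, int],
    generators: Mapping[str, Iterator[GuidePairRecord]],
    name: str = "pilot",
) -> LibraryManifest:
    """Draw exactly the requested number of vectors per design class.

    ``generators`` maps each class key to an iterator of records; a
    generator that runs dry before its requested count raises.  The
    per-class tallies are recorded in the manifest metadata.
    """
    records: list[GuidePairRecord] = []
    tallies: dict[str, int] = {}
    for cls, count in class_specs.items():
        if count < 0:
            raise ValueError(f"negative count for class {cls!r}")
        gen = generators.get(cls)
        if gen is None and count > 0:
            raise ValueError(f"no generator for class {cls!r}")
        taken = 0
        while taken < count:
            try:
                records.append(next(gen))
            except StopIteration:
                raise ValueError(
                    f"generator for class {cls!r} exhausted after {taken} "
                    f"of {count} vectors"
                ) from None
            taken += 1
        tallies[cls] = taken
    return LibraryManifest(records, name=name, metadata={"class_sizes": tallies})


#: Printed vector counts of the six pilot-library classes (total 8914).
PILOT_CLASS_SIZES: dict[str, int] = {
    "scaffold_position": 2952,
    "gi_pairs": 2872,
    "negative_controls": 1884,
    "copy_number": 600,
    "cancer_controls": 320,
    "dsb_distance": 286,
}


def write_manifest(manifest: LibraryManifest, path) -> None:
    """Write a manifest as UTF-8 TSV with the canonical column header."""
    manifest.to_frame().to_csv(path, sep="\t", index=False)


def read_manifest(path, name: str | None = None) -> LibraryManifest:
    """Read a TSV manifest written by :func:`write_manifest`.

    Raises ``ValueError`` naming the offending row/field for missing
    columns, duplicate vector ids, or invalid spacers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(GuidePairRecord(**{c: row[c] for c in MANIFEST_COLUMNS}))
        except ValueError as err:
            raise ValueError(f"manifest {path} row {idx}: {err}") from err
    return LibraryManifest(records, name=name or str(path))
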