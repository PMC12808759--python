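"""Paired-read guide-pair quantification and recombination calling.

Read anatomy is fixed by the custom sequencing primers: read 1 starts at
spacer-1 base 2 (the primer's trailing G consumes the spacer's leading
guanine) and read 2 starts at the reverse complement of spacer 2.  Each
read pair is resolved against the designed library at Hamming distance 0
or 1 per read and classified into one of eight mutually exclusive
categories:

DESIGNED_PAIR   both spacers resolved and the pair is in the manifest
SWAP            both resolved but the pair was never designed
                (template switching / lentiviral recombination)
GUIDE1_ONLY     read 2 carries the position-1 spacer (a recombinant
                vector retaining only guide 1)
GUIDE2_ONLY     read 1 carries the position-2 spacer
PARTIAL_R1      only read 1 resolved
PARTIAL_R2      only read 2 resolved
AMBIGUOUS       a read matched two or more spacers equally well
UNMAPPED        neither read resolved
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .constants import reverse_complement
from .libdesign import LibraryManifest

CATEGORIES = (
    "DESIGNED_PAIR",
    "SWAP",
    "GUIDE1_ONLY",
    "GUIDE2_ONLY",
    "PARTIAL_R1",
    "PARTIAL_R2",
    "AMBIGUOUS",
    "UNMAPPED",
)

#: Sentinel returned by match_spacer when two keys tie at the best distance.
AMBIGUOUS = "__AMBIGUOUS__"


class SpacerIndex:
    """Per-position exact-lookup tables over the manifest's spacers.

    Position-1 keys are spacers minus their leading G (read-1 anatomy);
    position-2 keys are full spacers (matched against the reverse
    complement of the read-2 prefix).  Keys are bucketed by length, and
    cross-position buckets (full position-1 spacers, G-trimmed position-2
    spacers) support single-guide-vector detection.
    """

    def __init__(self, manifest: LibraryManifest) -> None:
        self.manifest = manifest
        # {length: {key: spacer}} per bucket
        self.pos1: dict[int, dict[str, str]] = {}
        self.pos2: dict[int, dict[str, str]] = {}
        self.pos1_full: dict[int, dict[str, str]] = {}
        self.pos2_trim: dict[int, dict[str, str]] = {}
        self.designed_pairs: dict[tuple[str, str], str] = {}
        self.spacer_gene: dict[tuple[int, str], str] = {}

        sp1_set, sp2_set = set(), set()
        for rec in manifest:
            self.designed_pairs[rec.spacer_pair] = rec.vector_id
            sp1_set.add(rec.spacer1)
            sp2_set.add(rec.spacer2)
            self.spacer_gene[(1, rec.spacer1)] = rec.gene1
            self.spacer_gene[(2, rec.spacer2)] = rec.gene2

        for sp in sorted(sp1_set):
            key = sp[1:]
            bucket = self.pos1.setdefault(len(key), {})
            if key in bucket and bucket[key] != sp:
                raise ValueError(
                    f"position-1 spacers {bucket[key]!r} and {sp!r} collide "
                    "after leading-G trim"
                )
            bucket[key] = sp
            self.pos1_full.setdefault(len(sp), {})[sp] = sp
        for sp in sorted(sp2_set):
            self.pos2.setdefault(len(sp), {})[sp] = sp
            self.pos2_trim.setdefault(len(sp) - 1, {})[sp[1:]] = sp

        self._warn_prefix_collisions()

    def _warn_prefix_collisions(self) -> None:
        for buckets in (self.pos1, self.pos2):
            lengths = sorted(buckets, reverse=True)
            for i, long_len in enumerate(lengths):
                for short_len in lengths[i + 1 :]:
                    short = buckets[short_len]
                    hits = [
                        k for k in buckets[long_len] if k[:short_len] in short
                    ]
                    if hits:
                        warnings.warn(
                            f"{len(hits)} spacer(s) of length {long_len} share "
                            f"a length-{short_len} prefix with shorter spacers; "
                            "longest-bucket-first matching will prefer the "
                            "longer spacer",
                            UserWarning,
                            stacklevel=3,
                        )

    @property
    def pos1_lengths(self) -> list[int]:
        return sorted(self.pos1, reverse=True)

    @property
    def pos2_lengths(self) -> list[int]:
        return sorted(self.pos2, reverse=True)


def _lookup(bucket: dict[str, str], candidate: str, max_mismatch: int):
    """Resolve a candidate in one length bucket.

    Returns ``(spacer, n_mismatches)``, ``(AMBIGUOUS, 1)`` on a distance-1
    tie, or ``(None, None)``.  Exact hits always win; at ``max_mismatch=1``
    the 3L single-substitution neighbourhood of the candidate is probed.
    """
    hit = bucket.get(candidate)
    if hit is not None:
        return hit, 0
    if max_mismatch >= 1:
        found = None
        for i, base in enumerate(candidate):
            prefix, suffix = candidate[:i], candidate[i + 1 :]
            for sub in "ACGT":
                if sub == base:
                    continue
                hit = bucket.get(prefix + sub + suffix)
                if hit is not None:
                    if found is not None and hit != found:
                        return AMBIGUOUS, 1
                    found = hit
        if found is not None:
            return found, 1
    return None, None


def extract_spacers(
    read1: str, read2: str, lengths1, lengths2
) -> tuple[dict[int, str], dict[int, str]]:
    """Candidate spacer strings per position and length.

    Position-1 candidates are the first L-1 bases of read 1 (the leading G
    is primer-consumed); position-2 candidates are the reverse complement
    of the first L bases of read 2.  Reads too short for a length yield no
    candidate at that length.
    """
    read1 = read1.upper()
    read2 = read2.upper()
    cand1 = {L: read1[: L - 1] for L in lengths1 if len(read1) >= L - 1}
    cand2 = {
        L: reverse_complement(read2[:L]) for L in lengths2 if len(read2) >= L
    }
    return cand1, cand2


def match_spacer(
    index: SpacerIndex, candidate: str, position: int, max_mismatch: int = 1
):
    """Resolve one candidate against one position's buckets.

    Returns ``(spacer, mismatches)``; ``(AMBIGUOUS, 1)`` if two spacers tie
    at distance 1; ``(None, None)`` if nothing matches.  Longest length
    bucket is tried first; the first unique hit wins.  ``candidate`` is
    matched as-is, so for position 1 pass the G-trimmed sequence (the key
    buckets are keyed by trimmed length).
    """
    if not candidate:
        raise ValueError("empty candidate")
    buckets = index.pos1 if position == 1 else index.pos2
    for key_len in sorted(buckets, reverse=True):
        if len(candidate) < key_len:
            continue
        hit, mm = _lookup(buckets[key_len], candidate[:key_len], max_mismatch)
        if hit is not None:
            return hit, mm
    return None, None


@dataclass(frozen=True)
class ReadPairCall:
    """Classification of one read pair."""

    category: str
    guide1: str | None = None
    guide2: str | None = None
    vector_id: str | None = None
    mismatches1: int | None = None
    mismatches2: int | None = None


def classify_read_pair(
    index: SpacerIndex, read1: str, read2: str, max_mismatch: int = 1
) -> ReadPairCall:
    """Classify one read pair into the eight categories.

    Resolution order: both positions resolved -> DESIGNED_PAIR or SWAP
    (or GUIDE1_ONLY when both reads carry the very same spacer, which in a
    mirrored library resolves in both buckets); read 2 carrying the same
    position-1 spacer as read 1 -> GUIDE1_ONLY; read 1 carrying the same
    position-2 spacer as read 2 -> GUIDE2_ONLY; any tie -> AMBIGUOUS; one
    side resolved -> PARTIAL_R1/R2; else UNMAPPED.
    """
    r1 = read1.upper()
    r2 = read2.upper()

    def prefix1(key_len):
        return r1[:key_len] if len(r1) >= key_len else None

    def prefix2(key_len):
        return reverse_complement(r2[:key_len]) if len(r2) >= key_len else None

    def resolve(buckets, prefix_fn):
        for key_len in sorted(buckets, reverse=True):
            cand = prefix_fn(key_len)
            if cand is None:
                continue
            hit, mm = _lookup(buckets[key_len], cand, max_mismatch)
            if hit is not None:
                return hit, mm
        return None, None

    g1, mm1 = resolve(index.pos1, prefix1)
    g2, mm2 = resolve(index.pos2, prefix2)

    amb1, amb2 = g1 == AMBIGUOUS, g2 == AMBIGUOUS

    if g1 and g2 and not (amb1 or amb2):
        pair = (g1, g2)
        vec = index.designed_pairs.get(pair)
        if vec is not None:
            return ReadPairCall("DESIGNED_PAIR", g1, g2, vec, mm1, mm2)
        if g1 == g2:
            # same spacer on both reads: a single-guide vector whose one
            # spacer happens to be library-designed in both positions
            return ReadPairCall("GUIDE1_ONLY", g1, None, None, mm1, mm2)
        return ReadPairCall("SWAP", g1, g2, None, mm1, mm2)

    if g1 and not amb1 and not g2:
        # guide1-only vector: read 2 reads back the position-1 spacer
        x, xmm = resolve(index.pos1_full, prefix2)
        if x == g1:
            return ReadPairCall("GUIDE1_ONLY", g1, None, None, mm1, xmm)
    if g2 and not amb2 and not g1:
        # guide2-only vector: read 1 reads the position-2 spacer (G-trimmed)
        x, xmm = resolve(index.pos2_trim, prefix1)
        if x == g2:
            return ReadPairCall("GUIDE2_ONLY", None, g2, None, xmm, mm2)

    if amb1 or amb2:
        return ReadPairCall("AMBIGUOUS", None, None, None, mm1, mm2)
    if g1:
        return ReadPairCall("PARTIAL_R1", g1, None, None, mm1, None)
    if g2:
        return ReadPairCall("PARTIAL_R2", None, g2, None, None, mm2)
    return ReadPairCall("UNMAPPED")


@dataclass
class CountTable:
    """Per-vector counts and per-sample read-pair category tallies."""

    counts: pd.DataFrame  # vectors x samples, integer
    tallies: pd.DataFrame  # categories x samples, integer
    marginals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            index=["gRNA1_resolved", "gRNA2_resolved"]
        )
    )  # per-read marginal resolution tallies x samples

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self, sample: str) -> int:
        return int(self.tallies[sample].sum())

    def validate(self) -> None:
        for s in self.samples:
            if int(self.counts[s].sum()) != int(
                self.tallies.loc["DESIGNED_PAIR", s]
            ):
                raise ValueError(
                    f"sample {s}: vector counts do not sum to the "
                    "DESIGNED_PAIR tally"
                )


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def quantify_run(
    manifest: LibraryManifest,
    fastq1,
    fastq2,
    max_mismatch: int = 1,
    sample: str = "sample",
) -> CountTable:
    """Count guide pairs from one synchronised paired FASTQ run.

    Accepts plain or gzipped FASTQ.  Raises on desynchronised files
    (unequal record counts).  Deterministic for fixed input.
    """
    index = manifest if isinstance(manifest, SpacerIndex) else SpacerIndex(manifest)
    vec_counts = dict.fromkeys(
        (rec.vector_id for rec in index.manifest), 0
    )
    tallies = dict.fromkeys(CATEGORIES, 0)
    n1_resolved = n2_resolved = 0

    with _open_text(fastq1) as fh1, _open_text(fastq2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"desynchronised FASTQ pair: {fastq1} and {fastq2} have "
                    "unequal record counts"
                )
            call = classify_read_pair(index, rec1[1], rec2[1], max_mismatch)
            tallies[call.category] += 1
            if call.vector_id is not None:
                vec_counts[call.vector_id] += 1
            if call.category in ("DESIGNED_PAIR", "SWAP", "GUIDE1_ONLY",
                                 "PARTIAL_R1"):
                n1_resolved += 1
            if call.category in ("DESIGNED_PAIR", "SWAP", "GUIDE2_ONLY",
                                 "PARTIAL_R2"):
                n2_resolved += 1

    counts = pd.DataFrame({sample: pd.Series(vec_counts, dtype=int)})
    counts.index.name = "vector_id"
    tally_df = pd.DataFrame(
        {sample: pd.Series(tallies, dtype=int)}
    ).reindex(list(CATEGORIES))
    marg = pd.DataFrame(
        {sample: [n1_resolved, n2_resolved]},
        index=["gRNA1_resolved", "gRNA2_resolved"],
    )
    table = CountTable(counts, tally_df, marg)
    table.validate()
    return table


def merge_count_tables(tables: list[CountTable]) -> CountTable:
    """Column-concatenate single-sample count tables into one."""
    return CountTable(
        pd.concat([t.counts for t in tables], axis=1),
        pd.concat([t.tallies for t in tables], axis=1),
        pd.concat([t.marginals for t in tables], axis=1),
    )


def category_summary(table: CountTable, sample: str | None = None) -> dict:
    """Category proportions plus gRNA1/gRNA2 marginal resolution rates.

    Proportions sum to 1 over the eight categories; marginal rates are
    computed over all read pairs.  Raises on a zero-read table.
    """
    if sample is None:
        if len(table.samples) != 1:
            raise ValueError("sample must be named for multi-sample tables")
        sample = table.samples[0]
    total = table.total_reads(sample)
    if total == 0:
        raise ValueError(f"sample {sample}: zero reads")
    out = {
        cat: float(table.tallies.loc[cat, sample]) / total for cat in CATEGORIES
    }
    if sample in table.marginals.columns:
        out["gRNA1_resolved_rate"] = (
            float(table.marginals.loc["gRNA1_resolved", sample]) / total
        )
        out["gRNA2_resolved_rate"] = (
            float(table.marginals.loc["gRNA2_resolved", sample]) / total
        )
    out["total_reads"] = total
    return out


def write_counts(table: CountTable, prefix) -> None:
    """Write counts TSV, category-summary TSV and a JSON run report."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(f"{prefix}.counts.tsv", sep="\t")
    table.tallies.to_csv(f"{prefix}.categories.tsv", sep="\t")
    report = {s: category_summary(table, s) for s in table.samples}
    with open(f"{prefix}.report.json", "w") as fh:
        json.dump(report, fh, indent=2)


def read_counts(path) -> pd.DataFrame:
    """Read a counts TSV (vector_id index, one column per sample)."""
    return pd.read_csv(path, sep="\t", index_col="vector_id")
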