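"""Synthetic dual-guide screens with known ground truth.

The generator emulates a pooled anchor-library fitness screen: a manifest
built with the real design rules (anchor genes fixed in cassette position
2, singleton vectors pairing each targeting guide with cutting controls,
control x control pairs for the interaction null); lognormal plasmid
abundances; exponential selection over D population doublings at per-vector
fitness f (log2 growth deviation per doubling), multinomially sampled at
fixed read depth for day-3 and day-14 replicates; and paired reads with
the real read anatomy (read 1 starts at spacer-1 base 2, read 2 at the
reverse complement of spacer 2) carrying configurable substitution errors,
guide-pair swaps, and single-guide-vector signatures.

All randomness flows from the single ``seed`` in :class:`SimParams`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import LEADERS, OLIGO_LEFT_ARM, SCAFFOLDS, TRNA_GLY, reverse_complement
from .libdesign import GuidePairRecord, LibraryManifest, build_anchor_library
from .quantify import CountTable
from .screen_stats import EffectTable, SampleSpec, ScreenDesign

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class SimParams:
    """Study conditions of the simulated screen.

    Fitness ``f`` is the log2 growth deviation per population doubling, so
    a vector's expected LFC after ``doublings`` D is D*f (up to the global
    sum-normalisation shift).  Defaults emulate a desk-scale version of a
    triplicate day-3 vs day-14 colorectal-line screen: a handful of
    strongly depleting essential genes (f = -0.5, i.e. LFC -2 over D = 4),
    near-neutral cutting controls, moderate lognormal library skew
    (sigma = 0.5), 1e5 reads per sample, and low technical artefact rates
    in line with an optimised tRNA-spacer library (0.3% base error, 2%
    swaps, 2% single-guide vectors).
    """

    n_anchor_genes: int = 4
    n_library_genes: int = 10
    guides_per_anchor: int = 2
    guides_per_library: int = 2
    n_nonessential_genes: int = 3
    guides_per_nonessential: int = 2
    n_intergenic_genes: int = 8
    guides_per_intergenic: int = 2
    #: intergenic genes whose guides join the non-essential genes as the
    #: designated singleton-control set; the rest appear only in the
    #: control x control null pairs, so undesigned (swap) combinations
    #: exist for every position-1 spacer
    singleton_intergenic_genes: int = 3
    spacer_length: int = 20
    scaffold1: str = "Mod7"
    leader_len: int = 6

    essential_fraction: float = 0.3
    essential_fitness: float = -0.5
    fitness_noise_sd: float = 0.02
    n_interactions: int = 2
    interaction_lfc: float = -2.0

    abundance_sigma: float = 0.5
    doublings: float = 4.0
    n_replicates: int = 3
    read_depth: int = 100_000
    base_error_rate: float = 0.003
    swap_rate: float = 0.02
    single_guide_rate: float = 0.02
    read_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "swap_rate", "single_guide_rate",
                     "essential_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.read_length < self.spacer_length:
            raise ValueError("read_length shorter than the spacer length")


@dataclass
class SimulationTruth:
    """Ground truth sufficient to verify every downstream estimate."""

    vector_fitness: pd.Series  # f per vector (log2 per doubling)
    pair_deltas: pd.DataFrame  # gene_a, gene_b, delta (LFC scale)
    gene_fitness: dict[str, float]
    control_genes: dict[str, str]
    abundance: pd.Series | None = None  # plasmid shares
    expected_lfc: pd.Series | None = None  # D*f - renormalisation shift
    true_counts: pd.DataFrame | None = None
    read_truth: pd.DataFrame | None = None  # per-category true read tallies


def _random_spacers(rng: np.random.Generator, n: int, length: int,
                    taken: set[str]) -> list[str]:
    out = []
    while len(out) < n:
        sp = "G" + "".join(rng.choice(_BASES, size=length - 1))
        if sp not in taken:
            taken.add(sp)
            out.append(sp)
    return out


def simulate_manifest(params: SimParams) -> tuple[LibraryManifest, SimulationTruth]:
    """Build a manifest with the anchor-library design rules plus truth.

    Essential library genes (a seeded ``essential_fraction`` subset) get
    fitness ``essential_fitness``; anchors and controls are near-neutral;
    ``n_interactions`` anchor x library pairs carry an extra interaction
    effect of ``interaction_lfc`` (on the final-LFC scale).  Control x
    control double vectors over the intergenic genes provide the
    interaction null.
    """
    rng = np.random.default_rng(params.seed)
    taken: set[str] = set()

    def gene_guides(prefix, n_genes, n_guides):
        return {
            f"{prefix}{i}": _random_spacers(rng, n_guides, params.spacer_length, taken)
            for i in range(n_genes)
        }

    anchors = gene_guides("ANC", params.n_anchor_genes, params.guides_per_anchor)
    library = gene_guides("LIB", params.n_library_genes, params.guides_per_library)
    noness = gene_guides("NE", params.n_nonessential_genes,
                         params.guides_per_nonessential)
    interg = gene_guides("IG", params.n_intergenic_genes,
                         params.guides_per_intergenic)
    control_genes = {g: "nonessential" for g in noness}
    control_genes.update({g: "intergenic" for g in interg})
    # designated singleton-control subset: all non-essential genes plus a
    # few intergenic genes (so both control classes support estimation)
    singleton_ig = dict(
        sorted(interg.items())[: params.singleton_intergenic_genes]
    )
    controls = {**noness, **singleton_ig}

    manifest = build_anchor_library(
        anchors, library, controls,
        guides_per_gene=max(params.guides_per_anchor, params.guides_per_library),
        scaffold1=params.scaffold1, name="sim",
    )

    # control x control pairs for the empirical interaction null, plus
    # singleton vectors for each intergenic gene (paired with the
    # non-essential controls) so the null deltas carry the same
    # expectation-estimation error as real pair deltas
    extra: list[GuidePairRecord] = []
    ig_names = sorted(interg)
    k = len(manifest)
    for i, ga in enumerate(ig_names):
        for gb in ig_names[i + 1:]:
            for sa in interg[ga]:
                for sb in interg[gb]:
                    extra.append(GuidePairRecord(
                        f"sim_null_{k:06d}", ga, sa, params.scaffold1,
                        gb, sb, "intergenic_control"))
                    k += 1
    for ga in ig_names:
        for sa in interg[ga]:
            for gb in sorted(noness):
                for sb in noness[gb]:
                    extra.append(GuidePairRecord(
                        f"sim_ctrl_{k:06d}", ga, sa, params.scaffold1,
                        gb, sb, "singleton"))
                    k += 1
    manifest = LibraryManifest(
        list(manifest) + extra, name="sim",
        metadata={"control_genes": control_genes},
    )

    # gene fitness: seeded essential subset of library genes depletes
    gene_fitness = {g: 0.0 for g in list(anchors) + list(controls)}
    lib_names = sorted(library)
    n_ess = int(round(params.essential_fraction * len(lib_names)))
    essential = list(rng.choice(lib_names, size=n_ess, replace=False))
    for g in lib_names:
        gene_fitness[g] = params.essential_fitness if g in essential else 0.0

    # interacting anchor x library pairs (among non-essential library genes
    # so the interaction is not confounded with single-gene essentiality)
    neutral_lib = [g for g in lib_names if g not in essential]
    pairs = [(a, l) for a in sorted(anchors) for l in neutral_lib]
    idx = rng.choice(len(pairs), size=min(params.n_interactions, len(pairs)),
                     replace=False)
    delta_per_doubling = params.interaction_lfc / params.doublings
    pair_delta = {tuple(sorted(pairs[i])): params.interaction_lfc for i in idx}

    fitness = {}
    for rec in manifest:
        f = gene_fitness.get(rec.gene1, 0.0) + gene_fitness.get(rec.gene2, 0.0)
        key = tuple(sorted((rec.gene1, rec.gene2)))
        if rec.design_class == "double_ko" and key in pair_delta:
            f += delta_per_doubling
        if params.fitness_noise_sd > 0:
            f += rng.normal(0.0, params.fitness_noise_sd)
        fitness[rec.vector_id] = f

    truth = SimulationTruth(
        vector_fitness=pd.Series(fitness, name="fitness"),
        pair_deltas=pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "delta": d}
             for (a, b), d in sorted(pair_delta.items())]
        ),
        gene_fitness=gene_fitness,
        control_genes=control_genes,
    )
    return manifest, truth


def screen_design(n_replicates: int) -> ScreenDesign:
    samples = []
    for r in range(1, n_replicates + 1):
        samples.append(SampleSpec(f"day3_r{r}", "day3", str(r)))
        samples.append(SampleSpec(f"day14_r{r}", "day14", str(r)))
    return ScreenDesign(samples)


def simulate_counts(
    manifest: LibraryManifest,
    truth: SimulationTruth,
    params: SimParams,
) -> CountTable:
    """Multinomial day-3/day-14 replicate counts under selection.

    Day-3 shares follow the lognormal plasmid abundance; day-14 shares are
    abundance * 2^(D*f), renormalised.  Each replicate is an independent
    multinomial draw of ``read_depth`` reads.  Updates ``truth`` in place
    with the drawn counts, plasmid shares and the exact expected LFC
    (D*f minus the renormalisation shift).
    """
    rng = np.random.default_rng(params.seed + 1)
    vec_ids = [rec.vector_id for rec in manifest]
    n = len(vec_ids)
    abund = rng.lognormal(mean=0.0, sigma=params.abundance_sigma, size=n)
    shares3 = abund / abund.sum()
    f = truth.vector_fitness.loc[vec_ids].to_numpy()
    growth = 2.0 ** (params.doublings * f)
    w = shares3 * growth
    shares14 = w / w.sum()

    cols = {}
    for r in range(1, params.n_replicates + 1):
        cols[f"day3_r{r}"] = rng.multinomial(params.read_depth, shares3)
        cols[f"day14_r{r}"] = rng.multinomial(params.read_depth, shares14)
    counts = pd.DataFrame(cols, index=pd.Index(vec_ids, name="vector_id"))

    truth.abundance = pd.Series(shares3, index=vec_ids, name="share")
    shift = float(np.log2(w.sum()))  # global renormalisation shift
    truth.expected_lfc = pd.Series(
        params.doublings * f - shift, index=vec_ids, name="expected_lfc"
    )
    truth.true_counts = counts

    tallies = pd.DataFrame(
        0, index=["DESIGNED_PAIR", "SWAP", "GUIDE1_ONLY", "GUIDE2_ONLY",
                  "PARTIAL_R1", "PARTIAL_R2", "AMBIGUOUS", "UNMAPPED"],
        columns=list(cols),
    )
    tallies.loc["DESIGNED_PAIR"] = counts.sum(axis=0)
    return CountTable(counts, tallies)


def simulate_effect_table(
    manifest: LibraryManifest,
    truth: SimulationTruth,
    params: SimParams,
    noise_sd: float = 0.2,
) -> EffectTable:
    """Vector-level LFCs as truth plus i.i.d. Gaussian guide noise.

    A direct effect-level simulator for statistical power studies: each
    vector's replicate LFC is D*f plus N(0, noise_sd) noise, bypassing the
    count layer (no normalisation shift, no sampling depth).
    """
    rng = np.random.default_rng(params.seed + 2)
    vec_ids = [rec.vector_id for rec in manifest]
    base = params.doublings * truth.vector_fitness.loc[vec_ids].to_numpy()
    cols = {
        str(r): base + rng.normal(0.0, noise_sd, size=len(vec_ids))
        for r in range(1, params.n_replicates + 1)
    }
    lfc = pd.DataFrame(cols, index=pd.Index(vec_ids, name="vector_id"))
    return EffectTable(lfc, design=screen_design(params.n_replicates))


def _cassette_template(rec: GuidePairRecord, leader_len: int) -> tuple[str, str]:
    """(read-1 template, read-2 template) for a designed vector."""
    upstream = (rec.spacer1 + SCAFFOLDS[rec.scaffold1] + LEADERS[leader_len]
                + TRNA_GLY)
    r1 = upstream[1:] + rec.spacer2 + SCAFFOLDS["imp"]
    r2 = reverse_complement(upstream + rec.spacer2)
    return r1, r2


def _single_guide_templates(spacer: str) -> tuple[str, str]:
    """Templates for a recombinant vector carrying one guide only.

    The retained spacer sits directly between the U6 junction and the imp
    scaffold, so both reads report the same spacer.
    """
    r1 = spacer[1:] + SCAFFOLDS["imp"]
    r2 = reverse_complement(OLIGO_LEFT_ARM + spacer)
    return r1, r2


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hit = rng.random(arr.size) < rate
    if not hit.any():
        return seq
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_reads(
    manifest: LibraryManifest,
    counts: pd.Series,
    params: SimParams,
    fastq1,
    fastq2,
) -> pd.DataFrame:
    """Write one sample's paired FASTQ and return per-read truth tallies.

    For each read pair: with probability ``single_guide_rate`` a
    single-guide-vector signature is emitted (guide 1 or guide 2 retained,
    equal odds); otherwise with probability ``swap_rate`` read 2 takes the
    position-2 spacer of a different vector, rejecting partners that would
    recreate a designed pair; otherwise the designed pair is emitted.
    Substitution errors are applied per base at ``base_error_rate``.
    ``counts`` gives the true read count per vector id (its sum is the
    number of pairs written).  Returns a per-vector frame of true
    category counts with columns designed/swap/guide1_only/guide2_only.
    """
    rng = np.random.default_rng(params.seed + 3)
    recs = {rec.vector_id: rec for rec in manifest}
    vec_ids = [v for v in counts.index if counts[v] > 0]
    designed = set(manifest.spacer_pairs)
    L = params.read_length

    templates = {
        v: _cassette_template(recs[v], params.leader_len) for v in vec_ids
    }

    # valid swap partners per position-1 spacer: any position-2 spacer that
    # does not recreate a designed pair (or a same-spacer signature)
    pos2_spacers = sorted({rec.spacer2 for rec in manifest})
    swap_partners: dict[str, list[str]] = {}
    if params.swap_rate > 0:
        for sp1 in {rec.spacer1 for rec in manifest}:
            swap_partners[sp1] = [
                s2 for s2 in pos2_spacers
                if s2 != sp1 and (sp1, s2) not in designed
            ]

    truth_rows = {v: {"designed": 0, "swap": 0, "guide1_only": 0,
                      "guide2_only": 0} for v in vec_ids}

    def open_out(path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix == ".gz":
            return gzip.open(path, "wt")
        return open(path, "w")

    qual = "I" * L
    i = 0
    with open_out(fastq1) as out1, open_out(fastq2) as out2:
        for v in vec_ids:
            rec = recs[v]
            t1, t2 = templates[v]
            for _ in range(int(counts[v])):
                u = rng.random()
                if u < params.single_guide_rate:
                    if rng.random() < 0.5:
                        r1, r2 = _single_guide_templates(rec.spacer1)
                        truth_rows[v]["guide1_only"] += 1
                    else:
                        r1, r2 = _single_guide_templates(rec.spacer2)
                        truth_rows[v]["guide2_only"] += 1
                elif u < params.single_guide_rate + params.swap_rate:
                    # reassign read 2 to a random undesigned partner
                    # (template switch downstream of guide 1)
                    partners = swap_partners[rec.spacer1]
                    if not partners:
                        raise RuntimeError(
                            f"vector {v}: every position-2 spacer forms a "
                            "designed pair; cannot inject a swap"
                        )
                    sp2 = partners[rng.integers(len(partners))]
                    r1 = t1
                    r2 = reverse_complement(
                        rec.spacer1 + SCAFFOLDS[rec.scaffold1]
                        + LEADERS[params.leader_len] + TRNA_GLY + sp2
                    )
                    truth_rows[v]["swap"] += 1
                else:
                    r1, r2 = t1, t2
                    truth_rows[v]["designed"] += 1
                r1 = _add_errors(rng, r1[:L], params.base_error_rate)
                r2 = _add_errors(rng, r2[:L], params.base_error_rate)
                out1.write(f"@sim_{i}/1\n{r1}\n+\n{qual}\n")
                out2.write(f"@sim_{i}/2\n{r2}\n+\n{qual}\n")
                i += 1

    df = pd.DataFrame.from_dict(truth_rows, orient="index")
    df.index.name = "vector_id"
    return df


def simulate_run(params: SimParams, out_dir=None):
    """Full desk-scale simulation: manifest, counts, and one FASTQ pair.

    Reads are generated for the first day-3 replicate.  If ``out_dir`` is
    given, writes manifest.tsv, counts.tsv, truth.tsv and R1/R2 fastq.gz
    there; returns (manifest, truth, counts, read_truth, paths).
    """
    from .libdesign import write_manifest

    manifest, truth = simulate_manifest(params)
    counts = simulate_counts(manifest, truth, params)
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        f1 = out_dir / "reads_R1.fastq.gz"
        f2 = out_dir / "reads_R2.fastq.gz"
    else:
        raise ValueError("out_dir is required to write FASTQ output")
    read_truth = simulate_reads(
        manifest, counts.counts["day3_r1"], params, f1, f2
    )
    write_manifest(manifest, out_dir / "manifest.tsv")
    counts.counts.to_csv(out_dir / "counts.tsv", sep="\t")
    truth.vector_fitness.to_frame().to_csv(out_dir / "truth.tsv", sep="\t")
    read_truth.to_csv(out_dir / "read_truth.tsv", sep="\t")
    return manifest, truth, counts, read_truth, (f1, f2)
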