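"""Additive genetic-interaction scoring.

The expected fitness of a double knockout under no interaction is the sum
of the two single-knockout effects (each estimated from singleton vectors
that pair the gene's guides with cutting controls — intergenic by default,
since non-targeting guides do not control for double-strand-break
toxicity).  The interaction score is

    delta = observed double-KO LFC - (singleton_A + singleton_B)

with negative delta indicating synthetic lethality and positive delta
buffering.  Significance is assessed against an empirical null of deltas
from control x control pairs: z = (delta - mean(null)) / sd(null), a
two-sided normal p-value, and Benjamini-Hochberg FDR across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .libdesign import LibraryManifest
from .screen_stats import EffectTable

#: design classes usable as the singleton control side
CONTROL_CLASSES = ("intergenic", "nonessential", "nontargeting")


@dataclass(frozen=True)
class SingletonEffect:
    gene: str
    lfc: float
    n_vectors: int
    control_class: str


def estimate_singletons(
    effects: EffectTable,
    manifest: LibraryManifest,
    control_genes: dict[str, str] | None = None,
    control_class: str = "intergenic",
) -> dict[str, SingletonEffect]:
    """Single-knockout effect per gene from its singleton vectors.

    ``control_genes`` maps each control gene name to its class
    ("intergenic", "nonessential" or "nontargeting"); if omitted it is
    taken from ``manifest.metadata['control_genes']``.  A singleton vector
    contributes to the gene on its non-control side when its control side
    belongs to ``control_class``.  Raises for a gene with no singleton
    vectors of the requested class.
    """
    if control_class not in CONTROL_CLASSES:
        raise ValueError(f"control_class must be one of {CONTROL_CLASSES}")
    if control_genes is None:
        control_genes = manifest.metadata.get("control_genes")
        if control_genes is None:
            raise ValueError(
                "control_genes not given and absent from manifest metadata"
            )
    vec_mean = effects.vector_means()
    sums: dict[str, list[float]] = {}
    target_genes: set[str] = set()
    for rec in manifest:
        if rec.design_class != "singleton":
            if rec.design_class == "double_ko":
                target_genes.update((rec.gene1, rec.gene2))
            continue
        if rec.vector_id not in vec_mean.index:
            continue
        c1 = control_genes.get(rec.gene1)
        c2 = control_genes.get(rec.gene2)
        if c1 == control_class and rec.gene2 not in control_genes:
            sums.setdefault(rec.gene2, []).append(vec_mean[rec.vector_id])
        elif c2 == control_class and rec.gene1 not in control_genes:
            sums.setdefault(rec.gene1, []).append(vec_mean[rec.vector_id])
        target_genes.update(
            g for g in (rec.gene1, rec.gene2) if g not in control_genes
        )
    missing = sorted(target_genes - set(sums))
    if missing:
        raise ValueError(
            f"no {control_class!r}-paired singleton vectors for gene(s): "
            f"{missing[:5]}"
        )
    return {
        gene: SingletonEffect(gene, float(np.mean(v)), len(v), control_class)
        for gene, v in sums.items()
    }


def gi_delta(
    effects: EffectTable,
    singletons: dict[str, SingletonEffect],
    manifest: LibraryManifest,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Observed vs additive-expected double-KO effect per gene pair.

    Pairs default to all distinct double_ko gene pairs in the manifest.
    Returns a frame indexed by (gene_a, gene_b) with columns observed,
    expected, delta and n_vectors.
    """
    vec_mean = effects.vector_means()
    by_pair: dict[tuple[str, str], list[float]] = {}
    for rec in manifest:
        if rec.design_class != "double_ko" or rec.vector_id not in vec_mean.index:
            continue
        key = tuple(sorted((rec.gene1, rec.gene2)))
        by_pair.setdefault(key, []).append(vec_mean[rec.vector_id])
    if pairs is None:
        pairs = sorted(by_pair)
    rows = []
    for a, b in pairs:
        key = tuple(sorted((a, b)))
        if key not in by_pair:
            raise ValueError(f"no double-KO vectors for pair {key}")
        for g in key:
            if g not in singletons:
                raise ValueError(f"no singleton estimate for gene {g!r}")
        observed = float(np.mean(by_pair[key]))
        expected = singletons[key[0]].lfc + singletons[key[1]].lfc
        rows.append(
            {
                "gene_a": key[0],
                "gene_b": key[1],
                "observed": observed,
                "expected": expected,
                "delta": observed - expected,
                "n_vectors": len(by_pair[key]),
            }
        )
    return pd.DataFrame(rows).set_index(["gene_a", "gene_b"])


def control_null_deltas(
    effects: EffectTable,
    manifest: LibraryManifest,
    control_genes: dict[str, str] | None = None,
    singletons: dict[str, SingletonEffect] | None = None,
) -> np.ndarray:
    """Null interaction deltas from control x control double vectors.

    For each pair of distinct control genes with double vectors (design
    classes such as intergenic_control), the null delta is the mean
    observed LFC minus the two control genes' own singleton-style
    effects, mirroring the real delta computation so the null carries the
    same expectation-estimation error.  A control gene's own effect is
    estimated from its ``singleton`` vectors whose position-2 partner is a
    different control gene (falling back to ``singletons`` or 0 when no
    such vectors exist — cutting controls sit near zero by construction).
    """
    if control_genes is None:
        control_genes = manifest.metadata.get("control_genes")
        if control_genes is None:
            raise ValueError(
                "control_genes not given and absent from manifest metadata"
            )
    vec_mean = effects.vector_means()
    by_pair: dict[tuple[str, str], list[float]] = {}
    ctrl_single: dict[str, list[float]] = {}
    for rec in manifest:
        if rec.gene1 not in control_genes or rec.gene2 not in control_genes:
            continue
        if rec.gene1 == rec.gene2 or rec.vector_id not in vec_mean.index:
            continue
        val = vec_mean[rec.vector_id]
        if rec.design_class == "singleton":
            ctrl_single.setdefault(rec.gene1, []).append(val)
            continue
        key = tuple(sorted((rec.gene1, rec.gene2)))
        by_pair.setdefault(key, []).append(val)

    def own_effect(gene: str) -> float:
        if gene in ctrl_single:
            return float(np.mean(ctrl_single[gene]))
        if singletons and gene in singletons:
            return singletons[gene].lfc
        return 0.0

    deltas = []
    for (a, b), vals in sorted(by_pair.items()):
        deltas.append(float(np.mean(vals)) - own_effect(a) - own_effect(b))
    return np.asarray(deltas)


def permutation_null_deltas(
    scores: pd.DataFrame, n_permutations: int = 1000, seed: int = 0
) -> np.ndarray:
    """Fallback null: recentre observed deltas by shuffling expectations.

    Pairs observed double-KO effects with randomly permuted additive
    expectations; usable when the library carries no control x control
    double vectors.
    """
    rng = np.random.default_rng(seed)
    obs = scores["observed"].to_numpy()
    exp = scores["expected"].to_numpy()
    out = []
    for _ in range(n_permutations):
        out.append(obs[rng.integers(len(obs))] - exp[rng.integers(len(exp))])
    return np.asarray(out)


def gi_significance(
    scores: pd.DataFrame,
    null_deltas,
    fdr_method: str = "fdr_bh",
    min_null: int = 20,
) -> pd.DataFrame:
    """Attach z, two-sided normal p and BH FDR to interaction scores.

    ``null_deltas`` is the empirical null (>= ``min_null`` values with
    non-zero spread); z standardises each delta against its mean and SD.
    """
    null = np.asarray(null_deltas, dtype=float)
    if null.size < min_null:
        raise ValueError(
            f"null too small: {null.size} deltas (need >= {min_null})"
        )
    mu, sd = null.mean(), null.std(ddof=1)
    if sd == 0:
        raise ValueError("null deltas have zero spread")
    out = scores.copy()
    out["z"] = (out["delta"] - mu) / sd
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    out["fdr"] = multipletests(out["p"], method=fdr_method)[1]
    return out
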