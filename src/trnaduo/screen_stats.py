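"""Screen fitness statistics.

Counts are sum-normalised per sample, converted to log2 fold changes of a
treatment role (typically day 14) over a control role (day 3 or plasmid)
with replicates paired by id, and aggregated to gene level by averaging.
On top of the effect table the module computes the standard screen
benchmarks: Cohen's D with a two-sided Welch t-test between vector groups,
essential-gene recall AUC over the depletion ranking, and the positional
bias of guide activity between cassette positions 1 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .libdesign import LibraryManifest
from .quantify import CountTable

ROLES = ("plasmid", "day3", "day14")


@dataclass(frozen=True)
class SampleSpec:
    name: str
    role: str
    replicate: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"sample {self.name}: unknown role {self.role!r}")


@dataclass
class ScreenDesign:
    """Sample sheet plus the comparison of a treatment vs a control role."""

    samples: list[SampleSpec]
    treatment_role: str = "day14"
    control_role: str = "day3"

    def __post_init__(self) -> None:
        for role in (self.treatment_role, self.control_role):
            if not self.role_samples(role):
                raise ValueError(f"no samples with compared role {role!r}")
        for role in ROLES:
            reps = [s.replicate for s in self.role_samples(role)]
            if len(reps) != len(set(reps)):
                raise ValueError(f"duplicate replicate ids within role {role!r}")

    def role_samples(self, role: str) -> list[SampleSpec]:
        return [s for s in self.samples if s.role == role]

    def paired_replicates(self) -> list[tuple[str, str, str]]:
        """(replicate, treatment sample, control sample) triples.

        Replicates are paired by id; a replicate present in only one of
        the compared roles is dropped.
        """
        treat = {s.replicate: s.name for s in self.role_samples(self.treatment_role)}
        ctrl = {s.replicate: s.name for s in self.role_samples(self.control_role)}
        shared = sorted(set(treat) & set(ctrl))
        if not shared:
            raise ValueError("no replicate ids shared between compared roles")
        return [(r, treat[r], ctrl[r]) for r in shared]

    @classmethod
    def from_yaml(cls, path) -> "ScreenDesign":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        samples = [
            SampleSpec(s["name"], s["role"], str(s["replicate"]))
            for s in cfg["samples"]
        ]
        comp = cfg.get("comparison", {})
        return cls(
            samples,
            treatment_role=comp.get("treatment", "day14"),
            control_role=comp.get("control", "day3"),
        )


def normalise_counts(
    counts: CountTable | pd.DataFrame, scale: float = 1e7
) -> pd.DataFrame:
    """Sum-normalise each sample column to a fixed total.

    Every column of the returned frame sums to ``scale`` (default 1e7).
    Downstream log-fold-changes are invariant to the choice of scale.
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    sums = df.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"zero-sum sample column(s): {bad}")
    return df / sums * scale


@dataclass
class EffectTable:
    """Per-vector log2 fold changes per replicate."""

    lfc: pd.DataFrame  # vectors x replicates
    design: ScreenDesign | None = None
    annotations: pd.DataFrame | None = None

    @property
    def replicates(self) -> list[str]:
        return list(self.lfc.columns)

    def vector_means(self) -> pd.Series:
        return self.lfc.mean(axis=1)


def log2_fold_change(
    norm_counts: pd.DataFrame,
    design: ScreenDesign,
    pseudocount: float = 0.5,
) -> EffectTable:
    """LFC = log2(treatment + pc) - log2(control + pc) per paired replicate.

    ``pseudocount`` must be positive if any compared cell is zero.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    cols = {}
    for rep, treat, ctrl in design.paired_replicates():
        t = norm_counts[treat] + pseudocount
        c = norm_counts[ctrl] + pseudocount
        if (t <= 0).any() or (c <= 0).any():
            raise ValueError(
                "zero normalised count with pseudocount 0; use a positive "
                "pseudocount"
            )
        cols[rep] = np.log2(t) - np.log2(c)
    lfc = pd.DataFrame(cols)
    lfc.index.name = "vector_id"
    return EffectTable(lfc, design=design)


def aggregate_gene(
    effects: EffectTable,
    manifest: LibraryManifest,
    grouping: str = "gene_pair",
) -> pd.DataFrame:
    """Average vector LFCs to gene (or gene-pair) level.

    Replicates are averaged first, then member vectors (order fixed).
    ``grouping='gene_pair'`` groups on the sorted (gene1, gene2) tuple;
    ``grouping='gene'`` groups singleton-style vectors on gene1.  Raises
    for a vector absent from the manifest or a group left empty.
    """
    vec_mean = effects.vector_means()
    ann = manifest.to_frame().set_index("vector_id")
    missing = vec_mean.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"vectors not in manifest: {list(missing)[:5]}")
    ann = ann.loc[vec_mean.index]
    if grouping == "gene":
        keys = ann["gene1"]
    elif grouping == "gene_pair":
        keys = pd.Series(
            [tuple(sorted((g1, g2))) for g1, g2 in zip(ann["gene1"], ann["gene2"])],
            index=ann.index,
        )
    else:
        raise ValueError("grouping must be 'gene' or 'gene_pair'")
    grouped = vec_mean.groupby(keys)
    out = grouped.agg(lfc="mean", n_vectors="size")
    if grouping == "gene_pair":
        out.index = pd.MultiIndex.from_tuples(out.index,
                                              names=["gene_a", "gene_b"])
    else:
        out.index.name = "gene"
    return out


@dataclass
class EffectStats:
    cohens_d: float
    t_stat: float
    p_value: float
    n_x: int
    n_y: int


def cohens_d_ttest(x, y) -> EffectStats:
    """Cohen's D (pooled SD) plus a two-sided Welch t-test.

    d = (mean(x) - mean(y)) / s_pooled with the (n-1)-weighted pooled SD.
    Two degenerate equal groups give d = 0, p = 1; zero pooled variance
    with unequal means is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return EffectStats(0.0, 0.0, 1.0, nx, ny)
        raise ValueError("zero pooled variance with unequal group means")
    d = diff / np.sqrt(sp2)
    t_stat, p = stats.ttest_ind(x, y, equal_var=False)
    return EffectStats(float(d), float(t_stat), float(p), nx, ny)


@dataclass
class RecallResult:
    curve: np.ndarray  # (n+1, 2): fraction ranked, recall
    auc: float
    n_items: int
    n_positives: int


def recall_auc(scores: pd.Series, positive_ids) -> RecallResult:
    """Recall curve and AUC of a positive set over an ascending ranking.

    Items are ranked ascending by score (most depleted first), ties broken
    by stable id order.  The curve runs over x = fraction of items
    considered, y = fraction of positives recovered; the AUC is the
    trapezoid over x in [0, 1].
    """
    scores = pd.Series(scores)
    positive_ids = set(positive_ids)
    unknown = positive_ids - set(scores.index)
    if unknown:
        raise ValueError(f"positive ids not scored: {sorted(unknown)[:5]}")
    if not positive_ids:
        raise ValueError("empty positive set")
    ranked = scores.sort_values(kind="stable")
    n = len(ranked)
    hits = np.array([idx in positive_ids for idx in ranked.index])
    recall = np.concatenate([[0.0], np.cumsum(hits) / len(positive_ids)])
    xcoord = np.arange(n + 1) / n
    auc = float(np.trapezoid(recall, xcoord))
    return RecallResult(
        np.column_stack([xcoord, recall]), auc, n, len(positive_ids)
    )


@dataclass
class PositionBias:
    pearson_r: float
    slope: float
    intercept: float
    n_guides: int
    per_guide: pd.DataFrame = field(repr=False, default=None)


def position_bias(effects: EffectTable, manifest: LibraryManifest) -> PositionBias:
    """Positional balance of guide activity in a mirrored library.

    For every spacer observed in both cassette positions, its mean LFC
    over position-1 vectors is paired with its mean over position-2
    vectors; Pearson's r and the OLS slope (position-2 on position-1)
    quantify the balance.  Needs >= 3 such guides.
    """
    vec_mean = effects.vector_means()
    ann = manifest.to_frame().set_index("vector_id").loc[vec_mean.index]
    pos1 = vec_mean.groupby(ann["spacer1"]).mean()
    pos2 = vec_mean.groupby(ann["spacer2"]).mean()
    shared = pos1.index.intersection(pos2.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} guides observed in both positions (need >= 3)"
        )
    a = pos1.loc[shared].to_numpy()
    b = pos2.loc[shared].to_numpy()
    r = float(stats.pearsonr(a, b).statistic)
    fit = stats.linregress(a, b)
    per_guide = pd.DataFrame({"pos1_lfc": a, "pos2_lfc": b}, index=shared)
    return PositionBias(r, float(fit.slope), float(fit.intercept),
                        len(shared), per_guide)
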