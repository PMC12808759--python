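# Methods

## The cassette model

A dual-guide expression cassette is the exact concatenation

```
spacer1 · scaffold1 · leader · tRNA(Gly) · spacer2
```

with the position-2 (imp) scaffold supplied by the vector backbone
immediately downstream of spacer 2. The parts are fixed sequence
constants (`trnaduo.constants`): three interchangeable 76-nt position-1
scaffolds (WT; Mod6 with the lower-stem T→C flip that removes the TTTT
pol III terminator; Mod7 with additional structure-preserving nexus and
hairpin substitutions), the 86-nt imp scaffold, the 71-nt human glycine
tRNA body and its 6- or 30-nt native leader. Spacers are stored full
length, 17–20 nt with a mandatory leading G (required for U6
transcription); the canonical geometry — 193-nt cassette, 173-nt
spacer-to-spacer distance, 244-nt synthesis oligo — assumes 20-nt
spacers. A leaderless cassette is accepted but triggers a warning, since
removing the leader partially reduces position-1 guide activity. All
sequences are uppercase-normalised.

The synthesis-oligo cloning arms are the primer-annealing regions of the
library amplification primers: the left arm is the 3'-terminal 25 nt of
the forward primer (ending `ACACC`, so the spacer's leading G completes
the U6 `ACACCG` junction) and the right arm is the reverse complement of
the 3'-terminal 26 nt of the reverse primer, which equals the first
26 nt of the imp scaffold. Only the 51-nt total is geometrically
constrained; this particular split is the package's documented choice and
both arms are plain constants that a caller can override.

## Read anatomy and pair classification

The custom sequencing primers fix the read anatomy: the read-1 primer
ends in `...ACACCG`, so its trailing G consumes the spacer's first base
and read 1 begins at spacer-1 base 2; the read-2 primer anneals in the
imp scaffold, so read 2 begins at the reverse complement of spacer 2.
Matching therefore uses G-trimmed keys for position 1 and full spacers
(against the reverse-complemented read-2 prefix) for position 2, bucketed
by length.

Matching policy: an exact hit always wins; at the 1-mismatch setting the
3L single-substitution neighbourhood of the candidate is probed and a
unique Hamming-distance-1 hit wins, while two equidistant hits yield
AMBIGUOUS (excluded from counts). Longer length buckets are tried first
and the first unique hit wins; cross-length prefix collisions are
reported as warnings when the index is built. Mismatches are allowed per
read, not per pair. Base qualities are ignored — matching is by sequence
only.

Each read pair is assigned to exactly one of eight categories:

| category | rule |
| --- | --- |
| DESIGNED_PAIR | both spacers resolved, pair present in the manifest |
| SWAP | both resolved, pair absent, spacers distinct |
| GUIDE1_ONLY | read 2 carries the same position-1 spacer as read 1 |
| GUIDE2_ONLY | read 1 carries the same position-2 spacer as read 2 |
| PARTIAL_R1 / PARTIAL_R2 | only read 1 / only read 2 resolved |
| AMBIGUOUS | any tie at the best distance |
| UNMAPPED | neither read resolved |

The single-guide signatures arise from recombinant vectors that retain
one spacer directly between the U6 junction and the imp scaffold, so both
reads report the same spacer. In a library where one spacer is designed
in both positions the two single-guide orientations produce identical
read pairs; that degenerate case is called GUIDE1_ONLY by convention, so
only the *sum* of the two single-guide categories is identifiable there.
Category tallies always partition the read total, and per-vector counts
sum to the DESIGNED_PAIR tally.

## Screen statistics

Counts are sum-normalised per sample to a fixed total (default 1e7; all
downstream log-fold-changes are invariant to this constant). LFC is
log2(treatment + pc) − log2(control + pc) per replicate, replicates
paired by id, with a default pseudocount of 0.5 on the normalised scale
(pc = 0 is allowed only when no compared cell is zero). Gene-level values
average replicates first, then member vectors — the order is fixed.
Vectors with fewer than 10 reads in the reference sample (plasmid or
day 3, configurable) are removed before analysis; the threshold reflects
the bimodal low mode of plasmid count distributions, whose vectors also
show elevated replicate CV.

Group effect sizes use Cohen's D with the (n−1)-weighted pooled SD and a
two-sided Welch t-test. Essential-gene recall ranks items ascending by
LFC (most depleted first, ties broken by stable id order) and integrates
recall over the ranked fraction by trapezoid. Positional balance pairs
each spacer's mean LFC in position 1 with its mean in position 2 across a
mirrored library and reports Pearson's r and the OLS slope.

The Gini coefficient is the exact relative mean absolute difference
(computed via the sorted-rank identity), not a trapezoid approximation;
zeros are retained because dropouts are informative. It equals
1 − 2 × the exact area under the piecewise-linear Lorenz curve, and the
two routes are cross-checked in the tests.

## Genetic-interaction scoring

The double-knockout effect expected under no interaction is the sum of
the two single-knockout effects, each estimated as the mean LFC of the
gene's singleton vectors paired with cutting controls — intergenic by
default, because non-targeting guides do not control for double-strand-
break toxicity. The interaction score is delta = observed − expected;
negative means synthetic lethal, positive means buffering.

Significance uses an empirical null of deltas computed over
control × control double vectors with the same estimator structure as
real pairs (each control gene's own effect comes from its singleton
vectors against a *different* control class), so the null carries the
same expectation-estimation error as the scores it calibrates;
z-standardisation against the null mean/SD, two-sided normal p, and
Benjamini–Hochberg FDR across pairs follow. At least 20 null deltas are
required. When a library carries no control × control vectors, a seeded
permutation fallback recentres observed effects against shuffled
expectations. This additive delta is a deliberately transparent score; it
does not model guide-efficacy heterogeneity the way dedicated Bayesian
interaction models do, so its scores are not numerically exchangeable
with theirs, and because singleton estimates are shared across all pairs
of a gene, miscalibration concentrates as correlated false positives on
genes with outlying singleton estimates.

## The simulator

`simulate` emulates a pooled anchor-library fitness screen in a
fast-growing cancer line, desk-scaled:

- **Manifest** — built with the real design rules: anchor guides fixed in
  position 2, library guides in position 1, singleton vectors pairing
  every targeting guide with a designated control subset (non-essential
  plus a few intergenic genes — in the large-scale design this role is
  played by six guides over three non-essential genes), intergenic ×
  intergenic double vectors for the interaction null, and singleton
  vectors for the intergenic genes themselves so null deltas can subtract
  their own effects. Keeping the designated singleton subset small also
  guarantees undesigned guide-pair combinations exist, which is what
  makes swaps observable.
- **Fitness** — per-vector fitness f is the log2 growth deviation per
  population doubling; the expected LFC over D doublings is D·f. A seeded
  fraction of library genes (default 30%) is essential with f = −0.5
  (LFC −2 at the default D = 4 — a typical strong depletion over an
  11-day growth window); controls are neutral; selected anchor × library
  pairs carry an extra interaction effect (default −2 on the LFC scale).
  Per-vector Gaussian fitness noise (default sd 0.02 per doubling)
  models guide-efficacy variability.
- **Counts** — day-3 shares follow a lognormal abundance (default
  σ = 0.5, matching the mild skew of a well-cloned library; the resulting
  plasmid Gini of ≈ 0.2–0.3 sits in the range reported for real oligo
  pools); day-14 shares are abundance × 2^(D·f), renormalised; each
  replicate is an independent multinomial draw at the configured depth.
  Because sum normalisation renormalises the depleted library, raw LFC
  equals D·f only up to a global shift (log2 of the total share change);
  the truth object records the exact expected LFC, and recovery checks
  recentre on the neutral-population median, the standard practice.
  Optional dispersion beyond multinomial is deliberately absent by
  default — no noise model for it is identifiable from desk data.
- **Reads** — templates follow the real anatomy (read 1 = G-trimmed
  spacer 1 plus downstream cassette; read 2 = reverse complement from
  spacer 2 backwards). With probability q a single-guide signature is
  emitted (either guide, equal odds); otherwise with probability s read 2
  takes the position-2 spacer of a random undesigned partner — swaps are
  modelled as read-2 reassignment only, matching the template-switching
  mechanism downstream of guide 1, and partners that would recreate a
  designed pair are excluded so the injected rate is exactly the
  detectable rate. Substitution errors are applied per base (no indels,
  consistent with Hamming matching downstream). All randomness flows
  from a single seed.
- **Effect-level simulation** — `simulate_effect_table` draws vector
  LFCs directly as D·f + N(0, sd) per replicate, bypassing the count
  layer; it is used for statistical power studies where the guide-level
  noise must be set exactly.

What the simulator does **not** model: MOI/transduction dynamics,
selection kinetics, PCR duplicates, indels, position-dependent error
profiles, copy-number effects, or overdispersion calibrated to a real
cell line. Passing tests therefore demonstrate the correctness of the
pipeline's logic and estimators under known generative conditions, not
the biological fidelity of any particular screen.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale runs chosen so
every stochastic check has comfortable statistical margin: the default
simulated library (704 vectors: 4 anchors × 10 library genes plus
controls) with 1e5 read pairs for round-trip and swap/single-guide rate
recovery (binomial SE ≈ 0.05–0.1%, asserted within 3 SE); 1e6 reads per
sample and three replicates for depletion recovery (gene-level estimates
pool ≥ 12 vectors, giving SE ≈ 0.013 LFC against the 0.05 assertion);
and a 500-pair interaction screen (10 anchors × 50 library genes, 4
vectors per pair, 190 null pairs from 20 intergenic genes) with guide
noise sd 0.2 for detection power (per-pair delta SE ≈ 0.067, so a −2
interaction sits at |z| ≈ 30 and power is effectively 1).

Other fixed choices: the normalisation scale is 1e7 (configurable, and
immaterial to LFCs); recall ties break by stable id order; Gini requires
n ≥ 2 and a positive sum; equidistant 1-mismatch hits are discarded as
AMBIGUOUS rather than assigned; the low-count filter is strict
(< min_count removed, exactly min_count retained); Cohen's D with zero
pooled variance is an error unless the groups are identical (then d = 0,
p = 1); gene aggregation raises on unannotated vectors rather than
dropping them silently.
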