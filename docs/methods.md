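# Methods

## Model and assumptions

`niee` treats disease progression as a three-stage process — a stable
normal state, a reversible pre-disease state near a tipping point, and a
stable disease state — and looks for the pre-disease signature: a local
group of genes whose expression fluctuations (SD) and mutual Pearson
correlations rise sharply together. Rather than scoring genes, it scores
**edges** of an externally supplied protein–protein interaction
background network, each edge being the smallest network unit that can
carry both correlation and fluctuation information from the first-order
neighbourhoods of its two endpoint genes.

The method is model-free in the sense that nothing is trained: a single
perturbed sample is appended to a cohort of *s* reference samples
(healthy individuals, normal or adjacent tissue), and every edge's
entropy/SD statistic is recomputed on the *s + 1* samples. The per-edge
score is the product of absolute changes, ΔH_E = |ΔSD_E| · |ΔH_E|, so an
edge scores highly only when the appended sample disturbs *both* the
fluctuation level and the correlation structure around the edge — the
two halves of the pre-disease signature.

Assumptions worth keeping in mind:

- The background network is trusted as given. Which gene pairs count as
  edges, and the node degrees used as weights α, β, come entirely from
  it. No network inference from expression is attempted, and no
  identifier mapping is done — expression rows and network nodes must
  share a namespace.
- Expression is assumed pre-processed (normalised, log-transformed as
  appropriate). The scores are invariant to a global positive scaling of
  all values only up to a known factor: entropies are scale-free, SDs
  (and therefore Δ scores) scale linearly.
- Pearson correlation over the reference cohort must be meaningful: a
  hard minimum of 3 samples is enforced and a warning is emitted below 8.

## The statistic, precisely

For gene *x* with first-order neighbours *y = 1..M* (M ≥ 2 guaranteed by
pruning):

- neighbour weights `p_xy = |PCC_xy| / Σ_y |PCC_xy|`;
- node entropy `H_gx = −(1/log M) Σ p_xy log p_xy` ∈ [0, 1];
- node SD: sample standard deviation (divisor s − 1);
- edge statistics: degree-weighted convex combinations with α, β the
  endpoint degrees in the analysis graph;
- per-sample global score ΔGH: the mean of ΔH_E over all edges; the
  key-local score ΔLH: the mean over the screened key edge set (a `sum`
  reduction is available and induces the same per-fixed-network sample
  ranking, differing only by the constant edge count).

Degenerate cases are defined, not left to chance:

- a zero-variance gene has PCC := 0 with everything (no co-fluctuation
  signal);
- if every |PCC| of a node is 0, its weights fall back to the uniform
  distribution — entropy exactly 1, the maximum-uncertainty state,
  continuous with near-zero-correlation inputs;
- `0 · log 0 := 0`; an exactly uniform weight vector returns entropy
  exactly 1.0 (the analytic maximum) instead of accumulating rounding
  from the `p log p` sum;
- logs are natural internally; the 1/log M normalisation cancels the
  base (asserted numerically in the tests).

Both endpoints use their own neighbour count (M₁, M₂): the two genes of
an edge generally have different degrees, and each node's entropy is
normalised by its own log M. Neighbour sets come from the pruned,
expression-aligned analysis graph and are identical for the reference
and perturbed computations.

Floating point: double precision throughout; edges are always processed
in lexicographic order so sums are bit-reproducible; the whole-network
scorer is a vectorised implementation verified against a deliberately
naive loop transcription of the formulas to 1e−10 on random instances.

## Background-network handling

Edges are kept at confidence ≥ 0.85 by default (both the STRING 0–1000
integer scale and a unit scale are supported; duplicate orientations of
a pair collapse to the maximum score; self-loops are dropped). Isolated
nodes are removed. Edges incident to degree-one nodes are then pruned
— by default *iteratively*, until every remaining node has at least two
neighbours. A single pass can itself create new leaves; iterating avoids
that and simultaneously guarantees M ≥ 2, so the log M normalisation is
always defined. End nodes with a single neighbour carry minimal
neighbourhood information, which is why their edges are eliminated.

When an expression matrix is attached (`align_to_network`), the network
is restricted to the shared genes and re-pruned with the same settings,
and gene weights/degrees are recomputed on that final analysis graph —
the weights must describe the neighbour sets actually used.

## Screening and early warnings

Per perturbed sample, the top `top_fraction` of edges by ΔH_E is taken
(ceiling count, ties at the cutoff all included so the selection is
order-independent). Edges reaching the top set in at least
`min_frequency` samples form the key local network; `min_frequency`
defaults to half the number of samples (rounded up) and must be chosen
with the data's structure in mind — in a tipping time series the
signature exists only after the transition, so a recurrence threshold of
2–3 is usually more appropriate than half of all time points. The
default `top_fraction` of 0.01 is calibrated to genome-scale background
networks (~10⁴–10⁵ edges); on small networks a larger fraction (we use
0.05 on ~160-edge synthetic studies) keeps the per-sample top set from
collapsing to one or two edges.

Early-warning flags on a score trajectory are a pure convention of this
package (no canonical criterion exists): position *t* is flagged iff it
has at least `min_history` predecessors (default 3) and its value
exceeds their mean by more than `k` (default 2) sample standard
deviations. Flags are strictly causal — truncating a trajectory never
changes earlier flags. With only three history points the threshold
estimate is noisy and the per-sample global score is right-skewed, so
the earliest flaggable position has a markedly higher false-flag rate
(~20% in the synthetic studies) than later ones (~5–8%); treat a flag at
the very first eligible position with caution, or raise `min_history`.

For staged (non-time-series) designs, per-sample scores are averaged
within each stage (`grouped_trajectory`) with the stage order supplied
explicitly.

## Synthetic studies

The generator plants the pre-disease signature in a controlled way. A
seeded random graph (Erdős–Rényi by default, p = 0.12 on 50 genes,
≈150 edges; a scale-free option exists) gets a designated module wired
into a clique so its internal edges survive pruning. Expression is
multivariate normal with unit variance and correlation `baseline_rho`
(default 0.3) on adjacent gene pairs, ~0 elsewhere — a Gaussian model
controls exactly the two quantities the score consumes, correlations and
SDs. Because an adjacency-patterned matrix need not be positive
definite, it is repaired by eigenvalue clipping (with a warning) and
re-unitised; the realised adjacent correlation is therefore slightly
below the nominal value at this density.

The reference cohort has 17 samples by default — the size of a typical
published reference cohort for this class of method. The perturbed
series has one sample per time point: draws from the baseline
distribution before the tipping index, and afterwards the module genes'
SD is multiplied by `sd_boost` (default 3) with intra-module correlation
raised to `rho_boost` (default 0.8). A null study sets `sd_boost = 1`
and `rho_boost = baseline_rho`, making the series distributionally
identical to the reference.

What passing tests on these fixtures shows — and what it does not: the
generator demonstrates that the pipeline detects a genuine
variance/correlation surge against a faithful null, with calibrated
false-flag behaviour. It does not emulate platform noise, library-size
variation, heavy-tailed expression, batch structure, or mean shifts, so
performance on real microarray/RNA-seq cohorts depends additionally on
preprocessing quality and background-network relevance.

## Problem sizes and verification

The test suite and the acceptance script run desk-scale studies: ≤ 50
genes, ≤ ~170 edges, 8–17 reference samples, 10 time points, 20 planted
and 50 null seeds. At these sizes the full pipeline scores a sample in
milliseconds; genome-scale networks (10⁴ genes) are handled by the same
vectorised path with memory linear in directed adjacency ×
samples. Verification is layered: hand-checked closed forms for every
scalar operation, a loop-based independent oracle for the whole scoring
path, symmetry/invariance properties (reference-order permutation,
endpoint-orientation, scaling covariance), and the planted-module
recovery experiments.

## Known limitations

- ΔH_E is a raw product of absolute changes with no null-distribution or
  p-value machinery; scores are comparable across samples for a fixed
  analysis graph, not across different graphs.
- The per-sample global score inherits a strong right skew from its
  quadratic dependence on the appended sample's deviation; threshold-
  based flagging on short histories is accordingly liberal at the first
  eligible position (see above).
- Pearson correlation only (a hook for alternative correlation measures
  exists but is not implemented); no handling of censored or missing
  values beyond the loader policies.
- A gene constant across the reference cohort contributes zero
  correlation everywhere; if many genes are constant, node entropies
  degenerate towards the uniform fallback.
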