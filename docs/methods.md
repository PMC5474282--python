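# Methods

## Data model

A billing table is reduced to a corpus of *clinical days*: all records
sharing (trace id, day index) form one day; within a day, all records of
one item form one *group* with an integer multiplicity. Days are the
documents of the topic model, activities the words, groups the units that
receive a single topic under the constraint. Day indices are kept exactly
as given (only their order within a trace matters; gaps are allowed), and
duplicate rows are summed, never deduplicated, because billing rows are
additive.

Amount normalization is necessary because items are billed on different
scales (tablets, millilitres, flat fees). The default `unit-scale` mode
divides each item's amounts by that item's smallest observed amount and
rounds half-up, so the most common dose of an item counts as one
occurrence; this preserves within-item relative frequency and produces
the integer multiplicities the group sampler needs. A plain `round` mode
(half-up, floor 1) is available when amounts are already counts. No
published rule exists for this step; the choice is recorded here and is
configurable.

## Samplers

The baseline is standard collapsed Gibbs for LDA with priors stored as
vectors (symmetric defaults α = 1.0, β = 0.01). φ and θ are point
estimates from the final post-burn-in state by default — reproducible
given the seed — with posterior-mean averaging over post-burn-in sweeps
behind a flag.

The constrained sampler moves each (day, activity) group atomically. The
group conditional is the gamma-ratio expansion

w_k = ∏_{j=0}^{A−1} (N_{d,¬}^{(k)} + α_k + j)(N_{k,¬}^{(v)} + β_v + j)/(N_{k,¬} + Σβ + j),

the unique form consistent with restricting-and-renormalizing the
collapsed joint to constraint-satisfying assignments and with the A = 1
reduction to the token conditional. It is evaluated in log space (long
products of count-sized factors overflow linear space for large A). Its
correctness is pinned by an independent oracle in the test suite: the
exact joint computed as a sequential Polya-urn predictive product, which
shares no code with the gamma-ratio path, agrees with the implementation
to 1e−10 on hundreds of random tiny instances.

Both sweeps run as numba-compiled kernels over flat index arrays; all
randomness enters through pre-drawn uniform variates from a seeded
generator, so runs replay exactly and the kernels can be checked
token-for-token against pure-Python reference sweeps (they are, in the
tests).

## Correlation limitation

IDF(v) = ln(D / df(v)) with the natural log (only ratios and orderings
matter downstream). The topic-number bound s(v) maps IDF linearly from
[min IDF, max IDF] onto [K, 1] with half-up rounding (constant IDF
degenerates to s ≡ K); a rank-quantile mapping, insensitive to IDF
outliers, is available via `s_mode="rank"`. RV(k, v) = N_k^(v)/rank(k, v)
uses ranks under φ (not φ̄), since pruning happens during sampling before
IDF adjustment is applied for reporting; φ ties break by activity index.

Pruning runs every δ sweeps (default δ = 300) after a burn-in (default
200 sweeps), removing at most **one** topic per activity per update —
the reading of "discard the topic with minimum RV" that cannot collapse
a list in a single step. A group whose current topic is pruned keeps its
counts until its next scheduled resample, where the pruned topic is
simply absent from its support; this keeps every sweep a valid
conditional update. The final pruning step is never scheduled on the
last sweep, so every group's final topic lies inside its activity's
final list. `run_cdg` warns when the sweep budget cannot complete
pruning (fewer than K − min s update events).

## Evaluation

* **RE** — Σ_v (count(v) − 1) over the union of per-topic top-N lists.
* **NKQM@N** — mean over topics of the 1/ln(j+1)-discounted relevance sum,
  normalized by Z_N = Σ_j 2/ln(j+1) (the all-"very relevant" sum), so the
  score lives in [0, 1]. The normalizer and log base are conventions
  chosen here; scores are consumed from a TSV, never computed — relevance
  judgements are human.
* **Perplexity** — exp(−mean token log-likelihood) over whatever corpus it
  is handed: in-sample when given the training days (the default
  throughout), held-out when the caller passes a reserved day split. The
  uniform model scores exactly V.
* **Topic labels** — a day's label is the smallest prefix of topics in
  decreasing θ_d order reaching τ_mass = 0.8, capped at τ_max = 3. The
  rule (and its parameters) are this package's formalization of
  "dominant topics of a day"; both are configurable.
* **K selection** — per-candidate perplexity and mean label size are
  min-max normalized over the candidate range and the K minimizing their
  absolute gap is chosen (the intersection of a falling and a rising
  curve). Ties go to the smaller K; a constant curve normalizes to zero,
  so selection degenerates gracefully to the other curve's minimum.

## Synthetic data

The generator emulates the shape of real billing extracts scaled to desk
size: 50 traces of 6–14 days (≈500 clinical days), vocabulary 50,
~8 groups/day, multiplicities 1 + Poisson(0.8), sparse planted
φ* ~ Dir(0.05), per-day θ* ~ Dir(0.5), optionally driven by a Markov
chain of treatment stages with one θ profile per stage. Each group draws
one true topic, one activity, and a multiplicity, so ground truth
satisfies the assignment constraint by construction; a drawn activity
colliding with a same-day group under a different topic is redrawn
(rejection), a same-topic collision merges. What the generator does
*not* emulate: real item-name semantics and prices, department-specific
coding, comorbidity-driven correlation between traces, and the heavy
vocabulary tail of real data (752/447 distinct items in real extracts).
Passing recovery tests therefore demonstrate algorithmic correctness
under the planted model, not clinical validity on real logs.

## A finding on parameter recovery

On the planted corpora the constrained sampler is a markedly better
optimizer of the shared collapsed objective than token-level LDA — it
reliably reaches joint log-probabilities far above both the baseline's
final states and the planted assignment itself (e.g. −3888 vs −4543 vs
−4592 on one corpus). Under the sparse word prior β = 0.01 that
posterior mode is a *harder partition* of the vocabulary than the
overlapping planted φ*, so better inference can land slightly farther
from the planted matrix in total-variation distance (median matched TV
over five seeds: ≈0.046 constrained vs ≈0.038 baseline, both well under
0.15), even while the redundancy of the resulting top-10 lists — the
quality the limitation targets — is clearly better (median RE 2 vs 5).
The corresponding acceptance test asserts the recovery comparison as
specified and is expected to fail on its second clause; we keep it
failing rather than weaken it, since the effect is a property of the
model under these conditions, not an implementation defect (the sampler
is oracle-verified).

## Numerical and degenerate cases

Weights are always strictly positive on allowed topics (positive
priors); cumulative-sum sampling guards the r ≥ total edge case by
falling back deterministically. K = 1 forces all assignments to topic 0
and sweeps are no-ops. Empty corpora, empty supports, non-positive
amounts, missing columns, and unparseable rows raise typed errors.
Directly-follows filtering drops a label node only when *all* of its
interior edges fall below threshold, so high thresholds reduce the graph
to its start/end markers; virtual start/end edges are themselves never
filtered, keeping start-flow conservation in the unfiltered graph.

## Problem sizes

Tests and the acceptance script run on generated corpora of ~300–500
clinical days, 2–4 thousand groups, and 500–1000 sweeps; the brute-force
oracles run on corpora of ≤ 4 groups where K^G enumeration is exact.
These sizes were chosen so the full suite completes in well under a
minute while keeping every stochastic check at sample sizes where the
asserted effects are stable across seeds.
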