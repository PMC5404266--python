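# Methods

## The model

`npps` treats m6A site identification as binary classification of
fixed-length RNA windows centered on a candidate adenosine. The method has
three stages: a class-conditional positional encoding (NPPS), an RBF-kernel
SVM, and cross-validated evaluation. The encoding is the substantive part;
the classifier and the evaluation protocol are standard.

### NPPS encoding

For a training class S (positives or negatives) of n windows of length l,
and an interval ξ ∈ {0, 1, …}, two relative-frequency matrices are fitted:

* Tₛ (4 × l): `single_freq[i, k] = (cᵢₖ + α) / (n + 4α)`, the probability of
  nucleotide i ∈ {A,C,G,U} at position k;
* T_d (16 × (l−ξ−1)): `pair_freq[j, k] = (cⱼₖ + α) / (n + 16α)`, the
  probability of the ordered pair j ∈ {A,C,G,U}² at positions (k, k+ξ+1).

ξ counts the nucleotides *between* the paired positions: ξ = 0 is the
contiguous dinucleotide and the number of pairs in a window is l − ξ − 1
(50, 49, …, 44 for l = 51 and ξ = 0 … 6). Pair rows are lexicographic over
{A,C,G,U}², so 'CG' is row 7 and 'G' is nucleotide row 3 (1-based).

A query position k with pair (a, b) is scored per class by the conditional
probability of the upstream base given the downstream one,
p = F[(a,b), k] / f[b, k+ξ+1], and the emitted feature is the difference
p⁺ − p⁻ between the positive- and negative-class conditionals. Since the
pair count never exceeds the downstream-base count, p ∈ [0, 1] for any
α ≥ 0 and every feature lies in [−1, 1]. Multi-interval vectors concatenate
the per-ξ blocks in ascending ξ, ascending position — 329 features for
l = 51, ξ ∈ {0…6}. Intuitively the encoding measures, position by position,
how much more compatible the window's gapped dinucleotides are with the
methylated than with the unmethylated training population.

Degenerate cases and conventions:

* **Zero denominator.** If a class never saw base b at position k+ξ+1
  (possible only with α = 0), both numerator and denominator are 0; the
  conditional is defined as 0, the α → 0 limit under additive smoothing.
  This keeps features bounded and makes the encoding total.
* **Pseudocount.** α defaults to 0 (plain relative frequencies). Smoothing
  is available (`pseudocount=`) for very small training sets, where zero
  denominators would otherwise be common.
* **Identity.** If S⁺ and S⁻ are the same multiset, every feature is exactly
  0 — a useful sanity check, asserted in the tests as an exact (not
  approximate) equality.
* Positions are 1-based in messages and file headers, 0-based internally.

### Classifier

C-SVC with RBF kernel (scikit-learn's libsvm binding), labels +1 (m6A) /
−1 (non-m6A), decision threshold 0 with a score of exactly 0 mapped to +1.
Features enter unscaled — they are already bounded in [−1, 1]. (C, γ) come
from exhaustive grid search over exponential grids (defaults C = 2⁻⁵…2¹⁵,
γ = 2⁻¹⁵…2³, step ×4; a ×2 fine-step variant and a 4×4 reduced variant for
experiments exist), maximizing mean positive-class F1 (defined as 0 when
precision + recall = 0) over stratified inner folds (default 5). Ties break
toward smaller C, then smaller γ, so the search is deterministic given the
fold seed. The libsvm stopping tolerance defaults to 1e-3; `train()` exposes
it because exact-symmetry properties (e.g. label-swap antisymmetry of the
decision scores) hold only up to solver precision.

### Evaluation

Sn, Sp, Acc, MCC from confusion counts; MCC is set to 0 when any factor of
its denominator is 0, and Sn/Sp are reported as absent (not 0) when the
corresponding class is missing from the evaluation set. On balanced sets
Acc = (Sn+Sp)/2 exactly. AUROC uses the Mann–Whitney rank formulation with
ties counted 1/2; AUPRC is the step-wise precision–recall integral
(scikit-learn's `average_precision_score`).

k-fold CV is stratified and seeded; k = n degrades to deterministic
leave-one-out (the jackknife), where stratification is impossible. Metrics
are reported both pooled over the k confusion counts (primary — and the only
sensible choice for the jackknife, whose per-fold reports are singletons)
and as per-fold means.

**Leakage policy.** The encoder is part of the learner, so it is refitted
inside every training fold; held-out windows are encoded with profiles they
did not contribute to. The (C, γ) search is nested one level further: inside
each inner fold the profiles are refitted again before encoding. This second
level matters in practice — scoring inner-validation windows on encodings
whose profiles included them systematically favours large-C/large-γ grid
points and costs several accuracy points on fixture data. A
`refit_per_fold=False` reproduction mode fits the encoder once on all data
before splitting; published whole-dataset protocols are sometimes run this
way, but it leaks class frequencies into validation folds and is off by
default. The label-shuffle/null-model tests guard the default path: chance
accuracy there certifies that neither profiles nor hyperparameters see
held-out labels.

## Synthetic data

`SyntheticSpec`/`generate` draw labeled windows position-independently:
negatives i.i.d. from a background composition (default uniform), positives
from `strength · motif + (1 − strength) · background` at the motif positions
and background elsewhere. The default motif is a 5-column soft DRACH-like
consensus (D = A/G/U, R = A/G, A, C, H = A/C/U; uniform within each
degenerate set) centered on the window, chosen because it is the canonical
m6A sequence context. Defaults, fixed once:

* `motif_strength = 1.0` — positives always carry a consensus-compatible
  5-mer; the class signal is then as clean as the degenerate columns allow.
* `center_a = True` — the central position is forced to A in *both* classes,
  as in real benchmarks, where negatives are windows around non-methylated
  adenosines. This removes the center as a trivial discriminator.
* 300 windows per class, seed 0.

With these defaults the Bayes accuracy is finite and computable: a negative
mimics the consensus at all four informative flanking positions with
probability (3/4)(1/2)(1/4)(3/4) = 9/128 ≈ 0.070, so no classifier can
exceed ≈ 0.965 accuracy, and the ≥ 0.95 recovery check runs close to that
ceiling. What the generator deliberately does **not** emulate: positional
dependence beyond the motif, motif-carrying negatives (available via a
second motif block, off by default), sequence-composition bias,
conservation, or secondary structure. Passing the synthetic tests therefore
demonstrates correct mechanics and leakage-free evaluation, not the
accuracy to expect on real transcriptome-derived data, which is
substantially harder (high-quality published predictors sit near 77–90%
accuracy depending on species).

## Problem sizes and numerical choices

* Recovery and null-model cross-validations run at 300/class and 500/class
  respectively, 10 folds, with the reduced 4×4 grid — together about two
  minutes on one CPU; the full default grid is for real experiments.
* Profile column sums are validated to 1 within 1e-9 on load; encoder
  equivalence against a brute-force recount is asserted at 1e-12.
* TSV feature tables print shortest round-trippable float representations
  and are read back with round-trip parsing, so write→read is bit-exact.
* Model files embed a SHA-256 of their payload and of the encoder's
  canonical JSON; predicting with mismatched profiles is refused.
* The null-model accuracy band [0.45, 0.55] is a ±3σ-scale band at n = 1000;
  the signal-recovery threshold (pooled Acc ≥ 0.95) is checked at a fixed
  generator seed, as befits a stochastic end-to-end check.

## Known limitations

* Jackknife with a non-trivial grid needs enough samples per class for the
  inner stratified folds; toy examples should pass a 1×1 grid (which skips
  the search).
* `grid_search` on pre-encoded features is exposed as a library operation,
  but CV deliberately does not use it on the default path (see leakage
  policy); users composing their own pipelines from features alone should
  be aware its F1 estimates are optimistic when the encoder saw the
  validation rows.
* Input windows must be pre-extracted; there is no genome-scanning mode.
* The optional center-A validation check is off by default; datasets whose
  windows are not A-centered are accepted.
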