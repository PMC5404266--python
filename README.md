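# npps — m6A site prediction from RNA sequence windows

N6-methyladenosine (m6A) is the most common internal mRNA modification;
locating methylated adenosines matters for understanding splicing, export and
translation, but experimental mapping is slow and expensive. `npps` is a
sequence-based predictor for m6A sites in fixed-length RNA windows (the
benchmark convention: 51 nt, the candidate A flanked by 25 nt on each side).
It is aimed at computational biologists who have labeled window sets
(methylated / non-methylated) and want a trainable, evaluable classifier with
a fully reproducible pipeline.

## Method

**Features — nucleotide pair position specificity (NPPS).** From the positive
training set S⁺ fit, for each interval ξ, two positional frequency matrices:
Tₛ⁺ (4 × l) with single-nucleotide probabilities f⁺ᵢ,ₖ, and T_d⁺
(16 × (l−ξ−1)) with ordered-pair probabilities F⁺ⱼ,ₖ for the pair at
positions (k, k+ξ+1) — ξ counts the nucleotides between the two, so ξ = 0 is
the contiguous dinucleotide. Fit Tₛ⁻, T_d⁻ on S⁻ the same way. A query
window is scored per position with the conditional probability of the
upstream base given the downstream one,

    pₖ± = F±_{j,k} / f±_{i,k+ξ+1},     Pₖ = pₖ⁺ − pₖ⁻,

and the feature vector P = (P₁ … P_{l−ξ−1}) lives in [−1, 1]^(l−ξ−1). A
never-seen downstream base (zero denominator) contributes 0 for that class.
Multi-interval features concatenate the blocks for ξ ∈ {0,…,6}; at l = 51
the joined dimension is 50+49+…+44 = **329**.

**Classifier.** An RBF-kernel C-SVC (libsvm via scikit-learn) on the raw
NPPS features, with (C, γ) chosen by exhaustive grid search (C: 2⁻⁵…2¹⁵,
γ: 2⁻¹⁵…2³) maximizing the positive-class F1 over stratified inner
cross-validation folds; ties go to smaller C, then smaller γ.

**Evaluation.** Sensitivity, specificity, accuracy and Matthews correlation
from pooled confusion counts under stratified k-fold cross-validation or the
jackknife (leave-one-out), plus AUROC/AUPRC from the pooled decision scores.
Within every fold the encoder profiles are refitted on the training portion
only, and the grid search refits them again inside each inner fold, so no
information from held-out windows reaches the features or hyperparameters.

A synthetic generator (`npps.simulate`) draws labeled windows with a
configurable DRACH-like consensus (D = A/G/U, R = A/G, H = A/C/U) around the
central A, so the whole pipeline is testable without external data.

## Worked example

```python
import npps

spec = npps.SyntheticSpec(n_pos=60, n_neg=60, seed=42)   # 51-nt windows
dataset = npps.generate(spec)

profiles = npps.NPPSProfileSet.fit_dataset(dataset, intervals=range(7))
print("joined dimension:", profiles.joined_dimension)

result = npps.kfold_cv(
    dataset, k=5,
    svm_config=npps.SVMConfig(c_grid=(8.0,), gamma_grid=(2.0**-7,)),
    seed=42,
)
print(result.pooled.summary())
```

prints

```
joined dimension: 329
samples: 120  (TP=57 TN=51 FP=9 FN=3)
Sn=95.00%  Sp=85.00%  Acc=90.00%  MCC=0.8040  F1=0.9048
AUROC=0.9286  AUPRC=0.8499
```

Of the 60 methylated windows, 57 are recovered (Sn 95%); 51 of 60 background
windows are rejected (Sp 85%); pooled accuracy is the balanced mean of the
two. The single-point (C, γ) grid here skips hyperparameter search for speed;
passing `npps.SVMConfig()` runs the full grid.

The same pipeline from the shell:

```sh
npps simulate --out-dir data --n-pos 300 --n-neg 300 --seed 1
npps cv --pos data/positives.fasta --neg data/negatives.fasta \
        --k 10 --grid reduced --seed 1 --out-prefix report
npps train --pos data/positives.fasta --neg data/negatives.fasta \
           --grid reduced --seed 1 --out model.bin
npps predict --model model.bin --profiles model.bin.profiles.json \
             --fasta data/positives.fasta --out calls.tsv
```

`report.json` / `report.tsv` carry per-fold and pooled metrics, fold
assignments, the chosen (C, γ) per fold, and a config echo; every artifact
embeds the seed, so a run is reconstructible from its outputs.

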