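# Methods

## Problem and model

The package predicts the *strength* of a protein–protein interaction (PPI),
a real value in [0, 1] derived from weighted interactome edge lists by
dividing each edge weight by the maximum weight. Predictions use only
protein domain information: which domain families occur on each protein,
where, and with what sequence.

The probabilistic backbone is the domain-based interaction model: two
proteins interact iff at least one pair of their constituent domains
interacts. If each domain pair (D_m, D_n) interacts independently with
probability p(D_m, D_n), then

    Pr(P_ij = 1) = 1 − ∏_{D_m ∈ P_i, D_n ∈ P_j} (1 − p(D_m, D_n)),

a noisy-OR over domain *instance* pairs. Three association-style estimators
of p from observed pair strengths are implemented:

* **ASSOC** — for binary labels: the fraction of supporting protein pairs
  that interact.
* **ASNM** — for real-valued strengths: the mean strength over supporting
  pairs. It reduces to ASSOC exactly on 0/1 strengths.
* **APM** — the mean of the exponent-corrected strength
  1 − (1 − ρ_ij)^{1/(|P_i||P_j|)}, which inverts the noisy-OR under the
  assumption that all domain pairs of a protein pair contribute equally.

A protein pair *supports* a domain pair when the two domains occur on
opposite proteins in either orientation, counted once per protein pair.
Domain pairs with no supporting pair are absent from the score table (no
evidence), not zero.

Alongside the probabilistic baseline, two feature mappings feed supervised
kernel regression:

* **DN** (dimension 2T for a T-domain universe): multiplicities of every
  universe domain on each protein of the pair.
* **SPD-k** (dimension 2·21^k): overlapping k-mer counts over each
  protein's domain subsequences, concatenated in order of appearance, on a
  21-letter alphabet (20 standard residues plus one catch-all for B, Z, J,
  X, U, O and anything non-standard).
* **APM score** (dimension 1): the noisy-OR combination of APM domain-pair
  scores for the pair.

Regressors: ε-insensitive support vector regression (SVR) and a relevance
vector machine (RVM), both with the Laplacian kernel
K(x, y) = exp(−σ‖x − y‖₂).

## Conventions and edge cases

* Pairs are unordered; every pair is keyed and oriented by the
  lexicographic order of the two protein ids, so feature vectors are
  invariant to the order in which a pair is written. Self-pairs
  (homodimers) are accepted and flagged via `PairRecord.is_self`.
* Domain coordinates are 1-based inclusive in files (UniProt feature
  convention) and 0-based half-open internally.
* |P_i| in the APM exponent counts domain instances (multiset cardinality),
  consistent with the multiplicity-aware DN feature; a `distinct_domains`
  flag switches to distinct-id counting. Repeated instances likewise
  contribute repeated factors in the noisy-OR product.
* The noisy-OR product is accumulated as ∑ log1p(−s) and returned via
  −expm1, so factors within 1e−12 of 1 do not round the result to 1; an
  exact score of 1 short-circuits to 1.
* k-mers spanning the junction between two concatenated domain regions are
  counted: the spectrum kernel is applied to the concatenation as one
  string. Overlapping domain regions are extracted independently (shared
  residues appear once per covering region).
* Proteins without domain annotations are retained with an empty domain
  list (all-zero DN/SPD features); the coverage filter is what removes such
  pairs from probabilistic-baseline evaluation. The APM estimator refuses
  domain-free proteins in *training* pairs, where its exponent is
  undefined.

## Regressors

**SVR.** The dual QP is solved by libsvm (scikit-learn) on a precomputed
Laplacian Gram matrix with tolerance 1e−6; the model retains the support
vectors, their dual coefficients (|coef| ≤ C) and the bias. ε defaults to
0.1 and is exposed. Support vectors are counted at |dual coefficient| >
1e−8.

**RVM.** Implemented here directly. The design matrix holds a constant
bias column plus one kernel column per training point (M = N + 1). Weights
carry independent zero-mean Gaussian priors with per-weight precisions α_i;
the noise precision is β (likelihood variance 1/β — β is a precision
throughout, the standard convention). Each sweep computes the posterior
Σ = (βΦᵀΦ + diag α)⁻¹, μ = βΣΦᵀy and re-estimates

    γ_i = 1 − α_i Σ_ii,   α_i ← γ_i/μ_i²,   β ← (N − Σγ_i)/‖y − Φμ‖².

Bases with α_i > 1e12 are pruned; iteration stops when max |Δ log α| <
1e−6 (or 1000 sweeps). Initialisation: α = 1e−4, β = 100/var(y) (capped at
1e10). ΦᵀΦ and Φᵀy are computed once per fit and sliced as bases are
pruned. The log marginal likelihood is recorded every sweep and is
non-decreasing to numerical tolerance.

Two numerical choices matter in practice:

* *β burn-in.* β is held at its initial value for the first 10 sweeps.
  With all N + 1 bases active the residual can be driven to ~0, and
  re-estimating β immediately locks the iteration onto that interpolating
  fixed point (β at its cap, no sparsity). Letting the weight precisions
  adapt first restores the expected behaviour: on a 3-component test
  function the fit retains ≤ 10 relevance vectors and recovers β near the
  true noise precision.
* *Jitter.* If the posterior precision cannot be Cholesky-factorised,
  escalating diagonal jitter (from 1e−10 of the mean diagonal) is added
  with a warning; β's re-estimate is also floored/capped (numerator ≥
  1e−12, β ≤ 1e12) so noise-free targets stay finite.

Predictions from both models are raw regression outputs by default;
clipping to [0, 1] is opt-in (`clip=True`), since evaluation is on raw
RMSE.

## Evaluation protocol

Threefold outer cross-validation over pairs; fold sizes differ by at most
one; assignments are drawn from a seeded generator and stored in the
`CVPlan`, which fixes the entire run. Within each outer-training split, σ
is selected by fivefold inner CV to minimise mean validation RMSE — ties
to the smallest σ, grid values whose training fails (e.g. RVM degeneracy)
skipped with a logged reason. Grids: σ ∈ {0.01, …, 0.1} (step 0.01),
C ∈ {1, 2, 5}; the RVM on the APM-score feature uses σ ∈ {3.0, …, 9.0}
(step 0.1), matched to that feature's small distances. The RVM has no C,
so it is fitted once per fold and recorded with C = None rather than
duplicated across the C grid.

Per fold, the APM table is rebuilt from the outer-training pairs only —
the test fold never influences the table, the σ choice or the fitted model
(a sentinel test perturbs test-fold strengths and asserts the fold's model
is bit-identical). Test pairs are restricted to those whose *every* domain
pair has a training-split score (coverage filter), and all models are
scored on this same kept set so they are comparable; for DN/SPD models the
unfiltered test RMSE is additionally reported, labelled as such. Training
RMSE is computed on the full outer-training set, not averaged over inner
folds. The report stores one (pair, observed, predicted) triple per kept
test pair, so every reported RMSE can be recomputed from the dump.

## Synthetic data generator

The generator emulates the three pipeline inputs. Proteins receive 1–4 domain
instances (40–120 residues, separated by 5–30 residue linkers) drawn from
a domain universe; every universe domain is guaranteed to appear at least
once (requires n_proteins ≥ n_domains). Sequences are i.i.d. uniform over
the 20 standard residues with a 2% ambiguity-code rate, so the 21st
alphabet symbol is exercised. With probability 0.1 an instance slot
repeats a domain already on its protein, exercising multiplicity paths.
Domain draws follow a Zipf rank^−1 popularity law (exponent configurable,
0 = uniform): domain-family occurrence in real proteomes is heavy-tailed,
and this is what gives the coverage filter realistic pass rates (~20% at
the reference scale; uniform draws give ~2%).

A `ddi_density` fraction of domain pairs receives a planted interaction
probability drawn from Beta(2, 5) (right-skewed, mean ≈ 0.29, emulating
normalized interactome weights being mostly small). Weighted pairs are
sampled uniformly among unordered protein pairs with *positive* clean
strength — an interactome edge list contains only interacting pairs — and
their strengths are clamp(clean + N(0, noise_sd), 0, 1) with noise_sd =
0.05 by default; the truncated-Gaussian noise is a stand-in, since real
strengths are observational weights with no known error model. A
configurable number of absent distinct-protein pairs is then added at
strength 0; these negatives sit outside the noisy-OR model, so
`PlantedTruth.clean_strengths` covers the modelled pairs only.
`reference_shape_config()` reproduces the reference benchmark scale: 758
proteins, 327 domains, 1387 weighted + 100 zero pairs = 1487.

What the generator does *not* emulate: homologous sequence similarity
within a domain family (regions of the same family are independent random
strings, so SPD carries less cross-protein signal than on real data),
correlated domain co-occurrence, and the statistics of real interactome
weights. Passing tests therefore demonstrate correctness of the machinery
and recovery under the generative model, not real-data accuracy.

## Problem sizes used in the shipped runs

The test suite and the acceptance script run the full protocol (all grids,
nested selection) on the reference-shape dataset for SVR+DN and the APM
baseline, and on a 120-protein / 35-domain / 220-pair replicate for the
remaining model-feature combinations — the RVM grid search is cubic in the
training-set size, and the replicate keeps the complete experiment matrix
cheap while leaving every code path identical.

## Known limitations

* The RVM update is the original fixed-point sweep over all bases, not the
  faster sequential basis-addition algorithm; fits beyond ~2000 training
  points would benefit from the latter.
* The coverage filter implements the strict reading ("every domain pair
  scored"); an any-pair variant is easy to add but changes comparability
  between the baseline and the feature models.
* ASSOC is only defined for binary strengths and is provided for
  completeness and for the ASNM reduction check; the evaluation protocol
  itself never binarises.
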