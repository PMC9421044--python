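# Methods

## Scope

`ribofit` implements the computational arm of a deep-mutational-scanning
study of a self-cleaving ribozyme: estimating per-variant catalytic activity
from co-transcriptional cleavage sequencing, quantifying pairwise epistasis,
organizing variants into a genotype network, and training
sequence-to-activity regressors to predict the effect of higher-order
mutation combinations. Experimental data are not bundled; a synthetic-data
module generates ground-truth landscapes and reads so that every stage is
testable end to end against a known truth.

## Activity estimation from reads

During in vitro transcription a fraction of molecules self-cleave, losing
their 5′ upstream segment. After reverse transcription and sequencing, each
read therefore carries (upstream segment +) ribozyme sequence + RT
primer-binding site, and cleavage state is read off structurally:

- the 3′ primer-binding site is located by **exact** substring match (no
  mismatch tolerance, no alignment). Absent or multiply-matching primer
  sites reject the read with a reason code.
- the ribozyme region is the L bases immediately 5′ of the primer site;
  the read is *cleaved* iff nothing precedes it, *uncleaved* iff exactly
  the expected upstream segment precedes it.
- in **match-list** mode the ribozyme region must equal one of the expected
  variant sequences (wild-type plus all mutants up to order 2); in
  **variable-positions** mode bases are read at the declared variable
  positions, and any deviation elsewhere rejects the read. Rejections are
  tallied by reason; cleaved + uncleaved + rejected = total is asserted in
  tests.

Per genotype, activity is the fraction cleaved, c/(c+u). Rows with fewer
than `min_reads` total reads (default 1, i.e. keep everything) are marked
missing (NaN), never zero-filled. Exact matching is chosen over fuzzy
matching for determinism and because the rejection rules (no unexpected
mutations anywhere on the read) imply it. Replicate FASTQ files are pooled
by counts by default; per-file tables are available since it is genuinely
ambiguous whether pooled counts or averaged fractions are preferable —
pooling weights replicates by depth.

## Pairwise epistasis

For a double mutant AB with constituent singles A and B,

    ε = log10(W_AB · W_wt / (W_A · W_B)),

with W the fraction cleaved. ε = 0 is the multiplicative null; ε < 0 means
the combination is worse than predicted from the singles. ε is computed on
raw fractions (the W_wt factor already normalizes). Quadruples containing a
zero or missing activity are excluded and counted rather than floored: a
pseudocount would invent the magnitude of exactly the quantity being
measured (an optional floor exists for sensitivity analysis, default off).
ε is symmetric in A and B and invariant under rescaling all four activities
— both are property-tested.

## Genotype network and quintiles

Nodes are genotypes; edges join pairs at Hamming distance 1 on the full
sequence. Neighbor search is indexed (hash the sequence, probe all 3L
single-base toggles), O(n·3L) instead of O(n²); tests verify it equals the
all-pairs oracle on random tables. Activity quintiles default to five
equal-width value bins over [0, 1] (right-closed); a rank-based equal-count
option is provided and labeled, since "quintile" is ambiguous between the
two conventions for skewed activity distributions.

## Predictive models

**Random Forest.** scikit-learn's `RandomForestRegressor` with library
default hyperparameters (recorded verbatim in the bundle) on the flattened
L×4 one-hot encoding, column order A,C,G,U, position-major. Feature
importance is the impurity-based (mean decrease in impurity) estimate,
mapped back to (position, base) labels and also aggregated per position;
it is only defined for this model — hybrid features are latent and
unmapped, so requesting importances for other kinds raises.

**LSTM hybrid.** A single-layer LSTM (32 hidden units) reads the sequence
through a learned 4-dimensional nucleotide embedding initialized from the
one-hot basis, so the untrained network sees exactly the one-hot input. It
is trained against fraction cleaved with MSE loss, minibatches of 64, Adam,
for a fixed 25 epochs with no validation split or early stopping. The final
hidden state h_n of each sequence is then the feature vector for a Random
Forest regressor. The LSTM (forward pass, backpropagation through time,
Adam, inverted dropout on h_n before the linear training head) is
implemented in NumPy inside the package; its gradients are verified against
central finite differences in the test suite, and training is
bit-reproducible from one integer seed.

Numerical choices where the design was open:

- *Learning rate.* Default 1e-3 (the conventional Adam default). The epoch
  count is fixed at 25, so the number of gradient steps scales with
  training-set size; the desk-scale fixtures here (≈10³ sequences rather
  than ≈10⁴) see roughly an order of magnitude fewer steps per epoch, and
  the bundled fixtures and analysis drivers therefore pass 1e-2 explicitly
  to reach comparable optimization within the same 25 epochs. Both settings
  are recorded in the bundle.
- *Dropout.* Configured at 0.2 and applied to h_n before the training head
  (a single recurrent layer has no between-layer position to drop).
- *Predictions* are reported raw; regression output can stray slightly
  outside [0, 1] and clipping is an explicit opt-in recorded in provenance.

**Baselines.** Ordinary least squares (minimum-norm solution, which handles
the rank-deficient one-hot design where each position's four indicators sum
to one) and scikit-learn's `MLPRegressor`, both on the one-hot features.

## Evaluation harness

Genotypes are binned by mutational distance (order) from the wild-type.
Per bin, 20% is held out at random for testing, except orders 1 and 2 (and
the wild-type), which go entirely to training. Per-bin test size is
round-half-up(0.2·n) — a 518-row bin splits 414/104. The split is persisted
and reused for every model and training condition, so all models are scored
on byte-identical test sets. Training sets are cumulative (all bins up to a
maximum order, nesting verified), optionally subsampled without replacement
to fractions {60, 40, 20, 10, 1}% with five replicates at the smallest
fraction. Metrics are Pearson r, R² (reported both as r² and as the
coefficient of determination, since the two conventions diverge for biased
predictions), and MSE; all are cross-checked against textbook-formula
recomputations to 1e-12. All randomness derives from one base seed through
SHA-256 of (seed, purpose-tag), so a single integer reproduces a whole run.

## The synthetic-data generator

The generator is a labeled fixture: the real experiment implies no
generative model, and every distributional choice below is a modeling
convenience, not an inference.

Latent activity is baseline + Σ additive + Σ pairwise (+ optional three-way
terms), pushed through a link to [0, 1]:

- *Link.* Logistic by default (activities span the full range; wild-type
  ≈ 0.8, i.e. baseline = logit 0.8). An exponential link min(1, exp(x)) is
  also provided: under it an additive latent model is exactly multiplicative
  in activity, so ε ≡ 0 — the clean null used by the epistasis-recovery
  tests. Under the logistic link an additive model leaves a small nonzero ε
  from link curvature, which is why the null tests use the exponential link.
- *Additive effects.* A mixture of near-neutral N(0, 0.15) (probability
  0.35) and deleterious N(−3, 1) draws, giving single mutants spanning the
  full activity range. Recovery fixtures use milder deleterious effects
  N(−1, 0.5) so that order-3 latents stay inside the link's responsive
  range — those fixtures certify model recovery on a learnable landscape,
  not robustness to saturation.
- *Epistasis.* A sampled fraction of mutation pairs carries negative
  pairwise terms (−Exp(scale/2)), reflecting the dominance of negative
  epistasis in RNA landscapes. Compensatory base pairs are planted
  structurally: both designated singles get strong deleterious effects
  (≈ −4) and the designated double a positive pairwise term placing its
  latent at baseline − 1, which guarantees the double outperforms both
  singles under any monotone link.
- *Three-way terms* (off by default) plant higher-order structure that is
  provably invisible in single- and double-mutant data; they exist to test
  that adding order-3 training data helps higher-order prediction.
- *Library.* Doped synthesis: each position mutates independently at 3%
  (97% wild-type, 1% each alternative), alternatives uniform.
- *Reads.* Depth per genotype is negative-binomial around the mean
  (dispersion 0 = fixed depth), mirroring the orders-of-magnitude coverage
  spread between single and double mutants in real libraries; each read is
  cleaved with probability equal to the genotype's true activity; optional
  uniform substitution errors (default 0); constant quality strings; output
  as DNA.

Deliberately not emulated: paired-end structure, PCR amplification bias,
base-quality variation, replicate index structure, and real secondary
structure (the compensatory pairs are planted, not folded). Passing tests
therefore certify the pipeline's correctness and internal consistency, not
the biological fidelity of any particular landscape.

## Problem sizes

The bundled fixtures and the acceptance script run at desk scale, chosen as
the smallest sizes at which each statistical check is well-powered: 500
genotypes × depths 100/1,000/10,000 for estimator consistency; an L=20
landscape (60 singles + 1,710 doubles training, 200 triples test) for model
recovery; a 2¹² combinatorial cube for the genotype network and the
higher-order-training experiment; 20,000 molecules for the simulated
library. The full factorial harness scales to the real dataset sizes
(≈30,000 sequences) without modification.

## Known limitations

- The exact-match classifier discards reads with any sequencing error; at
  realistic error rates this loses coverage but cannot bias fraction
  cleaved unless errors correlate with cleavage state (they do not in the
  simulator).
- The LSTM is CPU-only and single-layer by design; it is not a general
  deep-learning framework.
- ε excludes zero-activity variants, so the reported ε distribution
  conditions on all four activities being measurable and positive.
- R² = r² (the default convention) can be large even for biased
  predictions; the coefficient-of-determination column should be consulted
  when absolute calibration matters.
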