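# Methods

## Model

`amylometa`'s core is a stacked binary classifier over hexapeptides. Each
component predictor `j` maps a 6-mer `x` to a real score `S_j(x)`; the
meta-model is the logistic regression

    logit P(Y=1 | x) = β₀ + Σ_j β_j S_j(x),

with `Y = 1` for amyloid-forming peptides. The model's assumptions are the
usual ones for stacking with a linear-logistic combiner: component scores
are informative but imperfect, their errors are partly independent, and the
log-odds of aggregation is approximately linear in the scores over the range
seen in training. No calibration of the component scores is assumed; the
coefficients absorb affine differences in scale (optional column
standardisation is available and recorded in the fitted model, default off,
since fitted probabilities are invariant to it and raw coefficients are
easier to relate back to the component score units).

### Fitting

Maximum likelihood via iteratively reweighted least squares (damped Newton):
each iteration solves the weighted normal equations and applies step-halving
until the log-likelihood does not decrease, so the per-iteration
log-likelihood path is non-decreasing by construction (and asserted in
tests). Convergence is declared when the relative log-likelihood change
falls below `tol = 1e-8` (standard; results are insensitive to anything
tighter than 1e-6), with a cap of 100 iterations. The intercept is always
present. Perfect collinearity is detected by rank-revealing QR on the design
and reported with the offending column names.

Complete or quasi-complete separation makes the MLE non-existent; it is
*flagged* (warning + `separation_ = True`, `converged_ = False`), not
penalised away, because the meta-model is meant for noisy component scores
where separation indicates a degenerate input rather than a modelling
choice. Detection: the iteration budget is exhausted while the linear
predictor diverges, or the fit stalls with every observation classified
correctly at saturated probability (|η| > 10 everywhere).

### Component selection

Bidirectional stepwise search under BIC = −2 log L + p ln n (p counts the
intercept): starting from the intercept-only model, every single addition
and single deletion is refitted at each step and the move with the lowest
BIC is accepted if it strictly improves the current BIC. Ties prefer the
smaller model, then the lexicographically smaller scorer name, making the
procedure deterministic. BIC was chosen over AIC because the intended
setting — a panel of predictors several of which are near-duplicates —
needs the stronger penalty to discard redundant candidates at training-set
sizes of a few hundred peptides.

### Cross-validation and thresholds

Held-out probabilities come from leave-one-out (default) or seeded k-fold
CV; row `i` is always scored by a model fitted without row `i`'s fold, and
LOO output is invariant to row order. Decision thresholds are estimated on
CV scores, not fitted scores, to avoid optimism. Four criteria are offered:
minimal distance to the ROC's (0,1) corner (default), maximal Youden J,
and largest/smallest thresholds achieving a sensitivity/specificity target.
Candidate thresholds are the distinct score values plus +∞; a score equal
to the threshold counts as positive; optimisation ties resolve toward the
larger (more specific) threshold.

## Profiles, hot spots, variants

A sequence of length L yields L−5 hexapeptide windows; window `w` (1-based
start) is scored through the meta-model and its probability assigned to
residue `w+2`, so residues 1–2 and L−2..L carry no assigned value (reported
as NA, never as 0). A hot spot is a maximal run of consecutive windows with
probability ≥ threshold; its residue span is the union of the run's windows
(`run length + 5` residues). Runs are disjoint at the window level; the
residue spans of runs separated by fewer than six below-threshold windows
can overlap, so residue-level summaries use the union of hot residues.

- TA (total area) = Σ window probabilities over the whole sequence;
  threshold-independent.
- NHSA = Σ over a hot spot's windows of (probability − threshold), divided
  by the hot spot's residue count. The per-residue denominator makes hot
  spots of different lengths comparable; the window union (rather than only
  the third-residue positions) was chosen as the "predicted segment" because
  it is the set of residues the run's evidence actually covers.

Variant scoring compares a mutant profile to its wild type over a stated
region. Windows are attributed to the region by their start residue (an
unambiguous rule; any overlap rule shifts boundary windows by at most 5
positions). Two deltas are reported, since either can be the quantity of
interest: ΔTA (region-restricted total area) and ΔNHSA (sum over called hot
spots of their region-restricted area contributions). A single substitution
perturbs exactly the six windows containing it, so profile changes are
strictly local for missense variants; length-changing variants are labelled
frameshifts and the region is clipped to each sequence's own window range.
Residue policy for nonstandard letters (B, J, O, U, X, Z) is configurable:
reject (default), map ambiguity codes to a standard stand-in, or keep the
letter and mark every window containing it unscoreable.

## Evaluation toolbox

- ROC points via grouped distinct thresholds (ties merged); AUC by
  trapezoid, identical (to 1e-12, tested) to the tie-aware Mann–Whitney
  concordance estimator.
- Partial AUC over an FPR band is reported unnormalised, so a perfect
  classifier scores the band width. At a band edge that coincides with a
  vertical ROC segment, the right-going area starts at the segment's top and
  the left-ending area stops at its bottom; this makes the band decomposition
  exactly additive and the full band equal to the AUC.
- DeLong's test for paired AUCs via placement values (midranks), two-sided
  normal p-value; a zero-variance difference is p = 1 when the AUCs agree
  and an error otherwise.
- Bootstrap intervals are percentile, stratified within class (every
  replicate keeps both classes and the original class sizes), default 2000
  replicates, reproducible from a seed. BCa is out of scope.
- Confusion metrics: sens, spec, ACC, MCC, Q = (sens+spec)/2, F1. A zero
  denominator yields NaN plus the metric's name in an `undefined` set,
  rather than a silent 0 — except that specificity with TN = 0 and FP > 0 is
  a legitimate 0.
- Region predictions are scored per residue: each residue is classified by
  membership in the union of predicted vs. true regions, so the four counts
  sum to the sequence length and are invariant to how regions are split.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of the data this kind of
meta-predictor is built on, with all randomness drawn from a single seeded
generator per call (bit-reproducible from the config):

- **Scorer suite** — three residue scales and one 6×20 matrix whose
  parameters are standard-normal draws around a shared latent propensity
  (weights 0.75 latent / 0.66 idiosyncratic, giving inter-scorer
  correlations near 0.55: correlated but complementary, like a real predictor
  panel). These are synthetic stand-ins, not any published predictor's
  parameters.
- **Labelled hexapeptides** — default 116 positive / 162 negative (278
  total), the size of the experimentally characterised hexapeptide
  collections such models are trained on. Positives draw residues with
  weight ∝ exp(separation · propensity/2), negatives uniformly. The default
  separation 2.0 puts individual scorer AUCs in the 0.85–0.95 range —
  informative but imperfect components. Separation 0 makes the classes
  exactly exchangeable.
- **Logistic features** — equicorrelated Gaussian columns with labels from a
  known coefficient vector (default (−1, 0.8, −0.5, 0.6, 0.9)), for
  parameter-recovery and optimism experiments.
- **Selection benchmark** — 4 independent causal columns plus 7 noisy
  copies at correlation 0.9. The copy correlation matters: near 1 an
  original and its copy become statistically exchangeable and *no* selector
  can reliably prefer the original, so 0.9 was chosen as "strongly redundant
  yet identifiable"; at n = 3000 stepwise-BIC recovers exactly the causal
  set in ≈98% of replicates.
- **Annotated proteins** — background depleted in high-propensity residues
  (weight ∝ exp(−separation · propensity/2)) with planted 6–12-residue
  segments drawn at full enrichment exp(separation · propensity). Planted
  segments emulate *validated* hot spots — unambiguous aggregators — not
  borderline positives; at typical-positive enrichment, short planted
  segments are sometimes genuinely invisible to any trained model, which
  would measure the generator, not the pipeline. A scramble mode permutes a
  sequence uniformly (anagram), mirroring scrambled-peptide experiments.

What the synthetic data does **not** emulate: real amyloid sequence
statistics (β-sheet periodicity, gatekeeper residues, position-specific
motifs), biases of real residue composition, label noise from fibril
polymorphism, or the behaviour of the actual published component predictors.
Passing tests therefore demonstrate the statistical machinery — estimation,
selection, calibration, profile mechanics — under a controlled truth; they
say nothing about prediction quality on real proteomes, which depends
entirely on the component scorers plugged in.

## Problem sizes and numerical choices

Simulation studies use: parameter recovery n = 5000 × 50 replicates;
selection consistency n = 3000 × 100 replicates; null-calibration of the
DeLong test 1000 simulations at n = 100; bootstrap coverage 200 replications
at n = 200 with 500 resamples each; planted-segment recovery 20 proteins of
250 residues. These sizes put Monte-Carlo error well below the effect sizes
being checked while keeping a full run in tens of seconds on one CPU.

Degenerate inputs: sequences shorter than six residues have no windows and
are rejected for profiling; single-class label vectors are rejected
everywhere; zero-variance feature columns are rejected by the standardiser
with the column named; hexapeptides absent from an external score table
raise (or mark the window unscoreable during profiling). The precomputed
hexapeptide score store is an optional memoising wrapper (in-memory, with
TSV persistence) rather than a mandatory 20⁶ enumeration, which is a server
optimisation, not part of the method.

## Known limitations

- The four published component algorithms are not re-derived; they enter as
  pluggable scorer configurations (scale, matrix, or precomputed table), so
  absolute agreement with any published meta-predictor's scores is out of
  scope and coefficients are always re-estimated from a supplied dataset.
- Stepwise selection under BIC is greedy; with heavily correlated candidates
  it can substitute a near-duplicate for a causal score when the two are
  nearly exchangeable in likelihood.
- Percentile bootstrap intervals can slightly undercover for AUCs very close
  to 1; DeLong variance is asymptotic and needs a handful of observations
  per class.
- No regularised or Bayesian fitting; separation is flagged, not resolved.
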