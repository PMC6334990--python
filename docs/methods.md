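# Methods

`surpeeg` rebuilds, on synthetic ground truth, an analysis pipeline that asks
whether hierarchical (grammar-based) expectations about a word's part of
speech explain EEG amplitudes beyond purely sequential expectations. Every
stage — surprisal computation, single-trial regression ERP (rERP) analysis,
spatio-temporal cluster permutation testing, and hierarchical Bayesian model
comparison by WAIC — is implemented against data whose generating parameters
are known, so each inferential step can be validated by recovery rather than
by reference data.

## Surprisal and the three context models

For a word `w` in context `C`, surprisal is `-log2 p(w | C)` in bits. All
models operate over a closed 36-tag POS vocabulary, and differ only in `C`:

* **Null** — no context; every tag has probability 1/36, surprisal
  `log2(36) = 5.17` bits.
* **Ngram** — the two preceding tags, with Witten-Bell smoothing:
  `P(w|h) = (c(h,w) + T(h) P_lower(w|h')) / (c(h) + T(h))`, where `T(h)`
  counts distinct continuation types. The recursion bottoms out at a uniform
  1/V floor, so every tag has finite surprisal for any training corpus.
  Sentences are padded with two start symbols; no end-of-sentence event is
  modeled, so per-sentence surprisal sums telescope to `-log2` of the word
  sequence's probability.
* **SRN** — an Elman network (one-hot input, sigmoid hidden layer, softmax
  output) whose hidden state summarizes the full preceding tag sequence,
  trained by full backpropagation through time with early stopping on
  development-set perplexity (patience 3, deterministic given the seed).
  The hidden state resets at sentence boundaries. The reference architecture
  for real data is V–500–V; the package default is H = 32, ample for the
  small synthetic corpora used here, and H remains a config key.
* **CFG** — the probability of `w` given the set of parse structures
  compatible with the prefix, computed exactly as the ratio of successive
  *prefix probabilities* under a probabilistic context-free grammar.

### Prefix probabilities

Prefix probabilities come from a probabilistic Earley chart maintaining
forward (prefix) and inner probabilities per state. Left recursion and
unit-production chains are folded into two closure matrices computed by
geometric-series matrix inversion — the left-corner closure
`R_L = (I - P_L)^-1` used during prediction and the unit closure
`R_U = (I - P_U)^-1` used during completion — so unit-production rules never
enter the chart and left-recursive grammars terminate. Completions are
aggregated per (lhs, origin) and processed in decreasing-origin order, which
visits each completed constituent exactly once; this keeps heavily ambiguous
55-word sentences in the low milliseconds. The chart is validated against a
brute-force derivation enumerator on toy grammars (agreement to 1e-9) and
against geometric-series closed forms on left-recursive grammars.
Empty (epsilon) right-hand sides are not supported; the grammar loader
rejects them, along with per-lhs probability sums off by more than 1e-9.
Closure matrices with condition number above 1e12 raise an error (improper
grammar).

## The synthetic story grammar

The bundled 36-terminal grammar (`data/story36.grammar`) emulates the
statistical shape of a parsed naturalistic story: Penn-Treebank-style POS
terminals, a content/function split of roughly half and half, recursive
NP/PP/VP attachment, several clause-embedding rule types, and heavy-tailed
sentence lengths (expected yield ≈ 27 words; after rejection sampling at
`max_len = 60`, sampled corpora average ≈ 17–23 words per sentence with SD
≈ 13–15, inside the configured emulation band of 15–35).

Crucially, clauses carry a singular/plural register: the head noun (NN vs
NNS) selects the agreeing finite verb (VBZ vs VBP) across arbitrarily long
intervening modifiers, including relative clauses whose own verbs agree with
their local head. This places genuinely long-distance predictive information
in the grammar's hierarchical state — the kind of dependency a trigram
window cannot see and a recency-biased sequence model recovers only
partially — so the hierarchical and sequential surprisal series diverge for
principled reasons, not merely by sampling noise.

Sentence-length control uses rejection sampling rather than grammar
renormalization, so the probability bookkeeping used by the enumeration
tests stays exact.

### What the synthetic world cannot emulate

Because the corpus is generated *by* the scoring grammar, CFG surprisal is
the Bayes-true conditional of the synthetic world. Every sufficiently
powerful context model therefore correlates with it — including the
disagreement between two different estimators of local statistics (the
Witten-Bell trigram and the SRN smooth the same window differently, and
that difference correlates with the truth). In the target analyses on real
speech, the grammar is itself an imperfect model of English and is only
weakly correlated with the sequential predictors; that conditional
independence cannot be reproduced here. Concretely, the step-wise
comparison "does the SRN improve fit beyond the Ngram?" is genuinely
positive in this synthetic world whenever a grammar-derived effect is
injected, with an effect size a fixed fraction (~1/2) of the
grammar-unique one, at any sample size or noise level. Passing recovery
tests therefore show that the pipeline attributes injected effects to the
generating term and controls false positives — they do not show that every
qualitative significance pattern observed on real data re-emerges.

## EEG synthesis

Epochs span -0.3 to 1.0 s around each word onset (sample count
`round(1.3 fs) + 1`; reference rate 500 Hz, tests and the demo use 100 Hz).
The montage is a quasi-uniform sunflower layout on the unit disk with
union-of-k-nearest-neighbor adjacency (reference 61 electrodes; tests use
16 for speed). Amplitude is a sum of rank-one effects —
`x(word) x spatial(electrode) x Gaussian kernel(time) x subject gain` —
plus AR(1)-smoothed Gaussian noise:

* noise: marginal SD 1.0 (arbitrary units), lag-1 coefficient 0.3. Real EEG
  noise is neither stationary nor AR(1); the choice supplies the cluster
  test with a temporal-correlation challenge while keeping recovery exact.
* subject gain ~ Normal(1, 0.2), creating the between-subject variance the
  hierarchical model estimates.
* injected effect SNR is defined at the spatio-temporal peak: the kernel
  amplitude is set so that `amplitude x sd(predictor)` equals `SNR x noise
  SD` at the peak electrode and sample.
* simulated covariates: log word frequency is Gaussian per word class
  (function words more frequent: mean 12 vs 8), shifted copies provide
  previous/next-word frequency (the story is treated as continuous), and
  sound power at onset is standard normal.

Epochs are low-pass filtered at 40 Hz with a 4th-order Butterworth applied
forward-backward (zero phase; the single-pass cutoff gain 1/sqrt(2) becomes
1/2). No baseline correction is applied anywhere. Trial rejection draws
independent per-subject masks with the configured expected fraction
(default 0.135).

## rERP regression and the cluster test

Per subject, epoch amplitudes are regressed on mean-centered predictors by
OLS independently at every (electrode, sample); the design is rank-checked
and offending collinear columns are named in the error. A matched null fit
permutes the design-matrix rows once (seeded per subject), preserving
everything except the predictor–epoch pairing.

Group inference compares target against null coefficients with a
dependent-samples t-test at every point, clusters suprathreshold points
(two-sided p < 0.05) over spatio-temporal adjacency — same electrode at
consecutive samples or neighboring electrodes at the same sample — with
positive and negative t clustered separately, and sums t into cluster
masses. The permutation null swaps each subject's (target, null) pair with
probability 1/2 (equivalently sign-flips the paired differences),
recording the maximum absolute mass; corrected p uses the (+1)/(+1)
convention, so the smallest reportable p is `1/(n_perm + 1)`. One null
permutation per subject is drawn (matched pairs for the group test). The
test window is 0–1 s. On 200 pure-noise datasets the measured family-wise
false-positive rate at corrected alpha 0.05 is ≈ 0.045.

## ROIs and hierarchical comparison

Each significant whole-head effect defines an ROI: the cluster's time span
and the (at most) five electrodes with the largest summed |t| over that
span; ROIs whose chosen electrodes straddle the montage midline (x = 0) are
split into left and right halves. Per-trial amplitudes are averaged over
the ROI, predictors are centered and scaled into ±10, and word class is
sum-coded (content +1, function -1) and centered.

The hierarchical model is Gaussian:
`y = X beta + W b_subject + eps`, with by-subject random intercepts and
slopes for sentence order and word class, independent across effects (no
random-effect correlations — a deliberate simplification; the package's
comparisons concern population terms). Priors are weakly informative on the
scaled predictors: `beta ~ Normal(0, 10^2)`, and half-Cauchy(0, 5) on the
residual SD and each random-effect SD via their inverse-gamma scale-mixture
representations.

### Sampler

All full conditionals are conjugate, so the sampler is a blocked Gibbs:

1. one joint Gaussian draw of *all* coefficients (population and random) —
   `U = [X, Z]` has fixed `U'U`, so each sweep solves a single
   (p + Jq)-dimensional system;
2. conjugate inverse-gamma updates for the variances;
3. an ancillarity–sufficiency interweaving step that re-draws the group
   scales in the non-centered parameterization (`b = tau * eta`), where
   `(beta, tau)` is again a Gaussian regression given `eta` and the signed
   Cauchy prior on tau is handled by its normal/inverse-gamma mixture.

Step 3 removes the funnel that makes near-zero random-effect variances mix
slowly in a purely centered sweep; with it, split-R-hat stays ≈ 1.01 across
all model term sets used by the comparison schedule. Four chains of 1000
warm-up and 1000 kept iterations are the reference setting (the demo
pipeline uses 300/300); a fit is rejected with an error if any monitored
term has R-hat ≥ 1.1 (a quantity pinned to a constant — e.g. a variance at
its degenerate floor — counts as converged). Residual lag-1 autocorrelation
is reported per fit. The residual variance is floored at
`1e-12 x var(y)` so exactly-noiseless data remain numerically valid. The
sampler is validated against the analytic conjugate posterior on a
no-group-effect reduction and by parameter recovery at 20 subjects x 200
trials.

### WAIC and the step-wise schedule

`WAIC = -2 (lppd - p_waic)` with `lppd = sum_i log mean_s p(y_i|theta_s)`
and `p_waic = sum_i var_s log p(y_i|theta_s)` (sample variance over draws;
a reference implementation that uses the population variance differs by a
factor (S-1)/S in `p_waic`). The standard error of a WAIC difference comes
from the paired pointwise contributions. Four questions are asked per ROI —
CFG beyond {Ngram, SRN}; Ngram beyond CFG; SRN beyond CFG; SRN beyond
Ngram — each comparing a baseline (controls + word class + competing
surprisal terms + their word-class interactions) against that baseline plus
the tested main effect, and plus the main effect and its word-class
interaction. A difference is flagged when it exceeds twice its standard
error, with positive values favoring the larger model. Fits are cached per
(ROI, term set); each fit's sampler seed derives deterministically from the
master seed, ROI id, and term set, so the ledger is reproducible regardless
of schedule order.

## Pipeline, sizes, and determinism

`run_pipeline` executes corpus → models → surprisal → epochs → rERP →
cluster tests (3 models x 2 word classes) → ROIs → step-wise ledger from
one config; the master seed expands through a seed sequence into per-stage
seeds, and identical configs yield byte-identical summary JSON. Every JSON
artifact carries the config hash. The demo configuration uses 84 sentences
(≈ 1400–1700 words), 8 subjects, 16 electrodes at 100 Hz, 500
permutations, and 300/300 sampler iterations, chosen so a complete run
takes a few minutes on one CPU; the reference settings (61 electrodes,
500 Hz, 10000 permutations, 1000/1000 iterations) are config values away.
Subjects are screened by the exact binomial questionnaire rule (8
four-choice questions; at least 5 correct to exceed chance at alpha 0.05,
computed from the exact tail, not a normal approximation); a config flag
re-includes flagged subjects for sensitivity re-runs.

## Known limitations

* The synthetic world's true conditional *is* the grammar; see the caveat
  above on sequential-vs-sequential comparisons.
* Random effects are independent (no correlation matrix, unlike fully
  general mixed-model software); priors are fixed rather than
  version-dependent defaults.
* The n-gram model is not exported in ARPA back-off format; the
  interpolated Witten-Bell model is persisted as its count tables instead
  (an exact representation, whereas a back-off conversion is lossy).
* No overlap-corrected (continuous-time) rERP estimation; epochs are
  treated as independent trials, as in the target analysis.
* Lexical surprisal, audio preprocessing, artifact correction, and scalp
  interpolation are out of scope; synthetic data are generated clean.
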