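# surpeeg

Hierarchical versus sequential part-of-speech surprisal as predictors of
EEG epoch amplitudes — a fully synthetic, fully tested reimplementation of
a naturalistic-listening analysis pipeline.

## The problem

When people listen to ordinary connected speech, their brains form
expectations about upcoming words. Do those expectations reflect the
*hierarchical* structure of language (phrases inside phrases), or only the
*linear sequence* of recent words? One influential way to ask this with EEG
is to quantify each word's unexpectedness under competing language models as
**surprisal**,

```
surprisal(w) = -log2 p(w | C)        [bits]
```

where the models differ only in the context `C` used to predict the word's
part of speech (POS) over a closed 36-tag vocabulary:

| model | context `C` |
|---|---|
| Null  | none — uniform over 36 tags (5.17 bits everywhere) |
| Ngram | the two preceding tags (Witten-Bell smoothed trigram) |
| SRN   | a recurrent summary of the whole preceding sequence (Elman network) |
| CFG   | the parse structures compatible with the prefix (PCFG prefix probabilities via a probabilistic Earley chart) |

These per-word surprisals then enter a regression-ERP (rERP) analysis:
single-trial linear regression of epoch amplitudes at every
(electrode, time point), per subject, against matched row-permuted "null"
fits; a group-level spatio-temporal **cluster permutation test** controls
family-wise error; and significant effects define ROIs in which
**hierarchical Bayesian models** are compared step-wise by **WAIC** to ask
whether grammar-based surprisal improves fit *beyond* the sequential models
(and vice versa), including interactions with the content/function word
split.

No recorded EEG ships with this package. Instead, a synthetic-data layer —
a 36-tag story grammar with long-distance agreement, a corpus sampler, and
an epoch simulator with injected spatio-temporal effects and AR(1) noise —
provides ground truth against which every inferential stage is validated:
the cluster test's false-positive rate, recovery of injected effects, and
correct attribution of an effect to its generating term in the WAIC ledger.

## Worked example

Sample a story-shaped corpus, score it under all four models, and print the
linguistic-accuracy table:

```
$ surpeeg simulate-corpus --n-sentences 84 --seed 1 --out story.txt
wrote 84 sentences / 1453 words (mean length 17.3, sd 14.0) to story.txt

$ surpeeg surprise --corpus story.txt --models Ngram,SRN,CFG,Null --seed 1 --out surprisal.tsv
$ surpeeg report --surprisal surprisal.tsv --vocab-size 36
model    mean surprisal  perplexity  bits in context
Ngram              2.09        4.27             3.08
SRN                2.97        7.84             2.20
CFG                2.59        6.00             2.58
Null               5.17       36.00             0.00
```

Reading the table: with no context every tag costs `log2(36) = 5.17` bits
and perplexity equals the vocabulary size, 36. Each trained model reduces
the average cost of encoding the next tag; "bits in context" is how much
information the context carries (`5.17 - mean surprisal`). The trigram
predicts the text best here — as on real stimuli, a better text model is
not necessarily a better brain model, which is exactly what the EEG stage
tests.

The exact binomial comprehension-screening rule used to include simulated
participants:

```
$ surpeeg behavioral-threshold --n-questions 8 --n-choices 4 --alpha 0.05
minimum correct answers to exceed chance at alpha=0.05: 5 of 8
```

The full experiment — corpus, models, simulated multi-subject EEG with an
injected content-word CFG-surprisal effect over anterior electrodes
(200–500 ms), rERP fits, six cluster tests (3 models x 2 word classes),
ROI definition, and the step-wise WAIC ledger — runs from one command:

```
$ surpeeg run-all --seed 1 --out runs/demo
pipeline complete: 3 significant clusters; outputs in runs/demo
```

`runs/demo/summary.json` then contains the accuracy table, per-effect
cluster tables (mass, corrected p, electrodes, time window), the six ROIs,
and the ledger of WAIC differences ± standard errors per ROI and
hypothesis. Each stage can also be run separately (`train-ngram`,
`train-srn`, `simulate-eeg`, `rerp`, `cluster-test`, `compare`); see
`surpeeg --help`.

See `docs/methods.md` for the model definitions, the synthetic-data
assumptions (and what passing tests do and do not show about real data),
sampler design, and numerical choices.

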