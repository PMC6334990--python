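"""Per-word surprisal series and corpus-level accuracy metrics.

Surprisal of a word given a context is -log2 p(w | C), in bits.  The three
context models differ only in C: the trigram uses the two preceding tags, the
SRN a recurrent summary of the full preceding sequence, and the CFG the set
of parse structures compatible with the preceding tags.  A "Null" model with
no context assigns every tag the uniform probability 1/V, so its surprisal is
log2(V) everywhere.

Model accuracy over a corpus is summarized by mean surprisal, perplexity
(2 ** mean surprisal), and the bits of information the context carries
(log2(V) minus mean surprisal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .earley import EarleyParser
from .grammar import PCFG, POSCorpus
from .ngram import WittenBellTrigram
from .srn import SRNModel

__all__ = [
    "SurprisalSeries",
    "AccuracyReport",
    "ngram_surprisal",
    "srn_surprisal",
    "cfg_surprisal",
    "null_surprisal",
    "accuracy_report",
    "compare_mean_surprisal",
    "surprisal_table",
]


@dataclass(frozen=True)
class SurprisalSeries:
    """Per-word surprisal values (bits) from one model, in corpus word order."""

    model_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("surprisal values must be a 1-D array")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("surprisal values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)


def _per_sentence(corpus: POSCorpus, fn) -> np.ndarray:
    return np.concatenate([fn(tuple(s)) for s in corpus.sentences])


def ngram_surprisal(model: WittenBellTrigram, corpus: POSCorpus) -> SurprisalSeries:
    """Trigram surprisal; sentence-initial words use the start padding."""
    return SurprisalSeries("Ngram", _per_sentence(corpus, model.sequence_surprisals))


def srn_surprisal(model: SRNModel, corpus: POSCorpus) -> SurprisalSeries:
    """SRN surprisal; hidden state is reset at each sentence start."""
    return SurprisalSeries("SRN", _per_sentence(corpus, model.sequence_surprisals))


def cfg_surprisal(grammar: PCFG, corpus: POSCorpus) -> SurprisalSeries:
    """CFG surprisal from successive prefix-probability ratios."""
    parser = EarleyParser(grammar)
    return SurprisalSeries("CFG", _per_sentence(corpus, parser.sentence_surprisals))


def null_surprisal(corpus: POSCorpus, V: int | None = None) -> SurprisalSeries:
    """Uniform no-context model: log2(V) bits for every word."""
    V = V if V is not None else len(corpus.tagset)
    return SurprisalSeries("Null", np.full(corpus.n_words, math.log2(V)))


@dataclass(frozen=True)
class AccuracyReport:
    """Corpus-level linguistic accuracy of one surprisal model."""

    model_name: str
    mean_surprisal: float
    perplexity: float
    bits_in_context: float
    n_words: int


def accuracy_report(series: SurprisalSeries, V: int) -> AccuracyReport:
    """Mean surprisal (bits), perplexity = 2**mean, and context information.

    Perplexity is exponentiated from the unrounded mean, so a table rounding
    the mean to two decimals will not exactly reproduce ``2 ** mean``.
    """
    if len(series) == 0:
        raise ValueError("empty surprisal series")
    mean = float(series.values.mean())
    return AccuracyReport(
        model_name=series.model_name,
        mean_surprisal=mean,
        perplexity=2.0**mean,
        bits_in_context=math.log2(V) - mean,
        n_words=len(series),
    )


def compare_mean_surprisal(
    a: SurprisalSeries, b: SurprisalSeries
) -> tuple[float, int, float]:
    """Paired dependent-samples t-test over per-word surprisal differences.

    Returns (t, df, p) with df = n - 1 and a two-sided p.  When the
    differences have zero variance the statistic is undefined: t is reported
    as 0 if the mean difference is exactly 0, else NaN.
    """
    if len(a) != len(b):
        raise ValueError("series must be aligned to the same words")
    d = a.values - b.values
    n = len(d)
    df = n - 1
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        if float(d.mean()) == 0.0:
            return 0.0, df, 1.0
        return math.nan, df, math.nan
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def surprisal_table(
    corpus: POSCorpus, series: list[SurprisalSeries]
) -> pd.DataFrame:
    """Long-format table: sentence/word indices, tag, word class, surprisals."""
    rows = []
    for si, sent in enumerate(corpus.sentences):
        for wi, tag in enumerate(sent):
            rows.append(
                {
                    "sentence_index": si,
                    "word_index": wi,
                    "tag": tag,
                    "word_class": corpus.word_class_map.get(tag, ""),
                }
            )
    df = pd.DataFrame(rows)
    for s in series:
        if len(s) != len(df):
            raise ValueError(f"series {s.model_name!r} not aligned to corpus")
        df[f"surprisal_{s.model_name}"] = s.values
    return df
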