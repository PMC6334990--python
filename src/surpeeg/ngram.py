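"""Witten-Bell smoothed trigram model over POS tags.

The sequential n-gram context model: each word's probability is conditioned
on the two preceding tags.  Smoothing interpolates each order with the next
lower one, reserving mass for unseen continuations in proportion to the
number of distinct types observed after the history:

    P(w | h) = ( c(h, w) + T(h) * P_lower(w | h') ) / ( c(h) + T(h) )

where ``T(h)`` counts distinct continuation types of ``h`` and ``h'`` drops
the oldest tag.  The recursion bottoms out at a uniform 1/V floor over the
tagset, so every tag has finite surprisal under any training corpus.  Unseen
histories (c(h) = T(h) = 0) defer fully to the lower order.

Each sentence is padded with two start symbols; no end-of-sentence event is
modeled (the analysis only ever needs per-word probabilities), so the
per-sentence sum of surprisals telescopes to -log2 of the probability the
model assigns to the word sequence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .grammar import POSCorpus

__all__ = ["WittenBellTrigram", "train_ngram", "BOS"]

#: start-of-sentence padding symbol (never predicted, never in the vocabulary)
BOS = "<s>"


@dataclass
class WittenBellTrigram:
    """Counts and smoothed probabilities for a trigram POS model."""

    vocabulary: tuple[str, ...]
    counts: dict[tuple[str, ...], Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._vocab_set = frozenset(self.vocabulary)

    # -- training ----------------------------------------------------------

    @classmethod
    def fit(cls, corpus: POSCorpus) -> "WittenBellTrigram":
        model = cls(vocabulary=tuple(sorted(corpus.tagset)))
        counts: dict[tuple[str, ...], Counter] = defaultdict(Counter)
        for sent in corpus.sentences:
            padded = (BOS, BOS) + tuple(sent)
            for i in range(2, len(padded)):
                w = padded[i]
                counts[()][w] += 1
                counts[(padded[i - 1],)][w] += 1
                counts[(padded[i - 2], padded[i - 1])][w] += 1
        model.counts = dict(counts)
        return model

    # -- probabilities -----------------------------------------------------

    def prob(self, w: str, history: tuple[str, ...]) -> float:
        """Smoothed P(w | history); history is up to 2 preceding tags."""
        history = tuple(history)[-2:]
        if len(history) == 0:
            return self._interp(w, ())
        return self._interp(w, history)

    def _interp(self, w: str, h: tuple[str, ...]) -> float:
        lower = 1.0 / len(self.vocabulary) if not h else self._interp(w, h[1:])
        table = self.counts.get(h)
        if not table:
            return lower  # unseen history: defer fully to the next order down
        c_hw = table.get(w, 0)
        c_h = sum(table.values())
        t_h = len(table)
        return (c_hw + t_h * lower) / (c_h + t_h)

    def sequence_probs(self, sent: tuple[str, ...]) -> np.ndarray:
        padded = (BOS, BOS) + tuple(sent)
        return np.array(
            [
                self.prob(padded[i], (padded[i - 2], padded[i - 1]))
                for i in range(2, len(padded))
            ]
        )

    def sequence_surprisals(self, sent: tuple[str, ...]) -> np.ndarray:
        """Per-word surprisal in bits, sentence-initial words use BOS padding."""
        return -np.log2(self.sequence_probs(sent))


def save_ngram(model: WittenBellTrigram, path) -> None:
    """Persist counts as JSON (histories joined with spaces)."""
    import json
    from pathlib import Path

    payload = {
        "vocabulary": list(model.vocabulary),
        "counts": {" ".join(h): dict(t) for h, t in model.counts.items()},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_ngram(path) -> WittenBellTrigram:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    model = WittenBellTrigram(vocabulary=tuple(payload["vocabulary"]))
    model.counts = {
        tuple(h.split(" ")) if h else (): Counter(t)
        for h, t in payload["counts"].items()
    }
    return model


def train_ngram(corpus: POSCorpus) -> WittenBellTrigram:
    """Train a Witten-Bell smoothed trigram on a POS corpus."""
    if not corpus.sentences:
        raise ValueError("corpus is empty")
    return WittenBellTrigram.fit(corpus)
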