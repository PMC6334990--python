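"""Shared fixtures: toy grammars, sampled corpora, and a brute-force
derivation enumerator used as the independent oracle for prefix
probabilities."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from surpeeg.fixtures import story_grammar, story_word_classes
from surpeeg.grammar import PCFG, parse_grammar, sample_corpus

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


def enumerate_sentences(grammar: PCFG, max_len: int = 8) -> dict[tuple, float]:
    """All complete sentences of yield <= max_len with their probabilities.

    Independent of the Earley implementation: plain recursive leftmost
    expansion with probability bookkeeping, pruned at max_len.
    """
    out: dict[tuple, float] = {}
    rules_by_lhs: dict[str, list] = {}
    for r in grammar.rules:
        rules_by_lhs.setdefault(r.lhs, []).append(r)

    def rec(stack: list[str], emitted: list[str], prob: float) -> None:
        if prob < 1e-18:
            return
        if len(emitted) > max_len:
            return
        if not stack:
            key = tuple(emitted)
            out[key] = out.get(key, 0.0) + prob
            return
        sym, rest = stack[0], stack[1:]
        if sym in grammar.terminals:
            rec(rest, emitted + [sym], prob)
        else:
            for r in rules_by_lhs[sym]:
                rec(list(r.rhs) + rest, emitted, prob * r.prob)

    rec([grammar.start], [], 1.0)
    return out


def brute_prefix_probability(sentences: dict[tuple, float], prefix) -> float:
    prefix = tuple(prefix)
    return sum(p for s, p in sentences.items() if s[: len(prefix)] == prefix)


@pytest.fixture(scope="session")
def fixture_grammar() -> PCFG:
    return story_grammar()


@pytest.fixture(scope="session")
def word_classes() -> dict[str, str]:
    return story_word_classes()


@pytest.fixture(scope="session")
def fixture_corpus(fixture_grammar, word_classes):
    """84-sentence corpus sampled from the bundled grammar, stimulus scale."""
    return sample_corpus(
        fixture_grammar, 84, seed=1, max_len=60, word_class_map=word_classes
    )


@pytest.fixture(scope="session")
def small_corpus(fixture_grammar, word_classes):
    """Small corpus for fast EEG-side tests."""
    return sample_corpus(
        fixture_grammar, 25, seed=7, max_len=60, word_class_map=word_classes
    )


TOY_GRAMMARS = {
    "two-rule": "S -> a 0.7\nS -> a a 0.3",
    "deterministic": "S -> A A 1.0\nA -> a 1.0",
    "left-recursive": "S -> S a 0.4\nS -> a 0.6",
    "unit-chain": "S -> A 0.5\nS -> S b 0.5\nA -> B 0.6\nA -> a a 0.4\nB -> a 1.0",
    "branching": (
        "S -> NP VP 1.0\nNP -> d n 0.5\nNP -> n 0.5\n"
        "VP -> v NP 0.6\nVP -> v 0.4"
    ),
    "center-embed": "S -> a S b 0.3\nS -> c 0.7",
}


@pytest.fixture(params=sorted(TOY_GRAMMARS))
def toy_grammar(request) -> PCFG:
    return parse_grammar(TOY_GRAMMARS[request.param])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
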