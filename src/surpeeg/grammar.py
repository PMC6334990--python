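"""Probabilistic context-free grammars over part-of-speech tags.

A PCFG here is the hierarchical context model: weighted rewrite rules over
nonterminals whose terminal symbols are POS tags (the grammar is
un-lexicalized; words themselves never appear).  The module also provides
top-down sampling of POS-tagged corpora from a grammar, so that every
downstream stage can be exercised on synthetic text whose statistical shape
(sentence count, length distribution, content/function split) emulates a
naturalistic story stimulus.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Rule",
    "PCFG",
    "POSCorpus",
    "CorpusStats",
    "GrammarError",
    "load_grammar",
    "parse_grammar",
    "sample_corpus",
    "corpus_stats",
    "load_word_class_map",
]

#: probability tolerance for per-lhs normalization
NORM_TOL = 1e-9


class GrammarError(ValueError):
    """Malformed or improperly normalized grammar."""


@dataclass(frozen=True)
class Rule:
    """A single weighted rewrite rule ``lhs -> rhs[0] rhs[1] ...``."""

    lhs: str
    rhs: tuple[str, ...]
    prob: float

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.lhs} -> {' '.join(self.rhs)} {self.prob:g}"


@dataclass(frozen=True)
class PCFG:
    """Probabilistic context-free grammar over POS-tag terminals.

    Invariants (enforced by :meth:`validate`, called on construction via the
    loaders): rule probabilities sharing a left-hand side sum to one within
    1e-9; every right-hand-side symbol is a known nonterminal or terminal;
    the start symbol is a nonterminal; terminals never rewrite.
    """

    nonterminals: frozenset[str]
    terminals: frozenset[str]
    rules: tuple[Rule, ...]
    start: str

    def validate(self) -> None:
        if self.start not in self.nonterminals:
            raise GrammarError(f"start symbol {self.start!r} is not a nonterminal")
        if self.nonterminals & self.terminals:
            overlap = sorted(self.nonterminals & self.terminals)
            raise GrammarError(f"symbols both rewrite and terminate: {overlap}")
        sums: dict[str, float] = defaultdict(float)
        for r in self.rules:
            if r.lhs not in self.nonterminals:
                raise GrammarError(f"rule lhs {r.lhs!r} is not a nonterminal")
            if not r.rhs:
                raise GrammarError(f"empty right-hand side for {r.lhs!r}")
            if not (0.0 <= r.prob <= 1.0):
                raise GrammarError(f"rule probability {r.prob} outside [0, 1]: {r}")
            for sym in r.rhs:
                if sym not in self.nonterminals and sym not in self.terminals:
                    raise GrammarError(f"unknown symbol {sym!r} in rule {r}")
            sums[r.lhs] += r.prob
        for nt in self.nonterminals:
            if nt not in sums:
                raise GrammarError(f"nonterminal {nt!r} has no rules")
            if abs(sums[nt] - 1.0) > NORM_TOL:
                raise GrammarError(
                    f"probabilities for lhs {nt!r} sum to {sums[nt]:.12g}, not 1"
                )

    def rules_for(self, lhs: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.lhs == lhs)


def parse_grammar(text: str) -> PCFG:
    """Parse a grammar from the one-rule-per-line text format.

    Each non-comment line reads ``LHS -> RHS1 RHS2 ... PROB``.  Lines starting
    with ``#`` (and blank lines) are ignored.  The first rule's lhs is the
    start symbol.  Symbols that ever appear as an lhs are nonterminals; all
    remaining rhs symbols are terminals.
    """
    rules: list[Rule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            lhs_part, rhs_part = line.split("->", 1)
            lhs = lhs_part.strip()
            fields = rhs_part.split()
            if not lhs or len(fields) < 2:
                raise ValueError
            prob = float(fields[-1])
            rhs = tuple(fields[:-1])
        except ValueError:
            raise GrammarError(
                f"line {lineno}: cannot parse {raw.strip()!r}; "
                "expected 'LHS -> RHS1 RHS2 ... PROB'"
            ) from None
        rules.append(Rule(lhs, rhs, prob))
    if not rules:
        raise GrammarError("grammar contains no rules")
    nonterminals = frozenset(r.lhs for r in rules)
    terminals = frozenset(
        sym for r in rules for sym in r.rhs if sym not in nonterminals
    )
    g = PCFG(nonterminals, terminals, tuple(rules), rules[0].lhs)
    g.validate()
    return g


def load_grammar(path: str | Path) -> PCFG:
    """Load and validate a PCFG from a rule-per-line text file."""
    return parse_grammar(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# corpora


@dataclass
class POSCorpus:
    """Ordered sentences of POS tags plus a tag → word-class labeling.

    ``word_class_map`` assigns each tag to ``"content"`` (nouns, verbs,
    adjectives, ...) or ``"function"`` (determiners, prepositions,
    auxiliaries, ...); downstream analyses split and interact on this label.
    """

    sentences: list[tuple[str, ...]]
    tagset: frozenset[str]
    word_class_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, sent in enumerate(self.sentences):
            if not sent:
                raise ValueError(f"sentence {i} is empty")
            for tag in sent:
                if tag not in self.tagset:
                    raise ValueError(f"tag {tag!r} in sentence {i} not in tagset")
        if self.word_class_map:
            missing = self.tagset - self.word_class_map.keys()
            if missing:
                raise ValueError(f"tags without a word-class label: {sorted(missing)}")

    @property
    def n_words(self) -> int:
        return sum(len(s) for s in self.sentences)

    def words(self) -> Iterable[str]:
        for s in self.sentences:
            yield from s

    def word_classes(self) -> list[str]:
        return [self.word_class_map[t] for t in self.words()]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(" ".join(s) + "\n" for s in self.sentences), encoding="utf-8"
        )

    @classmethod
    def load(
        cls, path: str | Path, word_class_map: Mapping[str, str] | None = None
    ) -> "POSCorpus":
        sentences = [
            tuple(line.split())
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        tagset = frozenset(t for s in sentences for t in s)
        if word_class_map:
            # the word-class map defines the closed tag vocabulary; a sampled
            # corpus need not attest every tag
            tagset = tagset | frozenset(word_class_map)
        return cls(sentences, tagset, dict(word_class_map or {}))


def load_word_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (tag, class) with class in {content, function}."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("content", "function"):
            raise ValueError(f"line {lineno}: expected 'tag<TAB>content|function'")
        out[parts[0]] = parts[1]
    return out


@dataclass(frozen=True)
class CorpusStats:
    """Size and length moments of a corpus; sd_len uses the n-1 convention.

    ``sd_len`` is NaN for a single-sentence corpus (sample SD undefined).
    """

    n_words: int
    n_sentences: int
    mean_len: float
    sd_len: float
    n_content: int
    n_function: int


def corpus_stats(corpus: POSCorpus) -> CorpusStats:
    if not corpus.sentences:
        raise ValueError("corpus is empty")
    lens = np.array([len(s) for s in corpus.sentences], dtype=float)
    sd = float(lens.std(ddof=1)) if len(lens) > 1 else math.nan
    classes = corpus.word_classes() if corpus.word_class_map else []
    n_content = sum(c == "content" for c in classes)
    n_function = sum(c == "function" for c in classes)
    return CorpusStats(
        n_words=int(lens.sum()),
        n_sentences=len(lens),
        mean_len=float(lens.mean()),
        sd_len=sd,
        n_content=n_content,
        n_function=n_function,
    )


# ---------------------------------------------------------------------------
# sampling


def sample_sentence(
    grammar: PCFG, rng: np.random.Generator, max_len: int
) -> tuple[str, ...] | None:
    """Draw one sentence by top-down leftmost expansion.

    Returns None if the derivation's terminal yield exceeds ``max_len``
    (the caller rejects and redraws, keeping rule-probability bookkeeping
    exact for enumeration tests).
    """
    by_lhs: dict[str, tuple[Rule, ...]] = {}
    out: list[str] = []
    stack: list[str] = [grammar.start]
    while stack:
        sym = stack.pop()
        if sym in grammar.terminals:
            out.append(sym)
            if len(out) > max_len:
                return None
            continue
        rules = by_lhs.get(sym)
        if rules is None:
            rules = grammar.rules_for(sym)
            by_lhs[sym] = rules
        probs = np.array([r.prob for r in rules])
        idx = rng.choice(len(rules), p=probs / probs.sum())
        stack.extend(reversed(rules[idx].rhs))
        # cheap divergence guard: a runaway derivation grows the stack
        if len(stack) + len(out) > 50 * (max_len + 1):
            return None
    return tuple(out)


def sample_corpus(
    grammar: PCFG,
    n_sentences: int,
    seed: int,
    max_len: int = 60,
    word_class_map: Mapping[str, str] | None = None,
) -> POSCorpus:
    """Sample a corpus of ``n_sentences`` sentences; deterministic by seed.

    Derivations whose yield exceeds ``max_len`` are rejected and redrawn.  If
    the rejection rate exceeds 99% the grammar is assumed too divergent (its
    expected yield under top-down expansion is far beyond ``max_len``) and an
    error is raised.
    """
    if n_sentences < 0:
        raise ValueError("n_sentences must be >= 0")
    rng = np.random.default_rng(seed)
    sentences: list[tuple[str, ...]] = []
    attempts = 0
    while len(sentences) < n_sentences:
        attempts += 1
        sent = sample_sentence(grammar, rng, max_len)
        if sent is not None:
            sentences.append(sent)
        if attempts >= 200 and len(sentences) < 0.01 * attempts:
            raise RuntimeError(
                f"rejection rate {1 - len(sentences) / attempts:.1%} with "
                f"max_len={max_len}: the grammar appears too divergent to sample"
            )
    return POSCorpus(
        sentences, frozenset(grammar.terminals), dict(word_class_map or {})
    )
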