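"""Prefix probabilities for PCFGs via a probabilistic Earley chart.

The hierarchical context model conditions each word's probability on the set
of grammatical structures compatible with the preceding tags.  Concretely,
for a prefix w1..wi the *prefix probability* is the total probability mass of
all complete sentences that begin with those tags, and the incremental
probability of wi is the ratio of successive prefix probabilities.

The chart maintains, per Earley state, a *forward* probability (mass of all
derivations of the consumed prefix passing through the state) and an *inner*
probability (mass of the state's own partial constituent).  Left recursion
and unit-production chains — which would make naive prediction/completion
diverge — are folded into two closure matrices obtained by geometric-series
matrix inversion:

* left-corner closure  R_L = (I - P_L)^-1, where P_L[A, B] is the total
  probability of rules A -> B ... (B a leftmost nonterminal);
* unit closure         R_U = (I - P_U)^-1, where P_U[A, B] is the total
  probability of unit rules A -> B.

Prediction expands through R_L and completion through R_U, so states for
unit-production rules themselves never enter the chart.  Empty (epsilon)
right-hand sides are not supported (the grammar loader rejects them).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .grammar import PCFG, Rule

__all__ = ["EarleyParser", "cfg_prefix_probability", "ParseError"]

_COND_LIMIT = 1e12


class ParseError(ValueError):
    """Prefix not derivable, unknown terminal, or improper grammar."""


class _Cell:
    """One Earley item set: states keyed by (rule_id, dot, origin) holding
    [forward, inner], plus an index of states by the symbol after the dot."""

    __slots__ = ("states", "waiting")

    def __init__(self) -> None:
        self.states: dict[tuple[int, int, int], list[float]] = {}
        self.waiting: dict[str, list[tuple[int, int, int]]] = {}


class EarleyParser:
    """Chart parser computing exact prefix probabilities for a valid PCFG."""

    def __init__(self, grammar: PCFG):
        grammar.validate()
        self.grammar = grammar
        self.nts = sorted(grammar.nonterminals)
        self._nt_idx = {nt: i for i, nt in enumerate(self.nts)}
        n = len(self.nts)

        p_left = np.zeros((n, n))
        p_unit = np.zeros((n, n))
        for r in grammar.rules:
            first = r.rhs[0]
            if first in grammar.nonterminals:
                p_left[self._nt_idx[r.lhs], self._nt_idx[first]] += r.prob
            if len(r.rhs) == 1 and first in grammar.nonterminals:
                p_unit[self._nt_idx[r.lhs], self._nt_idx[first]] += r.prob

        self.R_L = self._invert(np.eye(n) - p_left, "left-corner")
        self.R_U = self._invert(np.eye(n) - p_unit, "unit-production")

        # rules that actually enter the chart: everything except unit
        # productions (those live entirely inside the closure matrices)
        self.chart_rules: list[Rule] = [
            r
            for r in grammar.rules
            if not (len(r.rhs) == 1 and r.rhs[0] in grammar.nonterminals)
        ]
        # per nonterminal: chart rules it can head
        self._rules_by_lhs: dict[str, list[int]] = defaultdict(list)
        for i, r in enumerate(self.chart_rules):
            self._rules_by_lhs[r.lhs].append(i)
        # per completed lhs C: nonterminals B with R_U[B, C] > 0 (unit parents)
        self._unit_parents: dict[str, list[tuple[str, float]]] = {
            c: [
                (b, float(self.R_U[self._nt_idx[b], ci]))
                for b in self.nts
                if self.R_U[self._nt_idx[b], ci] != 0.0
            ]
            for ci, c in enumerate(self.nts)
        }

    @staticmethod
    def _invert(mat: np.ndarray, what: str) -> np.ndarray:
        cond = np.linalg.cond(mat)
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            raise ParseError(
                f"{what} closure matrix is singular or ill-conditioned "
                f"(cond={cond:.3g}); the grammar is improper"
            )
        return np.linalg.inv(mat)

    # -- closure lookups ---------------------------------------------------

    def _rl(self, a: str, b: str) -> float:
        return float(self.R_L[self._nt_idx[a], self._nt_idx[b]])

    def _ru(self, a: str, b: str) -> float:
        return float(self.R_U[self._nt_idx[a], self._nt_idx[b]])

    # -- chart -------------------------------------------------------------

    def prefix_probabilities(self, tags: tuple[str, ...] | list[str]) -> np.ndarray:
        """Prefix probability after each of ``tags`` (length-n array).

        The empty prefix has probability 1 by definition and is not included.
        Raises :class:`ParseError` on an unknown terminal or a prefix with no
        grammatical continuation.
        """
        tags = tuple(tags)
        for t in tags:
            if t not in self.grammar.terminals:
                raise ParseError(f"unknown terminal {t!r}")

        chart = [_Cell() for _ in range(len(tags) + 1)]
        # initial prediction: dummy start state with forward = 1 expanded
        # through the left-corner closure from the start symbol
        self._predict(chart[0], {self.grammar.start: 1.0}, 0)

        prefix = np.empty(len(tags))
        for j, tag in enumerate(tags):
            scanned = self._scan(chart[j], tag, chart[j + 1])
            if scanned <= 0.0:
                raise ParseError(
                    f"prefix {' '.join(tags[: j + 1])!r} has zero probability "
                    f"(failure at position {j})"
                )
            prefix[j] = scanned
            self._complete(chart, j + 1)
            if j + 1 < len(tags):
                needs = self._needed_nonterminals(chart[j + 1])
                self._predict(chart[j + 1], needs, j + 1)
        return prefix

    def prefix_probability(self, tags: tuple[str, ...] | list[str]) -> float:
        """Total probability of complete sentences extending ``tags``."""
        tags = tuple(tags)
        if not tags:
            return 1.0
        return float(self.prefix_probabilities(tags)[-1])

    def sentence_surprisals(self, tags: tuple[str, ...] | list[str]) -> np.ndarray:
        """Per-word surprisal (bits): -log2 of successive prefix-prob ratios."""
        pp = self.prefix_probabilities(tags)
        logs = np.log2(pp)
        surp = -np.diff(np.concatenate(([0.0], logs)))
        # clip tiny negative values from float rounding of the ratio
        return np.clip(surp, 0.0, None)

    # -- steps -------------------------------------------------------------

    def _add(self, cell: "_Cell", rid: int, dot: int, origin: int) -> list[float]:
        key = (rid, dot, origin)
        st = cell.states.get(key)
        if st is None:
            st = cell.states[key] = [0.0, 0.0]
            rhs = self.chart_rules[rid].rhs
            if dot < len(rhs):
                cell.waiting.setdefault(rhs[dot], []).append(key)
        return st

    def _predict(self, cell: "_Cell", needed: dict[str, float], pos: int) -> None:
        """Expand forward mass ``needed[B]`` through R_L into new states."""
        for b, fwd in needed.items():
            if fwd == 0.0:
                continue
            bi = self._nt_idx[b]
            for ci, c in enumerate(self.nts):
                w = self.R_L[bi, ci]
                if w == 0.0:
                    continue
                for rid in self._rules_by_lhs.get(c, ()):
                    rule = self.chart_rules[rid]
                    st = self._add(cell, rid, 0, pos)
                    st[0] += fwd * w * rule.prob
                    st[1] = rule.prob

    def _needed_nonterminals(self, cell: "_Cell") -> dict[str, float]:
        """Forward mass expecting each nonterminal next, for prediction."""
        needs: dict[str, float] = defaultdict(float)
        for sym, keys in cell.waiting.items():
            if sym in self.grammar.nonterminals:
                for key in keys:
                    needs[sym] += cell.states[key][0]
        return dict(needs)

    def _scan(self, cell: "_Cell", tag: str, nxt: "_Cell") -> float:
        """Advance states expecting ``tag``; return summed forward mass."""
        total = 0.0
        for rid, dot, origin in cell.waiting.get(tag, ()):
            fwd, inner = cell.states[(rid, dot, origin)]
            st = self._add(nxt, rid, dot + 1, origin)
            st[0] += fwd
            st[1] += inner
            total += fwd
        return total

    def _complete(self, chart: list["_Cell"], j: int) -> None:
        """Propagate completed constituents ending at position ``j``.

        Inner-probability increments are aggregated per (lhs, origin) and
        processed in decreasing-origin order.  This visits each completed
        constituent exactly once: with no epsilon rules and unit chains
        pre-closed into R_U, a completion into origin k only ever produces
        completed states with strictly smaller origins.
        """
        pending: dict[int, dict[str, float]] = defaultdict(lambda: defaultdict(float))
        for (rid, dot, origin), (fwd, inner) in chart[j].states.items():
            if dot == len(self.chart_rules[rid].rhs) and inner != 0.0:
                pending[origin][self.chart_rules[rid].lhs] += inner
        while pending:
            k = max(pending)
            by_lhs = pending.pop(k)
            for lhs, d_inner in by_lhs.items():
                for b, w in self._unit_parents[lhs]:
                    for rid2, dot2, origin2 in chart[k].waiting.get(b, ()):
                        fwd2, inner2 = chart[k].states[(rid2, dot2, origin2)]
                        st = self._add(chart[j], rid2, dot2 + 1, origin2)
                        st[0] += fwd2 * w * d_inner
                        d_inn3 = inner2 * w * d_inner
                        st[1] += d_inn3
                        rhs2 = self.chart_rules[rid2].rhs
                        if dot2 + 1 == len(rhs2):
                            pending[origin2][self.chart_rules[rid2].lhs] += d_inn3


def cfg_prefix_probability(grammar: PCFG, prefix) -> float:
    """Convenience wrapper: prefix probability of ``prefix`` under ``grammar``."""
    return EarleyParser(grammar).prefix_probability(tuple(prefix))
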