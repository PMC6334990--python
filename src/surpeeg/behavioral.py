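"""Behavioral inclusion threshold from the exact binomial tail.

Participants answer ``n_questions`` multiple-choice questions with
``n_choices`` options each; a participant exceeds chance at level ``alpha``
when the probability of scoring at least their count by guessing alone is
below alpha.  The threshold is the smallest such count, computed from the
exact binomial upper tail (no normal approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["BehavioralRule", "behavioral_threshold"]


@dataclass(frozen=True)
class BehavioralRule:
    n_questions: int
    n_choices: int
    alpha: float
    threshold: int | None  # None when no score exceeds chance

    @property
    def attainable(self) -> bool:
        return self.threshold is not None

    def passes(self, n_correct: int) -> bool:
        return self.attainable and n_correct >= self.threshold


def behavioral_threshold(
    n_questions: int, n_choices: int, alpha: float
) -> BehavioralRule:
    """Smallest k with P(X >= k) < alpha for X ~ Binomial(n, 1/n_choices)."""
    if n_questions < 1 or n_choices < 2 or not (0.0 < alpha <= 1.0):
        raise ValueError("need n_questions >= 1, n_choices >= 2, alpha in (0, 1]")
    p = 1.0 / n_choices
    for k in range(n_questions + 1):
        tail = float(stats.binom.sf(k - 1, n_questions, p))  # P(X >= k)
        if tail < alpha:
            return BehavioralRule(n_questions, n_choices, alpha, k)
    return BehavioralRule(n_questions, n_choices, alpha, None)
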