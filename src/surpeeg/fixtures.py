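"""Bundled reference grammar and word-class map.

``story_grammar()`` returns the 36-terminal PCFG used throughout the package
as the synthetic stand-in for a parsed naturalistic story: Penn-Treebank-style
POS terminals, recursive NP/VP attachment, and several clause-embedding rules,
tuned so sampled sentence lengths are long-tailed with a mean in the
configured emulation band (15-35 words).
"""

from __future__ import annotations

from importlib import resources

from .grammar import PCFG, parse_grammar

__all__ = ["story_grammar", "story_word_classes", "EMULATION_LEN_BAND"]

#: acceptable mean sentence length (words) for corpora emulating the stimulus
EMULATION_LEN_BAND = (15.0, 35.0)


def _read(name: str) -> str:
    return (
        resources.files("surpeeg").joinpath("data", name).read_text(encoding="utf-8")
    )


def story_grammar() -> PCFG:
    """The bundled 36-tag story grammar."""
    return parse_grammar(_read("story36.grammar"))


def story_word_classes() -> dict[str, str]:
    """Tag → {content, function} map for the bundled grammar's terminals."""
    out: dict[str, str] = {}
    for line in _read("wordclass36.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        tag, cls = line.split("\t")
        out[tag] = cls
    return out
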