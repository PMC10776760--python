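"""Tokenization, part-of-speech categorization, and negation detection.

Tokens are bucketed into eight coarse categories: verb, adverb, noun,
adjective, pronoun, preposition, negation, and other. Negation membership
is lexical and takes precedence over the Penn tag bucket.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import _tagger
from .chain_corpus import normalize_text

__all__ = [
    "CATEGORIES",
    "PENN_TO_CATEGORY",
    "DEFAULT_NEGATION_LEXICON",
    "TokenAnnotation",
    "StoryAnnotation",
    "tokenize",
    "annotate_story",
    "pos_proportion",
]

CATEGORIES = (
    "verb", "adverb", "noun", "adjective", "pronoun", "preposition",
    "negation", "other",
)

PENN_TO_CATEGORY: dict[str, str] = {}
for _t in ("VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD"):
    PENN_TO_CATEGORY[_t] = "verb"
for _t in ("RB", "RBR", "RBS", "WRB"):
    PENN_TO_CATEGORY[_t] = "adverb"
for _t in ("NN", "NNS", "NNP", "NNPS"):
    PENN_TO_CATEGORY[_t] = "noun"
for _t in ("JJ", "JJR", "JJS"):
    PENN_TO_CATEGORY[_t] = "adjective"
for _t in ("PRP", "PRP$", "WP", "WP$"):
    PENN_TO_CATEGORY[_t] = "pronoun"
for _t in ("IN", "TO"):
    PENN_TO_CATEGORY[_t] = "preposition"

# "not"/"n't"/"no" are mandatory members; the rest are conventional
# negation lexemes and may be overridden by callers.
DEFAULT_NEGATION_LEXICON = frozenset(
    {"not", "n't", "no", "never", "neither", "nor", "none", "nothing",
     "nobody", "nowhere"}
)

_CONTRACTION_NT = re.compile(r"^(?P<stem>[A-Za-z]+)n[''`]?t$", re.IGNORECASE)
_IRREGULAR_NT = {
    "won't": ("will", "not"),
    "can't": ("can", "not"),
    "cannot": ("can", "not"),
    "shan't": ("shall", "not"),
    "ain't": ("is", "not"),
}
_CLITIC = re.compile(r"^(?P<stem>[A-Za-z]+)'(?P<clitic>s|re|ve|ll|d|m)$", re.IGNORECASE)
_WORD = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?|\d+(?:[.,]\d+)*")


@dataclass(frozen=True)
class TokenAnnotation:
    surface: str
    lemma: str
    pos_tag: str
    category: str
    is_negation: bool

    def __post_init__(self) -> None:
        assert self.lemma, "lemma must be non-empty"
        assert self.is_negation == (self.category == "negation")


@dataclass(frozen=True)
class StoryAnnotation:
    tokens: tuple[TokenAnnotation, ...]

    @property
    def word_count(self) -> int:
        return len(self.tokens)

    @property
    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for tok in self.tokens:
            counts[tok.category] += 1
        return counts

    def lemmas(self, categories: Iterable[str] | None = None) -> list[str]:
        wanted = set(categories) if categories is not None else None
        return [t.lemma for t in self.tokens if wanted is None or t.category in wanted]


def tokenize(text: str) -> list[str]:
    """Split text into word tokens.

    Punctuation-only tokens are dropped, "n't" contractions are split with
    the negative piece normalized to the token "not", and other clitics
    ('s, 're, 've, 'll, 'd, 'm) are split off. Surfaces keep their case.
    """
    text = normalize_text(text)
    tokens: list[str] = []
    for match in _WORD.finditer(text):
        word = match.group(0)
        low = word.lower()
        if low in _IRREGULAR_NT:
            stem, neg = _IRREGULAR_NT[low]
            if word[0].isupper():
                stem = stem.capitalize()
            tokens.extend([stem, neg])
            continue
        m = _CONTRACTION_NT.match(word)
        if m and low not in ("ant", "want", "went", "front", "point", "paint",
                             "print", "plant", "count", "grant", "hunt", "rent"):
            stem = m.group("stem")
            # only split when the stem is a plausible auxiliary
            if stem.lower() in ("do", "does", "did", "is", "are", "was", "were",
                                "has", "have", "had", "would", "should", "could",
                                "must", "need", "dare", "ought", "might", "wo",
                                "ca", "sha", "ai"):
                stem = {"wo": "will", "ca": "can", "sha": "shall", "ai": "is"}.get(
                    stem.lower(), stem
                )
                tokens.extend([stem, "not"])
                continue
        m = _CLITIC.match(word)
        if m:
            tokens.append(m.group("stem"))
            # possessive/auxiliary clitics carry no content; drop them
            continue
        tokens.append(word)
    return tokens


def _categorize(lemma: str, tag: str, negation_lexicon: frozenset[str]) -> str:
    if lemma in negation_lexicon:
        return "negation"
    return PENN_TO_CATEGORY.get(tag, "other")


def annotate_story(
    text: str,
    extra_lexicon: Mapping[str, tuple[str, str]] | None = None,
    negation_lexicon: frozenset[str] = DEFAULT_NEGATION_LEXICON,
) -> StoryAnnotation:
    """Tokenize, tag, lemmatize, and bucket every token of one story."""
    if not negation_lexicon >= {"not", "no"}:
        raise ValueError("negation lexicon must contain 'not' and 'no'")
    tokens = tokenize(text)
    tagged = _tagger.tag_tokens(tokens, extra_lexicon)
    annotations = []
    for surface, tag, lemma in tagged:
        category = _categorize(lemma, tag, negation_lexicon)
        annotations.append(
            TokenAnnotation(
                surface=surface,
                lemma=lemma,
                pos_tag=tag,
                category=category,
                is_negation=category == "negation",
            )
        )
    return StoryAnnotation(tokens=tuple(annotations))


def pos_proportion(annotation: StoryAnnotation, category: str) -> float:
    """Share of tokens in ``category``; errors on empty stories."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if annotation.word_count == 0:
        raise ValueError("pos_proportion undefined for an empty story")
    return annotation.category_counts[category] / annotation.word_count


def pooled_proportion(annotations: Iterable[StoryAnnotation], category: str) -> float:
    """Corpus-level pooled share: total category tokens / total tokens."""
    num = 0
    den = 0
    for ann in annotations:
        num += ann.category_counts[category]
        den += ann.word_count
    if den == 0:
        raise ValueError("pooled_proportion undefined: no tokens")
    return num / den
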