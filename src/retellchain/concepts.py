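"""Concept extraction and transmission metrics between consecutive retellings.

Stories are mapped to deduplicated concept sets at three granularities:
``synset`` (a disambiguated sense from a WordNet-style inventory),
``lemma`` (the base wordform), and ``root_hypernym`` (the topmost ancestor
of the selected synset). Between a parent and its retelling we measure
survival (fraction of parent concepts that reappear), novelty (fraction of
child concepts absent from the parent), and concept density.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .annotate import StoryAnnotation, annotate_story
from .chain_corpus import Chain

__all__ = [
    "LEVELS",
    "CONTENT_CATEGORIES",
    "Synset",
    "SenseInventory",
    "ConceptSet",
    "TransitionMetrics",
    "extract_concepts",
    "survival_rate",
    "novelty_rate",
    "chain_metrics",
]

LEVELS = ("synset", "lemma", "root_hypernym")
CONTENT_CATEGORIES = ("noun", "verb", "adjective", "adverb")

_CATEGORY_TO_POS = {"noun": "n", "verb": "v", "adjective": "a", "adverb": "r"}
_GLOSS_WORD = re.compile(r"[a-z]+")


@dataclass(frozen=True)
class Synset:
    """One concept node: identifier, POS letter, member lemmas, gloss."""

    id: str
    pos: str
    lemmas: tuple[str, ...]
    gloss: str
    hypernyms: tuple[str, ...] = ()

    def gloss_words(self) -> frozenset[str]:
        return frozenset(_GLOSS_WORD.findall(self.gloss.lower()))


class SenseInventory:
    """A WordNet-style sense inventory loaded from a JSON synset list.

    Sense order within a lemma follows file order and is treated as the
    frequency ranking (first sense = most frequent), which also breaks
    disambiguation ties.
    """

    def __init__(self, synsets: Sequence[Synset]):
        if not synsets:
            raise ValueError("empty sense inventory")
        self._synsets: dict[str, Synset] = {}
        self._by_lemma_pos: dict[tuple[str, str], list[Synset]] = {}
        for syn in synsets:
            if syn.id in self._synsets:
                raise ValueError(f"duplicate synset id {syn.id!r}")
            self._synsets[syn.id] = syn
            for lemma in syn.lemmas:
                self._by_lemma_pos.setdefault((lemma.lower(), syn.pos), []).append(syn)
        self._root_cache: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self._synsets)

    def __contains__(self, synset_id: str) -> bool:
        return synset_id in self._synsets

    def synset(self, synset_id: str) -> Synset:
        return self._synsets[synset_id]

    def senses(self, lemma: str, pos: str) -> list[Synset]:
        return list(self._by_lemma_pos.get((lemma.lower(), pos), []))

    @property
    def lemma_set(self) -> set[str]:
        return {lemma for lemma, _pos in self._by_lemma_pos}

    def root_hypernym(self, synset_id: str) -> str:
        """Topmost ancestor, ascending via the lexicographically smallest
        hypernym at each branching point."""
        if synset_id in self._root_cache:
            return self._root_cache[synset_id]
        current = synset_id
        seen = {current}
        while True:
            parents = [h for h in self._synsets[current].hypernyms if h in self._synsets]
            if not parents:
                break
            nxt = min(parents)
            if nxt in seen:  # defensive: cycles in a hand-built inventory
                break
            seen.add(nxt)
            current = nxt
        self._root_cache[synset_id] = current
        return current

    @classmethod
    def from_json(cls, path: str | Path) -> "SenseInventory":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls._from_payload(data)

    @classmethod
    def _from_payload(cls, data: dict) -> "SenseInventory":
        synsets = [
            Synset(
                id=entry["id"],
                pos=entry["pos"],
                lemmas=tuple(entry["lemmas"]),
                gloss=entry.get("gloss", ""),
                hypernyms=tuple(entry.get("hypernyms", ())),
            )
            for entry in data["synsets"]
        ]
        return cls(synsets)

    @classmethod
    def fixture(cls) -> "SenseInventory":
        """The miniature inventory shipped with the package."""
        ref = resources.files("retellchain.data").joinpath("toy_inventory.json")
        return cls._from_payload(json.loads(ref.read_text(encoding="utf-8")))


@dataclass(frozen=True)
class ConceptSet:
    level: str
    ids: frozenset[str]
    source_word_count: int
    covered_tokens: int = 0
    content_tokens: int = 0

    @property
    def coverage(self) -> float:
        if self.content_tokens == 0:
            return 0.0
        return self.covered_tokens / self.content_tokens

    @property
    def density(self) -> float:
        """Distinct concepts per word token of the source story."""
        if self.source_word_count == 0:
            return 0.0
        return len(self.ids) / self.source_word_count


@dataclass(frozen=True)
class TransitionMetrics:
    chain_id: str
    parent_index: int
    child_index: int
    level: str
    survival: float
    novelty: float
    child_count: int
    child_word_count: int

    @property
    def child_density(self) -> float:
        if self.child_word_count == 0:
            return 0.0
        return self.child_count / self.child_word_count


def disambiguate(
    lemma: str,
    pos: str,
    context: frozenset[str],
    inventory: SenseInventory,
) -> Synset | None:
    """Simplified-Lesk sense choice: maximize overlap between the story
    context and each candidate's gloss words plus member lemmas; ties go
    to the earliest-listed (most frequent) sense."""
    senses = inventory.senses(lemma, pos)
    if not senses:
        return None
    if len(senses) == 1:
        return senses[0]
    best, best_score = senses[0], -1
    for sense in senses:
        signature = sense.gloss_words() | {l.lower() for l in sense.lemmas}
        score = len(signature & context)
        if score > best_score:
            best, best_score = sense, score
    return best


def extract_concepts(
    annotation: StoryAnnotation,
    level: str,
    inventory: SenseInventory,
) -> ConceptSet:
    """Map content tokens (noun/verb/adjective/adverb) to concept ids.

    Tokens absent from the inventory are skipped and reflected in the
    coverage statistic. The disambiguation context is the story's full
    lemma set (sentence boundaries are not preserved by tokenization).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    context = frozenset(t.lemma for t in annotation.tokens)
    ids: set[str] = set()
    covered = 0
    content = 0
    for token in annotation.tokens:
        if token.category not in CONTENT_CATEGORIES:
            continue
        content += 1
        if level == "lemma":
            if token.lemma in inventory.lemma_set:
                covered += 1
                ids.add(token.lemma)
            continue
        pos = _CATEGORY_TO_POS[token.category]
        sense = disambiguate(token.lemma, pos, context - {token.lemma}, inventory)
        if sense is None:
            # fall back to any POS (coarse tagging may miss the inventory POS)
            for alt in "nvar":
                sense = disambiguate(token.lemma, alt, context - {token.lemma}, inventory)
                if sense is not None:
                    break
        if sense is None:
            continue
        covered += 1
        if level == "synset":
            ids.add(sense.id)
        else:
            ids.add(inventory.root_hypernym(sense.id))
    return ConceptSet(
        level=level,
        ids=frozenset(ids),
        source_word_count=annotation.word_count,
        covered_tokens=covered,
        content_tokens=content,
    )


def survival_rate(parent: ConceptSet, child: ConceptSet) -> float:
    """|parent ∩ child| / |parent| — fraction of parent concepts retained."""
    if parent.level != child.level:
        raise ValueError(f"level mismatch: {parent.level} vs {child.level}")
    if not parent.ids:
        raise ValueError("survival_rate undefined for an empty parent set")
    return len(parent.ids & child.ids) / len(parent.ids)


def novelty_rate(parent: ConceptSet, child: ConceptSet) -> float:
    """|child \\ parent| / |child| — fraction of child concepts newly created."""
    if parent.level != child.level:
        raise ValueError(f"level mismatch: {parent.level} vs {child.level}")
    if not child.ids:
        raise ValueError("novelty_rate undefined for an empty child set")
    return len(child.ids - parent.ids) / len(child.ids)


def chain_metrics(
    chain: Chain,
    level: str,
    inventory: SenseInventory,
    extra_lexicon=None,
    baseline: str = "parent",
) -> list[TransitionMetrics]:
    """One TransitionMetrics per transition (0→1, 1→2, 2→3).

    ``baseline='parent'`` compares each retelling against its immediate
    parent; ``'ancestors'`` compares against the union of all earlier
    versions' concepts.
    """
    if baseline not in ("parent", "ancestors"):
        raise ValueError(f"unknown baseline {baseline!r}")
    sets = [
        extract_concepts(annotate_story(v.text, extra_lexicon), level, inventory)
        for v in chain.versions
    ]
    metrics = []
    ancestor_ids: frozenset[str] = frozenset()
    for r in range(1, len(sets)):
        parent, child = sets[r - 1], sets[r]
        if baseline == "ancestors":
            ancestor_ids = ancestor_ids | parent.ids
            parent = ConceptSet(
                level=parent.level,
                ids=ancestor_ids,
                source_word_count=parent.source_word_count,
            )
        metrics.append(
            TransitionMetrics(
                chain_id=chain.chain_id,
                parent_index=r - 1,
                child_index=r,
                level=level,
                survival=survival_rate(parent, child) if parent.ids else float("nan"),
                novelty=novelty_rate(parent, child) if child.ids else float("nan"),
                child_count=len(child.ids),
                child_word_count=child.source_word_count,
            )
        )
    return metrics
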