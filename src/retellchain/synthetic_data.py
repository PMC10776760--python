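"""Synthetic chains, lexicons, and ratings with known ground truth.

Every analysis stage can be exercised offline: the generator records the
exact concept sets it placed in each story version, so pipeline-measured
survival and novelty can be compared against closed-form expectations, and
rating trajectories are drawn from the same spine + compression model the
trend module fits.

Stories are rendered as short templated clauses ("the dakel", "they did
not mopira") so the tagger behaves sensibly; rendering is separate from
concept bookkeeping, and each generated wordform is registered in an extra
tagger lexicon with its category.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chain_corpus import (
    CONDITIONS,
    Chain,
    RatingRecord,
    StoryVersion,
)
from .concepts import SenseInventory, Synset
from .lexical_norms import NormTable

__all__ = [
    "SimLexicon",
    "SimParams",
    "RatingParams",
    "build_toy_lexicon",
    "generate_chain",
    "generate_corpus",
    "simulate_ratings",
    "simulate_trend_matrix",
    "expected_metrics",
    "load_preset",
]

_CATEGORY_TAG = {"noun": "NN", "verb": "VB", "adjective": "JJ", "adverb": "RB"}
_CATEGORY_POS = {"noun": "n", "verb": "v", "adjective": "a", "adverb": "r"}
_ONSETS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class LexEntry:
    wordform: str
    lemma: str
    category: str
    synset_id: str
    root_id: str
    aoa: float
    concreteness: float
    valence: float
    arousal: float
    frequency: float


@dataclass
class SimLexicon:
    """Generated vocabulary: synonym groups with norms and root assignments."""

    entries: list[LexEntry]
    roots: tuple[str, ...]

    def __post_init__(self) -> None:
        self.by_synset: dict[str, list[LexEntry]] = {}
        for e in self.entries:
            self.by_synset.setdefault(e.synset_id, []).append(e)

    @property
    def synset_ids(self) -> list[str]:
        return sorted(self.by_synset)

    def synset_frequency(self, synset_id: str) -> float:
        return sum(e.frequency for e in self.by_synset[synset_id])

    def synset_aoa(self, synset_id: str) -> float:
        return float(np.mean([e.aoa for e in self.by_synset[synset_id]]))

    def synset_valence(self, synset_id: str) -> float:
        return float(np.mean([e.valence for e in self.by_synset[synset_id]]))

    def category(self, synset_id: str) -> str:
        return self.by_synset[synset_id][0].category

    def to_inventory(self) -> SenseInventory:
        """A consistent sense inventory: one synset per synonym group plus
        one root node per root group."""
        synsets = [
            Synset(id=r, pos="n", lemmas=(r.split(".")[0],),
                   gloss="a generated top level concept group")
            for r in self.roots
        ]
        for sid in self.synset_ids:
            group = self.by_synset[sid]
            synsets.append(
                Synset(
                    id=sid,
                    pos=_CATEGORY_POS[group[0].category],
                    lemmas=tuple(e.wordform for e in group),
                    gloss=f"generated {group[0].category} concept {sid}",
                    hypernyms=(group[0].root_id,),
                )
            )
        return SenseInventory(synsets)

    def to_norms(self) -> NormTable:
        frame = pd.DataFrame(
            [
                {
                    "word": e.wordform,
                    "aoa": e.aoa,
                    "concreteness": e.concreteness,
                    "valence": e.valence,
                    "arousal": e.arousal,
                    "frequency": e.frequency,
                }
                for e in self.entries
            ]
        )
        return NormTable(frame)

    def extra_tagger_lexicon(self) -> dict[str, tuple[str, str]]:
        return {
            e.wordform: (_CATEGORY_TAG[e.category], e.wordform) for e in self.entries
        }

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "roots": list(self.roots),
            "entries": [e.__dict__ for e in self.entries],
        }
        (directory / "sim_lexicon.json").write_text(
            json.dumps(payload, indent=1) + "\n", encoding="utf-8"
        )
        inv = {
            "synsets": [
                {"id": s, "pos": _CATEGORY_POS[self.category(s)],
                 "lemmas": [e.wordform for e in self.by_synset[s]],
                 "gloss": f"generated {self.category(s)} concept {s}",
                 "hypernyms": [self.by_synset[s][0].root_id]}
                for s in self.synset_ids
            ]
            + [
                {"id": r, "pos": "n", "lemmas": [r.split(".")[0]],
                 "gloss": "a generated top level concept group", "hypernyms": []}
                for r in self.roots
            ]
        }
        (directory / "sim_inventory.json").write_text(
            json.dumps(inv, indent=1) + "\n", encoding="utf-8"
        )
        self.to_norms().frame.reset_index().to_csv(
            directory / "sim_norms.csv", index=False
        )

    @classmethod
    def read(cls, directory: str | Path) -> "SimLexicon":
        payload = json.loads(
            (Path(directory) / "sim_lexicon.json").read_text(encoding="utf-8")
        )
        entries = [LexEntry(**e) for e in payload["entries"]]
        return cls(entries=entries, roots=tuple(payload["roots"]))


@dataclass(frozen=True)
class RatingParams:
    beta0: float = 0.0
    beta1: float = 0.0
    gamma: float = 0.0
    sigma: float = 0.3
    tau: float = 1.0
    scale_min: float = 0.0
    scale_max: float = 100.0
    unit: float = 12.0  # raw slider units per standardized unit


@dataclass(frozen=True)
class SimParams:
    n_chains: int = 50
    producer: str = "human"
    length0: int = 140  # words in the original story
    length_decay: float = 0.75
    p_surv: float = 0.42
    innovation_rate: float = 1.0  # fraction of the fresh-slot budget actually filled
    p_syn: float = 0.3
    aoa_shift: float = 0.0
    negation_rate_happy: float = 0.02
    negation_rate_sad: float = 0.04
    valence_tilt: float = 0.3
    content_fraction: float = 0.45  # concepts per rendered word in version 0
    rating: RatingParams = field(default_factory=RatingParams)
    seed: int = 0

    def validate(self) -> None:
        for name in ("length_decay", "p_surv", "innovation_rate", "p_syn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.length0 < 20:
            raise ValueError("length0 too short to render 60-character retellings")


def load_preset(name: str) -> SimParams:
    """Presets are data: read from the packaged presets.json."""
    ref = resources.files("retellchain.data").joinpath("presets.json")
    presets = json.loads(ref.read_text(encoding="utf-8"))
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    payload = dict(presets[name])
    rating = RatingParams(**payload.pop("rating", {}))
    return SimParams(rating=rating, **payload)


def _make_wordform(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            _ONSETS[rng.integers(len(_ONSETS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if word not in used:
            used.add(word)
            return word


def build_toy_lexicon(n_synsets: int, seed: int = 0) -> SimLexicon:
    """Deterministic synthetic lexicon.

    Distributions (documented for the distributional tests): categories
    noun/verb/adjective/adverb at 45/30/15/10%; AOA ~ Normal(6, 2.5)
    truncated at 1.5; concreteness ~ Uniform(1.5, 5); valence ~
    Normal(5, 1.5) clipped to [1, 9]; arousal ~ Uniform(2, 7); frequency
    weights ~ LogNormal(0, 1). Each synset owns 1-3 unique wordforms.
    """
    if n_synsets < 10:
        raise ValueError("n_synsets must be at least 10")
    rng = np.random.default_rng(seed)
    n_roots = max(3, n_synsets // 8)
    roots = tuple(f"root{i:02d}.n.01" for i in range(n_roots))
    used: set[str] = {r.split(".")[0] for r in roots}
    categories = rng.choice(
        ["noun", "verb", "adjective", "adverb"], size=n_synsets,
        p=[0.45, 0.30, 0.15, 0.10],
    )
    entries: list[LexEntry] = []
    for i in range(n_synsets):
        category = str(categories[i])
        sid = f"sim{i:04d}.{_CATEGORY_POS[category]}.01"
        root = roots[int(rng.integers(n_roots))]
        aoa = max(1.5, float(rng.normal(6.0, 2.5)))
        concreteness = float(rng.uniform(1.5, 5.0))
        valence = float(np.clip(rng.normal(5.0, 1.5), 1.0, 9.0))
        arousal = float(rng.uniform(2.0, 7.0))
        n_forms = int(rng.integers(1, 4))
        for _ in range(n_forms):
            entries.append(
                LexEntry(
                    wordform=_make_wordform(rng, used),
                    lemma="",  # filled below: lemma == wordform
                    category=category,
                    synset_id=sid,
                    root_id=root,
                    aoa=round(aoa + float(rng.normal(0, 0.2)), 3),
                    concreteness=round(concreteness, 3),
                    valence=round(valence, 3),
                    arousal=round(arousal, 3),
                    frequency=round(float(rng.lognormal(0.0, 1.0)), 4),
                )
            )
    entries = [replace(e, lemma=e.wordform) for e in entries]
    return SimLexicon(entries=entries, roots=roots)


def _tilted_weights(
    lexicon: SimLexicon, synset_ids: Sequence[str], aoa_shift: float,
    valence_tilt: float = 0.0,
) -> np.ndarray:
    """Frequency weights, optionally exponentially tilted so the expected
    AOA of a draw moves by ``aoa_shift`` years, and tilted toward high
    (positive tilt) or low valence."""
    freq = np.array([lexicon.synset_frequency(s) for s in synset_ids])
    aoa = np.array([lexicon.synset_aoa(s) for s in synset_ids])
    val = np.array([lexicon.synset_valence(s) for s in synset_ids])
    w = freq.astype(float)
    if valence_tilt:
        w = w * np.exp(valence_tilt * (val - 5.0))
    if aoa_shift:
        base_mean = float(np.sum(w * aoa) / np.sum(w))

        def tilted_mean(lam: float) -> float:
            tw = w * np.exp(lam * (aoa - aoa.mean()))
            return float(np.sum(tw * aoa) / np.sum(tw))

        lo, hi = (0.0, 5.0) if aoa_shift > 0 else (-5.0, 0.0)
        target = base_mean + aoa_shift
        for _ in range(60):  # bisection; tilted_mean is monotone in lam
            mid = 0.5 * (lo + hi)
            if tilted_mean(mid) < target:
                lo = mid
            else:
                hi = mid
        w = w * np.exp(0.5 * (lo + hi) * (aoa - aoa.mean()))
    return w / w.sum()


def _sample_synsets(
    rng: np.random.Generator, synset_ids: Sequence[str], weights: np.ndarray,
    size: int,
) -> list[str]:
    size = min(size, len(synset_ids))
    idx = rng.choice(len(synset_ids), size=size, replace=False, p=weights)
    return [synset_ids[i] for i in idx]


def _render(
    concepts: Sequence[tuple[str, str]],  # (wordform, category)
    rng: np.random.Generator,
    negation_rate: float,
) -> str:
    """Render concepts as templated clauses joined into sentences."""
    clauses = []
    for wordform, category in concepts:
        negate = rng.uniform() < negation_rate
        if category == "noun":
            clause = f"there was no {wordform}" if negate else f"they saw the {wordform}"
        elif category == "verb":
            clause = f"they did not {wordform}" if negate else f"they would {wordform}"
        elif category == "adjective":
            clause = f"it was not {wordform}" if negate else f"it was {wordform}"
        else:
            clause = f"they never went {wordform}" if negate else f"they went {wordform}"
        clauses.append(clause)
    sentences = []
    i = 0
    while i < len(clauses):
        take = int(rng.integers(2, 4))
        group = clauses[i: i + take]
        sentence = " and ".join(group)
        sentences.append(sentence[0].upper() + sentence[1:] + ".")
        i += take
    return " ".join(sentences)


def generate_chain(
    params: SimParams,
    lexicon: SimLexicon,
    seed: int,
    chain_id: str = "c0",
    condition: str = "happy",
) -> tuple[Chain, dict]:
    """Generate one chain plus its ground-truth concept bookkeeping.

    Returns ``(chain, truth)`` where ``truth`` holds, per version, the
    placed synset ids, lemma (wordform) sets, root ids, and per-transition
    expected survival/novelty given the realized parent size.
    """
    params.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    synset_ids = lexicon.synset_ids
    sad_side = condition in ("sad", "mildly_sad")
    tilt = -params.valence_tilt if sad_side else params.valence_tilt
    if condition.startswith("mildly"):
        tilt *= 0.5
    w0 = _tilted_weights(lexicon, synset_ids, 0.0, tilt)
    neg_rate = params.negation_rate_sad if sad_side else params.negation_rate_happy

    n0 = max(2, round(params.length0 * params.content_fraction))
    version_synsets: list[list[str]] = [_sample_synsets(rng, synset_ids, w0, n0)]
    wordform_of: dict[str, str] = {}
    for sid in version_synsets[0]:
        group = lexicon.by_synset[sid]
        freqs = np.array([e.frequency for e in group])
        wordform_of[sid] = group[int(rng.choice(len(group), p=freqs / freqs.sum()))].wordform
    version_words: list[list[tuple[str, str]]] = [
        [(wordform_of[s], lexicon.category(s)) for s in version_synsets[0]]
    ]
    expected: list[dict[str, float]] = []

    fresh_weights = _tilted_weights(lexicon, synset_ids, params.aoa_shift)
    id_index = {s: i for i, s in enumerate(synset_ids)}
    for r in range(1, 4):
        parent = version_synsets[r - 1]
        target = max(1, round(len(parent) * params.length_decay))
        keep_mask = rng.uniform(size=len(parent)) < params.p_surv
        survivors = [s for s, keep in zip(parent, keep_mask) if keep]
        n_fresh_budget = max(0, target - len(survivors))
        n_fresh = int(round(params.innovation_rate * n_fresh_budget))
        pool = [s for s in synset_ids if s not in set(parent)]
        if pool and n_fresh > 0:
            pw = fresh_weights[[id_index[s] for s in pool]]
            pw = pw / pw.sum()
            fresh = _sample_synsets(rng, pool, pw, n_fresh)
        else:
            fresh = []
        child = survivors + fresh
        if not child:  # degenerate settings: keep at least one fresh concept
            child = _sample_synsets(rng, synset_ids, fresh_weights, 1)
            fresh = child
        expected.append(
            {
                "survival": params.p_surv,
                "novelty": (
                    1.0 - min(1.0, params.p_surv * len(parent) / target)
                    if params.innovation_rate == 1.0
                    else float("nan")
                ),
                "parent_size": len(parent),
                "target_size": target,
            }
        )
        words = []
        for sid in child:
            group = lexicon.by_synset[sid]
            prev = wordform_of.get(sid)
            if prev is not None and len(group) > 1 and rng.uniform() < params.p_syn:
                others = [e.wordform for e in group if e.wordform != prev]
                wordform_of[sid] = others[int(rng.integers(len(others)))]
            elif prev is None:
                freqs = np.array([e.frequency for e in group])
                wordform_of[sid] = group[
                    int(rng.choice(len(group), p=freqs / freqs.sum()))
                ].wordform
            words.append((wordform_of[sid], lexicon.category(sid)))
        version_synsets.append(child)
        version_words.append(words)

    versions = []
    for r in range(4):
        text = _render(version_words[r], rng, neg_rate)
        while r > 0 and len(text) < 60:  # corpus rule: retellings >= 60 chars
            text = text + " They would wait again."
        versions.append(
            StoryVersion(
                chain_id=chain_id,
                retelling_index=r,
                producer=params.producer,
                condition=condition,
                text=text,
            )
        )
    chain = Chain(
        chain_id=chain_id,
        condition=condition,
        producer=params.producer,
        versions=tuple(versions),
    )
    truth = {
        "synsets": [set(v) for v in version_synsets],
        "lemmas": [set(w for w, _ in words) for words in version_words],
        "roots": [
            {lexicon.by_synset[s][0].root_id for s in v} for v in version_synsets
        ],
        "expected": expected,
    }
    return chain, truth


def generate_corpus(
    params: SimParams,
    lexicon: SimLexicon,
    seed: int | None = None,
) -> tuple[list[Chain], dict[str, dict]]:
    """Generate ``params.n_chains`` chains cycling through the conditions."""
    seed = params.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    chains = []
    truths = {}
    for i in range(params.n_chains):
        chain_id = f"{params.producer}{i:04d}"
        condition = CONDITIONS[i % len(CONDITIONS)]
        chain, truth = generate_chain(
            params, lexicon, seed=int(root.spawn(1)[0].generate_state(1)[0]),
            chain_id=chain_id, condition=condition,
        )
        chains.append(chain)
        truths[chain_id] = truth
    return chains, truths


def expected_metrics(params: SimParams) -> pd.DataFrame:
    """Closed-form per-transition expectations implied by the generator.

    Survival is ``p_surv`` by construction. With ``innovation_rate = 1``
    the child has exactly ``target = round(parent * decay)`` concepts of
    which ``Binomial(parent, p_surv)`` survive, so expected novelty is
    ``1 - p_surv * parent / target``.
    """
    n = max(2, round(params.length0 * params.content_fraction))
    rows = []
    for r in range(1, 4):
        target = max(1, round(n * params.length_decay))
        rows.append(
            {
                "transition": r,
                "expected_survival": params.p_surv,
                "expected_novelty": 1.0 - min(1.0, params.p_surv * n / target),
                "expected_parent_size": n,
                "expected_child_size": target,
            }
        )
        n = target
    return pd.DataFrame(rows)


def simulate_trend_matrix(
    n_stories: int,
    beta0: float = 0.0,
    beta1: float = 0.0,
    gamma: float = 0.0,
    sigma: float = 0.3,
    tau: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw a (n_stories, 4) matrix straight from the trend likelihood."""
    rng = np.random.default_rng(seed)
    r = np.arange(4.0)
    delta = rng.normal(0.0, tau, size=n_stories)
    latent = beta0 + beta1 * r + delta[:, None] * np.exp(-gamma * r)
    return latent + rng.normal(0.0, sigma, size=(n_stories, 4))


def simulate_ratings(
    chains: Iterable[Chain],
    params: SimParams,
    n_raters: int = 10,
    seed: int = 0,
    item: str = "happiness",
) -> list[RatingRecord]:
    """Rater scores from the spine/compression model, clipped to the scale."""
    rp = params.rating
    rng = np.random.default_rng(seed)
    mid = 0.5 * (rp.scale_min + rp.scale_max)
    records = []
    r = np.arange(4.0)
    for chain in chains:
        delta = rng.normal(0.0, rp.tau)
        latent = rp.beta0 + rp.beta1 * r + delta * np.exp(-rp.gamma * r)
        for idx in range(4):
            noise = rng.normal(0.0, rp.sigma, size=n_raters)
            raw = mid + rp.unit * (latent[idx] + noise)
            raw = np.clip(raw, rp.scale_min, rp.scale_max)
            for j in range(n_raters):
                records.append(
                    RatingRecord(
                        chain_id=chain.chain_id,
                        retelling_index=idx,
                        item=item,
                        rater_id=f"r{j:03d}",
                        score=float(raw[j]),
                        scale_min=rp.scale_min,
                        scale_max=rp.scale_max,
                    )
                )
    return records
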