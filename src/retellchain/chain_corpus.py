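"""Data model, readers/writers, and validation for retelling chains and ratings.

A *chain* is one original story (retelling index 0) plus three ordered
retellings (indices 1-3) produced either by human participants or by an
LLM account. Ratings attach slider scores for four affect items to
individual story versions.

Canonical on-disk schema (CSV or JSONL):

* corpus rows: ``chain_id, retelling_index, producer, condition, text``
* rating rows: ``chain_id, retelling_index, item, rater_id, score,
  scale_min, scale_max``
"""

from __future__ import annotations

import csv
import io
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PRODUCERS",
    "CONDITIONS",
    "RATING_ITEMS",
    "StoryVersion",
    "Chain",
    "RatingRecord",
    "SchemaError",
    "CorpusValidationError",
    "load_corpus",
    "write_corpus",
    "load_ratings",
    "write_ratings",
    "validate_chain",
    "validate_corpus",
]

PRODUCERS = ("human", "llm")
CONDITIONS = ("happy", "mildly_happy", "mildly_sad", "sad")
RATING_ITEMS = ("happiness", "sadness", "picture", "affected")

N_VERSIONS = 4
MIN_RETELLING_CHARS = 60

CORPUS_COLUMNS = ("chain_id", "retelling_index", "producer", "condition", "text")
RATING_COLUMNS = (
    "chain_id",
    "retelling_index",
    "item",
    "rater_id",
    "score",
    "scale_min",
    "scale_max",
)

# Typographic characters normalized to ASCII before any annotation.
_CHAR_MAP = str.maketrans(
    {
        "‘": "'",
        "’": "'",
        "“": '"',
        "”": '"',
        "–": "-",
        "—": "-",
        "…": "...",
        " ": " ",
    }
)


class SchemaError(ValueError):
    """A required column is missing or a field value is malformed."""


class CorpusValidationError(ValueError):
    """A chain or rating violates a structural invariant."""


def normalize_text(text: str) -> str:
    """Map smart quotes/dashes/ligatures to ASCII equivalents (NFKC first)."""
    return unicodedata.normalize("NFKC", text).translate(_CHAR_MAP)


@dataclass(frozen=True)
class StoryVersion:
    """One story version inside a chain."""

    chain_id: str
    retelling_index: int
    producer: str
    condition: str
    text: str

    def __post_init__(self) -> None:
        if self.retelling_index not in (0, 1, 2, 3):
            raise CorpusValidationError(
                f"retelling_index must be 0-3, got {self.retelling_index!r} "
                f"(chain {self.chain_id})"
            )
        if self.producer not in PRODUCERS:
            raise SchemaError(f"unknown producer {self.producer!r} (chain {self.chain_id})")
        if self.condition not in CONDITIONS:
            raise SchemaError(f"unknown condition {self.condition!r} (chain {self.chain_id})")


@dataclass(frozen=True)
class Chain:
    """An original story plus its three ordered retellings."""

    chain_id: str
    condition: str
    producer: str
    versions: tuple[StoryVersion, ...]

    def __post_init__(self) -> None:
        indices = [v.retelling_index for v in self.versions]
        if indices != list(range(N_VERSIONS)):
            raise CorpusValidationError(
                f"chain {self.chain_id!r}: expected retelling indices 0..3, got {indices}"
            )
        for v in self.versions:
            if v.chain_id != self.chain_id or v.condition != self.condition:
                raise CorpusValidationError(
                    f"chain {self.chain_id!r}: version {v.retelling_index} has "
                    f"mismatched chain_id/condition"
                )

    @property
    def original(self) -> StoryVersion:
        return self.versions[0]

    @property
    def retellings(self) -> tuple[StoryVersion, ...]:
        return self.versions[1:]


@dataclass(frozen=True)
class RatingRecord:
    """One rater's score for one affect item on one story version."""

    chain_id: str
    retelling_index: int
    item: str
    rater_id: str
    score: float
    scale_min: float = 0.0
    scale_max: float = 100.0

    def __post_init__(self) -> None:
        if self.item not in RATING_ITEMS:
            raise SchemaError(f"unknown rating item {self.item!r}")
        if not (self.scale_min <= self.score <= self.scale_max):
            raise CorpusValidationError(
                f"score {self.score} outside scale [{self.scale_min}, {self.scale_max}] "
                f"(chain {self.chain_id}, item {self.item})"
            )


def _read_rows(path: str | Path, fmt: str | None) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "csv"
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            return [dict(row) for row in reader]
    if fmt == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        return rows
    raise ValueError(f"unknown format {fmt!r}")


def _require_columns(rows: Sequence[dict], required: Sequence[str], what: str) -> None:
    if not rows:
        return
    missing = [c for c in required if c not in rows[0]]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def load_corpus(path: str | Path, format: str | None = None) -> list[Chain]:
    """Load and validate a chain corpus from CSV or JSONL.

    Rows are grouped by ``chain_id``; output is deterministically ordered
    by chain_id then retelling_index regardless of input row order.
    """
    rows = _read_rows(path, format)
    _require_columns(rows, CORPUS_COLUMNS, f"corpus file {path}")
    by_chain: dict[str, list[StoryVersion]] = {}
    for row in rows:
        try:
            idx = int(row["retelling_index"])
        except (TypeError, ValueError):
            raise SchemaError(
                f"non-integer retelling_index {row.get('retelling_index')!r} "
                f"in chain {row.get('chain_id')!r}"
            ) from None
        version = StoryVersion(
            chain_id=str(row["chain_id"]),
            retelling_index=idx,
            producer=str(row["producer"]),
            condition=str(row["condition"]),
            text=normalize_text(str(row["text"])),
        )
        by_chain.setdefault(version.chain_id, []).append(version)

    chains: list[Chain] = []
    bad: list[str] = []
    for chain_id in sorted(by_chain):
        versions = sorted(by_chain[chain_id], key=lambda v: v.retelling_index)
        indices = [v.retelling_index for v in versions]
        if indices != list(range(N_VERSIONS)):
            bad.append(chain_id)
            continue
        chains.append(
            Chain(
                chain_id=chain_id,
                condition=versions[0].condition,
                producer=versions[0].producer,
                versions=tuple(versions),
            )
        )
    if bad:
        raise CorpusValidationError(
            "chain(s) without exactly one version per index 0-3: " + ", ".join(bad)
        )
    return chains


def write_corpus(chains: Iterable[Chain], path: str | Path) -> None:
    """Serialize chains to the canonical CSV form (sorted, UTF-8, '\\n' EOL)."""
    ordered = sorted(chains, key=lambda c: c.chain_id)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CORPUS_COLUMNS)
    for chain in ordered:
        for v in chain.versions:
            writer.writerow(
                [v.chain_id, v.retelling_index, v.producer, v.condition, v.text]
            )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def load_ratings(path: str | Path) -> list[RatingRecord]:
    """Load rating records; scores coerced to float, out-of-range rejected."""
    rows = _read_rows(path, None)
    _require_columns(rows, RATING_COLUMNS[:5], f"ratings file {path}")
    records = []
    for row in rows:
        try:
            score = float(row["score"])
        except (TypeError, ValueError):
            raise SchemaError(f"non-numeric score {row.get('score')!r}") from None
        records.append(
            RatingRecord(
                chain_id=str(row["chain_id"]),
                retelling_index=int(row["retelling_index"]),
                item=str(row["item"]),
                rater_id=str(row["rater_id"]),
                score=score,
                scale_min=float(row.get("scale_min", 0.0) or 0.0),
                scale_max=float(row.get("scale_max", 100.0) or 100.0),
            )
        )
    records.sort(key=lambda r: (r.chain_id, r.retelling_index, r.item, r.rater_id))
    return records


def write_ratings(records: Iterable[RatingRecord], path: str | Path) -> None:
    ordered = sorted(
        records, key=lambda r: (r.chain_id, r.retelling_index, r.item, r.rater_id)
    )
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(RATING_COLUMNS)
    for r in ordered:
        writer.writerow(
            [
                r.chain_id,
                r.retelling_index,
                r.item,
                r.rater_id,
                _fmt_num(r.score),
                _fmt_num(r.scale_min),
                _fmt_num(r.scale_max),
            ]
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def validate_chain(
    chain: Chain,
    lexicon: set[str] | None = None,
    gibberish_threshold: float = 0.5,
) -> list[str]:
    """Return a list of human-readable issues; empty iff the chain is clean.

    Structural violations (empty text, too-short retellings) are errors.
    A low in-lexicon token fraction is reported as a gibberish *warning*,
    mirroring the corpus-curation rule of excluding defective stories.
    """
    issues: list[str] = []
    for v in chain.versions:
        if not v.text.strip():
            issues.append(f"chain {chain.chain_id}: empty text at index {v.retelling_index}")
            continue
        if v.retelling_index > 0 and len(v.text.strip()) < MIN_RETELLING_CHARS:
            issues.append(
                f"chain {chain.chain_id}: text shorter than {MIN_RETELLING_CHARS} "
                f"characters at index {v.retelling_index}"
            )
        if lexicon:
            tokens = [t.lower() for t in v.text.split() if any(ch.isalpha() for ch in t)]
            tokens = [t.strip(".,!?;:\"'()") for t in tokens]
            tokens = [t for t in tokens if t]
            if tokens:
                frac = sum(t in lexicon for t in tokens) / len(tokens)
                if frac < gibberish_threshold:
                    issues.append(
                        f"chain {chain.chain_id}: warning: possible gibberish at index "
                        f"{v.retelling_index} (in-lexicon fraction {frac:.2f} < "
                        f"{gibberish_threshold})"
                    )
    return issues


def validate_corpus(
    chains: Iterable[Chain],
    lexicon: set[str] | None = None,
    gibberish_threshold: float = 0.5,
) -> list[str]:
    issues = []
    for chain in chains:
        issues.extend(validate_chain(chain, lexicon, gibberish_threshold))
    return issues
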