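"""Psycholinguistic norm merging, word-preservation coding, and the
preservation / story-mean age-of-acquisition analyses.

A word type from a parent story is *preserved* when its lemma occurs in the
immediately following retelling. Preservation is modelled with a logistic
regression on standardized norms (age of acquisition, frequency, length,
concreteness, valence) with an effect-coded producer term and a
producer x AOA interaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotate import StoryAnnotation

__all__ = [
    "NORM_NAMES",
    "NormEntry",
    "NormTable",
    "PreservationRecord",
    "load_norms",
    "load_norm_table",
    "code_preservation",
    "fit_preservation_model",
    "story_mean_aoa",
    "PerfectSeparationError",
]

logger = logging.getLogger(__name__)

NORM_NAMES = ("aoa", "concreteness", "valence", "arousal", "frequency")

# producer effect coding: mean of the two groups is the grand intercept and
# the interaction coefficient is the full human-llm slope difference
PRODUCER_CODE = {"human": 0.5, "llm": -0.5}


class PerfectSeparationError(RuntimeError):
    """Raised when the logistic fit is degenerate; suggests penalization."""


@dataclass(frozen=True)
class NormEntry:
    word: str
    aoa: float | None = None
    concreteness: float | None = None
    valence: float | None = None
    arousal: float | None = None
    frequency: float | None = None

    @property
    def length(self) -> int:
        return len(self.word)


class NormTable:
    """Lemma-keyed norm lookup built from one or more value tables."""

    def __init__(self, frame: pd.DataFrame):
        if "word" not in frame.columns:
            raise ValueError("norm table requires a 'word' column")
        self._frame = frame.set_index("word") if frame.index.name != "word" else frame

    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, word: str) -> bool:
        return word in self._frame.index

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def get(self, word: str) -> NormEntry | None:
        if word not in self._frame.index:
            return None
        row = self._frame.loc[word]
        kwargs = {}
        for name in NORM_NAMES:
            if name in row.index:
                value = row[name]
                kwargs[name] = None if pd.isna(value) else float(value)
        return NormEntry(word=word, **kwargs)

    def value(self, word: str, norm: str) -> float | None:
        if norm not in self._frame.columns or word not in self._frame.index:
            return None
        v = self._frame.loc[word, norm]
        return None if pd.isna(v) else float(v)

    def coverage(self, words: Iterable[str], norm: str = "aoa") -> float:
        words = list(words)
        if not words:
            return 0.0
        return sum(self.value(w, norm) is not None for w in words) / len(words)


def _read_norm_file(path: str | Path, value_name: str) -> pd.DataFrame:
    """Read a (word, value[, ...]) CSV; also accepts the Kuperman-style
    layout (Word, Rating.Mean) by a named preset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "word" in cols and value_name in cols:
        sub = frame[[cols["word"], cols[value_name]]]
    elif "word" in cols and "rating.mean" in cols:  # Kuperman layout
        sub = frame[[cols["word"], cols["rating.mean"]]]
    elif "word" in cols and "value" in cols:
        sub = frame[[cols["word"], cols["value"]]]
    elif len(frame.columns) >= 2 and "word" in cols:
        other = [c for c in frame.columns if c != cols["word"]][0]
        sub = frame[[cols["word"], other]]
    else:
        raise ValueError(f"{path}: expected columns word + value")
    sub = sub.copy()
    sub.columns = ["word", value_name]
    bad = pd.to_numeric(sub[value_name], errors="coerce").isna() & sub[value_name].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.values)[0]) + 2  # header is line 1
        raise ValueError(
            f"{path}: non-numeric value {sub[value_name][bad].iloc[0]!r} at line {line}"
        )
    sub[value_name] = pd.to_numeric(sub[value_name])
    sub["word"] = sub["word"].astype(str).str.lower()
    # duplicate words resolved by mean
    return sub.groupby("word", as_index=False)[value_name].mean()


def load_norms(paths: Mapping[str, str | Path]) -> NormTable:
    """Merge one file per norm name into a single lemma-keyed table."""
    merged: pd.DataFrame | None = None
    for name, path in paths.items():
        if name not in NORM_NAMES:
            raise ValueError(f"unknown norm name {name!r}; expected one of {NORM_NAMES}")
        table = _read_norm_file(path, name)
        merged = table if merged is None else merged.merge(table, on="word", how="outer")
    if merged is None:
        merged = pd.DataFrame({"word": []})
    return NormTable(merged)


def load_norm_table(path: str | Path) -> NormTable:
    """Load a single wide CSV holding several norm columns at once."""
    frame = pd.read_csv(path)
    frame.columns = [c.lower() for c in frame.columns]
    frame["word"] = frame["word"].astype(str).str.lower()
    agg = {c: "mean" for c in frame.columns if c != "word"}
    return NormTable(frame.groupby("word", as_index=False).agg(agg))


def fixture_norms() -> NormTable:
    ref = resources.files("retellchain.data").joinpath("toy_norms.csv")
    with resources.as_file(ref) as path:
        return load_norm_table(path)


@dataclass(frozen=True)
class PreservationRecord:
    chain_id: str
    transition: int  # child retelling index
    producer: str
    word: str
    preserved: bool
    norms: NormEntry | None = None


def code_preservation(
    parent: StoryAnnotation,
    child: StoryAnnotation,
    norms: NormTable | None = None,
    chain_id: str = "",
    transition: int = 1,
    producer: str = "human",
    unit: str = "type",
) -> list[PreservationRecord]:
    """One record per distinct parent lemma type (or per token with
    ``unit='token'``); preserved iff the lemma occurs in the child."""
    if parent.word_count == 0 or child.word_count == 0:
        raise ValueError("code_preservation requires non-empty annotations")
    if unit not in ("type", "token"):
        raise ValueError(f"unknown unit {unit!r}")
    child_lemmas = set(t.lemma for t in child.tokens)
    if unit == "type":
        parent_words: Sequence[str] = sorted(set(t.lemma for t in parent.tokens))
    else:
        parent_words = [t.lemma for t in parent.tokens]
    records = []
    for lemma in parent_words:
        entry = norms.get(lemma) if norms is not None else None
        records.append(
            PreservationRecord(
                chain_id=chain_id,
                transition=transition,
                producer=producer,
                word=lemma,
                preserved=lemma in child_lemmas,
                norms=entry,
            )
        )
    return records


_PREDICTORS = ("aoa", "frequency", "length", "concreteness", "valence")


def preservation_frame(records: Iterable[PreservationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "chain_id": rec.chain_id,
            "transition": rec.transition,
            "producer": rec.producer,
            "word": rec.word,
            "preserved": int(rec.preserved),
        }
        if rec.norms is not None:
            for name in ("aoa", "concreteness", "valence", "arousal", "frequency"):
                row[name] = getattr(rec.norms, name)
            row["length"] = rec.norms.length
        rows.append(row)
    return pd.DataFrame(rows)


def fit_preservation_model(
    records: Iterable[PreservationRecord] | pd.DataFrame,
    predictors: Sequence[str] = _PREDICTORS,
) -> pd.DataFrame:
    """Logistic regression of preservation on standardized norms.

    Model: preserved ~ producer + z(predictors) + producer:z(aoa), producer
    effect-coded (human +0.5, llm -0.5). Returns a coefficient table with
    estimates, standard errors, Wald z and p-values, and 95% CI bounds.
    """
    frame = (
        records.copy()
        if isinstance(records, pd.DataFrame)
        else preservation_frame(records)
    )
    producers = set(frame["producer"])
    if not producers >= {"human", "llm"}:
        raise ValueError("records from both producers are required")
    cols = ["preserved", "producer", *predictors]
    data = frame[cols].dropna()
    dropped = len(frame) - len(data)
    if dropped:
        logger.info("fit_preservation_model: dropped %d rows lacking norms", dropped)
    n_params = len(predictors) + 3
    if len(data) < 10 * (n_params - 1):
        raise ValueError(
            f"too few complete-case rows ({len(data)}) for {n_params} parameters"
        )
    X = pd.DataFrame(index=data.index)
    X["intercept"] = 1.0
    X["producer"] = data["producer"].map(PRODUCER_CODE)
    for name in predictors:
        col = data[name].astype(float)
        sd = col.std(ddof=1)
        X[name] = 0.0 if sd == 0 else (col - col.mean()) / sd
    X["producer:aoa"] = X["producer"] * X["aoa"]
    y = data["preserved"].astype(float)
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels raises variably
        raise PerfectSeparationError(
            f"logistic fit failed ({exc}); consider a penalized fit"
        ) from exc
    if not np.all(np.isfinite(fit.bse)):
        raise PerfectSeparationError(
            "non-finite standard errors (likely separation); "
            "consider a penalized fit"
        )
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "z": fit.tvalues,
            "p": fit.pvalues,
            "ci_low": fit.conf_int()[0],
            "ci_high": fit.conf_int()[1],
        }
    )
    table.index.name = "term"
    table.attrs["n"] = int(len(data))
    table.attrs["dropped"] = int(dropped)
    return table


def story_mean_aoa(
    annotation: StoryAnnotation, norms: NormTable
) -> tuple[float, float]:
    """Token-level mean AOA of a story and the covered-token fraction.

    Repeated words count repeatedly; tokens without an AOA norm are
    excluded from the mean but reflected in the coverage fraction.
    """
    if annotation.word_count == 0:
        raise ValueError("story_mean_aoa undefined for an empty story")
    values = []
    for token in annotation.tokens:
        v = norms.value(token.lemma, "aoa")
        if v is not None:
            values.append(v)
    if not values:
        raise ValueError("story_mean_aoa undefined: no tokens with an AOA norm")
    return float(np.mean(values)), len(values) / annotation.word_count
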