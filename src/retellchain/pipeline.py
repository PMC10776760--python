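"""End-to-end orchestration: validate -> annotate -> concepts -> norms ->
stats -> trend, with per-stage CSV/JSON outputs and a summary report that
records seeds, versions, and a config hash."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, affect_trend, annotate, concepts, lexical_norms
from . import chain_corpus, synthetic_data, transmission_stats

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_all", "load_config"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    corpus: str
    out_dir: str
    ratings: str | None = None
    inventory: str | None = None  # JSON sense inventory; default: packaged toy
    norms: str | None = None  # wide CSV; default: packaged toy norms
    sim_lexicon: str | None = None  # registers generated wordforms with the tagger
    gibberish_threshold: float = 0.5
    level: str = "synset"
    rating_item: str = "happiness"
    seed: int = 0
    mcmc_chains: int = 4
    mcmc_draws: int = 2000
    mcmc_warmup: int = 2000
    run_trend: bool = True
    run_stats: bool = True

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Flat ``key = value`` config file."""
    values: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        values[key] = value
    kwargs: dict = {}
    for f, typ in (
        ("corpus", str), ("out_dir", str), ("ratings", str), ("inventory", str),
        ("norms", str), ("sim_lexicon", str), ("gibberish_threshold", float),
        ("level", str), ("rating_item", str), ("seed", int),
        ("mcmc_chains", int), ("mcmc_draws", int), ("mcmc_warmup", int),
    ):
        if f in values:
            kwargs[f] = typ(values[f])
    for f in ("run_trend", "run_stats"):
        if f in values:
            kwargs[f] = values[f].lower() in ("1", "true", "yes")
    unknown = set(values) - set(kwargs)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**kwargs)


def _annotation_table(chains, extra_lexicon) -> tuple[pd.DataFrame, dict]:
    rows = []
    annotations = {}
    for chain in chains:
        for v in chain.versions:
            ann = annotate.annotate_story(v.text, extra_lexicon)
            annotations[(chain.chain_id, v.retelling_index)] = ann
            row = {
                "chain_id": chain.chain_id,
                "retelling_index": v.retelling_index,
                "producer": chain.producer,
                "condition": chain.condition,
                "word_count": ann.word_count,
            }
            row.update(ann.category_counts)
            rows.append(row)
    return pd.DataFrame(rows), annotations


def run_all(config: RunConfig) -> dict:
    """Execute every stage; any failure aborts with the stage name while
    retaining the outputs already written."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }

    stage = "validate"
    try:
        chains = chain_corpus.load_corpus(config.corpus)
        inventory = (
            concepts.SenseInventory.from_json(config.inventory)
            if config.inventory
            else concepts.SenseInventory.fixture()
        )
        from ._tagger import KNOWN_WORDS

        issues = chain_corpus.validate_corpus(
            chains, inventory.lemma_set | set(KNOWN_WORDS), config.gibberish_threshold
        )
        (out / "validation.json").write_text(
            json.dumps({"n_chains": len(chains), "issues": issues}, indent=1)
        )
        hard = [i for i in issues if "warning" not in i]
        if hard:
            raise chain_corpus.CorpusValidationError("; ".join(hard[:10]))
        summary["stages"][stage] = {"n_chains": len(chains), "n_issues": len(issues)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "annotate"
    try:
        extra = None
        if config.sim_lexicon:
            extra = synthetic_data.SimLexicon.read(
                Path(config.sim_lexicon).parent
            ).extra_tagger_lexicon()
        story_table, annotations = _annotation_table(chains, extra)
        story_table.to_csv(out / "annotations.csv", index=False)
        summary["stages"][stage] = {"n_stories": len(story_table)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "concepts"
    try:
        metric_rows = []
        for chain in chains:
            for level in concepts.LEVELS:
                for m in concepts.chain_metrics(chain, level, inventory, extra):
                    metric_rows.append(
                        {
                            "chain_id": m.chain_id,
                            "producer": chain.producer,
                            "condition": chain.condition,
                            "level": m.level,
                            "parent_index": m.parent_index,
                            "child_index": m.child_index,
                            "survival": m.survival,
                            "novelty": m.novelty,
                            "child_count": m.child_count,
                            "child_density": m.child_density,
                        }
                    )
        metrics = pd.DataFrame(metric_rows)
        metrics.to_csv(out / "transition_metrics.csv", index=False)
        by = (
            metrics.groupby(["producer", "level", "child_index"])[
                ["survival", "novelty", "child_density"]
            ]
            .mean()
            .reset_index()
        )
        summary["stages"][stage] = {
            "means": by.to_dict(orient="records"),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "norms"
    try:
        norms = (
            lexical_norms.load_norm_table(config.norms)
            if config.norms
            else lexical_norms.fixture_norms()
        )
        records = []
        aoa_rows = []
        for chain in chains:
            for r in range(1, 4):
                parent = annotations[(chain.chain_id, r - 1)]
                child = annotations[(chain.chain_id, r)]
                records.extend(
                    lexical_norms.code_preservation(
                        parent, child, norms, chain.chain_id, r, chain.producer
                    )
                )
            for r in range(4):
                ann = annotations[(chain.chain_id, r)]
                try:
                    mean_aoa, coverage = lexical_norms.story_mean_aoa(ann, norms)
                except ValueError:
                    mean_aoa, coverage = float("nan"), 0.0
                aoa_rows.append(
                    {
                        "chain_id": chain.chain_id,
                        "producer": chain.producer,
                        "retelling_index": r,
                        "mean_aoa": mean_aoa,
                        "coverage": coverage,
                    }
                )
        pres_frame = lexical_norms.preservation_frame(records)
        pres_frame.to_csv(out / "preservation.csv", index=False)
        pd.DataFrame(aoa_rows).to_csv(out / "story_mean_aoa.csv", index=False)
        stage_summary = {"n_records": len(pres_frame)}
        if {"human", "llm"} <= set(pres_frame["producer"]):
            try:
                coef = lexical_norms.fit_preservation_model(records)
                coef.to_csv(out / "preservation_model.csv")
                stage_summary["aoa_coefficient"] = float(coef.loc["aoa", "estimate"])
                stage_summary["aoa_p"] = float(coef.loc["aoa", "p"])
                stage_summary["interaction_p"] = float(coef.loc["producer:aoa", "p"])
            except ValueError as exc:
                stage_summary["preservation_model"] = f"skipped: {exc}"
        summary["stages"][stage] = stage_summary
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "stats"
    if config.run_stats:
        try:
            trend_rows = story_table[story_table["retelling_index"].isin([1, 2, 3])]
            stats_summary = {}
            if {"human", "llm"} <= set(trend_rows["producer"]):
                wc = transmission_stats.fit_wordcount_trend(trend_rows)
                stats_summary["wordcount"] = {
                    "slope_human": wc.coef("slope_human"),
                    "slope_llm": wc.coef("slope_llm"),
                    "slope_diff_p": wc.contrasts["slope_human_minus_llm"]["p"],
                    "dispersions": wc.dispersions,
                }
                neg = trend_rows.rename(columns={"negation": "count"})
                contrast = transmission_stats.negation_condition_contrast(neg)
                stats_summary["negation_condition"] = {
                    "pooled": contrast.extras["pooled_proportions"],
                    "interaction_p": contrast.contrasts["interaction"]["p"],
                }
                for category in ("verb", "noun", "negation"):
                    cat = trend_rows.rename(columns={category: "count"})
                    fit = transmission_stats.fit_pos_trend(cat, category)
                    stats_summary[f"pos_{category}"] = {
                        "producer_contrast": fit.contrasts[
                            "producer_human_minus_llm"
                        ]["estimate"],
                        "p": fit.contrasts["producer_human_minus_llm"]["p"],
                        "family": fit.family,
                    }
            else:
                stats_summary["skipped"] = "needs both producers"
            (out / "stats.json").write_text(json.dumps(stats_summary, indent=1))
            summary["stages"][stage] = stats_summary
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "trend"
    if config.run_trend and config.ratings:
        try:
            ratings = chain_corpus.load_ratings(config.ratings)
            data = affect_trend.standardize_ratings(ratings, config.rating_item)
            fit = affect_trend.fit_trend(
                data,
                chains=config.mcmc_chains,
                draws=config.mcmc_draws,
                warmup=config.mcmc_warmup,
                seed=config.seed,
            )
            (out / "trend_fit.json").write_text(
                json.dumps(
                    {
                        "summaries": fit.summaries,
                        "rope_decisions": fit.rope_decisions,
                        "diagnostics": fit.diagnostics,
                    },
                    indent=1,
                )
            )
            fit.spine_prediction().to_csv(out / "trend_spine.csv", index=False)
            draws = pd.DataFrame(
                {name: arr.reshape(-1) for name, arr in fit.posterior.items()}
            )
            draws.to_csv(out / "trend_draws.csv", index=False)
            summary["stages"][stage] = {
                "rope_decisions": fit.rope_decisions,
                "slope_median": fit.summaries["beta1"]["median"],
                "gamma_median": fit.summaries["gamma"]["median"],
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
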