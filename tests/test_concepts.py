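import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retellchain import synthetic_data as sd
from retellchain.annotate import annotate_story
from retellchain.chain_corpus import Chain, StoryVersion
from retellchain.concepts import (
    ConceptSet,
    chain_metrics,
    disambiguate,
    extract_concepts,
    novelty_rate,
    survival_rate,
)


def make_set(ids, level="synset"):
    return ConceptSet(level=level, ids=frozenset(ids), source_word_count=len(ids))


class TestExtractConcepts:
    def test_empty_annotation(self, inventory):
        cs = extract_concepts(annotate_story(""), "synset", inventory)
        assert cs.ids == frozenset()

    def test_deduplication_at_every_level(self, inventory):
        ann = annotate_story("dog dog dog")
        for level in ("synset", "lemma", "root_hypernym"):
            assert len(extract_concepts(ann, level, inventory).ids) == 1

    def test_riparian_bank_sense_selected(self, inventory):
        ann = annotate_story("he sat by the river bank")
        cs = extract_concepts(ann, "synset", inventory)
        assert "bank.n.02" in cs.ids and "bank.n.01" not in cs.ids

    def test_lesk_oracle_hand_computed(self, inventory):
        # context for "bank" = {he, sit, by, the, river}; gloss overlaps:
        # bank.n.01 "...institution...money...loans" -> 0
        # bank.n.02 "...land beside a body of water such as a river..." -> 1
        context = frozenset(t.lemma for t in annotate_story("he sat by the river bank").tokens)
        sense = disambiguate("bank", "n", context - {"bank"}, inventory)
        scores = {
            s.id: len((s.gloss_words() | set(s.lemmas)) & (context - {"bank"}))
            for s in inventory.senses("bank", "n")
        }
        assert scores["bank.n.02"] > scores["bank.n.01"]
        assert sense.id == "bank.n.02"

    def test_financial_bank_sense_selected(self, inventory):
        ann = annotate_story("she took her money to the bank for a deposit")
        cs = extract_concepts(ann, "synset", inventory)
        assert "bank.n.01" in cs.ids

    def test_first_sense_tie_break(self, inventory):
        # no disambiguating context: first-listed (financial) sense wins
        sense = disambiguate("bank", "n", frozenset(), inventory)
        assert sense.id == "bank.n.01"

    def test_root_hypernym_level(self, inventory):
        ann = annotate_story("the apple")
        cs = extract_concepts(ann, "root_hypernym", inventory)
        assert cs.ids == frozenset({"entity.n.01"})

    def test_fruit_and_apple_share_root(self, inventory):
        a = extract_concepts(annotate_story("an apple"), "root_hypernym", inventory)
        b = extract_concepts(annotate_story("the fruit"), "root_hypernym", inventory)
        assert a.ids == b.ids

    def test_unknown_level_errors(self, inventory):
        with pytest.raises(ValueError, match="unknown level"):
            extract_concepts(annotate_story("dog"), "frame", inventory)

    def test_coverage_counts_skipped_tokens(self, inventory):
        ann = annotate_story("the dog zorped")  # "zorp" not in the inventory
        cs = extract_concepts(ann, "synset", inventory)
        assert cs.content_tokens == 2
        assert cs.covered_tokens == 1
        assert cs.coverage == pytest.approx(0.5)

    def test_function_words_never_enter(self, inventory):
        ann = annotate_story("the of and it they by")
        assert extract_concepts(ann, "synset", inventory).ids == frozenset()


class TestRates:
    def test_identical_sets(self):
        p = make_set({"a", "b"})
        assert survival_rate(p, p) == 1.0
        assert novelty_rate(p, p) == 0.0

    def test_disjoint_sets(self):
        p, c = make_set({"a", "b"}), make_set({"x", "y"})
        assert survival_rate(p, c) == 0.0
        assert novelty_rate(p, c) == 1.0

    def test_half_survival(self):
        p = make_set({"a", "b", "c", "d"})
        c = make_set({"a", "b", "x"})
        assert survival_rate(p, c) == 0.5

    def test_subset_child_zero_novelty(self):
        assert novelty_rate(make_set({"a", "b", "c"}), make_set({"a"})) == 0.0

    def test_empty_parent_errors(self):
        with pytest.raises(ValueError):
            survival_rate(make_set(set()), make_set({"a"}))

    def test_empty_child_errors(self):
        with pytest.raises(ValueError):
            novelty_rate(make_set({"a"}), make_set(set()))

    def test_level_mismatch_errors(self):
        with pytest.raises(ValueError, match="level mismatch"):
            survival_rate(make_set({"a"}, "synset"), make_set({"a"}, "lemma"))

    @given(
        st.sets(st.integers(0, 30), min_size=1, max_size=20),
        st.sets(st.integers(0, 30), min_size=1, max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_complement_properties(self, parent, child):
        p = make_set({str(i) for i in parent})
        c = make_set({str(i) for i in child})
        s = survival_rate(p, c)
        n = novelty_rate(p, c)
        # conservation: survived + lost = all parent concepts
        assert s * len(p.ids) + len(p.ids - c.ids) == pytest.approx(len(p.ids))
        # novelty complement identity
        assert n == pytest.approx(1 - len(c.ids & p.ids) / len(c.ids))
        assert 0.0 <= s <= 1.0 and 0.0 <= n <= 1.0


def _chain_from_texts(texts, chain_id="c1"):
    return Chain(
        chain_id=chain_id,
        condition="happy",
        producer="human",
        versions=tuple(
            StoryVersion(chain_id, i, "human", "happy", t) for i, t in enumerate(texts)
        ),
    )


class TestChainMetrics:
    def test_identical_texts(self, inventory):
        text = "the dog ran to the river and the man watched the bird " * 2
        metrics = chain_metrics(_chain_from_texts([text] * 4), "synset", inventory)
        assert len(metrics) == 3
        for m in metrics:
            assert m.survival == 1.0
            assert m.novelty == 0.0

    def test_disjoint_content(self, inventory):
        texts = [
            "the dog saw the cat and the dog ran fast to the yard...!",
            "a man met his wife in the town and they walked to a house",
            "the apple fell from the tree into the water with the fruit",
            "the story was sad and the word was old and they felt sorrow",
        ]
        metrics = chain_metrics(_chain_from_texts(texts), "synset", inventory)
        for m in metrics:
            assert m.survival == 0.0
            assert m.novelty == 1.0

    def test_token_order_permutation_invariance(self, inventory):
        t1 = "the dog ran to the river and the man watched the bird flying"
        words = t1.split()
        t2 = " ".join(reversed(words))
        a = extract_concepts(annotate_story(t1), "lemma", inventory)
        b = extract_concepts(annotate_story(t2), "lemma", inventory)
        assert a.ids == b.ids

    def test_density_is_count_over_words(self, inventory):
        metrics = chain_metrics(
            _chain_from_texts(["the dog saw the cat and it ran away to the tree"] * 4),
            "synset",
            inventory,
        )
        m = metrics[0]
        assert m.child_density == pytest.approx(m.child_count / m.child_word_count)

    def test_simulated_ground_truth_exact(self, sim_lexicon, human_params):
        chain, truth = sd.generate_chain(human_params, sim_lexicon, seed=11)
        inv = sim_lexicon.to_inventory()
        extra = sim_lexicon.extra_tagger_lexicon()
        for level, key in (("synset", "synsets"), ("lemma", "lemmas"),
                           ("root_hypernym", "roots")):
            for m in chain_metrics(chain, level, inv, extra):
                parent = truth[key][m.parent_index]
                child = truth[key][m.child_index]
                # brute-force set algebra on the simulator's recorded truth
                assert m.survival == pytest.approx(len(parent & child) / len(parent))
                assert m.novelty == pytest.approx(len(child - parent) / len(child))

    def test_ancestors_baseline_never_increases_novelty(self, sim_lexicon, human_params):
        chain, _ = sd.generate_chain(human_params, sim_lexicon, seed=12)
        inv = sim_lexicon.to_inventory()
        extra = sim_lexicon.extra_tagger_lexicon()
        parent = chain_metrics(chain, "synset", inv, extra, baseline="parent")
        ancestors = chain_metrics(chain, "synset", inv, extra, baseline="ancestors")
        for mp, ma in zip(parent, ancestors):
            assert ma.novelty <= mp.novelty + 1e-12


@pytest.mark.slow
def test_survival_converges_to_generating_p(sim_lexicon, human_params):
    # Monte-Carlo: estimated survival within 2 se of p_surv at n=200 chains
    params = sd.SimParams(**{**human_params.__dict__, "n_chains": 200})
    chains, truths = sd.generate_corpus(params, sim_lexicon, seed=21)
    inv = sim_lexicon.to_inventory()
    extra = sim_lexicon.extra_tagger_lexicon()
    values = [
        m.survival
        for chain in chains
        for m in chain_metrics(chain, "synset", inv, extra)
    ]
    mean = np.mean(values)
    se = np.std(values, ddof=1) / np.sqrt(len(values))
    assert abs(mean - params.p_surv) < 2 * se + 1e-9
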