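import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from retellchain import lexical_norms as ln
from retellchain import synthetic_data as sd
from retellchain.annotate import annotate_story


class TestLoadNorms:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "aoa.csv"
        path.write_text("word,value\n")
        table = ln.load_norms({"aoa": path})
        assert len(table) == 0

    def test_duplicate_words_resolved_by_mean(self, tmp_path):
        path = tmp_path / "aoa.csv"
        path.write_text("word,value\ncat,3.5\ncat,4.5\n")
        table = ln.load_norms({"aoa": path})
        assert table.value("cat", "aoa") == pytest.approx(4.0)

    def test_non_numeric_value_reports_line(self, tmp_path):
        path = tmp_path / "aoa.csv"
        path.write_text("word,value\ncat,3.5\ndog,oops\n")
        with pytest.raises(ValueError, match="line 3"):
            ln.load_norms({"aoa": path})

    def test_kuperman_layout_preset(self, tmp_path):
        path = tmp_path / "kuperman.csv"
        path.write_text("Word,Rating.Mean\nCat,3.5\n")
        table = ln.load_norms({"aoa": path})
        assert table.value("cat", "aoa") == pytest.approx(3.5)

    def test_unknown_norm_name_rejected(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text("word,value\ncat,1\n")
        with pytest.raises(ValueError, match="unknown norm"):
            ln.load_norms({"weirdness": path})

    def test_fixture_norms_cover_fixture_inventory(self, norms, inventory):
        assert norms.coverage(inventory.lemma_set, "aoa") == pytest.approx(1.0)


class TestCodePreservation:
    def test_identity_all_preserved(self):
        ann = annotate_story("the dog ran home")
        records = ln.code_preservation(ann, ann)
        assert records and all(r.preserved for r in records)

    def test_disjoint_none_preserved(self):
        parent = annotate_story("the dog ran home")
        child = annotate_story("a cat sat there")
        records = ln.code_preservation(parent, child)
        assert records and not any(r.preserved for r in records)

    def test_lemma_matching_running_ran(self):
        parent = annotate_story("he was running")
        child = annotate_story("he ran")
        records = {r.word: r.preserved for r in ln.code_preservation(parent, child)}
        assert records["run"] is True

    def test_one_record_per_type(self):
        parent = annotate_story("dog dog dog cat")
        records = ln.code_preservation(parent, annotate_story("dog"))
        assert sorted(r.word for r in records) == ["cat", "dog"]

    def test_token_unit_mode(self):
        parent = annotate_story("dog dog cat")
        records = ln.code_preservation(parent, annotate_story("dog"), unit="token")
        assert len(records) == 3

    def test_anti_monotone_under_child_deletion(self):
        parent = annotate_story("the dog ran to the river and the man watched")
        full_child = annotate_story("the dog ran to the river and the man watched")
        reduced_child = annotate_story("the dog ran")
        full = {r.word: r.preserved for r in ln.code_preservation(parent, full_child)}
        reduced = {
            r.word: r.preserved for r in ln.code_preservation(parent, reduced_child)
        }
        for word, flag in reduced.items():
            assert flag <= full[word]

    def test_empty_annotation_errors(self):
        ann = annotate_story("dog")
        with pytest.raises(ValueError):
            ln.code_preservation(ann, annotate_story(""))

    def test_norms_attached_when_available(self, norms):
        parent = annotate_story("the dog barked zorp")
        records = {r.word: r for r in ln.code_preservation(parent, parent, norms)}
        assert records["dog"].norms is not None
        assert records["zorp"].norms is None


def _simulate_records(n, aoa_slope, seed, producer_effect=0.0, interaction=0.0):
    rng = np.random.default_rng(seed)
    producer = np.where(rng.uniform(size=n) < 0.5, "human", "llm")
    code = np.where(producer == "human", 0.5, -0.5)
    cols = {k: rng.standard_normal(n) for k in
            ("aoa", "frequency", "length", "concreteness", "valence")}
    eta = (0.3 + aoa_slope * cols["aoa"] + producer_effect * code
           + interaction * code * cols["aoa"])
    preserved = rng.uniform(size=n) < expit(eta)
    return pd.DataFrame({"preserved": preserved.astype(int), "producer": producer, **cols})


class TestFitPreservationModel:
    def test_aoa_slope_recovery(self):
        frame = _simulate_records(5000, aoa_slope=-0.5, seed=42)
        table = ln.fit_preservation_model(frame)
        assert table.loc["aoa", "estimate"] == pytest.approx(-0.5, abs=0.1)

    def test_interaction_recovery(self):
        frame = _simulate_records(8000, aoa_slope=-0.3, seed=7, interaction=-0.6)
        table = ln.fit_preservation_model(frame)
        assert table.loc["producer:aoa", "estimate"] == pytest.approx(-0.6, abs=0.15)
        assert table.loc["producer:aoa", "p"] < 0.01

    def test_null_calibration_coverage(self):
        # 95% CI covers the true null in at least 90% of 50 replicates
        covered = 0
        for seed in range(50):
            frame = _simulate_records(800, aoa_slope=0.0, seed=seed)
            table = ln.fit_preservation_model(frame)
            if table.loc["aoa", "ci_low"] <= 0.0 <= table.loc["aoa", "ci_high"]:
                covered += 1
        assert covered >= 45

    def test_requires_both_producers(self):
        frame = _simulate_records(500, aoa_slope=0.0, seed=1)
        with pytest.raises(ValueError, match="both producers"):
            ln.fit_preservation_model(frame[frame["producer"] == "human"])

    def test_too_few_rows_errors(self):
        frame = _simulate_records(30, aoa_slope=0.0, seed=1)
        with pytest.raises(ValueError, match="too few"):
            ln.fit_preservation_model(frame)

    def test_rows_without_norms_dropped(self):
        frame = _simulate_records(600, aoa_slope=-0.5, seed=3)
        frame.loc[:49, "aoa"] = np.nan
        table = ln.fit_preservation_model(frame)
        assert table.attrs["dropped"] == 50
        assert table.attrs["n"] == 550

    def test_separation_raises_diagnostic(self):
        frame = _simulate_records(400, aoa_slope=0.0, seed=5)
        frame["preserved"] = (frame["aoa"] > 0).astype(int)  # perfect separation
        with pytest.raises(ln.PerfectSeparationError, match="penal"):
            ln.fit_preservation_model(frame)


class TestStoryMeanAoa:
    def _norms(self, mapping):
        return ln.NormTable(pd.DataFrame(
            {"word": list(mapping), "aoa": list(mapping.values())}
        ))

    def test_constant_aoa(self):
        ann = annotate_story("dog cat dog")
        norms = self._norms({"dog": 5.0, "cat": 5.0})
        mean, coverage = ln.story_mean_aoa(ann, norms)
        assert mean == 5.0 and coverage == 1.0

    def test_uncovered_tokens_excluded(self):
        ann = annotate_story("dog cat zorp")
        norms = self._norms({"dog": 4.0, "cat": 6.0})
        mean, coverage = ln.story_mean_aoa(ann, norms)
        assert mean == pytest.approx(5.0)
        assert coverage == pytest.approx(2 / 3)

    def test_tokens_not_types(self):
        ann = annotate_story("dog dog cat")
        norms = self._norms({"dog": 4.0, "cat": 7.0})
        mean, _ = ln.story_mean_aoa(ann, norms)
        assert mean == pytest.approx(5.0)  # (4+4+7)/3, not (4+7)/2

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError):
            ln.story_mean_aoa(annotate_story("zorp blarg"), self._norms({"dog": 4.0}))

    def test_order_invariance_and_shift_linearity(self):
        norms_a = self._norms({"dog": 4.0, "cat": 6.0, "tree": 8.0})
        norms_b = self._norms({"dog": 6.0, "cat": 8.0, "tree": 10.0})
        m1, _ = ln.story_mean_aoa(annotate_story("dog cat tree"), norms_a)
        m2, _ = ln.story_mean_aoa(annotate_story("tree dog cat"), norms_a)
        m3, _ = ln.story_mean_aoa(annotate_story("dog cat tree"), norms_b)
        assert m1 == m2
        assert m3 == pytest.approx(m1 + 2.0)

    def test_llm_profile_aoa_step_recovered(self):
        # all-fresh llm profile: the +1.5-year sampling tilt should appear
        # as a step increase in story-mean AOA from retelling 1 on. The
        # lexicon must dwarf the per-story draw, otherwise the
        # without-replacement sampling exhausts the pool and mutes the tilt.
        lexicon = sd.build_toy_lexicon(800, seed=2)
        params = sd.SimParams(
            producer="llm", p_surv=0.0, length_decay=1.0, p_syn=0.0,
            aoa_shift=1.5, n_chains=80, length0=20,
        )
        chains, _ = sd.generate_corpus(params, lexicon, seed=13)
        norms = lexicon.to_norms()
        sim_lexicon = lexicon
        base, later = [], []
        for chain in chains:
            for v in chain.versions:
                ann = annotate_story(v.text, sim_lexicon.extra_tagger_lexicon())
                mean, _cov = ln.story_mean_aoa(ann, norms)
                (base if v.retelling_index == 0 else later).append(mean)
        step = np.mean(later) - np.mean(base)
        assert step == pytest.approx(1.5, abs=0.2)
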