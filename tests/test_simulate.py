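import dataclasses

import numpy as np
import pandas as pd
import pytest

from rdocpheno import (
    generate_cohort,
    generate_lexicon,
    generate_notes,
    los_binary,
    make_stub_dictionary,
    prepare_document,
    score_corpus,
)
from rdocpheno.errors import ValidationError
from rdocpheno.simulate import GeneratorSpec, LosModel


def pipeline_scores(spec, lexicon, cohort, provider=None):
    notes = generate_notes(spec, lexicon, cohort)
    docs = [prepare_document(n, provider) for n in notes]
    vectors = score_corpus(docs, lexicon)
    return pd.DataFrame([{"admission_id": v.admission_id, **v.scores} for v in vectors])


class TestLexiconGeneration:
    def test_counts_and_uniqueness(self, small_spec):
        lex = generate_lexicon(small_spec)
        assert len(lex.domains) == 5
        all_terms = [t for d in lex.domains for t in lex.terms[d]]
        assert len(all_terms) == len(set(all_terms)) == 100

    def test_same_seed_identical(self, small_spec):
        assert generate_lexicon(small_spec) == generate_lexicon(small_spec)

    def test_domains_pairwise_disjoint_and_disjoint_from_filler(self, small_spec):
        lex = generate_lexicon(small_spec)
        seen = set()
        for d in lex.domains:
            assert not (lex.terms[d] & seen)
            seen |= lex.terms[d]
        filler = {f"filler{i}" for i in range(small_spec.filler_vocab_size)}
        tokens = {tok for t in seen for tok in t.split(" ")}
        assert not (tokens & filler)

    def test_two_word_fraction_one_makes_all_terms_phrases(self, small_spec):
        spec = dataclasses.replace(small_spec, two_word_fraction=1.0)
        lex = generate_lexicon(spec)
        assert all(" " in t for d in lex.domains for t in lex.terms[d])

    def test_oversized_lexicon_rejected(self, small_spec):
        with pytest.raises(ValidationError):
            generate_lexicon(dataclasses.replace(small_spec, n_domains=1000, terms_per_domain=1000))


class TestCohortGeneration:
    def test_default_spec_reproduces_study_shape(self):
        cohort, _ = generate_cohort(GeneratorSpec(seed=3))
        assert len(cohort) == 732
        assert cohort.df["patient_id"].nunique() == 571
        sizes = cohort.df["diagnosis"].value_counts()
        assert sizes["depression"] == 612 and sizes["schizophrenia"] == 83 and sizes["bipolar_disorder"] == 37

    def test_same_seed_byte_identical(self, small_spec):
        a, _ = generate_cohort(small_spec)
        b, _ = generate_cohort(small_spec)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_different_seed_differs(self, small_spec):
        a, _ = generate_cohort(small_spec)
        b, _ = generate_cohort(dataclasses.replace(small_spec, seed=small_spec.seed + 1))
        assert not a.df.equals(b.df)

    def test_los_respects_drawn_outcome_arm(self, small_spec):
        cohort, truth = generate_cohort(small_spec)
        los = cohort.df["los_days"].to_numpy()
        assert (los > 0).all()
        # every stay is strictly on one side of the threshold by construction
        assert set(los_binary(los, 3.0)) <= {0, 1}

    def test_null_outcome_model_gives_half_long_stays(self):
        spec = GeneratorSpec(
            seed=9,
            group_sizes={"depression": 5000},
            patients_per_group={"depression": 5000},
            terms_per_domain=10,
            los_model=LosModel(intercept=0.0, domain_coefs={}),
        )
        cohort, _ = generate_cohort(spec)
        frac = los_binary(cohort.df["los_days"].to_numpy(), 3.0).mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_infeasible_duration_model_rejected(self, small_spec):
        bad = LosModel(long_lognorm=(np.log(0.01), 0.05))  # no mass above 3 days
        with pytest.raises(ValidationError):
            generate_cohort(dataclasses.replace(small_spec, los_model=bad))


class TestNotes:
    def test_pipeline_scores_equal_cohort_scores_exactly(self, small_spec):
        lex = generate_lexicon(small_spec)
        cohort, _ = generate_cohort(small_spec)
        piped = pipeline_scores(small_spec, lex, cohort)
        merged = cohort.df.merge(piped, on="admission_id", suffixes=("_cohort", "_pipe"))
        for d in lex.domains:
            assert (merged[f"{d}_cohort"] == merged[f"{d}_pipe"]).all()

    def test_term_probs_zero_and_one_are_extreme_scores(self, small_spec):
        for p, expected in [(0.0, 0.0), (1.0, 1.0)]:
            probs = {g: {d: p for d in small_spec.domain_names()} for g in small_spec.groups()}
            spec = dataclasses.replace(small_spec, term_probs=probs)
            lex = generate_lexicon(spec)
            cohort, _ = generate_cohort(spec)
            piped = pipeline_scores(spec, lex, cohort)
            assert (piped[list(lex.domains)].to_numpy() == expected).all()

    def test_same_seed_identical_notes(self, small_spec):
        lex = generate_lexicon(small_spec)
        cohort, _ = generate_cohort(small_spec)
        a = generate_notes(small_spec, lex, cohort)
        b = generate_notes(small_spec, lex, cohort)
        assert a == b

    def test_bilingual_notes_need_the_stub_to_score(self, small_spec):
        spec = dataclasses.replace(small_spec, bilingual_fraction=1.0)
        lex = generate_lexicon(spec)
        cohort, _ = generate_cohort(spec)
        untranslated = pipeline_scores(spec, lex, cohort)
        assert (untranslated[list(lex.domains)].to_numpy() == 0.0).all()
        stub = make_stub_dictionary(spec, lex)
        translated = pipeline_scores(spec, lex, cohort, provider=stub)
        merged = cohort.df.merge(translated, on="admission_id", suffixes=("_c", "_p"))
        for d in lex.domains:
            assert (merged[f"{d}_c"] == merged[f"{d}_p"]).all()

    def test_mean_pipeline_score_near_inclusion_probability(self):
        p, m, n = 0.2, 20, 1200
        spec = GeneratorSpec(
            seed=21,
            group_sizes={"depression": n},
            patients_per_group={"depression": n},
            term_probs={"depression": {d: p for d in GeneratorSpec().domain_names()}},
            terms_per_domain=m,
            filler_vocab_size=50,
            note_filler_mean=20.0,
        )
        lex = generate_lexicon(spec)
        cohort, _ = generate_cohort(spec)
        piped = pipeline_scores(spec, lex, cohort)
        se = np.sqrt(p * (1 - p) / m / n)
        for d in lex.domains:
            assert abs(piped[d].mean() - p) < 3 * se


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"group_sizes": {"depression": 0}, "patients_per_group": {"depression": 1}},
            {"group_sizes": {"depression": 5}, "patients_per_group": {"depression": 9}},
            {"two_word_fraction": 1.5},
            {"term_probs": {"depression": {}}},
        ],
    )
    def test_bad_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            GeneratorSpec(seed=0, **kwargs).validate()
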