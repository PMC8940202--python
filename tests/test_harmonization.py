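"""Lexical/semantic matching, value standardization, and harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cohortlink as cl
from cohortlink.harmonization import HarmonizationConfig, HarmonizationError
from cohortlink.synthetic import DefectConfig, GeneratorConfig, PerturbationConfig

from conftest import make_table


def dp_levenshtein(a: str, b: str) -> int:
    """Independent quadratic dynamic-programming edit-distance oracle."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]


class TestNormalize:
    @pytest.mark.parametrize("raw,tokens", [
        ("Anti-La", ["anti", "la"]),
        ("  GENDER ", ["gender"]),
        ("salivary_gland-swelling", ["salivary", "gland", "swelling"]),
        ("", []),
    ])
    def test_examples(self, raw, tokens):
        assert cl.normalize(raw) == tokens

    @settings(derandomize=True, max_examples=100)
    @given(st.text(max_size=30))
    def test_idempotent_and_clean(self, s):
        once = cl.normalized_form(s)
        assert cl.normalized_form(once) == once
        assert once == once.lower().strip()


class TestLexicalSimilarity:
    def test_identity_empty_and_example(self):
        assert cl.lexical_similarity("lymphadenopathy",
                                     "lymphadenopathy") == 1.0
        assert cl.lexical_similarity("abc", "abd") == pytest.approx(
            2 / 3, abs=1e-4)
        assert cl.lexical_similarity("", "abc") == 0.0

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        letters = np.array(list("abcdefg "))
        for _ in range(1000):
            a = "".join(rng.choice(letters, rng.integers(1, 12)))
            b = "".join(rng.choice(letters, rng.integers(1, 12)))
            fa, fb = cl.normalized_form(a), cl.normalized_form(b)
            if not fa or not fb:
                expected = 0.0
            elif fa == fb:
                expected = 1.0
            else:
                expected = 1 - dp_levenshtein(fa, fb) / max(len(fa), len(fb))
            assert cl.lexical_similarity(a, b) == pytest.approx(
                expected, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.text(max_size=20), st.text(max_size=20))
    def test_symmetric_and_bounded(self, a, b):
        s = cl.lexical_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(cl.lexical_similarity(b, a))


class TestLexicalMatch:
    def test_exact_name_accepted(self, disease_corpus):
        m = cl.lexical_match(["lymphadenopathy"], disease_corpus)
        assert len(m) == 1 and m[0].reference_term == "lymphadenopathy"
        assert m[0].score == 1.0 and m[0].method == "lexical"

    def test_below_threshold_rejected(self, tiny_model):
        corpus = cl.build_corpus(tiny_model)
        assert cl.lexical_match(["x1"], corpus, 0.8) == []

    def test_tie_goes_to_lexicographically_first_column(self, tiny_model):
        corpus = cl.build_corpus(tiny_model)
        m = cl.lexical_match(["GENDER", "Gender"], corpus, 0.8)
        accepted = {x.source_column for x in m}
        assert accepted == {"GENDER"}    # "G" < "g" lexicographically

    def test_injective_partial_bijection(self, disease_corpus, rng):
        cols = [t + suffix for t in disease_corpus.term_names
                for suffix in ("", "x")]
        rng.shuffle(cols)
        m = cl.lexical_match(cols, disease_corpus, 0.6)
        assert len({x.source_column for x in m}) == len(m)
        assert len({x.reference_term for x in m}) == len(m)


class TestSemanticMatch:
    def test_synonym_gives_full_token_score(self):
        ont = cl.ReferenceOntology([
            cl.ReferenceTerm("gender", cl.ValueDomain(
                "categorical", categories=("female", "male")))])
        corpus = cl.build_corpus(
            ont, cl.StaticSynonymSource({"gender": ["sex"]}))
        m = cl.semantic_match(["sex"], corpus, 0.6)
        assert len(m) == 1 and m[0].reference_term == "gender"
        assert m[0].score >= 0.8        # full token score x weight 0.8

    def test_score_formula_by_hand(self, disease_corpus):
        # column "glandular swelling" vs "salivary gland swelling":
        # token "glandular" in pool via the gland->glandular synonym, token
        # "swelling" equal -> mean token score 1; no ancestor overlap
        cfg = HarmonizationConfig()
        s = cl.semantic_score("glandular swelling",
                              "salivary gland swelling", disease_corpus, cfg)
        assert s == pytest.approx(0.8 * 1.0 + 0.2 * 0.0)

    def test_gibberish_stays_unmatched(self, disease_corpus):
        assert cl.semantic_match(["zzqq"], disease_corpus, 0.6) == []


class TestTransforms:
    def test_category_case_recode(self, tiny_model):
        corpus = cl.build_corpus(tiny_model)
        t = make_table("c", {"gender": ["Male", "Female", "Male"]})
        matches = cl.lexical_match(["gender"], corpus)
        tr, warns = cl.build_transforms(matches, t, corpus)
        assert tr["gender"].kind == "recode"
        assert tr["gender"].mapping == {"Male": "male", "Female": "female"}

    def test_binary_lexicon(self, disease_corpus):
        t = make_table("c", {"lymphadenopathy": ["yes", "no", "yes"]})
        matches = cl.lexical_match(["lymphadenopathy"], disease_corpus)
        tr, _ = cl.build_transforms(matches, t, disease_corpus)
        assert tr["lymphadenopathy"].mapping == {"yes": "1", "no": "0"}

    def test_configured_unit_rescale(self, disease_corpus):
        # C4 recorded in g/L; configured factor 100 converts to mg/dL
        t = make_table("c", {"C4": ["0.25", "0.31"]})
        cfg = HarmonizationConfig(unit_conversions={"C4": (100.0, 0.0)})
        matches = cl.lexical_match(["C4"], disease_corpus)
        tr, _ = cl.build_transforms(matches, t, disease_corpus, cfg)
        assert tr["C4"].kind == "affine"
        assert tr["C4"].apply("0.25") == pytest.approx(25.0)


class TestHarmonize:
    def test_canonical_cohort_is_fixpoint(self, default_study):
        cohorts, truth = default_study
        clean = truth.cohorts["cohort_0"].clean
        out, mapping, cov = cl.harmonize(clean, truth.corpus)
        planted = set(clean.df.columns)
        assert {m.source_column for m in mapping.matches
                if m.accepted} == planted
        assert all(tr.kind == "identity"
                   for term, tr in mapping.transforms.items())
        # output column order follows the model's depth-first order
        order = [t for t in truth.corpus.term_names if t in planted]
        assert list(out.df.columns) == order

    def test_shared_schema_across_disjoint_vocabularies(self, default_study):
        cohorts, truth = default_study
        c0 = truth.cohorts["cohort_0"].clean
        c1 = truth.cohorts["cohort_1"].clean
        shared = [c for c in c0.df.columns if c in set(c1.df.columns)]
        a, _, _ = cl.harmonize(
            cl.CohortTable("a", c0.df[shared].copy()), truth.corpus)
        b, _, _ = cl.harmonize(
            cl.CohortTable("b", c1.df[shared].copy()), truth.corpus)
        assert list(a.df.columns) == list(b.df.columns)

    def test_harmonizing_harmonized_is_identity(self, default_study):
        cohorts, truth = default_study
        cur, _ = cl.curate(cohorts[2], truth.model)
        h, _, cov1 = cl.harmonize(cur, truth.corpus)
        h2, mapping2, cov2 = cl.harmonize(h, truth.corpus)
        assert cov2.n_matched == len(h.df.columns)
        assert all(tr.kind == "identity"
                   for tr in mapping2.transforms.values())
        pd.testing.assert_frame_equal(
            h2.df.astype(str), h.df[list(h2.df.columns)].astype(str))

    def test_no_alignment_errors(self, disease_corpus):
        t = make_table("c", {"qqq1": ["1"], "qqq2": ["2"]})
        with pytest.raises(HarmonizationError, match="no alignment"):
            cl.harmonize(t, disease_corpus)

    def test_coverage_monotone_in_lexical_threshold(self, default_study):
        cohorts, truth = default_study
        cur, _ = cl.curate(cohorts[0], truth.model)
        pcts = []
        for thr in (0.95, 0.9, 0.8, 0.7, 0.6):
            _, _, cov = cl.harmonize(
                cur, truth.corpus, HarmonizationConfig(lexical_threshold=thr))
            pcts.append(cov.coverage_pct)
        assert all(a <= b + 1e-9 for a, b in zip(pcts, pcts[1:]))

    def test_mapping_recovery_on_perturbed_cohorts(self):
        """With bounded edits and synonym swaps, planted column->term pairs
        are recovered nearly always (20 seeded replicates)."""
        total = hits = 0
        for seed in range(20):
            cfg = GeneratorConfig(
                seed=seed, n_cohorts=2, rows=(100, 100),
                perturbation=PerturbationConfig(edit_fraction=0.15,
                                                synonym_swap_prob=0.3),
                defects=(DefectConfig(), DefectConfig()))
            cohorts, truth = cl.generate_study(cfg)
            for c in cohorts:
                gt = truth.cohorts[c.cohort_id]
                _, mapping, _ = cl.harmonize(c, truth.corpus)
                acc = mapping.accepted
                for col, term in gt.column_map.items():
                    total += 1
                    hits += acc.get(col) == term
        assert hits / total >= 0.95
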