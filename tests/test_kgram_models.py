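import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hubseq.kgram_models import (
    KgramClassifierSpec,
    MarkovClassModel,
    NBKgramModel,
    TrainingError,
    extract_kgrams,
    load_model,
    save_model,
    score_sequence,
    train_markov,
    train_nb_kgram,
    train_nb_multinomial,
)
from hubseq.sequence_io import AMINO_ACIDS, ProteinRecord
from hubseq.synthetic_data import binary_corpus, sample_generator, GeneratorTemplate, ClassPlan

from conftest import make_dataset


class TestExtractKgrams:
    @pytest.mark.parametrize(
        "seq,k,expected,total",
        [
            ("AAD", 1, {"A": 2, "D": 1}, 3),
            ("AAD", 2, {"AA": 1, "AD": 1}, 2),
            ("AXD", 2, {}, 0),  # both windows touch the dropped X
            ("AXDE", 2, {"DE": 1}, 1),
            ("ACDEF", 3, {"ACD": 1, "CDE": 1, "DEF": 1}, 3),
        ],
    )
    def test_window_counts(self, seq, k, expected, total):
        prof = extract_kgrams(seq, k)
        assert prof.counts == expected
        assert prof.total == total

    def test_sequence_shorter_than_k_is_flagged(self):
        prof = extract_kgrams("AC", 4)
        assert prof.total == 0 and prof.too_short

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            extract_kgrams("ACD", 5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        seq=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60),
        k=st.integers(min_value=1, max_value=4),
    )
    def test_total_is_window_count(self, seq, k):
        prof = extract_kgrams(seq, k)
        assert prof.total == max(len(seq) - k + 1, 0)
        assert all(len(g) == k for g in prof.counts)
        assert sum(prof.counts.values()) == prof.total


class TestTraining:
    def test_multinomial_add_one_smoothing(self):
        # class c = {"AAD"}: N_c = 3 letters, so theta = (n+1)/(3+20)
        ds = make_dataset({"c": ["AAD"], "d": ["CCC"]})
        m = train_nb_multinomial(ds)
        assert math.exp(m.gram_log_prob("c", "A")) == pytest.approx(3 / 23, abs=1e-12)
        assert math.exp(m.gram_log_prob("c", "D")) == pytest.approx(2 / 23, abs=1e-12)
        assert math.exp(m.gram_log_prob("c", "C")) == pytest.approx(1 / 23, abs=1e-12)

    def test_equal_class_sizes_give_equal_priors(self):
        ds = make_dataset({"c": ["AAD"], "d": ["CCC"]})
        m = train_nb_multinomial(ds)
        assert m.log_prior["c"] == pytest.approx(math.log(0.5))
        assert m.log_prior["d"] == pytest.approx(math.log(0.5))

    def test_kgram_add_one_smoothing_k2(self):
        # class c = {"AAD"}: two 2-grams, theta = (n+1)/(2+400)
        ds = make_dataset({"c": ["AAD"], "d": ["CCCC"]})
        m = train_nb_kgram(ds, 2)
        assert math.exp(m.gram_log_prob("c", "AA")) == pytest.approx(2 / 402, abs=1e-12)
        assert math.exp(m.gram_log_prob("c", "AC")) == pytest.approx(1 / 402, abs=1e-12)

    def test_class_with_no_windows_is_uniform(self):
        # every "c" sequence is shorter than k, so smoothing forces 1/400
        ds = make_dataset({"c": ["A", "C"], "d": ["ACDE"]})
        m = train_nb_kgram(ds, 2)
        assert math.exp(m.log_default["c"]) == pytest.approx(1 / 400, abs=1e-12)
        assert m.log_theta["c"] == {}

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_theta_normalises_over_full_gram_space(self, k):
        ds = make_dataset({"c": ["ACDEFGHIKL" * 3], "d": ["MNPQRSTVWY" * 3]})
        m = train_nb_kgram(ds, k)
        for cls in m.classes:
            total = sum(math.exp(v) for v in m.log_theta[cls].values())
            total += (20**k - len(m.log_theta[cls])) * math.exp(m.log_default[cls])
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_markov_add_one_smoothing(self):
        # class c = {"AAD"}: context A seen twice -> P(a|A) = (n+1)/(2+20)
        ds = make_dataset({"c": ["AAD"], "d": ["CCCC"]})
        m = train_markov(ds, 2)
        assert math.exp(m.transition_log_prob("c", "A", "A")) == pytest.approx(2 / 22, abs=1e-12)
        assert math.exp(m.transition_log_prob("c", "A", "D")) == pytest.approx(2 / 22, abs=1e-12)
        assert math.exp(m.transition_log_prob("c", "A", "C")) == pytest.approx(1 / 22, abs=1e-12)

    def test_unseen_context_is_uniform(self):
        ds = make_dataset({"c": ["AAD"], "d": ["CCCC"]})
        m = train_markov(ds, 2)
        for a in "ACDW":
            assert math.exp(m.transition_log_prob("c", "W", a)) == pytest.approx(1 / 20)

    def test_transition_rows_sum_to_one(self):
        ds = make_dataset({"c": ["ACDEFGACDF"], "d": ["MNPQRSTVWY"]})
        m = train_markov(ds, 2)
        for cls in m.classes:
            for ctx in m.transitions[cls]:
                total = sum(
                    math.exp(m.transition_log_prob(cls, ctx, a)) for a in AMINO_ACIDS
                )
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_class_rejected(self):
        ds = make_dataset({"c": ["AAD", "ADA"]}, )
        ds.binary = False
        with pytest.raises(TrainingError, match="no training sequences"):
            train_nb_kgram(ds, 1, classes=["c", "d"])
        with pytest.raises(TrainingError, match="no training sequences"):
            train_markov(ds, 2, classes=["c", "d"])


def brute_force_markov_loglik(train_seqs: list[str], query: str, k: int) -> float:
    """Independent oracle: Laplace-estimated order-(k-1) chain log-likelihood
    by direct counting and per-position products."""
    order = k - 1
    total = 0.0
    if order > 0 and len(query) >= order:
        ctx = query[:order]
        n_start = sum(1 for s in train_seqs if len(s) >= order and s[:order] == ctx)
        n_seqs = sum(1 for s in train_seqs if len(s) >= order)
        total += math.log((n_start + 1) / (n_seqs + 20**order))
    for i in range(len(query) - k + 1):
        ctx, sym = query[i : i + order], query[i + order]
        n_ctx_sym = sum(
            1 for s in train_seqs for j in range(len(s) - k + 1) if s[j : j + k] == ctx + sym
        )
        n_ctx = sum(
            1
            for s in train_seqs
            for j in range(len(s) - k + 1)
            if s[j : j + order] == ctx
        )
        total += math.log((n_ctx_sym + 1) / (n_ctx + 20))
    return total


class TestScoring:
    def test_markov_matches_brute_force_on_short_strings(self):
        # all strings of length <= 6 over a 3-letter sub-alphabet
        sub = "ACD"
        train = {"c": ["ACDACD", "AADCAD"], "d": ["DDCAAC", "CCDDAA"]}
        ds = make_dataset(train)
        for k in (2, 3):
            model = train_markov(ds, k)
            queries = [""]
            for _ in range(6):
                queries = queries + [q + ch for q in queries for ch in sub if len(q + ch) <= 6]
            queries = sorted(set(q for q in queries if q))
            assert len(queries) == 3 + 9 + 27 + 81 + 243 + 729
            for q in queries:
                for cls in ("c", "d"):
                    expected = brute_force_markov_loglik(train[cls], q, k)
                    assert model.log_likelihood(cls, q) == pytest.approx(expected, abs=1e-9), (
                        q, k, cls,
                    )

    def test_multinomial_nb1gram_nb1_equivalence(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(
            {
                "c": ["".join(rng.choice(list("ACDEF"), 30)) for _ in range(5)],
                "d": ["".join(rng.choice(list("KLMNP"), 30)) for _ in range(5)],
            }
        )
        mult = train_nb_multinomial(ds)
        nb1 = train_nb_kgram(ds, 1)
        mk1 = train_markov(ds, 1)
        for _ in range(100):
            q = "".join(rng.choice(list(AMINO_ACIDS), 25))
            s_mult = score_sequence(mult, q).log_scores
            s_nb1 = score_sequence(nb1, q).log_scores
            s_mk1 = score_sequence(mk1, q).log_scores
            for cls in ("c", "d"):
                assert s_mult[cls] == pytest.approx(s_nb1[cls], abs=1e-9)
                assert s_mult[cls] == pytest.approx(s_mk1[cls], abs=1e-9)

    def test_symmetric_model_ties_break_to_first_sorted_label(self):
        ds = make_dataset({"b": ["ACDE"], "a": ["ACDE"]})
        m = train_nb_kgram(ds, 2)
        sp = score_sequence(m, "MNPQ")
        assert sp.label == "a"
        assert sp.margin == pytest.approx(0.0, abs=1e-12)

    def test_short_sequence_scores_on_prior_alone(self):
        ds = make_dataset({"c": ["AAAD", "AADA"], "d": ["CCCC"]})
        m = train_nb_kgram(ds, 4)
        sp = score_sequence(m, "AC")
        assert sp.prior_only
        assert sp.label == "c"  # prior 2/3 beats 1/3

    def test_emitted_sequences_score_higher_under_their_own_class(self):
        # Monte-Carlo discrimination: 100 fresh draws at length 200
        ds, spec = binary_corpus(50, 200, seed=303, concentration=0.1, min_separation=0.3)
        model = train_markov(ds, 2)
        rng = np.random.default_rng(404)
        failures = 0
        for name in ("alpha", "beta"):
            for _ in range(50):
                seq = spec.emitters[name].emit(200, rng)
                if score_sequence(model, seq).label != name:
                    failures += 1
        assert failures <= 1  # expected failure rate < 1%


class TestSerialization:
    @pytest.mark.parametrize("kind", ["nb", "markov"])
    def test_roundtrip_preserves_scores(self, tmp_path, kind):
        ds = make_dataset({"c": ["ACDEFGHIKL" * 2], "d": ["MNPQRSTVWY" * 2]})
        model = train_nb_kgram(ds, 3) if kind == "nb" else train_markov(ds, 3)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert type(back) is type(model)
        for q in ("ACDMNP", "GHIKLW"):
            assert score_sequence(back, q).log_scores == score_sequence(model, q).log_scores


class TestClassifierSpec:
    def test_cv_adapter_scores_are_positive_class_log_odds(self, separated_corpus):
        ds, _ = separated_corpus
        spec = KgramClassifierSpec("markov", 2, "alpha")
        fitted = spec.fit(ds)
        labels, scores = spec.predict(fitted, ds.records[:10], ds)
        for rec, label, s in zip(ds.records[:10], labels, scores):
            assert (s > 0) == (label == "alpha")
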