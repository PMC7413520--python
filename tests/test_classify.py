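"""Naive Bayes and LDA assignment: posteriors, oracles, symmetries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from conftest import make_matrix

import canisnp as cs
from canisnp.classify import ClassifierConfig, NaiveBayesClassifier


def _two_pop_matrix(panel, wolf_rows, dog_rows):
    rows = {}
    pops = {}
    for k, r in enumerate(wolf_rows):
        rows[f"w{k}"] = r
        pops[f"w{k}"] = "wolf"
    for k, r in enumerate(dog_rows):
        rows[f"d{k}"] = r
        pops[f"d{k}"] = "dog"
    return make_matrix(panel, rows, pops)


class TestNaiveBayesFit:
    def test_laplace_smoothed_class_conditionals(self, toy_panel):
        # 80 wolves all HOM_A, 5 dogs all HOM_B at every locus; alpha = 1
        m = _two_pop_matrix(toy_panel, [[2, 2, 2]] * 80, [[0, 0, 0]] * 5)
        model = cs.fit_classifier(m, ClassifierConfig(model="naive_bayes", smoothing_alpha=1.0))
        p_hom_a_wolf = np.exp(model.log_probs_["wolf"][0, 0])
        assert p_hom_a_wolf == pytest.approx(81 / 83)
        assert np.exp(model.log_probs_["wolf"][0, 1]) == pytest.approx(1 / 83)

    def test_zero_alpha_equals_raw_proportions(self, toy_panel):
        m = _two_pop_matrix(
            toy_panel, [[2, 1, 0], [2, 1, 0], [1, 1, 0], [2, 2, 0]], [[0, 0, 2]] * 3
        )
        model = cs.fit_classifier(m, ClassifierConfig(model="naive_bayes", smoothing_alpha=0.0))
        assert np.exp(model.log_probs_["wolf"][0, 0]) == pytest.approx(0.75)

    def test_single_population_rejected(self, toy_panel):
        m = make_matrix(toy_panel, {"a": [2, 1, 0], "b": [2, 1, 0]}, {"a": "x", "b": "x"})
        with pytest.raises(ValueError, match="two populations"):
            cs.fit_classifier(m, ClassifierConfig())

    def test_empty_locus_subset_rejected(self, toy_panel):
        m = _two_pop_matrix(toy_panel, [[2, 2, 2]] * 2, [[0, 0, 0]] * 2)
        with pytest.raises(ValueError, match="subset"):
            cs.fit_classifier(m, ClassifierConfig(locus_subset=[]))


class TestNaiveBayesPosteriors:
    def test_single_locus_het_query_hand_computation(self, toy_panel):
        """Two-term Bayes by hand: membership = smoothed HET probs renormalized."""
        panel1 = cs.PanelDefinition((toy_panel.loci[0],))
        m = _two_pop_matrix(panel1, [[2], [2], [2], [1]], [[1], [1], [0], [0]])
        model = cs.fit_classifier(m, ClassifierConfig(smoothing_alpha=1.0))
        query = make_matrix(panel1, {"q": [1]}, {"q": "unknown"})
        (res,) = cs.membership_probabilities(model, query)
        p_het_wolf = (1 + 1) / (4 + 3)
        p_het_dog = (2 + 1) / (4 + 3)
        assert res.membership["wolf"] == pytest.approx(p_het_wolf / (p_het_wolf + p_het_dog))
        assert res.membership["dog"] == pytest.approx(p_het_dog / (p_het_wolf + p_het_dog))

    def test_enumeration_oracle_on_small_panels(self, toy_panel):
        """Posteriors match an exhaustive independent enumeration (<=3 loci)."""
        rng = np.random.default_rng(17)
        wolf_rows = rng.integers(0, 3, size=(12, 3)).tolist()
        dog_rows = rng.integers(0, 3, size=(15, 3)).tolist()
        training = _two_pop_matrix(toy_panel, wolf_rows, dog_rows)
        alpha = 0.7
        model = cs.fit_classifier(training, ClassifierConfig(smoothing_alpha=alpha))

        # independent brute-force computation from the raw training lists
        def class_prob(rows, locus, state):
            counts = sum(1 for r in rows if r[locus] == state)
            return (counts + alpha) / (len(rows) + 3 * alpha)

        combos = list(itertools.product([0, 1, 2], repeat=3))
        query = make_matrix(
            toy_panel,
            {f"q{i}": list(c) for i, c in enumerate(combos)},
            {f"q{i}": "unknown" for i in range(len(combos))},
        )
        results = cs.membership_probabilities(model, query)
        for combo, res in zip(combos, results):
            lw = np.prod([class_prob(wolf_rows, l, s) for l, s in enumerate(combo)])
            ld = np.prod([class_prob(dog_rows, l, s) for l, s in enumerate(combo)])
            assert res.membership["wolf"] == pytest.approx(lw / (lw + ld), abs=1e-12)
            assert res.predicted == ("dog" if ld >= lw else "wolf")

    def test_label_permutation_swaps_membership_columns(self, toy_panel):
        rng = np.random.default_rng(3)
        rows_a = rng.integers(0, 3, size=(10, 3)).tolist()
        rows_b = rng.integers(0, 3, size=(10, 3)).tolist()
        query = make_matrix(
            toy_panel, {"q": [1, 0, 2], "r": [2, 2, 2]}, {"q": "unknown", "r": "unknown"}
        )
        m1 = _two_pop_matrix(toy_panel, rows_a, rows_b)
        swapped = m1.copy()
        swapped.populations = m1.populations.map({"wolf": "dog", "dog": "wolf"})
        for cfg in (ClassifierConfig(model="naive_bayes"), ClassifierConfig(model="lda")):
            r1 = cs.membership_probabilities(cs.fit_classifier(m1, cfg), query)
            r2 = cs.membership_probabilities(cs.fit_classifier(swapped, cfg), query)
            for a, b in zip(r1, r2):
                assert a.membership["wolf"] == pytest.approx(b.membership["dog"])
                assert a.membership["dog"] == pytest.approx(b.membership["wolf"])

    def test_posteriors_normalized_and_finite_with_smoothing(self, reference, freqs):
        query = cs.simulate_population(freqs, cs.SimulationConfig("dog", 40, seed=41))
        for cfg in (ClassifierConfig(model="naive_bayes"), ClassifierConfig(model="lda")):
            results = cs.membership_probabilities(cs.fit_classifier(reference, cfg), query)
            for r in results:
                assert sum(r.membership.values()) == pytest.approx(1.0, abs=1e-9)
                assert all(np.isfinite(v) for v in r.log_likelihoods.values())

    def test_identical_populations_give_half_membership(self, toy_panel):
        rows = [[2, 1, 0]] * 4
        m = _two_pop_matrix(toy_panel, rows, rows)
        model = cs.fit_classifier(m, ClassifierConfig())
        query = make_matrix(toy_panel, {"q": [2, 1, 0]}, {"q": "unknown"})
        (res,) = cs.membership_probabilities(model, query)
        assert res.membership["wolf"] == pytest.approx(0.5)

    def test_missing_loci_contribute_nothing(self, reference, freqs):
        query = cs.simulate_population(freqs, cs.SimulationConfig("wolf", 10, seed=42))
        masked = query.copy()
        masked.dosage.iloc[:, :6] = -1
        model = cs.fit_classifier(reference, ClassifierConfig())
        full = cs.membership_probabilities(model, query)
        part = cs.membership_probabilities(model, masked)
        # log-likelihood of the masked individuals uses only the last 6 loci
        half_model = cs.fit_classifier(
            reference, ClassifierConfig(locus_subset=reference.locus_ids[6:])
        )
        expected = cs.membership_probabilities(half_model, query)
        for a, b in zip(part, expected):
            assert a.membership["wolf"] == pytest.approx(b.membership["wolf"])
        assert any(
            f.membership["wolf"] != pytest.approx(p.membership["wolf"])
            for f, p in zip(full, part)
        )

    def test_all_missing_individual_flagged_unassignable(self, reference, toy_panel):
        model = cs.fit_classifier(reference, ClassifierConfig())
        query = reference.subset_individuals(reference.individual_ids[:1]).copy()
        query.dosage.iloc[:, :] = -1
        (res,) = cs.membership_probabilities(model, query)
        assert "unassignable" in res.flags
        assert res.membership["wolf"] == pytest.approx(0.5)

    def test_hybrid_flag_on_intermediate_individuals(self, reference, freqs):
        f1 = cs.simulate_f1_hybrids(
            freqs, freqs, 20, seed=43, population_a="wolf", population_b="dog"
        )
        model = cs.fit_classifier(reference, ClassifierConfig(model="naive_bayes"))
        results = cs.membership_probabilities(model, f1)
        for r in results:  # flag fires exactly below the advisory threshold
            assert ("possible_hybrid" in r.flags) == (max(r.membership.values()) < 1 - 1e-7)
        flagged = sum("possible_hybrid" in r.flags for r in results)
        assert flagged >= 10  # most F1s sit between the pure classes


class TestLda:
    def test_posteriors_track_sklearn_reference(self, toy_panel):
        """Cross-check against scikit-learn LDA on well-conditioned data."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(5)
        wolf_rows = rng.binomial(2, 0.85, size=(120, 3)).tolist()
        dog_rows = rng.binomial(2, 0.25, size=(120, 3)).tolist()
        m = _two_pop_matrix(toy_panel, wolf_rows, dog_rows)
        model = cs.fit_classifier(m, ClassifierConfig(model="lda"))
        combos = list(itertools.product([0, 1, 2], repeat=3))
        query = make_matrix(
            toy_panel,
            {f"q{i}": list(c) for i, c in enumerate(combos)},
            {f"q{i}": "unknown" for i in range(len(combos))},
        )
        ours = cs.membership_probabilities(model, query)
        X = np.array(dog_rows + wolf_rows) / 2.0
        y = ["dog"] * len(dog_rows) + ["wolf"] * len(wolf_rows)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        sk_probs = sk.predict_proba(np.array(combos) / 2.0)
        for r, p in zip(ours, sk_probs):
            assert r.membership["dog"] == pytest.approx(p[0], abs=0.02)
        agree = np.mean(
            [r.predicted == c for r, c in zip(ours, sk.predict(np.array(combos) / 2.0))]
        )
        assert agree == 1.0

    def test_identical_class_means_give_uniform_posteriors(self, toy_panel):
        rows = [[2, 0, 1], [0, 2, 1], [1, 1, 2], [1, 1, 0]]
        m = _two_pop_matrix(toy_panel, rows, rows)
        model = cs.fit_classifier(m, ClassifierConfig(model="lda"))
        query = make_matrix(toy_panel, {"q": [1, 1, 1]}, {"q": "unknown"})
        (res,) = cs.membership_probabilities(model, query)
        assert res.membership["wolf"] == pytest.approx(0.5, abs=1e-6)

    def test_separation_on_simulated_reference(self, reference):
        """Both classifiers reach >= 0.97 per-population training-set accuracy."""
        truth = reference.populations.to_dict()
        for cfg in (ClassifierConfig(model="naive_bayes"), ClassifierConfig(model="lda")):
            model = cs.fit_classifier(reference, cfg)
            results = cs.membership_probabilities(model, reference)
            _, acc = cs.assign_individuals(results, truth)
            assert acc["wolf"] >= 0.97 and acc["dog"] >= 0.97


class TestAccuracyTabulation:
    def test_counting(self, toy_panel):
        results = [
            cs.AssignmentResult("a", {"wolf": 0.9, "dog": 0.1}, "wolf", {}),
            cs.AssignmentResult("b", {"wolf": 0.2, "dog": 0.8}, "dog", {}),
            cs.AssignmentResult("c", {"wolf": 0.4, "dog": 0.6}, "dog", {}),
        ]
        frame, acc = cs.assign_individuals(
            results, {"a": "wolf", "b": "dog", "c": "wolf"}
        )
        assert acc == {"dog": 1.0, "wolf": 0.5, "overall": pytest.approx(2 / 3)}

    def test_without_labels_assignments_still_returned(self):
        results = [cs.AssignmentResult("a", {"wolf": 1.0, "dog": 0.0}, "wolf", {})]
        frame, acc = cs.assign_individuals(results)
        assert acc is None
        assert frame.loc[0, "predicted"] == "wolf"
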