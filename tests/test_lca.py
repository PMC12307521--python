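from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from morphrep import (
    derive_morphs,
    fit_lca,
    generate_dataset,
    prepare_lca_inputs,
    select_model,
    summarize_morph_repertoire,
)
from morphrep.lca import ActionResult, ActionVectors, LcaModel, ReduceKError

from conftest import make_tokens, planted_action, small_config


def vectors_from_matrix(matrix: np.ndarray, n_levels: list[int]) -> ActionVectors:
    return ActionVectors(
        gesture_action="Act",
        matrix=np.asarray(matrix, dtype=int),
        modifiers=tuple(f"m{i}" for i in range(len(n_levels))),
        level_labels=tuple(tuple(f"l{j}" for j in range(L)) for L in n_levels),
        token_ids=tuple(f"T{i}" for i in range(len(matrix))),
        constant_modifiers={},
    )


def closed_form_k1_loglik(matrix: np.ndarray) -> float:
    """Independent-multinomial log-likelihood at the empirical marginals."""
    n = len(matrix)
    total = 0.0
    for m in range(matrix.shape[1]):
        _, counts = np.unique(matrix[:, m], return_counts=True)
        total += (counts * np.log(counts / n)).sum()
    return float(total)


class TestFitLca:
    def test_identical_vectors_k1_degenerate(self):
        vectors = vectors_from_matrix(np.zeros((12, 2)), [2, 2])
        model = fit_lca(vectors, k=1, seed=0)
        assert model.class_weights == pytest.approx([1.0])
        assert (model.assignments == 0).all()
        for p in model.item_response:
            assert p[0, 0] == pytest.approx(1.0)
        assert model.log_likelihood == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_k1_equals_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        matrix = np.column_stack(
            [rng.integers(0, 3, size=60), rng.integers(0, 2, size=60), rng.integers(0, 4, size=60)]
        )
        vectors = vectors_from_matrix(matrix, [3, 2, 4])
        model = fit_lca(vectors, k=1, seed=seed)
        assert model.log_likelihood == pytest.approx(
            closed_form_k1_loglik(matrix), abs=1e-10
        )
        for m in range(3):
            levels, counts = np.unique(matrix[:, m], return_counts=True)
            for level, count in zip(levels, counts):
                assert model.item_response[m][0, level] == pytest.approx(
                    count / 60, abs=1e-10
                )

    def test_two_balanced_clusters_recovered_exactly(self):
        matrix = np.array([[0, 0]] * 20 + [[1, 1]] * 20)
        vectors = vectors_from_matrix(matrix, [2, 2])
        model = fit_lca(vectors, k=2, seed=0)
        assert sorted(model.class_weights) == pytest.approx([0.5, 0.5], abs=1e-9)
        first, second = model.assignments[:20], model.assignments[20:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]
        # exact-enumeration oracle over the two distinct vectors: perfect
        # separation gives LL = sum_c n_c log(n_c / n) = 40 log(1/2)
        assert model.log_likelihood == pytest.approx(40 * np.log(0.5), abs=1e-8)

    def test_loglik_never_positive_and_monotone(self):
        rng = np.random.default_rng(7)
        matrix = rng.integers(0, 3, size=(50, 3))
        vectors = vectors_from_matrix(matrix, [3, 3, 3])
        model = fit_lca(vectors, k=3, seed=7)
        assert model.log_likelihood <= 1e-12
        diffs = np.diff(model.ll_history)
        assert (diffs >= -1e-9).all()

    def test_k_exceeding_distinct_vectors(self):
        vectors = vectors_from_matrix(np.array([[0, 0]] * 5 + [[1, 1]] * 5), [2, 2])
        with pytest.raises(ReduceKError):
            fit_lca(vectors, k=3, seed=0)

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(3)
        matrix = rng.integers(0, 3, size=(80, 4))
        vectors = vectors_from_matrix(matrix, [3, 3, 3, 3])
        a = fit_lca(vectors, k=3, seed=42)
        b = fit_lca(vectors, k=3, seed=42)
        assert a.log_likelihood == b.log_likelihood
        assert (a.assignments == b.assignments).all()
        np.testing.assert_array_equal(a.class_weights, b.class_weights)

    def test_label_permutation_leaves_inventory_unchanged(self):
        matrix = np.array([[0, 0]] * 24 + [[1, 1]] * 16)
        vectors = vectors_from_matrix(matrix, [2, 2])
        model = fit_lca(vectors, k=2, seed=0)
        perm = np.array([1, 0])
        inverse = np.argsort(perm)
        permuted = dataclasses.replace(
            model,
            class_weights=model.class_weights[perm],
            item_response=tuple(p[perm] for p in model.item_response),
            assignments=inverse[model.assignments],
        )
        assert permuted.bic == model.bic
        morphs_a, un_a = derive_morphs(model)
        morphs_b, un_b = derive_morphs(permuted)
        assert [(m.morph_id, m.token_count, sorted(m.token_ids)) for m in morphs_a] == [
            (m.morph_id, m.token_count, sorted(m.token_ids)) for m in morphs_b
        ]
        assert un_a == un_b


class TestSelectModel:
    def test_single_configuration_selects_k1(self):
        vectors = vectors_from_matrix(np.zeros((30, 2)), [2, 2])
        model = select_model(vectors, seed=0)
        assert model.k == 1

    def test_two_separated_components_select_k2(self):
        matrix = np.array([[0, 0, 0]] * 30 + [[1, 1, 1]] * 30)
        vectors = vectors_from_matrix(matrix, [2, 2, 2])
        model = select_model(vectors, seed=0)
        assert model.k == 2

    def test_bic_formula(self):
        matrix = np.array([[0, 0]] * 20 + [[1, 1]] * 20)
        vectors = vectors_from_matrix(matrix, [2, 2])
        model = fit_lca(vectors, k=2, seed=0)
        d = (2 - 1) + 2 * ((2 - 1) + (2 - 1))
        assert model.n_parameters == d
        assert model.bic == pytest.approx(-2 * model.log_likelihood + d * np.log(40))

    def test_planted_k_recovered_with_noise(self):
        config = small_config(seed=4, n_tokens=600, epsilon=0.02)
        dataset = generate_dataset(config)
        tokens = dataset.tokens[dataset.tokens["gesture_action"] == "Gamma"]
        from morphrep import default_vocabulary

        vectors, _ = prepare_lca_inputs(tokens, default_vocabulary())
        model = select_model(vectors["Gamma"], seed=0)
        assert model.k == 3


class TestPrepareInputs:
    def test_unclear_tokens_removed(self, vocab):
        tokens = make_tokens(
            ["A"] * 12,
            body_part=["hand"] * 10 + ["unclear"] * 2,
            contact_recipient=["contact"] * 6 + ["no_contact"] * 6,
        )
        vectors, report = prepare_lca_inputs(tokens, vocab)
        assert report.n_unclear == 2
        assert vectors["A"].n_obs == 10
        assert report.n_analyzed == 10

    def test_action_below_threshold_routed_unspecified(self, vocab):
        tokens = make_tokens(
            ["A"] * 9, contact_recipient=["contact"] * 5 + ["no_contact"] * 4
        )
        vectors, report = prepare_lca_inputs(tokens, vocab)
        assert vectors == {}
        assert report.unspecified_actions == {"A": 9}

    def test_invariant_modifier_dropped(self, vocab):
        tokens = make_tokens(
            ["A"] * 12,
            lateral_use=["right"] * 12,
            contact_recipient=["contact"] * 6 + ["no_contact"] * 6,
            body_part=["hand"] * 6 + ["foot"] * 6,
        )
        vectors, report = prepare_lca_inputs(tokens, vocab)
        assert "lateral_use" not in vectors["A"].modifiers
        assert vectors["A"].constant_modifiers["lateral_use"] == "right"
        assert "lateral_use" in report.dropped_invariant["A"]

    def test_non_applicable_modifiers_ignored(self):
        from morphrep import default_vocabulary

        vocab = default_vocabulary(applicability={"A": ("body_part", "repetition")})
        tokens = make_tokens(
            ["A"] * 12,
            lateral_use=["unclear"] * 12,  # unclear on a non-applicable modifier
            body_part=["hand"] * 6 + ["foot"] * 6,
            repetition=["single"] * 6 + ["repeated"] * 6,
        )
        vectors, report = prepare_lca_inputs(tokens, vocab)
        assert report.n_unclear == 0
        assert vectors["A"].modifiers == ("body_part", "repetition")


def _manual_model(assignment_sizes: list[int], k: int | None = None) -> LcaModel:
    k = k or len(assignment_sizes)
    assignments = np.concatenate(
        [np.full(size, idx) for idx, size in enumerate(assignment_sizes)]
    )
    n = len(assignments)
    item = []
    for _ in range(2):
        p = np.full((k, 2), 0.5)
        for c in range(k):
            p[c, c % 2] = 0.9
            p[c, 1 - c % 2] = 0.1
        item.append(p)
    return LcaModel(
        gesture_action="Act",
        k=k,
        class_weights=np.array(assignment_sizes, dtype=float) / n,
        item_response=tuple(item),
        log_likelihood=-1.0,
        bic=2.0,
        n_obs=n,
        n_parameters=k - 1 + 2 * k,
        assignments=assignments,
        posterior_margin=np.ones(n),
        modifiers=("m0", "m1"),
        level_labels=(("l0", "l1"), ("l0", "l1")),
        token_ids=tuple(f"T{i}" for i in range(n)),
        ll_history=np.array([-2.0, -1.0]),
        converged=True,
    )


class TestDeriveMorphs:
    def test_k1_single_morph(self):
        model = _manual_model([30])
        morphs, unassigned = derive_morphs(model)
        assert len(morphs) == 1
        assert morphs[0].morph_id == "Act.1_1"
        assert morphs[0].token_count == 30
        assert unassigned == []

    def test_small_class_becomes_unassigned(self):
        model = _manual_model([26, 4])
        morphs, unassigned = derive_morphs(model, morph_min=5)
        assert len(morphs) == 1
        assert morphs[0].token_count == 26
        assert len(unassigned) == 4

    def test_naming_with_three_morphs(self):
        model = _manual_model([10, 30, 20])
        morphs, _ = derive_morphs(model)
        assert [m.morph_id for m in morphs] == ["Act.1_3", "Act.2_3", "Act.3_3"]
        assert [m.token_count for m in morphs] == [30, 20, 10]

    def test_all_classes_below_threshold(self):
        model = _manual_model([4, 3])
        morphs, unassigned = derive_morphs(model, morph_min=5)
        assert morphs == []
        assert len(unassigned) == 7

    def test_token_conservation(self):
        model = _manual_model([12, 6, 4])
        morphs, unassigned = derive_morphs(model, morph_min=5)
        assert sum(m.token_count for m in morphs) + len(unassigned) == model.n_obs

    def test_modal_configuration_includes_constants(self):
        model = _manual_model([20])
        morphs, _ = derive_morphs(model, constant_modifiers={"lateral_use": "right"})
        assert morphs[0].modal_configuration["lateral_use"] == "right"
        assert morphs[0].modal_configuration["m0"] == "l0"


class TestSummarize:
    def _result(self, name, sizes, morph_min=5):
        model = _manual_model(sizes)
        morphs, unassigned = derive_morphs(model, morph_min=morph_min)
        morphs = [dataclasses.replace(m, gesture_action=name) for m in morphs]
        return ActionResult(name, model, morphs, unassigned)

    def test_unit_identities(self):
        results = [
            self._result("Uni1", [20]),
            self._result("Uni2", [15]),
            self._result("Poly1", [10, 8]),
            self._result("Poly2", [9, 7, 6]),
        ]
        repertoire, stats = summarize_morph_repertoire(results, ["Unspec1", "Unspec2"])
        assert stats["n_unimorphic"] == 2
        assert stats["n_polymorphic"] == 2
        assert stats["n_unspecified"] == 2
        assert stats["n_polymorphic_morphs"] == 5
        assert stats["n_units"] == 2 + 5 + 2
        assert stats["morphs_per_polymorphic_mean"] == pytest.approx(2.5)
        assert stats["morphs_per_polymorphic_range"] == (2, 3)

    def test_zero_polymorphic_mean_absent(self):
        repertoire, stats = summarize_morph_repertoire([self._result("Uni", [12])], [])
        assert stats["morphs_per_polymorphic_mean"] is None
        assert stats["morphs_per_polymorphic_sd"] is None

    def test_unassigned_fraction(self):
        results = [self._result("Act", [20, 4])]
        repertoire, _ = summarize_morph_repertoire(results, [])
        assert repertoire.n_unassigned == 4
        assert repertoire.unassigned_fraction == pytest.approx(4 / 24)


class TestPlantedRecovery:
    """Brute-force grouping oracle: with epsilon=0 and components differing in
    >=2 modifiers, morphs must equal the partition by identical vectors."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_partition_recovery(self, seed, vocab):
        config = small_config(seed=seed, n_tokens=400)
        dataset = generate_dataset(config)
        tokens = dataset.tokens
        vectors, _ = prepare_lca_inputs(tokens, vocab)
        merged = tokens.merge(
            dataset.truth[["token_id", "component_index"]], on="token_id"
        )
        for action, av in vectors.items():
            model = select_model(av, seed=seed)
            morphs, unassigned = derive_morphs(model)
            assert unassigned == []
            truth_sub = merged.set_index("token_id").loc[list(av.token_ids)]
            planted = {
                frozenset(truth_sub.index[truth_sub["component_index"] == c])
                for c in truth_sub["component_index"].unique()
            }
            derived = {frozenset(m.token_ids) for m in morphs}
            assert derived == planted
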