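"""Signature extraction, mu path, final model and held-out evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from l1l2sig import (LabeledDataset, Signature, SyntheticSpec, CVResult,
                     evaluate_test, extract_signature, final_model, fit_rls,
                     generate_dataset, mu_path, nested_cv)
from l1l2sig.linear_model import ConfusionCounts


def _cv_with_freqs(freqs, mu=1.0, K=10):
    ids = list(freqs)
    return CVResult(mu=mu, K=K, seed=0, variable_ids=ids, fold_selected=[],
                    fold_params=[(0.1, 0.01)] * K,
                    fold_confusion=[ConfusionCounts(1, 0, 0, 1)] * K,
                    frequencies=pd.Series(freqs))


def test_threshold_is_inclusive():
    cv = _cv_with_freqs({"A": 100.0, "B": 40.0, "C": 30.0})
    sig = extract_signature(cv, threshold=40)
    assert sig.variable_ids == ["A", "B"]


def test_threshold_100_keeps_only_everywhere_selected():
    cv = _cv_with_freqs({"A": 100.0, "B": 90.0})
    assert extract_signature(cv, threshold=100).variable_ids == ["A"]


def test_ordering_descending_frequency_ties_by_id():
    cv = _cv_with_freqs({"Z": 50.0, "A": 50.0, "M": 80.0})
    assert extract_signature(cv, threshold=40).variable_ids == ["M", "A", "Z"]


def test_empty_signature_is_allowed():
    cv = _cv_with_freqs({"A": 10.0})
    assert len(extract_signature(cv, threshold=40)) == 0


@given(st.lists(st.floats(0, 100), min_size=1, max_size=30),
       st.integers(1, 100), st.integers(1, 100))
def test_extraction_monotone_in_threshold(freqs, t_low, t_high):
    """Lowering the threshold never removes a variable."""
    t_low, t_high = min(t_low, t_high), max(t_low, t_high)
    cv = _cv_with_freqs({f"v{i}": round(f, 1) for i, f in enumerate(freqs)})
    low = set(extract_signature(cv, threshold=t_low).variable_ids)
    high = set(extract_signature(cv, threshold=t_high).variable_ids)
    assert high <= low


def test_invalid_threshold_rejected():
    cv = _cv_with_freqs({"A": 50.0})
    for bad in (0, -5, 101):
        with pytest.raises(ValueError, match="threshold"):
            extract_signature(cv, threshold=bad)


def test_mu_path_validation(small_strong_dataset):
    data, _ = small_strong_dataset
    with pytest.raises(ValueError, match="ascending"):
        mu_path(data, mu_values=[1.0, 0.1], K_outer=3, K_inner=3)
    with pytest.raises(ValueError, match="largest mu"):
        mu_path(data, mu_values=[0.1, 0.5], K_outer=3, K_inner=3)


def test_mu_path_single_level_equals_nested_cv(small_strong_dataset):
    data, _ = small_strong_dataset
    path = mu_path(data, mu_values=[1.0], K_outer=4, K_inner=3, seed=6)
    cv = nested_cv(data, mu=1.0, K_outer=4, K_inner=3, seed=6)
    assert path.reported.variable_ids == \
        extract_signature(cv).variable_ids
    assert path.entries[-1][2].mean_error == cv.mean_error
    assert path.minimal_list_size == len(path.reported)


def test_duplicated_variables_share_frequency_along_path():
    """Exactly duplicated variables receive identical coefficients at any
    mu > 0, so their selection frequencies coincide at every path level."""
    spec = SyntheticSpec(n_samples=50, n_variables=30, block_size=3,
                         n_blocks=3, n_informative=4, effect_size=2.0,
                         seed=13)
    data, _ = generate_dataset(spec)
    X = data.X.copy()
    X[:, 20] = X[:, 0]  # duplicate an informative variable
    data = LabeledDataset(X, data.y, data.variable_ids, data.sample_ids)
    path = mu_path(data, mu_values=[0.1, 1.0], K_outer=4, K_inner=3, seed=13)
    for _, _, cv in path.entries:
        a = cv.frequencies[data.variable_ids[0]]
        b = cv.frequencies[data.variable_ids[20]]
        assert a == b
    assert path.entries[-1][2].frequencies[data.variable_ids[0]] > 0


def test_final_model_single_variable_matches_rls_closed_form(tiny_dataset):
    sig = Signature(entries=[("vA", 100.0)], mu_level=1.0, threshold=40.0)
    model = final_model(tiny_dataset, sig, lam=0.5)
    Xc = tiny_dataset.X[:, [0]] - tiny_dataset.X[:, 0].mean()
    expected = fit_rls(Xc, tiny_dataset.y, 0.5)
    np.testing.assert_allclose(model.weights.beta, expected)


def test_final_model_all_variables_is_plain_rls(tiny_dataset):
    sig = Signature(entries=[("vA", 100.0), ("vB", 60.0)], mu_level=1.0,
                    threshold=40.0)
    model = final_model(tiny_dataset, sig, lam=0.1)
    Xc, _ = tiny_dataset.centered()
    np.testing.assert_allclose(model.weights.beta,
                               fit_rls(Xc, tiny_dataset.y, 0.1))


def test_final_model_lambda_defaults_to_fold_median(tiny_dataset):
    cv = _cv_with_freqs({"vA": 100.0})
    cv.fold_params = [(0.1, lam) for lam in (0.01, 0.1, 1.0)]
    sig = Signature(entries=[("vA", 100.0)], mu_level=1.0, threshold=40.0)
    model = final_model(tiny_dataset, sig, cv=cv)
    assert model.weights.lam == pytest.approx(0.1)


def test_final_model_empty_signature_rejected(tiny_dataset):
    sig = Signature(entries=[], mu_level=1.0, threshold=40.0)
    with pytest.raises(ValueError, match="empty signature"):
        final_model(tiny_dataset, sig, lam=0.1)


def _separable_dataset(n=92, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1.0] * (n // 2) + [-1.0] * (n - n // 2))
    X = rng.standard_normal((n, 5))
    X[:, 0] = y * 3.0 + 0.1 * rng.standard_normal(n)
    ids = [f"v{j}" for j in range(5)]
    return LabeledDataset(X, y, ids, [f"s{i}" for i in range(n)])


def test_training_set_as_test_set_scores_zero_error():
    data = _separable_dataset()
    sig = Signature(entries=[("v0", 100.0)], mu_level=1.0, threshold=40.0)
    model = final_model(data, sig, lam=1e-6)
    counts = evaluate_test(model, data)
    assert counts.error == 0
    assert counts.total == data.n_samples


def test_planted_misclassification_count():
    """Flipping 7 labels of a 92-sample perfectly-separable test set must
    produce exactly a 7/92 error decomposition."""
    train = _separable_dataset(n=92, seed=1)
    sig = Signature(entries=[("v0", 100.0)], mu_level=1.0, threshold=40.0)
    model = final_model(train, sig, lam=1e-6)
    y_flipped = train.y.copy()
    flip = [0, 5, 10, 50, 60, 70, 91]
    y_flipped[flip] *= -1
    test = LabeledDataset(train.X, y_flipped, train.variable_ids,
                          train.sample_ids)
    counts = evaluate_test(model, test)
    assert counts.error == pytest.approx(7 / 92)
    assert counts.FP + counts.FN == 7


def test_evaluate_test_invariant_to_sample_order():
    train = _separable_dataset(n=40, seed=2)
    sig = Signature(entries=[("v0", 100.0), ("v1", 60.0)], mu_level=1.0,
                    threshold=40.0)
    model = final_model(train, sig, lam=0.01)
    perm = np.random.default_rng(0).permutation(40)
    shuffled = LabeledDataset(train.X[perm], train.y[perm],
                              train.variable_ids,
                              [train.sample_ids[i] for i in perm])
    a, b = evaluate_test(model, train), evaluate_test(model, shuffled)
    assert (a.TP, a.FN, a.FP, a.TN) == (b.TP, b.FN, b.FP, b.TN)


def test_evaluate_test_lists_missing_variables():
    train = _separable_dataset(n=30, seed=3)
    sig = Signature(entries=[("v0", 100.0)], mu_level=1.0, threshold=40.0)
    model = final_model(train, sig, lam=0.01)
    test = LabeledDataset(train.X[:, 1:], train.y, train.variable_ids[1:],
                          train.sample_ids)
    with pytest.raises(KeyError, match="v0"):
        evaluate_test(model, test)


def test_all_positive_predictions_on_all_positive_labels():
    train = _separable_dataset(n=30, seed=4)
    sig = Signature(entries=[("v0", 100.0)], mu_level=1.0, threshold=40.0)
    model = final_model(train, sig, lam=1e-6)
    pos = train.X[train.y == 1]
    test = LabeledDataset(pos, np.ones(len(pos)), train.variable_ids,
                          [f"t{i}" for i in range(len(pos))])
    counts = evaluate_test(model, test)
    assert counts.TP == len(pos)
    assert counts.FN == counts.FP == counts.TN == 0
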