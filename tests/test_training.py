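"""Offline training protocol: example construction, split, back-prop,
model selection."""

import math

import numpy as np
import pytest

from nestscale import (DegenerateInputError, FeatureVector, MLPParameters,
                       Pattern, TrainConfig, TrainingExample,
                       build_training_set, evaluate_model, mlp_forward,
                       select_model, split_dataset, train_mlp)
from nestscale.training import training_loss_curve


def _pattern(weights, stable):
    weights = np.asarray(weights, dtype=float)
    return Pattern(weights=weights, stable=np.asarray(stable, dtype=bool),
                   ticks=np.arange(len(weights)))


def _toy_examples(n=60, seed=3):
    """Sequences whose target equals their modal value — learnable by a
    tiny network, with a closed-form best answer."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        v = float(rng.integers(100, 191))
        k = int(rng.integers(5, 15))
        f = FeatureVector(max_1=v, n_1=k, max_2=v + 2, n_2=1,
                          max_c1=v, nc_1=k, max_c2=v + 2, nc_2=1, n_el=k + 3)
        out.append(TrainingExample(features=f, target=v))
    return out


def _constant_model(grams, r=300.0, hidden=3):
    """A network that outputs ``grams`` for every input."""
    p = grams / r
    bias = math.log(p / (1.0 - p))
    return MLPParameters(
        hidden_weights=np.zeros((9, hidden)),
        hidden_biases=np.zeros(hidden),
        output_weights=np.zeros(hidden),
        output_bias=bias,
        resample_factor=r,
    )


class TestBuildTrainingSet:
    def test_mixed_pattern_yields_target_and_unstable_features(self):
        p = _pattern([150.0, 151.0, 140.0, 160.0, 138.0, 161.0],
                     [True, True, False, False, False, False])
        (ex,) = build_training_set([p])
        assert ex.target == pytest.approx(150.5)
        assert ex.features.n_el == 4  # stable samples removed

    def test_all_stable_and_all_unstable_skipped(self):
        mixed = _pattern([150.0] * 3 + [140.0] * 3,
                         [True] * 3 + [False] * 3)
        all_stable = _pattern([150.0] * 5, [True] * 5)
        all_unstable = _pattern([150.0] * 5, [False] * 5)
        examples = build_training_set([all_stable, mixed, all_unstable])
        assert len(examples) == 1

    def test_empty_eligible_set_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_training_set([_pattern([150.0] * 5, [False] * 5)])


class TestSplit:
    def test_half_split_sizes(self):
        examples = _toy_examples(100)
        train, test = split_dataset(examples, 0.5, seed=0)
        assert (len(train), len(test)) == (50, 50)

    def test_ceiling_rule(self):
        train, test = split_dataset(_toy_examples(3), 0.5, seed=0)
        assert (len(train), len(test)) == (2, 1)

    def test_reproducible_and_exhaustive(self):
        examples = _toy_examples(41)
        for seed in (0, 1, 99):
            tr1, te1 = split_dataset(examples, 0.3, seed)
            tr2, te2 = split_dataset(examples, 0.3, seed)
            assert tr1 == tr2 and te1 == te2
            ids = {id(e) for e in tr1} | {id(e) for e in te1}
            assert len(ids) == 41  # disjoint and exhaustive

    def test_too_few_examples_rejected(self):
        with pytest.raises(DegenerateInputError):
            split_dataset(_toy_examples(1), 0.5, seed=0)


class TestTrainMLP:
    def test_toy_loss_decreases_monotonically_to_small_values(self):
        """Plain gradient descent on a noiseless modal-value toy set:
        the training MSE decreases monotonically below 1e-3 (scaled)."""
        cfg = TrainConfig(seed=7, momentum=0.0, learning_rate=0.5,
                          epochs=6000, patience=10**9)
        losses = training_loss_curve(_toy_examples(), cfg, hidden_size=3)
        assert (np.diff(losses) <= 1e-15).all()
        assert losses[-1] < 1e-3
        assert losses[-1] < losses[0]

    def test_single_example_is_fitted(self):
        cfg = TrainConfig(seed=7, epochs=3000)
        examples = _toy_examples(1)
        model = train_mlp(examples, cfg, hidden_size=2)
        assert evaluate_model(model, examples) == pytest.approx(100.0,
                                                                abs=0.01)

    def test_same_seed_gives_identical_parameters(self):
        cfg = TrainConfig(seed=11, epochs=500)
        examples = _toy_examples(20)
        m1 = train_mlp(examples, cfg, hidden_size=3)
        m2 = train_mlp(examples, cfg, hidden_size=3)
        assert np.array_equal(m1.hidden_weights, m2.hidden_weights)
        assert np.array_equal(m1.output_weights, m2.output_weights)
        assert m1.output_bias == m2.output_bias

    def test_empty_training_set_rejected(self):
        with pytest.raises(DegenerateInputError):
            train_mlp([], TrainConfig(), 3)

    def test_matches_sklearn_reference_on_toy_set(self):
        """Independent cross-check: our back-prop reaches the same
        quality as scikit-learn's MLPRegressor on the toy problem."""
        from sklearn.neural_network import MLPRegressor

        examples = _toy_examples(80)
        cfg = TrainConfig(seed=5, epochs=8000)
        ours = train_mlp(examples, cfg, hidden_size=3)
        our_acc = evaluate_model(ours, examples)

        x = np.stack([cfg.input_scaling.scale(e.features) for e in examples])
        y = np.array([e.target for e in examples])
        sk = MLPRegressor(hidden_layer_sizes=(3,), activation="logistic",
                          solver="lbfgs", max_iter=5000,
                          random_state=0).fit(x, y)
        sk_acc = float(np.mean([
            100.0 * (1 - abs(t - p) / t) for t, p in zip(y, sk.predict(x))
        ]))
        assert our_acc >= sk_acc - 1.0


class TestSelection:
    def test_parsimony_rule_prefers_small_networks(self):
        test = [TrainingExample(
            features=FeatureVector(150.0, 5, 0.0, 0, 150.0, 5, 0.0, 0, 5),
            target=150.0)]
        # constant models engineered to score 97.0 / 98.5 / 98.55
        candidates = {
            1: _constant_model(150.0 * 0.97),
            3: _constant_model(150.0 * 0.985),
            9: _constant_model(150.0 * 0.9855),
        }
        chosen = select_model(candidates, test, tol=0.1)
        assert chosen is candidates[3]

    def test_exact_tie_takes_smallest_hidden_size(self):
        test = [TrainingExample(
            features=FeatureVector(150.0, 5, 0.0, 0, 150.0, 5, 0.0, 0, 5),
            target=150.0)]
        same = {h: _constant_model(148.0, hidden=h) for h in (2, 4, 7)}
        assert select_model(same, test) is same[2]

    def test_single_candidate_returned(self):
        test = [TrainingExample(
            features=FeatureVector(150.0, 5, 0.0, 0, 150.0, 5, 0.0, 0, 5),
            target=150.0)]
        only = {4: _constant_model(150.0)}
        assert select_model(only, test) is only[4]


class TestEvaluate:
    def test_order_invariant(self):
        examples = _toy_examples(30)
        model = _constant_model(145.0)
        assert evaluate_model(model, examples) == pytest.approx(
            evaluate_model(model, examples[::-1]))

    def test_constant_model_accuracy_matches_closed_form(self):
        test = [TrainingExample(
            features=FeatureVector(150.0, 5, 0.0, 0, 150.0, 5, 0.0, 0, 5),
            target=150.0)]
        model = _constant_model(150.0 * 1.015)
        assert evaluate_model(model, test) == pytest.approx(98.5, abs=0.01)
        perfect = _constant_model(150.0)
        assert evaluate_model(perfect, test) == pytest.approx(100.0)
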