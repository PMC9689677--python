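"""Divergence-to-representative classifier vs a line-by-line oracle."""

import math

import numpy as np
import pytest

from bgaudit import divergence as dv
from bgaudit.entropy import shannon_entropy

from conftest import random_density

EPS = dv.DEFAULT_EPSILON


# ---------------------------------------------------------------------------
# Independent brute-force oracle: plain-Python re-statement of the
# shuffle/average/normalize/compare procedure, kept free of numpy
# vectorization and of the implementation under test.
# ---------------------------------------------------------------------------

def oracle_cross_entropy(p, q, log=math.log):
    return -sum(pi * log(qi + EPS) for pi, qi in zip(p, q))


def oracle_mse(p, q):
    return sum((pi - qi) ** 2 for pi, qi in zip(p, q))


def oracle_fit_predict(Xtrain, ytrain, Xtest, fn):
    X0 = [x for x, y in zip(Xtrain, ytrain) if y == 0]
    X1 = [x for x, y in zip(Xtrain, ytrain) if y == 1]
    nbins = len(Xtrain[0])
    M0 = [sum(x[i] for x in X0) / len(X0) for i in range(nbins)]
    M1 = [sum(x[i] for x in X1) / len(X1) for i in range(nbins)]
    M0 = [v / sum(M0) for v in M0]
    M1 = [v / sum(M1) for v in M1]
    D0 = [fn(x, M0) for x in Xtrain]   # over the WHOLE training set
    D1 = [fn(x, M1) for x in Xtrain]
    m0 = sum(D0) / len(D0)
    m1 = sum(D1) / len(D1)
    s0 = math.sqrt(sum((d - m0) ** 2 for d in D0) / len(D0))
    s1 = math.sqrt(sum((d - m1) ** 2 for d in D1) / len(D1))
    preds = []
    for x in Xtest:
        dt0 = (fn(x, M0) - m0) / s0
        dt1 = (fn(x, M1) - m1) / s1
        preds.append(1 if dt1 < dt0 else 0)
    return (M0, M1, m0, s0, m1, s1), preds


def _random_instance(r, n_bins, n_samples):
    X = np.vstack([random_density(r, n_bins, full_support=True) for _ in range(n_samples)])
    y = r.integers(0, 2, size=n_samples)
    # guarantee both classes twice over
    y[:2], y[2:4] = 0, 1
    return X, y


class TestDivergences:
    def test_cross_entropy_of_uniform_with_itself_is_log30(self):
        u = np.full(30, 1 / 30)
        assert dv.cross_entropy(u, u) == pytest.approx(np.log(30), abs=1e-9)

    def test_one_hot_against_uniform_is_log30(self):
        p = np.zeros(30)
        p[0] = 1.0
        assert dv.cross_entropy(p, np.full(30, 1 / 30)) == pytest.approx(np.log(30), abs=1e-9)

    def test_self_cross_entropy_equals_shannon_entropy(self, rng):
        for _ in range(20):
            p = random_density(rng, 12, full_support=True)
            assert dv.cross_entropy(p, p) == pytest.approx(
                shannon_entropy(p, "nats"), abs=1e-6
            )

    def test_gibbs_inequality_on_random_pairs(self, rng):
        """H(P, Q) >= H(P, P) for full-support densities."""
        for _ in range(1000):
            p = random_density(rng, 10, full_support=True)
            q = random_density(rng, 10, full_support=True)
            assert dv.cross_entropy(p, q) >= dv.cross_entropy(p, p) - 1e-12

    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([0.3, 0.7], [0.3, 0.7], 0.0),
            ([1.0, 0.0], [0.0, 1.0], 2.0),
            ([0.5, 0.5], [1.0, 0.0], 0.5),
        ],
    )
    def test_mse_worked_values(self, p, q, expected):
        assert dv.mse(np.array(p), np.array(q)) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dv.mse(np.ones(3) / 3, np.ones(4) / 4)
        with pytest.raises(ValueError):
            dv.cross_entropy(np.ones(3) / 3, np.ones(4) / 4)


class TestSplit:
    def test_two_thirds_of_260_is_173(self):
        train, test = dv.split(260, dv.SplitSpec(seed=0))
        assert len(train) == 173 and len(test) == 87

    def test_minimal_split(self):
        train, test = dv.split(3, dv.SplitSpec(seed=1))
        assert len(train) == 2 and len(test) == 1

    def test_deterministic_and_partitioning(self):
        a = dv.split(50, dv.SplitSpec(seed=9))
        b = dv.split(50, dv.SplitSpec(seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert sorted(np.concatenate(a)) == list(range(50))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            dv.split(2, dv.SplitSpec(seed=0))


class TestFit:
    def test_representatives_are_class_means(self):
        a = np.array([0.2, 0.3, 0.5])
        b = np.array([0.6, 0.3, 0.1])
        X = np.vstack([a, a, b, b])
        model = dv.fit(X, [0, 0, 1, 1], divergence="mse")
        assert np.allclose(model.M0, a)
        assert np.allclose(model.M1, b)

    def test_single_class_training_rejected(self):
        X = np.vstack([random_density(np.random.default_rng(0), 5) for _ in range(4)])
        with pytest.raises(dv.FittingError):
            dv.fit(X, [0, 0, 0, 0], divergence="mse")

    def test_zero_divergence_spread_fails_loudly(self):
        a = np.array([0.5, 0.5])
        X = np.vstack([a, a, a, a])
        with pytest.raises(dv.FittingError):
            dv.fit(X, [0, 0, 1, 1], divergence="mse")

    def test_hand_built_instance_matches_oracle_statistics(self):
        X = np.array(
            [
                [0.7, 0.2, 0.1],
                [0.6, 0.3, 0.1],
                [0.5, 0.3, 0.2],
                [0.1, 0.3, 0.6],
                [0.2, 0.2, 0.6],
                [0.1, 0.1, 0.8],
            ]
        )
        y = [0, 0, 0, 1, 1, 1]
        for div, fn in (("mse", oracle_mse), ("cross_entropy", oracle_cross_entropy)):
            model = dv.fit(X, y, divergence=div)
            (M0, M1, m0, s0, m1, s1), _ = oracle_fit_predict(X.tolist(), y, [], fn)
            assert np.allclose(model.M0, M0, atol=1e-12)
            assert np.allclose(model.M1, M1, atol=1e-12)
            for got, want in ((model.m0, m0), (model.s0, s0), (model.m1, m1), (model.s1, s1)):
                assert got == pytest.approx(want, abs=1e-10)

    def test_order_of_training_samples_is_irrelevant(self, rng):
        X, y = _random_instance(np.random.default_rng(5), 6, 20)
        perm = np.random.default_rng(6).permutation(20)
        a = dv.fit(X, y, divergence="cross_entropy")
        b = dv.fit(X[perm], y[perm], divergence="cross_entropy")
        Xtest = np.vstack([random_density(rng, 6) for _ in range(10)])
        assert np.array_equal(dv.predict(a, Xtest), dv.predict(b, Xtest))


class TestPredict:
    @pytest.mark.parametrize("div", ["mse", "cross_entropy"])
    def test_matches_oracle_on_many_random_instances(self, div):
        """fit/predict agree with the brute-force procedure on 120 random
        small instances (3–10 bins, 6–40 samples)."""
        fn = oracle_mse if div == "mse" else oracle_cross_entropy
        r = np.random.default_rng(2022)
        for _ in range(120):
            n_bins = int(r.integers(3, 11))
            n_train = int(r.integers(6, 41))
            n_test = int(r.integers(1, 15))
            X, y = _random_instance(r, n_bins, n_train)
            Xtest = np.vstack([random_density(r, n_bins, full_support=True)
                               for _ in range(n_test)])
            model = dv.fit(X, y, divergence=div)
            got = dv.predict(model, Xtest)
            _, want = oracle_fit_predict(X.tolist(), y.tolist(), Xtest.tolist(), fn)
            assert got.tolist() == want

    def test_log_base_does_not_change_predictions(self):
        """z-normalization absorbs the log base of the cross-entropy."""
        r = np.random.default_rng(11)
        X, y = _random_instance(r, 8, 30)
        Xtest = np.vstack([random_density(r, 8, full_support=True) for _ in range(20)])
        model = dv.fit(X, y, divergence="cross_entropy")
        got = dv.predict(model, Xtest)
        _, want = oracle_fit_predict(
            X.tolist(), y.tolist(), Xtest.tolist(),
            lambda p, q: oracle_cross_entropy(p, q, log=math.log2),
        )
        assert got.tolist() == want

    def test_sample_equal_to_representative_takes_its_class(self):
        a = np.array([0.8, 0.15, 0.05])
        b = np.array([0.05, 0.15, 0.8])
        X = np.vstack([a, a * 0.9 + b * 0.1, b, b * 0.9 + a * 0.1])
        model = dv.fit(X, [0, 0, 1, 1], divergence="mse")
        assert dv.predict(model, np.vstack([model.M1]))[0] == 1
        assert dv.predict(model, np.vstack([model.M0]))[0] == 0

    def test_exact_tie_goes_to_class_zero(self):
        model = dv.DivergenceModel(
            M0=np.array([0.5, 0.5]),
            M1=np.array([0.5, 0.5]),
            m0=0.0, s0=1.0, m1=0.0, s1=1.0,
            divergence="mse",
        )
        assert dv.predict(model, np.array([[0.4, 0.6]]))[0] == 0

    def test_nearest_centroid_equivalence_with_equal_stats(self, rng):
        """With equal (m, s) the MSE rule reduces to nearest centroid."""
        for _ in range(100):
            M0 = random_density(rng, 5, full_support=True)
            M1 = random_density(rng, 5, full_support=True)
            x = random_density(rng, 5, full_support=True)
            model = dv.DivergenceModel(
                M0=M0, M1=M1, m0=0.3, s0=0.7, m1=0.3, s1=0.7, divergence="mse"
            )
            want = 1 if dv.mse(x, M1) < dv.mse(x, M0) else 0
            assert dv.predict(model, x[None, :])[0] == want


class TestPerClassSwitch:
    def test_per_class_stats_pools_only_matching_class(self):
        X = np.array(
            [[0.7, 0.3], [0.8, 0.2], [0.2, 0.8], [0.3, 0.7], [0.75, 0.25], [0.25, 0.75]]
        )
        y = [0, 0, 1, 1, 0, 1]
        pooled = dv.fit(X, y, divergence="mse")
        restricted = dv.fit(X, y, divergence="mse", per_class_stats=True)
        assert not np.isclose(pooled.m0, restricted.m0)
        assert np.allclose(pooled.M0, restricted.M0)


def test_model_json_round_trip():
    r = np.random.default_rng(1)
    X, y = _random_instance(r, 6, 12)
    model = dv.fit(X, y, divergence="cross_entropy")
    clone = dv.DivergenceModel.from_json(model.to_json())
    Xtest = np.vstack([random_density(r, 6) for _ in range(8)])
    assert np.array_equal(dv.predict(model, Xtest), dv.predict(clone, Xtest))
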