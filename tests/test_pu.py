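import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sozpu
from sozpu.core_io import ConfigError
from sozpu.pu import (
    PUClassifier,
    PUTrainConfig,
    empirical_risk,
    prior_from_composition,
    pu_risk,
    supervised_risk,
    train_pu,
)


class TestEmpiricalRisk:
    def test_confident_positives_have_near_zero_risk(self):
        assert empirical_risk(np.full(10, 50.0), +1, "sigmoid") == pytest.approx(0, abs=1e-9)

    def test_sigmoid_midpoint(self):
        assert empirical_risk(np.zeros(7), +1, "sigmoid") == 0.5
        assert empirical_risk(np.zeros(7), -1, "sigmoid") == 0.5

    def test_hand_evaluated_pair(self):
        # l(z,-1) = sigma(z); (sigma(1) + sigma(-1))/2 = 0.5 exactly
        assert empirical_risk(np.array([1.0, -1.0]), -1, "sigmoid") == pytest.approx(0.5)

    def test_empty_scores_rejected(self):
        with pytest.raises(ConfigError):
            empirical_risk(np.array([]), +1)

    def test_invalid_target_rejected(self):
        with pytest.raises(ConfigError):
            empirical_risk(np.ones(3), 0)


class TestPURisk:
    def test_all_positive_classifier_zero_one(self):
        """g that calls everything positive: R_p+ = 0, R_u- = 1, R_p- = 1, so
        r_pu = pi_p*0 + 1 - pi_p = 1 - pi_p."""
        zp = np.ones(20)
        zu = np.ones(50)
        for pi_p in (0.2, 0.5, 0.7):
            comp = pu_risk(zp, zu, pi_p, loss="zero_one")
            assert comp.r_pu == pytest.approx(1 - pi_p)

    def test_small_prior_limit(self):
        zp = np.random.default_rng(0).standard_normal(30)
        zu = np.random.default_rng(1).standard_normal(100)
        comp = pu_risk(zp, zu, 1e-9 + 1e-12, loss="sigmoid")
        assert comp.r_pu == pytest.approx(comp.r_u_minus, abs=1e-8)

    def test_composition_exact_equals_supervised_risk(self):
        """With X_u made of k score-identical copies of the positives plus m
        negatives and pi_p = k/(k+m), the PU risk equals the revealed-label
        supervised risk exactly."""
        rng = np.random.default_rng(2)
        zp = rng.standard_normal(40)
        zn = rng.standard_normal(60) - 1.0
        k_copies = 2
        zu = np.concatenate([np.tile(zp, k_copies), zn])
        pi_p = (k_copies * len(zp)) / len(zu)
        comp = pu_risk(zp, zu, pi_p, loss="sigmoid")
        assert comp.r_pu == pytest.approx(
            supervised_risk(zp, zn, pi_p, "sigmoid"), abs=1e-14
        )

    def test_invalid_prior_rejected(self):
        with pytest.raises(ConfigError):
            pu_risk(np.ones(3), np.ones(3), 1.2)

    def test_correction_floors_negative_part(self):
        # confident positives (R_p- ~ 1) with confidently-negative unlabeled
        # scores (R_u- ~ 0) drive R_u- - pi_p R_p- below zero
        zp = np.full(10, 10.0)
        zu = np.full(10, -10.0)
        raw = pu_risk(zp, zu, 0.9, nn_correction=False)
        cor = pu_risk(zp, zu, 0.9, nn_correction=True)
        assert raw.r_pu < cor.r_pu
        assert cor.r_pu == pytest.approx(0.9 * cor.r_p_plus, abs=1e-12)
        assert cor.corrected

    def test_correction_inactive_when_negative_part_positive(self):
        rng = np.random.default_rng(3)
        zp = rng.standard_normal(30) + 1
        zu = rng.standard_normal(80) - 1
        raw = pu_risk(zp, zu, 0.3, nn_correction=False)
        cor = pu_risk(zp, zu, 0.3, nn_correction=True)
        assert raw.r_pu == cor.r_pu
        assert not cor.corrected


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.05, 0.95))
def test_pu_risk_identity(seed, pi_p):
    """The uncorrected estimator satisfies
    r_pu = pi_p*R_p+ + R_u- - pi_p*R_p- to machine precision."""
    rng = np.random.default_rng(seed)
    zp = 3 * rng.standard_normal(rng.integers(1, 50))
    zu = 3 * rng.standard_normal(rng.integers(1, 80))
    comp = pu_risk(zp, zu, pi_p, loss="sigmoid", nn_correction=False)
    assert comp.r_pu == pytest.approx(
        pi_p * comp.r_p_plus + comp.r_u_minus - pi_p * comp.r_p_minus, abs=1e-15
    )
    # with a [0,1]-bounded loss every component is in [0,1]
    for v in (comp.r_p_plus, comp.r_p_minus, comp.r_u_minus):
        assert 0.0 <= v <= 1.0


def test_uncorrected_risk_is_unbiased():
    """Resampling the unlabeled set from the positive/negative pools leaves
    the mean PU risk within 2 standard errors of the supervised risk."""
    rng = np.random.default_rng(4)
    pool_p = rng.standard_normal(400) + 1.0
    pool_n = rng.standard_normal(600) - 1.0
    pi_p = 0.4
    target = supervised_risk(pool_p, pool_n, pi_p, "sigmoid")
    vals = []
    for _ in range(200):
        n_u = 300
        take_p = rng.binomial(n_u, pi_p)
        zu = np.concatenate([
            rng.choice(pool_p, size=take_p, replace=True),
            rng.choice(pool_n, size=n_u - take_p, replace=True),
        ])
        vals.append(pu_risk(pool_p, zu, pi_p, "sigmoid").r_pu)
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - target) <= 2 * se


class TestPrior:
    def test_fold_composition_arithmetic(self):
        assert prior_from_composition(6750, 2142, 11358) == pytest.approx(
            (6750 - 2142) / 11358
        )
        assert prior_from_composition(6750, 2142, 11358) == pytest.approx(0.4057, abs=5e-4)

    def test_all_positives_labeled_rejected(self):
        with pytest.raises(ConfigError):
            prior_from_composition(100, 100, 500)

    def test_balanced_unlabeled_none_labeled(self):
        assert prior_from_composition(500, 0, 1000) == 0.5


class TestPUTraining:
    @staticmethod
    def _pu_problem(rng, n_pos=300, n_neg=300, labeled_frac=0.15, sep=4.0):
        Xp_all = rng.normal((+sep / 2, 0), 1.0, size=(n_pos, 2))
        Xn_all = rng.normal((-sep / 2, 0), 1.0, size=(n_neg, 2))
        n_lab = int(round(labeled_frac * n_pos))
        X_p = Xp_all[:n_lab]
        X_u = np.vstack([Xp_all[n_lab:], Xn_all])
        pi_p = prior_from_composition(n_pos, n_lab, len(X_u))
        y_u = np.array(["SOZ"] * (n_pos - n_lab) + ["NONSOZ"] * n_neg, dtype=object)
        return X_p, X_u, pi_p, y_u

    def test_separable_problem_learned_from_15pct_labels(self):
        rng = np.random.default_rng(0)
        X_p, X_u, pi_p, y_u = self._pu_problem(rng)
        res = train_pu(X_p, X_u, pi_p, PUTrainConfig(epochs=50, seed=0),
                       eval_set=(X_u, y_u))
        assert res.epoch_trace[-1] >= 95.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        X_p, X_u, pi_p, y_u = self._pu_problem(rng, n_pos=120, n_neg=120)
        t1 = train_pu(X_p, X_u, pi_p, PUTrainConfig(epochs=10, seed=5),
                      eval_set=(X_u, y_u)).epoch_trace
        t2 = train_pu(X_p, X_u, pi_p, PUTrainConfig(epochs=10, seed=5),
                      eval_set=(X_u, y_u)).epoch_trace
        np.testing.assert_array_equal(t1, t2)

    def test_pu_decision_agrees_with_supervised_rule(self):
        """Median over 10 seeds: PU training recovers a decision rule agreeing
        with the fully supervised one on >90% of held-out points."""
        from sozpu.classifiers import FCNNClassifier

        agreements = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X_p, X_u, pi_p, y_u = self._pu_problem(rng, n_pos=200, n_neg=200)
            held = rng.normal(0, 2.0, size=(300, 2))
            pu = PUClassifier(pi_p=pi_p, epochs=40, seed=seed)
            s = np.concatenate([np.ones(len(X_p), int), np.zeros(len(X_u), int)])
            pu.fit(np.vstack([X_p, X_u]), s)
            sup = FCNNClassifier(epochs=40, seed=seed)
            sup.fit(X_u, y_u)
            agreements.append(np.mean(pu.predict(held) == sup.predict(held)))
        assert np.median(agreements) > 0.90

    def test_invalid_prior_rejected(self):
        clf = PUClassifier(pi_p=1.5, epochs=1)
        with pytest.raises(ConfigError):
            clf.fit(np.zeros((4, 2)), np.array([1, 1, 0, 0]))

    def test_needs_both_pools(self):
        clf = PUClassifier(pi_p=0.5, epochs=1)
        with pytest.raises(ConfigError):
            clf.fit(np.zeros((4, 2)), np.array([1, 1, 1, 1]))
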