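"""GMM-HMM correctness: densities, forward-backward and Viterbi against
brute-force path enumeration, EM monotonicity, parameter recovery, and
the epoch posterior grid."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegevent.edf_io import CLASS_ORDER, ClassLabel
from eegevent.features import FeatureSequence
from eegevent.hmm import (
    EpochPosteriorGrid,
    HmmModel,
    HmmTrainConfig,
    batch_loglik,
    baum_welch_update,
    forward_backward,
    gaussian_mixture_density,
    score_epochs,
    state_log_likelihoods,
    train_class_models,
    train_model,
    transition_posteriors,
    viterbi,
)

# ---------------------------------------------------------------------------
# Independent oracle: exhaustive sum/max over all state paths
# ---------------------------------------------------------------------------

def brute_force(model: HmmModel, obs: np.ndarray):
    """(log-likelihood, best path, best log score) by path enumeration."""
    T = obs.shape[0]
    S = model.n_states
    log_b = state_log_likelihoods(obs, model)
    with np.errstate(divide="ignore"):
        log_a = np.log(model.trans)
    total = -np.inf
    best_score, best_path = -np.inf, None
    for path in itertools.product(range(S), repeat=T):
        if path[0] != 0:
            continue
        score = log_b[0, path[0]]
        for t in range(1, T):
            score += log_a[path[t - 1], path[t]] + log_b[t, path[t]]
        total = np.logaddexp(total, score)
        if score > best_score:
            best_score, best_path = score, path
    return total, np.array(best_path), best_score


def random_model(rng: np.random.Generator, n_states: int, dim: int = 2,
                 n_comp: int = 1) -> HmmModel:
    trans = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        stay = rng.uniform(0.2, 0.8)
        trans[i, i], trans[i, i + 1] = stay, 1 - stay
    trans[-1, -1] = 1.0
    w = rng.dirichlet(np.ones(n_comp), size=n_states)
    means = rng.normal(0, 2, size=(n_states, n_comp, dim))
    variances = rng.uniform(0.5, 2.0, size=(n_states, n_comp, dim))
    return HmmModel(trans, w, means, variances)


def toy_2state() -> HmmModel:
    return HmmModel(
        trans=np.array([[0.6, 0.4], [0.0, 1.0]]),
        weights=np.ones((2, 1)),
        means=np.array([[[-1.0]], [[2.0]]]),
        variances=np.array([[[1.0]], [[0.5]]]),
    )


class TestDensity:
    def test_standard_normal_at_mode(self):
        m = HmmModel(np.eye(1), np.ones((1, 1)), np.zeros((1, 1, 1)),
                     np.ones((1, 1, 1)))
        val = gaussian_mixture_density(np.array([0.0]), m, state=0)
        assert np.isclose(val, 1.0 / np.sqrt(2 * np.pi))

    def test_duplicate_components_degenerate(self):
        m1 = HmmModel(np.eye(1), np.ones((1, 1)), np.zeros((1, 1, 3)),
                      np.ones((1, 1, 3)))
        m2 = HmmModel(np.eye(1), np.full((1, 2), 0.5),
                      np.zeros((1, 2, 3)), np.ones((1, 2, 3)))
        x = np.array([0.3, -0.2, 1.0])
        assert np.isclose(gaussian_mixture_density(x, m1, 0),
                          gaussian_mixture_density(x, m2, 0))

    def test_26dim_identity_covariance_at_mean(self):
        d = 26
        m = HmmModel(np.eye(1), np.ones((1, 1)), np.zeros((1, 1, d)),
                     np.ones((1, 1, d)))
        val = gaussian_mixture_density(np.zeros(d), m, 0)
        assert np.isclose(val, (2 * np.pi) ** (-d / 2))


class TestForwardBackward:
    def test_single_state_loglik(self, rng):
        m = HmmModel(np.eye(1), np.ones((1, 1)), np.zeros((1, 1, 2)),
                     np.ones((1, 1, 2)))
        obs = rng.normal(size=(5, 2))
        trellis = forward_backward(m, obs)
        expected = state_log_likelihoods(obs, m).sum()
        assert np.isclose(trellis.loglik, expected)

    def test_toy_matches_brute_force(self, rng):
        m = toy_2state()
        obs = rng.normal(size=(3, 1))
        trellis = forward_backward(m, obs)
        total, _, _ = brute_force(m, obs)
        assert np.isclose(trellis.loglik, total, atol=1e-10)

    def test_alpha_beta_product_constant(self, rng):
        m = random_model(rng, 3)
        obs = rng.normal(size=(6, 2))
        trellis = forward_backward(m, obs)
        products = (trellis.alpha * trellis.beta).sum(axis=1)
        assert np.allclose(products, 1.0, atol=1e-9)

    def test_underflow_raises(self):
        from eegevent.hmm import UnderflowError

        m = HmmModel(np.eye(1), np.ones((1, 1)),
                     np.zeros((1, 1, 1)), np.full((1, 1, 1), 1e-12))
        with pytest.raises(UnderflowError):
            forward_backward(m, np.array([[1e6]]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), n_states=st.integers(1, 3),
           T=st.integers(1, 6))
    def test_property_forward_equals_path_sum(self, seed, n_states, T):
        rng = np.random.default_rng(seed)
        m = random_model(rng, n_states)
        obs = rng.normal(size=(T, 2))
        trellis = forward_backward(m, obs)
        total, _, _ = brute_force(m, obs)
        assert np.isclose(trellis.loglik, total, atol=1e-9)

    def test_matches_hmmlearn(self, rng):
        """Independent cross-check against hmmlearn's forward scoring."""
        from hmmlearn.hmm import GaussianHMM

        m = random_model(rng, 3, dim=2)
        obs = rng.normal(size=(20, 2))
        ref = GaussianHMM(n_components=3, covariance_type="diag",
                          init_params="")
        ref.startprob_ = np.array([1.0, 0.0, 0.0])
        ref.transmat_ = m.trans
        ref.means_ = m.means[:, 0, :]
        ref.covars_ = m.variances[:, 0, :]
        assert np.isclose(forward_backward(m, obs).loglik, ref.score(obs),
                          atol=1e-8)


class TestTransitionPosteriors:
    def test_single_state_all_one(self, rng):
        m = HmmModel(np.eye(1), np.ones((1, 1)), np.zeros((1, 1, 2)),
                     np.ones((1, 1, 2)))
        obs = rng.normal(size=(4, 2))
        xi = transition_posteriors(forward_backward(m, obs), m, obs)
        assert np.allclose(xi[1:, 0, 0], 1.0)

    def test_toy_matches_enumeration(self, rng):
        m = toy_2state()
        obs = rng.normal(size=(4, 1))
        xi = transition_posteriors(forward_backward(m, obs), m, obs)
        # brute-force posterior of transition (i at t-1, j at t)
        log_b = state_log_likelihoods(obs, m)
        with np.errstate(divide="ignore"):
            log_a = np.log(m.trans)
        joint = np.zeros((4, 2, 2))
        total = -np.inf
        for path in itertools.product(range(2), repeat=4):
            if path[0] != 0:
                continue
            score = log_b[0, 0]
            for t in range(1, 4):
                score += log_a[path[t - 1], path[t]] + log_b[t, path[t]]
            if not np.isfinite(score):
                continue
            total = np.logaddexp(total, score)
            for t in range(1, 4):
                joint[t, path[t - 1], path[t]] += np.exp(score)
        joint /= np.exp(total)
        assert np.allclose(xi[1:], joint[1:], atol=1e-10)

    def test_forbidden_transition_zero(self, rng):
        m = toy_2state()  # a_10 == 0
        obs = rng.normal(size=(5, 1))
        xi = transition_posteriors(forward_backward(m, obs), m, obs)
        assert np.all(xi[:, 1, 0] == 0.0)

    def test_rows_sum_to_one(self, rng):
        m = random_model(rng, 3)
        obs = rng.normal(size=(6, 2))
        xi = transition_posteriors(forward_backward(m, obs), m, obs)
        assert np.allclose(xi[1:].sum(axis=(1, 2)), 1.0, atol=1e-9)


class TestBaumWelch:
    def test_em_monotone_on_model_data(self, rng):
        m = random_model(rng, 2)
        data = rng.normal(size=(20, 8, 2))
        m1, ll0 = baum_welch_update(m, data)
        _, ll1 = baum_welch_update(m1, data)
        assert ll1 >= ll0 - 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_em_monotone_20_iterations(self, seed):
        rng = np.random.default_rng(seed)
        m = random_model(rng, 2, dim=2)
        data = rng.normal(size=(15, 6, 2))
        prev = -np.inf
        for _ in range(20):
            m, ll = baum_welch_update(m, data)
            assert ll >= prev - 1e-8 * max(1.0, abs(ll))
            prev = ll

    def test_left_right_mask_preserved(self, rng):
        m = random_model(rng, 3)
        data = rng.normal(size=(10, 6, 2))
        for _ in range(3):
            m, _ = baum_welch_update(m, data)
        assert np.all(np.tril(m.trans, k=-1) == 0.0)
        assert np.all(np.triu(m.trans, k=2) == 0.0)

    def test_parameter_recovery(self):
        """2-state 1-component model recovered from simulated sequences."""
        rng = np.random.default_rng(42)
        true = HmmModel(
            trans=np.array([[0.8, 0.2], [0.0, 1.0]]),
            weights=np.ones((2, 1)),
            means=np.array([[[0.0, 0.0]], [[3.0, -2.0]]]),
            variances=np.ones((2, 1, 2)),
        )
        seqs = []
        for _ in range(500):
            state, frames = 0, []
            for _t in range(20):
                frames.append(rng.normal(true.means[state, 0], 1.0))
                state = rng.choice(2, p=true.trans[state])
            seqs.append(frames)
        data = np.asarray(seqs)
        m = random_model(np.random.default_rng(1), 2, dim=2)
        for _ in range(30):
            m, _ = baum_welch_update(m, data)
        assert np.max(np.abs(m.means[:, 0, :] - true.means[:, 0, :])) < 0.1
        assert abs(m.trans[0, 0] - 0.8) < 0.05

    def test_recovery_improves_with_sample_size(self):
        rng = np.random.default_rng(9)
        true_means = np.array([[[0.0]], [[2.5]]])
        trans = np.array([[0.7, 0.3], [0.0, 1.0]])

        def fit(n):
            r = np.random.default_rng(100)
            seqs = []
            for _ in range(n):
                state, frames = 0, []
                for _t in range(12):
                    frames.append(r.normal(true_means[state, 0], 1.0))
                    state = r.choice(2, p=trans[state])
                seqs.append(frames)
            m = random_model(np.random.default_rng(2), 2, dim=1)
            for _ in range(25):
                m, _ = baum_welch_update(m, np.asarray(seqs))
            return np.max(np.abs(m.means - true_means))

        assert fit(500) <= fit(50) + 1e-6


class TestViterbi:
    def test_single_state(self, rng):
        m = HmmModel(np.eye(1), np.ones((1, 1)), np.zeros((1, 1, 2)),
                     np.ones((1, 1, 2)))
        obs = rng.normal(size=(5, 2))
        path, score = viterbi(m, obs)
        assert np.all(path == 0)
        assert np.isclose(score, state_log_likelihoods(obs, m).sum())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), n_states=st.integers(1, 3),
           T=st.integers(1, 6))
    def test_property_matches_enumeration(self, seed, n_states, T):
        rng = np.random.default_rng(seed)
        m = random_model(rng, n_states)
        obs = rng.normal(size=(T, 2))
        path, score = viterbi(m, obs)
        _, best_path, best_score = brute_force(m, obs)
        assert np.isclose(score, best_score, atol=1e-9)
        assert np.array_equal(path, best_path)

    def test_score_below_forward(self, rng):
        m = random_model(rng, 3)
        obs = rng.normal(size=(8, 2))
        _, score = viterbi(m, obs)
        assert score <= forward_backward(m, obs).loglik + 1e-10


class TestTraining:
    def test_missing_class_rejected(self, rng):
        segs = {c: rng.normal(size=(5, 10, 4)) for c in CLASS_ORDER}
        segs[ClassLabel.EYEM] = np.empty((0, 10, 4))
        with pytest.raises(ValueError, match="EYEM"):
            train_class_models(segs, HmmTrainConfig(n_components=1))

    def test_single_segment_trains(self, rng):
        data = rng.normal(size=(1, 10, 4))
        m = train_model(data, HmmTrainConfig(n_states=2, n_components=2,
                                             iters_per_stage=2,
                                             final_iters=2))
        m.validate()

    def test_separated_classes_score_highest_on_own_data(self, rng):
        """Held-out segments most likely under their own class model."""
        config = HmmTrainConfig(n_states=2, n_components=2,
                                iters_per_stage=3, final_iters=3)
        offsets = {c: 4.0 * i for i, c in enumerate(CLASS_ORDER)}
        train = {c: rng.normal(offsets[c], 1.0, size=(40, 10, 3))
                 for c in CLASS_ORDER}
        models = train_class_models(train, config)
        hits = total = 0
        for c in CLASS_ORDER:
            held = rng.normal(offsets[c], 1.0, size=(20, 10, 3))
            for seg in held:
                scores = [batch_loglik(models[k], seg[None]) for k in
                          CLASS_ORDER]
                hits += int(CLASS_ORDER[int(np.argmax(scores))] is c)
                total += 1
        assert hits / total >= 0.9


class TestScoreEpochs:
    def _features(self, data):
        return [FeatureSequence(frames=d, frame_step=0.1, channel_index=i)
                for i, d in enumerate(data)]

    def test_identical_models_uniform_posteriors(self, rng):
        m = random_model(rng, 2, dim=3)
        models = {c: m for c in CLASS_ORDER}
        feats = self._features(rng.normal(size=(4, 30, 3)))
        grid = score_epochs(models, feats)
        assert grid.scores.shape == (3, 4, 6)
        assert np.allclose(grid.scores, 1 / 6)

    def test_posterior_rows_normalized(self, rng):
        models = {c: random_model(rng, 2, dim=3) for c in CLASS_ORDER}
        feats = self._features(rng.normal(size=(4, 30, 3)))
        grid = score_epochs(models, feats)
        assert np.allclose(grid.scores.sum(axis=2), 1.0, atol=1e-9)

    def test_matching_model_wins(self, rng):
        models = {c: HmmModel(np.eye(1), np.ones((1, 1)),
                              np.full((1, 1, 3), 4.0 * i),
                              np.ones((1, 1, 3)), c)
                  for i, c in enumerate(CLASS_ORDER)}
        feats = self._features(
            rng.normal(0.0, 1.0, size=(1, 10, 3)))  # matches SPSW offset 0
        grid = score_epochs(models, feats)
        assert CLASS_ORDER[int(grid.scores[0, 0].argmax())] is ClassLabel.SPSW
        assert grid.scores[0, 0].max() > 0.5

    def test_channel_permutation_invariance(self, rng):
        models = {c: random_model(rng, 2, dim=3) for c in CLASS_ORDER}
        data = rng.normal(size=(4, 30, 3))
        grid = score_epochs(models, self._features(data))
        perm = [2, 0, 3, 1]
        grid_p = score_epochs(models, self._features(data[perm]))
        assert np.allclose(grid.scores[:, perm, :], grid_p.scores)
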