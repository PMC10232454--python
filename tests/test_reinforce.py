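import numpy as np
import pytest

import helpers_mdp as mdp
from smilesrl import nn
from smilesrl.nn import Adam
from smilesrl.reinforce import (
    ReinforceTuner, RLConfig, Trajectory, compute_returns,
    episode_gradient_weights, reinforce_step, rl_finetune,
)
from smilesrl.rewards import RewardSpec
from smilesrl.sampling import action_mask, policy_distribution, rollout
from smilesrl.vocab import BOS_ID, EOS_ID, build_char_vocab


def brute_force_returns(rewards, gamma):
    """Direct double-sum definition (rewards[t] is R_{t+1}):
    G_t = sum_{j>=t} gamma^(j-t) rewards[j]."""
    T = len(rewards)
    return [sum(gamma ** (j - t) * rewards[j] for j in range(t, T)) for t in range(T)]


class TestReturns:
    def test_terminal_reward_example(self):
        out = compute_returns([0.0, 0.0, 10.0], 0.99)
        assert out == pytest.approx([9.801, 9.9, 10.0], abs=1e-9)

    def test_gamma_one_propagates_terminal_reward(self):
        assert compute_returns([0.0, 0.0, 7.0], 1.0) == [7.0, 7.0, 7.0]

    def test_empty(self):
        assert compute_returns([], 0.9) == []

    def test_backward_recursion_equals_double_sum(self, rng):
        for _ in range(50):
            T = int(rng.integers(1, 12))
            rewards = rng.normal(size=T).tolist()
            gamma = float(rng.uniform(0.1, 1.0))
            assert compute_returns(rewards, gamma) == pytest.approx(
                brute_force_returns(rewards, gamma), rel=1e-12
            )


class TestTrajectory:
    def test_intermediate_rewards_must_be_zero(self):
        with pytest.raises(ValueError, match="intermediate"):
            Trajectory(actions=[3, 2], log_probs=[-1.0, -1.0],
                       rewards=[1.0, 0.0], returns=[0.0, 0.0],
                       terminal_smiles="C")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            Trajectory(actions=[3], log_probs=[], rewards=[0.0],
                       returns=[0.0], terminal_smiles="")

    def test_from_episode_builds_returns(self):
        from smilesrl.sampling import Episode

        tr = Trajectory.from_episode(
            Episode(actions=[3, 3, 2], log_probs=[-0.1] * 3, smiles="CC"),
            terminal_reward=10.0, gamma=0.99,
        )
        assert tr.rewards == [0.0, 0.0, 10.0]
        assert tr.returns == pytest.approx([9.801, 9.9, 10.0], abs=1e-9)


class TestConfig:
    def test_gamma_bounds(self):
        with pytest.raises(ValueError):
            RLConfig(gamma=0.0)
        with pytest.raises(ValueError):
            RLConfig(gamma=1.5)

    def test_defaults_follow_reference_setup(self):
        cfg = RLConfig()
        assert (cfg.gamma, cfg.n_steps, cfg.episodes_per_step) == (0.99, 100, 500)


class TestGradientOracle:
    """Exact-gradient checks on the enumerable toy MDP (gamma = 1)."""

    def test_expectation_equals_enumerated_gradient(self):
        params, cfg, vocab = mdp.make_toy_policy(seed=0)
        ga = mdp.expected_reinforce_gradient(params, cfg)
        gb = mdp.enumerated_objective_gradient(params, cfg)
        for k in ga:
            assert np.max(np.abs(ga[k] - gb[k])) < 1e-8, k

    def test_gradient_matches_finite_differences(self):
        params, cfg, vocab = mdp.make_toy_policy(seed=0)
        grads = mdp.enumerated_objective_gradient(params, cfg)
        h = 1e-6
        check = np.random.default_rng(2)
        for k in params:
            flat = params[k].reshape(-1)
            idx = check.integers(0, flat.size, size=min(4, flat.size))
            for i in idx:
                orig = flat[i]
                flat[i] = orig + h
                up = mdp.objective(params, cfg)
                flat[i] = orig - h
                lo = mdp.objective(params, cfg)
                flat[i] = orig
                fd = -(up - lo) / (2 * h)  # grads are of -J
                assert grads[k].reshape(-1)[i] == pytest.approx(fd, abs=1e-4), k

    def test_sampled_estimator_is_unbiased(self):
        """Batch-mean sampled gradients agree with the exact one within 3 SE."""
        params, cfg, vocab = mdp.make_toy_policy(seed=0)
        exact = mdp.enumerated_objective_gradient(params, cfg)
        direction = {k: np.random.default_rng(5).normal(size=v.shape)
                     for k, v in exact.items()}
        exact_proj = sum(float((exact[k] * direction[k]).sum()) for k in exact)

        def logits_fn(ids):
            return nn.forward(params, cfg, ids)

        rng = np.random.default_rng(123)
        projections = []
        for _ in range(100):
            eps = rollout(logits_fn, vocab, 100, mdp.MAX_STEPS, 1.0, rng)
            trajs = [Trajectory.from_episode(e, mdp.reward(e.smiles), 1.0) for e in eps]
            inputs, targets, weights = episode_gradient_weights(trajs)
            _, grads = nn.weighted_nll_loss(params, cfg, inputs, targets, weights,
                                            action_mask=action_mask(cfg.vocab_size))
            projections.append(
                sum(float((grads[k] * direction[k]).sum()) for k in grads))
        mean = np.mean(projections)
        se = np.std(projections, ddof=1) / np.sqrt(len(projections))
        assert abs(mean - exact_proj) < 3 * se + 1e-12


class TestReinforceStep:
    def test_zero_reward_leaves_params_unchanged(self, tiny_lm):
        model = tiny_lm.clone_with_params()
        before = {k: v.copy() for k, v in model.params_.items()}
        rl = RLConfig(n_steps=1, episodes_per_step=16, seed=0)
        reinforce_step(model.params_, model.config_, model.vocab_, rl,
                       lambda s: 0.0, np.random.default_rng(0), Adam(lr=1e-3))
        for k in before:
            assert np.array_equal(model.params_[k], before[k])

    def test_policy_improvement_toward_rewarded_token(self):
        """Rewarding strings that start with 'A' raises P(first token = A)."""
        vocab = build_char_vocab(["AB"])
        cfg = nn.DecoderConfig(vocab_size=len(vocab), n_layers=1, n_heads=2,
                               d_model=8, d_ff=16, max_len=6, dropout=0.0)
        params = nn.init_params(cfg, np.random.default_rng(3))
        a_id = vocab.token_to_id["A"]

        def p_first_a():
            logits = nn.forward(params, cfg, np.array([[BOS_ID]]))[0, -1]
            return policy_distribution(logits)[a_id]

        before = p_first_a()
        rl = RLConfig(n_steps=20, episodes_per_step=64, gamma=1.0, lr=1e-3, seed=0)
        rng = np.random.default_rng(0)
        opt = Adam(lr=rl.lr)
        for _ in range(20):
            reinforce_step(params, cfg, vocab, rl,
                           lambda s: 1.0 if s.startswith("A") else 0.0, rng, opt)
        assert p_first_a() > before

    def test_diagnostics_fields(self, tiny_lm):
        model = tiny_lm.clone_with_params()
        rl = RLConfig(n_steps=1, episodes_per_step=8, seed=0)
        _, diag = reinforce_step(model.params_, model.config_, model.vocab_, rl,
                                 RewardSpec(kind="qed"), np.random.default_rng(0))
        assert set(diag) == {"mean_reward", "validity", "diversity", "mean_len", "loss"}
        assert diag["mean_reward"] >= 0.0


class TestReinforceTuner:
    def test_zero_steps_is_identity(self, tiny_lm):
        tuner = ReinforceTuner(n_steps=0, episodes_per_step=8, seed=0).fit(tiny_lm)
        for k in tiny_lm.params_:
            assert np.array_equal(tuner.model_.params_[k], tiny_lm.params_[k])
        assert len(tuner.log_) == 0

    def test_log_length_equals_n_steps(self, tiny_lm):
        tuner = ReinforceTuner(n_steps=3, episodes_per_step=8, seed=0).fit(tiny_lm)
        assert len(tuner.log_) == 3
        assert list(tuner.log_.columns) == ["step", "mean_reward", "validity",
                                            "diversity", "mean_len", "loss"]

    def test_input_model_not_mutated(self, tiny_lm):
        before = {k: v.copy() for k, v in tiny_lm.params_.items()}
        ReinforceTuner(n_steps=2, episodes_per_step=8, seed=0).fit(tiny_lm)
        for k in before:
            assert np.array_equal(tiny_lm.params_[k], before[k])

    def test_functional_wrapper(self, tiny_lm):
        model, log = rl_finetune(tiny_lm, RLConfig(n_steps=2, episodes_per_step=8, seed=1))
        assert len(log) == 2
        assert model is not tiny_lm


class TestCheckpointing:
    def test_periodic_checkpoints_are_loadable(self, tiny_lm, tmp_path):
        from smilesrl.lm import SmilesGPT

        ReinforceTuner(n_steps=4, episodes_per_step=8, seed=0,
                       checkpoint_dir=tmp_path, checkpoint_every=2).fit(tiny_lm)
        files = sorted(tmp_path.glob("rl_step*.npz"))
        assert [f.name for f in files] == ["rl_step00002.npz", "rl_step00004.npz"]
        loaded = SmilesGPT.load(files[-1])
        assert loaded.config_ == tiny_lm.config_
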