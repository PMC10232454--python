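"""REINFORCE fine-tuning of the decoder policy on the SMILES-building MDP.

The MDP: states are token prefixes (the empty string initially), actions are
vocabulary tokens plus [EOS], transitions are deterministic appends, and the
reward is zero everywhere except the terminal state, where a molecular
property of the finished string is paid out. The policy gradient is the
Monte-Carlo estimate

    grad J = (1/N) sum_episodes sum_t G_t grad ln pi_theta(a_t | s_t)

with discounted returns G_t = sum_k gamma^(k-1) R_{t+k}; [EOS] is an action
whose log-probability enters the gradient even though the token is never
appended to the string. No baseline is subtracted by default (pure
REINFORCE); a moving-average baseline is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn
from .metrics import diversity as _diversity
from .nn import Adam
from .rewards import RewardSpec
from .sampling import Episode, action_mask, rollout
from .vocab import BOS_ID, EOS_ID, PAD_ID, Vocabulary


def compute_returns(rewards: Sequence[float], gamma: float) -> list[float]:
    """Discounted returns by backward recursion: G_t = R_{t+1} + gamma G_{t+1}.

    ``rewards[t]`` is the reward received after taking the action at step t
    (R_{t+1} in trajectory indexing). Empty input yields an empty list.
    """
    G = 0.0
    out = [0.0] * len(rewards)
    for t in range(len(rewards) - 1, -1, -1):
        G = rewards[t] + gamma * G
        out[t] = G
    return out


@dataclass
class Trajectory:
    """One finished episode with terminal-only rewards and discounted returns."""

    actions: list[int]
    log_probs: list[float]
    rewards: list[float]
    returns: list[float]
    terminal_smiles: str

    def __post_init__(self) -> None:
        n = len(self.actions)
        if not (len(self.log_probs) == len(self.rewards) == len(self.returns) == n):
            raise ValueError("trajectory field lengths differ")
        if any(r != 0.0 for r in self.rewards[:-1]):
            raise ValueError("intermediate rewards must be zero")

    @classmethod
    def from_episode(cls, ep: Episode, terminal_reward: float, gamma: float) -> "Trajectory":
        rewards = [0.0] * (len(ep.actions) - 1) + [float(terminal_reward)]
        return cls(
            actions=list(ep.actions), log_probs=list(ep.log_probs),
            rewards=rewards, returns=compute_returns(rewards, gamma),
            terminal_smiles=ep.smiles,
        )


@dataclass(frozen=True)
class RLConfig:
    """REINFORCE stage configuration (defaults follow the reference setup:
    100 steps of 500 episodes, discount factor 0.99)."""

    gamma: float = 0.99
    n_steps: int = 100
    episodes_per_step: int = 500
    reward: RewardSpec = field(default_factory=RewardSpec)
    seed: int = 0
    lr: float = 1e-5
    baseline: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.n_steps < 0 or self.episodes_per_step < 1:
            raise ValueError("n_steps must be >= 0 and episodes_per_step >= 1")


def episode_gradient_weights(trajectories: Sequence[Trajectory],
                             baseline: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack trajectories into padded (inputs, targets, weights) arrays.

    Teacher-forcing layout: inputs are [BOS]-prefixed action prefixes,
    targets the actions themselves, and weights (G_t - baseline) / N so that
    the weighted NLL of :func:`smilesrl.nn.weighted_nll_loss` is exactly the
    negated REINFORCE objective estimate.
    """
    N = len(trajectories)
    T = max(len(tr.actions) for tr in trajectories)
    inputs = np.full((N, T), PAD_ID, dtype=np.int64)
    targets = np.full((N, T), -1, dtype=np.int64)
    weights = np.zeros((N, T))
    inputs[:, 0] = BOS_ID
    for i, tr in enumerate(trajectories):
        L = len(tr.actions)
        # input at position t is the (t-1)-th appended token; [EOS] only ever
        # occurs as the final action, so actions[:-1] is exactly the string body
        inputs[i, 1:L] = tr.actions[:L - 1]
        targets[i, :L] = tr.actions
        weights[i, :L] = (np.asarray(tr.returns) - baseline) / N
    return inputs, targets, weights


def reinforce_step(params: dict, cfg: nn.DecoderConfig, vocab: Vocabulary,
                   rl_config: RLConfig, reward_fn: Callable[[str], float],
                   rng: np.random.Generator, opt: Optional[Adam] = None,
                   baseline_value: float = 0.0) -> tuple[dict, dict]:
    """One policy-gradient ascent step; returns (params, diagnostics).

    Samples ``episodes_per_step`` on-policy trajectories, scores the terminal
    strings, and ascends the Monte-Carlo gradient estimate in place.
    """
    def logits_fn(ids):
        return nn.forward(params, cfg, ids)

    eps = rollout(logits_fn, vocab, rl_config.episodes_per_step,
                  cfg.max_len - 1, 1.0, rng)
    trajectories = [
        Trajectory.from_episode(e, reward_fn(e.smiles), rl_config.gamma) for e in eps
    ]
    b = baseline_value if rl_config.baseline else 0.0
    inputs, targets, weights = episode_gradient_weights(trajectories, baseline=b)
    loss, grads = nn.weighted_nll_loss(
        params, cfg, inputs, targets, weights,
        action_mask=action_mask(cfg.vocab_size),
    )
    bad = [k for k, g in grads.items() if not np.all(np.isfinite(g))]
    if bad or not math.isfinite(loss):
        raise FloatingPointError(
            f"non-finite REINFORCE gradient (loss={loss}, arrays={bad[:5]}); "
            f"mean reward {np.mean([t.rewards[-1] for t in trajectories]):.4f}"
        )
    if opt is None:
        opt = Adam(lr=rl_config.lr)
    opt.step(params, grads)

    terminal_rewards = np.array([t.rewards[-1] for t in trajectories])
    smiles = [t.terminal_smiles for t in trajectories]
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        div = _diversity(smiles)
    diagnostics = {
        "mean_reward": float(terminal_rewards.mean()),
        "validity": float(np.mean([r > 0 for r in terminal_rewards])),
        "diversity": float(div),
        "mean_len": float(np.mean([len(t.actions) for t in trajectories])),
        "loss": float(loss),
    }
    return params, diagnostics


class ReinforceTuner(BaseEstimator):
    """Scikit-learn style REINFORCE fine-tuner for a fitted :class:`SmilesGPT`.

    ``fit(lm)`` copies the language model and runs ``n_steps`` policy-gradient
    steps against the configured reward; the tuned model is ``model_`` and
    the per-step training log (mean reward, validity, diversity, mean length)
    is ``log_``. The input model is not modified.
    """

    def __init__(self, reward: str = "qed", scorer=None, gamma: float = 0.99,
                 n_steps: int = 100, episodes_per_step: int = 500,
                 lr: float = 1e-5, baseline: bool = False, seed: int = 0,
                 checkpoint_dir=None, checkpoint_every: Optional[int] = None):
        self.reward = reward
        self.scorer = scorer
        self.gamma = gamma
        self.n_steps = n_steps
        self.episodes_per_step = episodes_per_step
        self.lr = lr
        self.baseline = baseline
        self.seed = seed
        self.checkpoint_dir = checkpoint_dir
        self.checkpoint_every = checkpoint_every

    def _rl_config(self) -> RLConfig:
        spec = RewardSpec(kind=self.reward, scorer=self.scorer)
        return RLConfig(gamma=self.gamma, n_steps=self.n_steps,
                        episodes_per_step=self.episodes_per_step,
                        reward=spec, seed=self.seed, lr=self.lr,
                        baseline=self.baseline)

    def fit(self, lm, y=None) -> "ReinforceTuner":
        rl = self._rl_config()
        model = lm.clone_with_params()
        rng = np.random.default_rng(rl.seed)
        opt = Adam(lr=rl.lr)
        rows = []
        running = 0.0
        for step in range(rl.n_steps):
            _, diag = reinforce_step(
                model.params_, model.config_, model.vocab_, rl, rl.reward,
                rng, opt, baseline_value=running,
            )
            running = 0.9 * running + 0.1 * diag["mean_reward"]
            rows.append({"step": step, **diag})
            if (self.checkpoint_dir is not None and self.checkpoint_every
                    and (step + 1) % self.checkpoint_every == 0):
                from pathlib import Path

                d = Path(self.checkpoint_dir)
                d.mkdir(parents=True, exist_ok=True)
                model.save(d / f"rl_step{step + 1:05d}.npz")
        self.model_ = model
        self.log_ = pd.DataFrame(
            rows, columns=["step", "mean_reward", "validity", "diversity",
                           "mean_len", "loss"],
        )
        return self


def rl_finetune(lm, rl_config: RLConfig) -> tuple["object", pd.DataFrame]:
    """Functional wrapper: fine-tune a fitted LM, returning (model, log)."""
    tuner = ReinforceTuner(
        reward=rl_config.reward.kind, scorer=rl_config.reward.scorer,
        gamma=rl_config.gamma, n_steps=rl_config.n_steps,
        episodes_per_step=rl_config.episodes_per_step, lr=rl_config.lr,
        baseline=rl_config.baseline, seed=rl_config.seed,
    )
    tuner.fit(lm)
    return tuner.model_, tuner.log_
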