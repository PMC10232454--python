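"""The desk-scale two-stage study: LM pretraining, REINFORCE, paired evaluation.

This mirrors the full two-stage recipe (language modeling, then QED-reward
REINFORCE, then a with/without-RL comparison on freshly sampled molecules) at
sizes a single CPU handles in minutes: a 5,000-molecule synthetic corpus, a
2-layer / d_model-64 decoder trained for 3 epochs, 30 RL steps of 128
episodes, and 1,000-sample evaluations. Directions (post-RL QED above
pre-RL, late-step reward above early-step) are the scientifically meaningful
outputs at this scale; magnitudes are not comparable to full-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import FixtureSpec, generate_fixture_corpus
from .lm import SmilesGPT
from .metrics import MetricsReport, evaluate
from .reinforce import ReinforceTuner


@dataclass(frozen=True)
class ProtocolConfig:
    """Scaled-down study conditions (see docs/methods.md for rationale)."""

    n_corpus: int = 5000
    max_heavy_atoms: int = 9
    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 64
    d_ff: int = 256
    max_len: int = 32
    lm_epochs: int = 3
    lm_batch_size: int = 32
    lm_lr: float = 1e-3
    rl_steps: int = 30
    rl_episodes: int = 128
    rl_lr: float = 1e-4
    gamma: float = 0.99
    n_eval: int = 1000


@dataclass
class ProtocolResult:
    pre: MetricsReport
    post: MetricsReport
    lm_loss_log: pd.DataFrame
    rl_log: pd.DataFrame

    @property
    def reward_first10_mean(self) -> float:
        return float(self.rl_log["mean_reward"].iloc[:10].mean())

    @property
    def reward_last10_mean(self) -> float:
        return float(self.rl_log["mean_reward"].iloc[-10:].mean())


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_two_stage_protocol(seed: int = 0,
                           config: ProtocolConfig = ProtocolConfig()) -> ProtocolResult:
    """Run the full scaled study; every stage is seeded from ``seed``."""
    s_corpus, s_lm, s_rl, s_eval = _derive_seeds(seed, 4)
    corpus = generate_fixture_corpus(
        FixtureSpec(n_molecules=config.n_corpus,
                    max_heavy_atoms=config.max_heavy_atoms, seed=s_corpus)
    )
    lm = SmilesGPT(
        n_layers=config.n_layers, n_heads=config.n_heads, d_model=config.d_model,
        d_ff=config.d_ff, max_len=config.max_len, epochs=config.lm_epochs,
        batch_size=config.lm_batch_size, lr=config.lm_lr, seed=s_lm,
    ).fit(corpus)
    pre_samples = lm.sample(config.n_eval, seed=s_eval)
    pre = evaluate(pre_samples, corpus, n_expected=config.n_eval)

    tuner = ReinforceTuner(
        reward="qed", gamma=config.gamma, n_steps=config.rl_steps,
        episodes_per_step=config.rl_episodes, lr=config.rl_lr, seed=s_rl,
    ).fit(lm)
    post_samples = tuner.model_.sample(config.n_eval, seed=s_eval)
    post = evaluate(post_samples, corpus, n_expected=config.n_eval)

    return ProtocolResult(pre=pre, post=post, lm_loss_log=lm.loss_log_,
                          rl_log=tuner.log_)
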