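"""Autoregressive episode rollout from a policy over SMILES tokens.

An episode starts from the empty string (the initial state), repeatedly
samples an action from the policy's next-token distribution given the
current prefix, and stops when the policy emits [EOS] (which is not appended
to the string) or the prefix reaches the maximum length; truncated episodes
are terminal states and are scored downstream like any other. [PAD] and
[BOS] are not actions: they are masked out of the sampling distribution, so
the policy support is the corpus tokens plus [EOS].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .nn import log_softmax
from .vocab import BOS_ID, EOS_ID, PAD_ID, Vocabulary


@dataclass(frozen=True)
class GenerationConfig:
    """Sampling parameters; temperature 1.0 is pure distribution sampling."""

    n_samples: int = 1
    max_len: int = 150
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass
class Episode:
    """One rollout: actions taken, their log-probabilities, the terminal string."""

    actions: list[int]
    log_probs: list[float]
    smiles: str


def action_mask(vocab_size: int) -> np.ndarray:
    """Boolean support of the policy: everything except [PAD] and [BOS]."""
    m = np.ones(vocab_size, dtype=bool)
    m[PAD_ID] = False
    m[BOS_ID] = False
    return m


def policy_distribution(logits: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Next-token probabilities with non-action tokens masked out."""
    masked = np.where(action_mask(logits.shape[-1]), logits / temperature, -np.inf)
    return np.exp(log_softmax(masked))


def rollout(logits_fn: Callable[[np.ndarray], np.ndarray], vocab: Vocabulary,
            n_samples: int, max_len: int, temperature: float,
            rng: np.random.Generator) -> list[Episode]:
    """Sample ``n_samples`` episodes in parallel from ``logits_fn``.

    ``logits_fn`` maps an id array (B, T) -- [BOS]-prefixed token prefixes --
    to logits (B, T, V); only the final position is consulted at each step.
    """
    if n_samples == 0:
        return []
    V = len(vocab)
    seqs = np.full((n_samples, 1), BOS_ID, dtype=np.int64)
    active = np.ones(n_samples, dtype=bool)
    actions: list[list[int]] = [[] for _ in range(n_samples)]
    logps: list[list[float]] = [[] for _ in range(n_samples)]

    for _ in range(max_len):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        logits = np.asarray(logits_fn(seqs[idx]))[:, -1, :]
        masked = np.where(action_mask(V), logits / temperature, -np.inf)
        logp = log_softmax(masked)
        probs = np.exp(logp)
        u = rng.random(len(idx))
        choice = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        choice = np.minimum(choice, V - 1)
        col = np.full(n_samples, PAD_ID, dtype=np.int64)
        for pos, (row, a) in enumerate(zip(idx, choice)):
            actions[row].append(int(a))
            logps[row].append(float(logp[pos, a]))
            if a == EOS_ID:
                active[row] = False
            else:
                col[row] = a
        seqs = np.concatenate([seqs, col[:, None]], axis=1)

    episodes = []
    for acts, lps in zip(actions, logps):
        body = [a for a in acts if a != EOS_ID]
        episodes.append(Episode(actions=acts, log_probs=lps, smiles=vocab.decode(body)))
    return episodes


def sample_one(logits_fn, vocab: Vocabulary, gen_config: GenerationConfig,
               rng: np.random.Generator) -> tuple[str, Episode]:
    """One episode; returns the SMILES string and its trajectory skeleton."""
    ep = rollout(logits_fn, vocab, 1, gen_config.max_len, gen_config.temperature, rng)[0]
    return ep.smiles, ep


def sample_batch(logits_fn, vocab: Vocabulary, gen_config: GenerationConfig) -> list[str]:
    """``n_samples`` independent draws, deterministic given the config seed."""
    rng = np.random.default_rng(gen_config.seed)
    eps = rollout(logits_fn, vocab, gen_config.n_samples, gen_config.max_len,
                  gen_config.temperature, rng)
    return [e.smiles for e in eps]
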