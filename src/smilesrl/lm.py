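"""SMILES language model: a causal decoder trained on next-token prediction.

:class:`SmilesGPT` is a scikit-learn style estimator. ``fit`` builds the
token vocabulary and minimizes mean next-token cross-entropy with teacher
forcing on ``[BOS] s [EOS]``-framed sequences (padding masked out of the
loss); ``sample`` draws molecules autoregressively from the fitted policy.
The fitted network doubles as the policy for REINFORCE fine-tuning.

Optimizer, learning rate and batch size are this package's defaults (Adam,
1e-4, 64); they are configuration, not part of the reference setup.
"""

from __future__ import annotations

import copy
import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn
from .nn import Adam, DecoderConfig
from .sampling import GenerationConfig, rollout
from .vocab import BOS_ID, EOS_ID, PAD_ID, Vocabulary, build_bpe_vocab, build_char_vocab


class SmilesGPT(BaseEstimator):
    """GPT-style decoder-only language model over SMILES strings.

    Parameters mirror the reference configuration (4 layers, 8 heads,
    d_model 512, d_ff 1024, max_len 150, 3 epochs, character tokenization);
    shrink them for desk-scale work.
    """

    def __init__(self, n_layers: int = 4, n_heads: int = 8, d_model: int = 512,
                 d_ff: int = 1024, max_len: int = 150, dropout: float = 0.1,
                 tokenizer: str = "char", bpe_vocab_size: int = 500,
                 epochs: int = 3, batch_size: int = 64, lr: float = 1e-4,
                 seed: int = 0):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_model = d_model
        self.d_ff = d_ff
        self.max_len = max_len
        self.dropout = dropout
        self.tokenizer = tokenizer
        self.bpe_vocab_size = bpe_vocab_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    # ------------------------------------------------------------------
    def _build_vocab(self, corpus: Sequence[str]) -> Vocabulary:
        if self.tokenizer == "char":
            return build_char_vocab(corpus)
        if self.tokenizer == "bpe":
            return build_bpe_vocab(corpus, target_size=self.bpe_vocab_size)
        raise ValueError(f"unknown tokenizer {self.tokenizer!r}")

    def _framed(self, corpus: Sequence[str]) -> list[list[int]]:
        framed = []
        n_skipped = 0
        for s in corpus:
            ids = self.vocab_.encode(s)
            if len(ids) + 2 > self.max_len:
                n_skipped += 1
                continue
            framed.append([BOS_ID] + ids + [EOS_ID])
        if n_skipped:
            warnings.warn(
                f"skipped {n_skipped} corpus strings longer than max_len-2", stacklevel=2
            )
        if not framed:
            raise ValueError("corpus is empty after length filtering")
        return framed

    def fit(self, X: Iterable[str], y=None) -> "SmilesGPT":
        """Train on an iterable of SMILES strings (one molecule each)."""
        corpus = [s for s in X]
        if not corpus:
            raise ValueError("corpus is empty")
        self.vocab_ = self._build_vocab(corpus)
        self.config_ = DecoderConfig(
            vocab_size=len(self.vocab_), n_layers=self.n_layers,
            n_heads=self.n_heads, d_model=self.d_model, d_ff=self.d_ff,
            max_len=self.max_len, dropout=self.dropout,
        )
        rng = np.random.default_rng(self.seed)
        self.params_ = nn.init_params(self.config_, rng)
        framed = self._framed(corpus)
        opt = Adam(lr=self.lr)
        rows = []
        self.batch_losses_: list[float] = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(framed))
            losses = []
            for start in range(0, len(framed), self.batch_size):
                batch = [framed[i] for i in order[start:start + self.batch_size]]
                loss = self._lm_step(batch, opt, rng)
                losses.append(loss)
                self.batch_losses_.append(loss)
            rows.append({"epoch": epoch, "loss": float(np.mean(losses))})
        self.loss_log_ = pd.DataFrame(rows)
        return self

    def _lm_step(self, batch: list[list[int]], opt: Adam,
                 rng: np.random.Generator) -> float:
        T = max(len(b) for b in batch)
        ids = np.full((len(batch), T), PAD_ID, dtype=np.int64)
        for i, b in enumerate(batch):
            ids[i, :len(b)] = b
        inputs = ids[:, :-1]
        targets = np.where(ids[:, 1:] == PAD_ID, -1, ids[:, 1:])
        loss, grads = nn.weighted_nll_loss(
            self.params_, self.config_, inputs, targets,
            train=True, rng=rng,
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite language-model loss {loss}")
        opt.step(self.params_, grads)
        return float(loss)

    # ------------------------------------------------------------------
    def logits_fn(self, ids: np.ndarray) -> np.ndarray:
        """Inference-mode logits for the sampler / RL stage (dropout off)."""
        return nn.forward(self.params_, self.config_, ids)

    def sample(self, n_samples: int, max_len: Optional[int] = None,
               temperature: float = 1.0, seed: int = 0,
               return_episodes: bool = False):
        """Draw molecules from the fitted policy (deterministic given seed)."""
        self._check_fitted()
        cfg = GenerationConfig(
            n_samples=n_samples,
            max_len=self.config_.max_len - 1 if max_len is None else max_len,
            temperature=temperature, seed=seed,
        )
        rng = np.random.default_rng(cfg.seed)
        eps = rollout(self.logits_fn, self.vocab_, cfg.n_samples, cfg.max_len,
                      cfg.temperature, rng)
        if return_episodes:
            return eps
        return [e.smiles for e in eps]

    def score(self, X: Iterable[str], y=None) -> float:
        """Mean per-token log-likelihood (higher is better) of a held-out corpus."""
        self._check_fitted()
        framed = self._framed(list(X))
        total_lp, total_n = 0.0, 0
        for start in range(0, len(framed), self.batch_size):
            batch = framed[start:start + self.batch_size]
            T = max(len(b) for b in batch)
            ids = np.full((len(batch), T), PAD_ID, dtype=np.int64)
            for i, b in enumerate(batch):
                ids[i, :len(b)] = b
            logits = nn.forward(self.params_, self.config_, ids[:, :-1])
            logp = nn.log_softmax(logits)
            tgt = ids[:, 1:]
            valid = tgt != PAD_ID
            picked = np.take_along_axis(logp, np.where(valid, tgt, 0)[..., None], -1)[..., 0]
            total_lp += float(picked[valid].sum())
            total_n += int(valid.sum())
        return total_lp / max(total_n, 1)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted; call fit() or load()")

    # ------------------------------------------------------------------
    def clone_with_params(self) -> "SmilesGPT":
        """Deep copy including fitted state (used by the RL stage)."""
        new = SmilesGPT(**self.get_params())
        if hasattr(self, "params_"):
            new.vocab_ = self.vocab_
            new.config_ = self.config_
            new.params_ = {k: v.copy() for k, v in self.params_.items()}
            if hasattr(self, "loss_log_"):
                new.loss_log_ = self.loss_log_.copy()
        return new

    def save(self, path) -> None:
        """Versioned checkpoint: hyperparameters + vocabulary + weights (lossless)."""
        self._check_fitted()
        path = Path(path)
        meta = json.dumps({
            "format": "smilesrl-checkpoint-v1",
            "estimator": self.get_params(),
            "config": self.config_.to_dict(),
            "vocab": json.loads(self.vocab_.to_json()),
        })
        with open(path, "wb") as fh:  # keep the exact filename (savez appends .npz)
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                     **self.params_)

    @classmethod
    def load(cls, path) -> "SmilesGPT":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != "smilesrl-checkpoint-v1":
                raise ValueError(f"unrecognized checkpoint format in {path}")
            model = cls(**meta["estimator"])
            model.config_ = DecoderConfig.from_dict(meta["config"])
            model.vocab_ = Vocabulary.from_json(json.dumps(meta["vocab"]))
            model.params_ = {k: data[k].copy() for k in data.files if k != "__meta__"}
        return model


def train_lm(corpus: Iterable[str], config: Optional[dict] = None,
             epochs: int = 3, seed: int = 0) -> SmilesGPT:
    """Functional wrapper: fit a :class:`SmilesGPT` on a SMILES corpus."""
    kwargs = dict(config or {})
    kwargs.update(epochs=epochs, seed=seed)
    return SmilesGPT(**kwargs).fit(corpus)
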