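"""An exhaustively enumerable toy molecule-building MDP for gradient oracles.

Vocabulary {A} plus specials, episode length capped at 2, reward 1 iff the
terminal string is exactly "A". Every trajectory can be enumerated:

    ([EOS],)      -> ""    (stop immediately)
    (A, [EOS])    -> "A"
    (A, A)        -> "AA"  (truncated at the length cap)

With discount 1 the REINFORCE estimator's expectation equals the gradient of
J(theta) = sum over terminal states of p_theta(s) R(s).
"""

import numpy as np

from smilesrl import nn
from smilesrl.nn import DecoderConfig
from smilesrl.sampling import action_mask
from smilesrl.vocab import BOS_ID, EOS_ID, build_char_vocab

MAX_STEPS = 2


def make_toy_policy(seed=0):
    vocab = build_char_vocab(["A"])
    cfg = DecoderConfig(vocab_size=len(vocab), n_layers=1, n_heads=2, d_model=4,
                        d_ff=8, max_len=4, dropout=0.0)
    params = nn.init_params(cfg, np.random.default_rng(seed))
    # break the near-uniform start so gradients are not pathologically small
    params["head.b"] += np.random.default_rng(seed + 1).normal(0, 0.5, cfg.vocab_size)
    return params, cfg, vocab


A_ID = 3  # only non-special token of the {A} vocabulary


def reward(smiles: str) -> float:
    return 1.0 if smiles == "A" else 0.0


def enumerate_trajectories(params, cfg):
    """All (actions, probability, terminal_smiles) triples of the toy MDP."""
    mask = action_mask(cfg.vocab_size)

    def step_probs(prefix):
        logits = nn.forward(params, cfg, np.array([prefix]))[0, -1]
        masked = np.where(mask, logits, -np.inf)
        return np.exp(nn.log_softmax(masked))

    p0 = step_probs([BOS_ID])
    p1 = step_probs([BOS_ID, A_ID])
    return [
        ((EOS_ID,), p0[EOS_ID], ""),
        ((A_ID, EOS_ID), p0[A_ID] * p1[EOS_ID], "A"),
        ((A_ID, A_ID), p0[A_ID] * p1[A_ID], "AA"),
    ]


def objective(params, cfg):
    """J(theta) = sum over terminal states of p_theta(s) R(s), by enumeration."""
    return float(sum(p * reward(s) for _, p, s in enumerate_trajectories(params, cfg)))


def expected_reinforce_gradient(params, cfg):
    """E[sum_t G_t grad ln pi] at gamma=1: per-trajectory backward passes
    averaged under the enumerated trajectory probabilities.

    Returns the gradient of the NEGATED objective (the loss convention of
    ``weighted_nll_loss``)."""
    from smilesrl.reinforce import Trajectory, episode_gradient_weights
    from smilesrl.sampling import Episode

    total = {k: np.zeros_like(v) for k, v in params.items()}
    for actions, p, smiles in enumerate_trajectories(params, cfg):
        tr = Trajectory.from_episode(
            Episode(actions=list(actions), log_probs=[0.0] * len(actions),
                    smiles=smiles),
            terminal_reward=reward(smiles), gamma=1.0)
        inputs, targets, weights = episode_gradient_weights([tr])
        _, grads = nn.weighted_nll_loss(
            params, cfg, inputs, targets, weights,
            action_mask=action_mask(cfg.vocab_size))
        for k in total:
            total[k] += p * grads[k]
    return total


def enumerated_objective_gradient(params, cfg):
    """grad(-J) computed by one probability-weighted batched backward pass."""
    from smilesrl.reinforce import Trajectory, episode_gradient_weights
    from smilesrl.sampling import Episode

    trajs, probs = [], []
    for actions, p, smiles in enumerate_trajectories(params, cfg):
        trajs.append(Trajectory.from_episode(
            Episode(actions=list(actions), log_probs=[0.0] * len(actions),
                    smiles=smiles),
            terminal_reward=reward(smiles), gamma=1.0))
        probs.append(p)
    inputs, targets, weights = episode_gradient_weights(trajs)
    weights = weights * np.array(probs)[:, None] * len(trajs)
    _, grads = nn.weighted_nll_loss(params, cfg, inputs, targets, weights,
                                    action_mask=action_mask(cfg.vocab_size))
    return grads
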