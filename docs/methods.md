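# Methods

## The model

The generator is a decoder-only transformer used autoregressively over
SMILES tokens. Token and position embeddings are both learned; each of the
`n_layers` blocks is the pre-norm residual form

    z = x + MHA(LayerNorm(x))
    out = z + MLP(LayerNorm(z))

with multi-head scaled dot-product attention `softmax(QKᵀ/√d + mask)V`
(causal mask: position *t* attends to positions ≤ *t* only), a two-layer
GELU feed-forward network, a final layer norm and a linear softmax head.
The full-scale configuration is 4 layers, 8 heads, d_model 512, d_ff 1024
and maximum sequence length 150.

Training minimizes mean next-token cross-entropy with teacher forcing on
`[BOS] s [EOS]`-framed sequences; padding positions are masked out of the
loss. Choices the underlying recipe leaves open were fixed as follows and
are configuration, not doctrine:

* learned positional embeddings (GPT convention);
* final layer norm before the output head (GPT-2 convention);
* Adam with learning rate 1e−4 (LM stage) and 1e−5 (RL stage) at full
  scale; batch size 64;
* truncated-normal weight initialization (σ = 0.02, clipped at 2σ), zero
  biases;
* dropout 0.1 applied to the embedding sum and to each sublayer output,
  disabled at sampling time;
* `[BOS]` is prepended during training and sampling; `[EOS]` terminates
  every training sequence.

Everything runs in float64 NumPy. The backward pass is hand-written and is
validated in the test suite against central finite differences for every
parameter family, including the dropout path.

## The molecule-building MDP and REINFORCE

States are token prefixes, starting from the empty string; actions are the
corpus-derived tokens plus `[EOS]` (`[PAD]` and `[BOS]` are masked out of
the sampling distribution — they are bookkeeping, not actions); appending
is deterministic, so p(s′|s,a) = 1. An episode ends when the policy emits
`[EOS]` (not appended to the string) or the length cap is reached;
truncated episodes are ordinary terminal states. Rewards are zero at every
intermediate step; the terminal state is scored by a validity-gated
property function (10·QED, exp(pIC50/3), or an external predictor's
probability in [0, 1]). Any unparseable terminal string scores exactly 0.

Fine-tuning ascends the Monte-Carlo policy gradient
(1/N) Σ_episodes Σ_t G_t ∇ ln π_θ(a_t|s_t) with discounted returns computed
by backward recursion (γ = 0.99 by default, 100 steps of exactly 500
episodes at full scale). `[EOS]`'s log-probability enters the gradient:
termination is a decision of the policy. No baseline is subtracted by
default (pure REINFORCE); a moving-average baseline sits behind a
non-default flag for variance-reduction experiments. Gradients are averaged
over episodes and summed over time steps. Because the LM loss is a full
softmax over the vocabulary while the policy excludes `[PAD]`/`[BOS]`, the
uniform-model cross-entropy baseline is exactly ln(vocab_size) while the
RL gradient uses the masked (action-space) softmax; the two conventions
are applied consistently in training and in the tests.

The two-stage order (LM first, then RL) is the supported path; RL from a
random initialization is known to collapse and is reachable only by
explicitly fine-tuning an untrained model.

### Gradient correctness

On a toy MDP small enough to enumerate (vocabulary {A} plus specials,
length cap 2, reward 1 iff the terminal string is "A"), the expectation of
the REINFORCE estimator is computed two structurally different ways —
per-trajectory backward passes averaged under the enumerated trajectory
probabilities, and a single probability-weighted batched backward — and
must agree within 1e−8; both must match central finite differences of the
enumerated objective J(θ) = Σ_s p_θ(s) R(s) within 1e−4. These checks use
γ = 1, where the estimator's expectation equals ∇J exactly; with γ < 1 the
estimator targets the discounted objective instead. Estimator unbiasedness
is checked separately by comparing batch-mean sampled gradients against
the exact gradient within three standard errors.

## Tokenization

Character-level tokenization is the default and is taken literally:
two-character element symbols (Cl, Br) split into single characters, which
is lossless because decoding is plain concatenation. Specials occupy fixed
ids (`[PAD]` 0, `[BOS]` 1, `[EOS]` 2) and corpus tokens are sorted by
codepoint, so vocabulary construction is deterministic. The alternative
BPE scheme seeds with the character alphabet and greedily merges the most
frequent adjacent pair (ties broken lexicographically) until 500
non-special tokens exist or no pair occurs twice; each corpus line is an
independent word, so merges never cross molecules. The merge list is
stored with the vocabulary, making re-encoding deterministic, and a BPE
vocabulary with zero merges is token-for-token the character vocabulary.

## Evaluation conventions

* **Validity**: percentage of generated strings RDKit parses and
  sanitizes. An empty generated set reports 0% with a warning.
* **Novelty / diversity**: computed on canonical SMILES (raw-string
  comparison would miscount rewritten duplicates) over valid molecules
  only; the report records this denominator choice. The full-scale
  protocol evaluates 25,000 samples.
* **QED / SAS**: RDKit's QED (geometric mean of eight drug-likeness
  properties, range [0, 1]) and the RDKit-contrib synthetic-accessibility
  score (range ≈ [1, 10], higher = harder). Both are consumed as oracles,
  computed after removing invalid molecules, with population (ddof = 0)
  standard deviations; duplicates are scored as often as they occur.
* Percentages are reported to two decimals, rounding half-up.
* Cross-dataset novelty scores one generated set against several named
  corpora with the same convention.

IC50 values are assumed to be in nanomolar, so pIC50 = 9 − log₁₀(IC50)
yields conventional pIC50 magnitudes; the predictor reward refuses outputs
outside [0, 1] rather than clamping, and a scorer failure on a *valid*
molecule raises instead of silently scoring 0, to keep the invalidity-zero
branch semantically clean.

The built-in `DescriptorScorer` is a deterministic ridge regression on
seven simple RDKit descriptors. It exists so the pIC50/predictor reward
paths are exercisable offline; it is a surrogate for interface purposes
and no statement about message-passing predictors follows from it. An
adapter for an external predictor run as a shell command is provided.

## Synthetic corpus generator

Fixture molecules are built as explicit molecular graphs: valence-respecting
random trees over C/N/O with optional branches and one optional 3–6
membered ring, sanitized and canonicalized by RDKit, deduplicated, then
seed-shuffled — so every output is valid and unique by construction and
generation is a pure function of the spec. Defaults: up to 9 heavy atoms,
all motifs enabled.

What this emulates: the token statistics, length distribution and
grammar-learning problem of small-molecule corpora, with enough QED
headroom (corpus mean ≈ 0.46) for reward optimization to have a visible
direction. What it does not emulate: aromatic systems, stereochemistry,
charges, macrocycles, and the property distributions of real screening
libraries. Passing the scaled study therefore demonstrates that the
two-stage mechanism works — the policy gradient moves the sampling
distribution toward higher-reward valid molecules — not that any
particular full-scale QED figure would be reproduced.

## Desk-scale study conditions

The scaled two-stage study (`smilesrl.protocol`, also run by
`scripts/acceptance.py`) uses: a 5,000-molecule synthetic corpus; a 2-layer,
4-head, d_model 64, d_ff 256 decoder with max length 32 trained 3 epochs;
30 REINFORCE steps of 128 episodes with the 10·QED reward and γ = 0.99;
paired pre/post evaluation of 1,000 samples with a shared evaluation seed.
Because the decoder is two orders of magnitude smaller than the full-scale
model, its optimizer settings are scaled accordingly: LM learning rate
1e−3 with batch 32, RL learning rate 1e−4. These are this package's
desk-scale choices; the full-scale defaults remain on the estimators. All
stage seeds derive from one master seed via `numpy.random.SeedSequence`.

## Known limitations

* NumPy on one CPU: full-corpus (10⁶-molecule) training is out of reach;
  the package targets mechanism-level correctness and desk-scale studies.
* Pure REINFORCE has high gradient variance; at larger scales the optional
  baseline (or more episodes per step) is advisable.
* Greedy BPE encoding applies merges in learned order rather than optimal
  segmentation — standard, but worth knowing when comparing vocabularies.
* The sampler draws from the full softmax at temperature 1.0 (as the
  two-stage recipe prescribes); top-k/nucleus truncation is deliberately
  absent.
* Novelty/diversity on valid-only denominators slightly favors models with
  low validity; the report carries the convention explicitly so numbers
  are comparable.
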