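"""Token vocabularies for SMILES strings.

Two schemes are supported:

``char``
    One token per character. SMILES survives per-character splitting (two-letter
    element symbols such as ``Cl`` become ``'C'``, ``'l'``), because decoding is
    plain concatenation, so round trips are exact.
``bpe``
    Byte-pair encoding seeded with the character alphabet; merges are learned
    greedily by pair frequency, each corpus line treated as an independent word.

Every vocabulary reserves three special tokens at fixed ids: ``[PAD]`` = 0,
``[BOS]`` = 1 and ``[EOS]`` = 2; corpus-derived tokens follow, sorted so that
two builds from the same corpus are identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

PAD, BOS, EOS = "[PAD]", "[BOS]", "[EOS]"
PAD_ID, BOS_ID, EOS_ID = 0, 1, 2
_SPECIALS = (PAD, BOS, EOS)


class VocabularyError(ValueError):
    """Raised for malformed corpora or unencodable/undecodable input."""


@dataclass(frozen=True)
class Vocabulary:
    """Bidirectional token <-> id map with reserved special tokens.

    Parameters
    ----------
    tokens
        All token strings in id order; positions 0..2 are the specials.
    scheme
        ``"char"`` or ``"bpe"``.
    merges
        Learned BPE merges in application order (empty for ``char``).
    """

    tokens: tuple[str, ...]
    scheme: str = "char"
    merges: tuple[tuple[str, str], ...] = ()
    token_to_id: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.scheme not in ("char", "bpe"):
            raise VocabularyError(f"unknown scheme {self.scheme!r}")
        if tuple(self.tokens[:3]) != _SPECIALS:
            raise VocabularyError("tokens must start with [PAD], [BOS], [EOS]")
        mapping = {t: i for i, t in enumerate(self.tokens)}
        if len(mapping) != len(self.tokens):
            raise VocabularyError("duplicate tokens in vocabulary")
        if self.scheme == "char":
            bad = [t for t in self.tokens[3:] if len(t) != 1]
            if bad:
                raise VocabularyError(f"char scheme requires length-1 tokens, got {bad[:5]}")
        object.__setattr__(self, "token_to_id", mapping)

    # -- introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def size(self) -> int:
        """Total vocabulary size including the three specials."""
        return len(self.tokens)

    @property
    def n_base(self) -> int:
        """Number of corpus-derived (non-special) tokens."""
        return len(self.tokens) - 3

    @property
    def specials(self) -> dict[str, int]:
        return {"pad": PAD_ID, "bos": BOS_ID, "eos": EOS_ID}

    # -- encoding ------------------------------------------------------
    def encode(self, s: str) -> list[int]:
        """Encode a SMILES string to token ids (no [BOS]/[EOS] framing)."""
        if self.scheme == "char":
            ids = []
            for pos, ch in enumerate(s):
                i = self.token_to_id.get(ch)
                if i is None or i < 3:
                    raise VocabularyError(
                        f"character {ch!r} at position {pos} is not in the vocabulary"
                    )
                ids.append(i)
            return ids
        pieces = _apply_merges(list(s), self.merges)
        ids = []
        consumed = 0
        for piece in pieces:
            i = self.token_to_id.get(piece)
            if i is None or i < 3:
                raise VocabularyError(
                    f"token {piece!r} at position {consumed} is not in the vocabulary"
                )
            ids.append(i)
            consumed += len(piece)
        return ids

    def decode(self, ids: Sequence[int]) -> str:
        """Concatenate token strings, stripping special tokens."""
        out = []
        for i in ids:
            if not 0 <= int(i) < len(self.tokens):
                raise VocabularyError(f"unknown token id {i}")
            if int(i) >= 3:
                out.append(self.tokens[int(i)])
        return "".join(out)

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "tokens": list(self.tokens),
                "merges": [list(m) for m in self.merges],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        d = json.loads(payload)
        return cls(
            tokens=tuple(d["tokens"]),
            scheme=d["scheme"],
            merges=tuple((a, b) for a, b in d.get("merges", [])),
        )


def _checked_lines(corpus: Iterable[str]) -> list[str]:
    lines = []
    for lineno, s in enumerate(corpus, start=1):
        s = s.rstrip("\n")
        if not s.isascii():
            raise VocabularyError(f"non-ASCII character on corpus line {lineno}: {s!r}")
        if s and not s.isprintable():
            raise VocabularyError(f"non-printable character on corpus line {lineno}: {s!r}")
        lines.append(s)
    if not lines or all(not s for s in lines):
        raise VocabularyError("corpus is empty")
    return lines


def build_char_vocab(corpus: Iterable[str]) -> Vocabulary:
    """One token per distinct character, ordered by codepoint after the specials."""
    lines = _checked_lines(corpus)
    alphabet = sorted({ch for s in lines for ch in s})
    return Vocabulary(tokens=_SPECIALS + tuple(alphabet), scheme="char")


def build_bpe_vocab(corpus: Iterable[str], target_size: int = 500) -> Vocabulary:
    """Greedy byte-pair encoding over per-line words.

    Merges the most frequent adjacent token pair (ties broken lexicographically)
    until ``target_size`` non-special tokens exist or no pair occurs at least
    twice. ``target_size`` equal to the alphabet size yields zero merges, i.e.
    the character vocabulary.
    """
    lines = _checked_lines(corpus)
    alphabet = sorted({ch for s in lines for ch in s})
    if target_size < len(alphabet):
        raise VocabularyError(
            f"target_size {target_size} is below the base alphabet size {len(alphabet)}"
        )

    # words as tuples of current tokens, with multiplicity
    word_counts: dict[tuple[str, ...], int] = {}
    for s in lines:
        if s:
            key = tuple(s)
            word_counts[key] = word_counts.get(key, 0) + 1

    tokens = set(alphabet)
    merges: list[tuple[str, str]] = []
    while len(tokens) < target_size:
        pair_counts: dict[tuple[str, str], int] = {}
        for word, cnt in word_counts.items():
            for a, b in zip(word, word[1:]):
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + cnt
        if not pair_counts:
            break
        # deterministic tie-break: highest count, then lexicographically smallest pair
        top = max(pair_counts.values())
        if top < 2:
            break
        best_pair = min(p for p, c in pair_counts.items() if c == top)
        merges.append(best_pair)
        merged = best_pair[0] + best_pair[1]
        tokens.add(merged)
        word_counts = {
            tuple(_merge_word(word, best_pair, merged)): cnt for word, cnt in word_counts.items()
        }

    ordered = sorted(alphabet) + [a + b for a, b in merges]
    return Vocabulary(tokens=_SPECIALS + tuple(ordered), scheme="bpe", merges=tuple(merges))


def _merge_word(word: Sequence[str], pair: tuple[str, str], merged: str) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(word):
        if i + 1 < len(word) and (word[i], word[i + 1]) == pair:
            out.append(merged)
            i += 2
        else:
            out.append(word[i])
            i += 1
    return out


def _apply_merges(
    pieces: list[str], merges: Sequence[tuple[str, str]]
) -> list[str]:
    s = "".join(pieces)  # concatenation is invariant under merging
    for pair in merges:
        merged = pair[0] + pair[1]
        if merged not in s:
            continue
        pieces = _merge_word(pieces, pair, merged)
    return pieces


def encode(s: str, vocab: Vocabulary) -> list[int]:
    """Functional alias for :meth:`Vocabulary.encode`."""
    return vocab.encode(s)


def decode(ids: Sequence[int], vocab: Vocabulary) -> str:
    """Functional alias for :meth:`Vocabulary.decode`."""
    return vocab.decode(ids)


class CharTokenizer(BaseEstimator, TransformerMixin):
    """Character-level SMILES tokenizer with the scikit-learn transformer API.

    ``fit`` builds the vocabulary from an iterable of SMILES strings;
    ``transform`` maps strings to lists of token ids and ``inverse_transform``
    maps them back. The fitted vocabulary is available as ``vocabulary_``.
    """

    def fit(self, X: Iterable[str], y=None):
        self.vocabulary_ = build_char_vocab(X)
        return self

    def transform(self, X: Iterable[str]) -> list[list[int]]:
        return [self.vocabulary_.encode(s) for s in X]

    def inverse_transform(self, X: Iterable[Sequence[int]]) -> list[str]:
        return [self.vocabulary_.decode(ids) for ids in X]


class BPETokenizer(BaseEstimator, TransformerMixin):
    """Byte-pair-encoding SMILES tokenizer (scikit-learn transformer API).

    Parameters
    ----------
    target_size
        Number of non-special tokens to learn (default 500).
    """

    def __init__(self, target_size: int = 500):
        self.target_size = target_size

    def fit(self, X: Iterable[str], y=None):
        self.vocabulary_ = build_bpe_vocab(X, target_size=self.target_size)
        return self

    def transform(self, X: Iterable[str]) -> list[list[int]]:
        return [self.vocabulary_.encode(s) for s in X]

    def inverse_transform(self, X: Iterable[Sequence[int]]) -> list[str]:
        return [self.vocabulary_.decode(ids) for ids in X]
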