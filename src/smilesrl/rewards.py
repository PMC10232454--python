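"""Terminal reward functions for the molecule-building episodes.

Every reward is validity-gated: a terminal string that RDKit cannot parse
scores exactly 0. For valid molecules the three reward kinds are

* ``qed``:        R = 10 * QED(molecule), in [0, 10]
* ``pic50``:      R = exp(pIC50 / 3) with pIC50 supplied by a scorer
* ``predictor``:  R = scorer probability in [0, 1] (an external activity
                  predictor; out-of-range outputs are an error, not clamped)

pIC50 follows the convention pIC50 = 9 - log10(IC50 in nM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .chem import is_valid, mol_from_smiles


@runtime_checkable
class PropertyScorer(Protocol):
    """SMILES -> real scoring interface (deterministic, total on valid SMILES)."""

    def score(self, smiles: str) -> float: ...


class ScorerError(RuntimeError):
    """A scorer failed on a *valid* molecule (distinct from the invalid-string zero)."""


@dataclass(frozen=True)
class RewardSpec:
    """Which terminal reward to use, plus the scorer handle where one is needed."""

    kind: str = "qed"
    scorer: Optional[PropertyScorer] = None

    def __post_init__(self) -> None:
        if self.kind not in ("qed", "pic50", "predictor"):
            raise ValueError(f"unknown reward kind {self.kind!r}")
        if self.kind in ("pic50", "predictor") and self.scorer is None:
            raise ValueError(f"reward kind {self.kind!r} requires a scorer")

    def __call__(self, smiles: str) -> float:
        if self.kind == "qed":
            return qed_reward(smiles)
        if self.kind == "pic50":
            return pic50_reward(smiles, self.scorer)
        return predictor_reward(smiles, self.scorer)


def qed_reward(smiles: str) -> float:
    """10 x QED for a valid molecule, 0 otherwise."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return 0.0
    from .chem import qed as _qed

    return 10.0 * _qed(mol)


def pic50_reward(smiles: str, scorer: PropertyScorer) -> float:
    """exp(pIC50 / 3) for a valid molecule, 0 otherwise."""
    if not is_valid(smiles):
        return 0.0
    try:
        value = float(scorer.score(smiles))
    except Exception as exc:  # scorer must be total on valid molecules
        raise ScorerError(f"scorer failed on valid molecule {smiles!r}") from exc
    if not math.isfinite(value):
        raise ScorerError(f"scorer returned non-finite pIC50 for {smiles!r}")
    return math.exp(value / 3.0)


def predictor_reward(smiles: str, scorer: PropertyScorer) -> float:
    """Raw predictor probability for a valid molecule, 0 otherwise."""
    if not is_valid(smiles):
        return 0.0
    try:
        value = float(scorer.score(smiles))
    except Exception as exc:
        raise ScorerError(f"scorer failed on valid molecule {smiles!r}") from exc
    if not 0.0 <= value <= 1.0:
        raise ScorerError(
            f"predictor output {value} for {smiles!r} outside [0, 1]"
        )
    return value


def pic50_from_ic50(ic50_nm: float) -> float:
    """pIC50 = 9 - log10(IC50), IC50 in nanomolar."""
    if not ic50_nm > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    return 9.0 - math.log10(ic50_nm)


# ---------------------------------------------------------------------------
# lightweight surrogate scorer
# ---------------------------------------------------------------------------

def _descriptors(smiles: str) -> np.ndarray:
    from rdkit.Chem import Crippen, Descriptors

    mol = mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    return np.array(
        [
            mol.GetNumHeavyAtoms(),
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Descriptors.NumHDonors(mol),
            Descriptors.NumHAcceptors(mol),
            Descriptors.NumRotatableBonds(mol),
            mol.GetRingInfo().NumRings(),
        ],
        dtype=float,
    )


class DescriptorScorer:
    """Deterministic ridge fit of a property on simple RDKit descriptors.

    A desk-scale surrogate satisfying the :class:`PropertyScorer` contract so
    the RL stage is testable offline. It is NOT an external message-passing
    property predictor and makes no claim to its accuracy; ``clip`` bounds
    the output (e.g. (0, 1) for probability-style targets).
    """

    def __init__(self, weights: np.ndarray, intercept: float,
                 mean: np.ndarray, scale: np.ndarray,
                 clip: Optional[tuple[float, float]] = None):
        self._w = weights
        self._b = intercept
        self._mu = mean
        self._sd = scale
        self._clip = clip

    def score(self, smiles: str) -> float:
        x = (_descriptors(smiles) - self._mu) / self._sd
        y = float(x @ self._w + self._b)
        if self._clip is not None:
            y = min(max(y, self._clip[0]), self._clip[1])
        return y

    @classmethod
    def fit(cls, smiles: list[str], values: list[float],
            clip: Optional[tuple[float, float]] = None,
            alpha: float = 1e-3) -> "DescriptorScorer":
        X = np.array([_descriptors(s) for s in smiles])
        y = np.asarray(values, dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        w = np.linalg.solve(Xs.T @ Xs + alpha * np.eye(Xs.shape[1]), Xs.T @ (y - y.mean()))
        return cls(w, float(y.mean()), mu, sd, clip)


def surrogate_scorer(training_csv, smiles_col: str = "smiles",
                     value_col: Optional[str] = None,
                     clip: Optional[tuple[float, float]] = None) -> DescriptorScorer:
    """Fit a :class:`DescriptorScorer` from a (smiles, value) CSV file."""
    try:
        df = pd.read_csv(training_csv)
    except Exception as exc:
        raise ValueError(f"cannot read training CSV {training_csv!r}") from exc
    if smiles_col not in df.columns:
        raise ValueError(f"column {smiles_col!r} missing from {training_csv!r}")
    if value_col is None:
        numeric = [c for c in df.columns if c != smiles_col and pd.api.types.is_numeric_dtype(df[c])]
        if not numeric:
            raise ValueError("no numeric property column found")
        value_col = numeric[0]
    return DescriptorScorer.fit(df[smiles_col].tolist(), df[value_col].tolist(), clip=clip)


class CommandScorer:
    """Adapter to an external predictor run as a shell command.

    The command receives one SMILES on stdin and must print one number on
    stdout, keeping any externally trained model outside the package core.
    """

    def __init__(self, command: str):
        self.command = command

    def score(self, smiles: str) -> float:
        import subprocess

        out = subprocess.run(
            self.command, shell=True, input=smiles.encode(),
            capture_output=True, check=True,
        )
        return float(out.stdout.decode().strip().split()[0])
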