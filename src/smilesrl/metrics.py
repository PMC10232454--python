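"""Evaluation metrics for generated molecule sets.

Validity is the percentage of generated strings RDKit can parse; novelty the
percentage of valid molecules whose canonical form is absent from the
training set; diversity the percentage of unique canonical forms among the
valid molecules. QED and SAS statistics are computed after removing all
invalid molecules. Molecule identity is always tested on canonical SMILES,
so trivially rewritten duplicates ("OCC" vs "CCO") are counted as the same
molecule. Percentages are reported to two decimals, rounding half-up.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import canonical_smiles, qed as _qed, sas as _sas


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _canonical_valid(smiles: Iterable[str]) -> list[str]:
    out = []
    for s in smiles:
        c = canonical_smiles(s)
        if c is not None:
            out.append(c)
    return out


def validity(generated: Sequence[str]) -> float:
    """Percentage of strings parseable as molecules; empty input reports 0."""
    if len(generated) == 0:
        warnings.warn("validity of an empty generated set is reported as 0%", stacklevel=2)
        return 0.0
    n_valid = sum(canonical_smiles(s) is not None for s in generated)
    return _round2(100.0 * n_valid / len(generated))


def novelty(generated: Sequence[str], training: Sequence[str]) -> float:
    """Percentage of valid generated molecules absent from the training set."""
    gen = _canonical_valid(generated)
    if not gen:
        warnings.warn("novelty of an empty/invalid generated set is reported as 0%", stacklevel=2)
        return 0.0
    train = set(_canonical_valid(training))
    n_novel = sum(c not in train for c in gen)
    return _round2(100.0 * n_novel / len(gen))


def diversity(generated: Sequence[str]) -> float:
    """Percentage of unique canonical molecules among the valid generated ones."""
    gen = _canonical_valid(generated)
    if not gen:
        warnings.warn("diversity of an empty/invalid generated set is reported as 0%", stacklevel=2)
        return 0.0
    return _round2(100.0 * len(set(gen)) / len(gen))


def property_stats(generated: Sequence[str]) -> tuple[float, float, float, float]:
    """(qed_mean, qed_sd, sas_mean, sas_sd) over the valid molecules only.

    Standard deviations are population (ddof=0) so a single molecule has sd 0.
    Duplicates are scored as often as they occur.
    """
    gen = _canonical_valid(generated)
    if not gen:
        raise ValueError("property_stats requires at least one valid molecule")
    qeds = np.array([_qed(s) for s in gen])
    sass = np.array([_sas(s) for s in gen])
    return (
        float(qeds.mean()), float(qeds.std()),
        float(sass.mean()), float(sass.std()),
    )


def cross_dataset_novelty(generated: Sequence[str],
                          corpora: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Novelty of one generated set against each named reference corpus."""
    out = {}
    for name, corpus in corpora.items():
        if len(corpus) == 0:
            gen = _canonical_valid(generated)
            out[name] = 100.0 if gen else 0.0
        else:
            out[name] = novelty(generated, corpus)
    return out


@dataclass(frozen=True)
class MetricsReport:
    """Full metric panel over one generated set.

    Percentages are in [0, 100]; QED statistics in [0, 1]; SAS statistics in
    roughly [1, 10]. QED/SAS, novelty and diversity are computed on valid
    molecules only (``denominator`` records that convention).
    """

    validity_pct: float
    novelty_pct: float
    diversity_pct: float
    qed_mean: float
    qed_sd: float
    sas_mean: float
    sas_sd: float
    n_generated: int
    n_valid: int
    n_expected: int
    denominator: str = "valid_only"

    def __post_init__(self) -> None:
        for name in ("validity_pct", "novelty_pct", "diversity_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.n_valid > self.n_generated:
            raise ValueError("n_valid cannot exceed n_generated")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_row(self) -> pd.DataFrame:
        """One-row frame in the conventional column order QED, SAS, Validity, Diversity, Novelty."""
        return pd.DataFrame(
            [{
                "QED": self.qed_mean, "QED_sd": self.qed_sd,
                "SAS": self.sas_mean, "SAS_sd": self.sas_sd,
                "Validity": self.validity_pct,
                "Diversity": self.diversity_pct,
                "Novelty": self.novelty_pct,
            }]
        )


def evaluate(generated: Sequence[str], training: Sequence[str],
             n_expected: int = 25000) -> MetricsReport:
    """Assemble the full report for a generated set against its training corpus."""
    gen_canon = _canonical_valid(generated)
    n_valid = len(gen_canon)
    if n_valid:
        qm, qs, sm, ss = property_stats(generated)
    else:
        qm = qs = sm = ss = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MetricsReport(
            validity_pct=validity(generated),
            novelty_pct=novelty(generated, training),
            diversity_pct=diversity(generated),
            qed_mean=qm, qed_sd=qs, sas_mean=sm, sas_sd=ss,
            n_generated=len(generated), n_valid=n_valid,
            n_expected=n_expected,
        )
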