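"""Deterministic synthetic SMILES corpora.

Emits small, chemically valid molecules (alkane chains with branches, 3-6
membered rings, N/O substitutions) so that tokenization, language modeling,
RL fine-tuning and the metric suite can all be exercised without downloading
any public corpus. Molecules are built as explicit molecular graphs with
valence-respecting random trees plus optional ring closures, sanitized and
canonicalized by RDKit, so every output is valid by construction. Generation
is a pure function of the spec (same spec, same corpus).

The chemistry is deliberately simple -- no aromatics, stereochemistry or
charges -- so a small decoder can learn the grammar quickly on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem import canonical_smiles, qed as _qed, sas as _sas

MOTIFS = frozenset({"chains", "rings", "branches", "heteroatoms"})

# max single-bond connections per element in the generator's neutral chemistry
_MAX_DEGREE = {"C": 4, "N": 3, "O": 2}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic synthetic corpus."""

    n_molecules: int
    max_heavy_atoms: int = 9
    seed: int = 0
    motifs: frozenset = field(default_factory=lambda: MOTIFS)

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.max_heavy_atoms < 1:
            raise ValueError("max_heavy_atoms must be >= 1")
        unknown = set(self.motifs) - MOTIFS
        if unknown:
            raise ValueError(f"unknown motifs {sorted(unknown)}")
        if not self.motifs:
            raise ValueError("at least one motif is required")


def _random_molecule(rng: np.random.Generator, spec: FixtureSpec) -> str:
    """One random valence-correct molecular graph as canonical SMILES."""
    n = int(rng.integers(1, spec.max_heavy_atoms + 1))
    branches = "branches" in spec.motifs
    rings = "rings" in spec.motifs
    hetero = "heteroatoms" in spec.motifs

    mol = Chem.RWMol()
    degree = []
    ring_members: list[int] = []

    start = 0
    if rings and n >= 3 and rng.random() < 0.4:
        k = int(rng.integers(3, min(6, n) + 1))
        for _ in range(k):
            ring_members.append(mol.AddAtom(Chem.Atom("C")))
            degree.append(0)
        for i in range(k):
            j = (i + 1) % k
            mol.AddBond(ring_members[i], ring_members[j], Chem.BondType.SINGLE)
            degree[ring_members[i]] += 1
            degree[ring_members[j]] += 1
        start = k

    prev = None if ring_members else -1
    for _ in range(start, n):
        idx = mol.AddAtom(Chem.Atom("C"))
        degree.append(0)
        if idx == 0:
            continue
        if branches or ring_members:
            candidates = [a for a in range(idx) if degree[a] < 4]
        else:  # pure chain: extend from the previous atom only
            candidates = [idx - 1] if degree[idx - 1] < 4 else []
        if not candidates:
            mol.RemoveAtom(idx)
            degree.pop()
            continue
        a = int(candidates[int(rng.integers(len(candidates)))])
        mol.AddBond(a, idx, Chem.BondType.SINGLE)
        degree[a] += 1
        degree[idx] += 1
    del prev

    if hetero:
        for atom in mol.GetAtoms():
            d = degree[atom.GetIdx()]
            if rng.random() < 0.25:
                choices = [el for el, md in _MAX_DEGREE.items() if md >= d and el != "C"]
                if choices:
                    atom.SetAtomicNum(Chem.Atom(choices[int(rng.integers(len(choices)))]).GetAtomicNum())

    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)


def generate_fixture_corpus(spec: FixtureSpec) -> list[str]:
    """Unique canonical molecules, seeded-shuffled, truncated to ``n_molecules``.

    Raises if the requested count exceeds what the motif/size space yields
    within the sampling budget, stating the maximum reached.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    ordered: list[str] = []
    budget = 200 * spec.n_molecules + 10000
    attempts = 0
    while len(ordered) < spec.n_molecules and attempts < budget:
        attempts += 1
        s = _random_molecule(rng, spec)
        if s not in seen:
            seen.add(s)
            ordered.append(s)
    if len(ordered) < spec.n_molecules:
        raise ValueError(
            f"fixture space exhausted: requested {spec.n_molecules} molecules but only "
            f"{len(ordered)} unique ones are reachable with max_heavy_atoms="
            f"{spec.max_heavy_atoms} and motifs {sorted(spec.motifs)}"
        )
    perm = np.random.default_rng(spec.seed + 1).permutation(len(ordered))
    return [ordered[i] for i in perm]


def corpus_stats(corpus: Sequence[str]) -> dict:
    """Corpus summary panel: count, mean QED, mean SAS, max heavy-atom count."""
    canon = []
    for s in corpus:
        c = canonical_smiles(s)
        if c is None:
            raise ValueError(f"corpus contains invalid SMILES: {s!r}")
        canon.append(c)
    from rdkit import Chem as _C

    n_atoms = [ _C.MolFromSmiles(c).GetNumHeavyAtoms() for c in canon ]
    return {
        "n": len(canon),
        "qed_mean": float(np.mean([_qed(c) for c in canon])),
        "sas_mean": float(np.mean([_sas(c) for c in canon])),
        "max_atoms": int(max(n_atoms)),
    }


def write_smi(path, smiles: Iterable[str]) -> None:
    Path(path).write_text("".join(s + "\n" for s in smiles))


def read_smi(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
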