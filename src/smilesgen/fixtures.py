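"""Valid-by-construction synthetic SMILES corpora and scripted mock
generators, so the whole pipeline is testable without any external
dataset.

Molecules are grown as random trees over a fragment-sized organic
element set, with optional ring closures and benzene-like aromatic
six-cycles, then sanitized by the toolkit; every emitted string is
asserted to parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: maximum single-bond connections per element in the builder
_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1, "Br": 1}

_DEFAULT_WEIGHTS = {
    "C": 0.62,
    "N": 0.10,
    "O": 0.14,
    "F": 0.04,
    "S": 0.04,
    "Cl": 0.04,
    "Br": 0.02,
}


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 1000
    hac_range: tuple[int, int] = (5, 40)
    element_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    ring_probability: float = 0.3
    branch_probability: float = 0.35
    aromatic_probability: float = 0.4
    pyrrole_probability: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hac_range
        if not (1 <= lo <= hi <= 60):
            raise ValueError("hac_range must lie within [1, 60]")
        total = sum(self.element_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("element_weights must sum to 1")
        if unknown := set(self.element_weights) - set(_VALENCE):
            raise ValueError(f"unsupported elements: {unknown}")
        if self.aromatic_probability > 0 and hi < 6:
            raise ValueError(
                "aromatic rings need hac_range max >= 6"
            )


def _grow_molecule(spec: FixtureSpec, rng: np.random.Generator) -> str:
    """One random molecule as canonical SMILES."""
    lo, hi = spec.hac_range
    target = int(rng.integers(lo, hi + 1))
    mol = Chem.RWMol()
    elements = list(spec.element_weights)
    weights = np.array([spec.element_weights[e] for e in elements])
    free: dict[int, int] = {}  # atom idx -> remaining valence

    def add_atom(symbol: str, aromatic: bool = False) -> int:
        atom = Chem.Atom(symbol)
        if aromatic:
            atom.SetIsAromatic(True)
        idx = mol.AddAtom(atom)
        free[idx] = _VALENCE[symbol] if not aromatic else 1
        return idx

    aromatic_ring = (
        target >= 6 and rng.random() < spec.aromatic_probability
    )
    if aromatic_ring:
        # benzene-like six-cycle, optionally pyrrole-type (5-ring with
        # [nH]) to exercise the A substitution token
        pyrrole = rng.random() < spec.pyrrole_probability and target >= 5
        size = 5 if pyrrole else 6
        ring = []
        for i in range(size):
            symbol = "N" if (pyrrole and i == 0) else "C"
            atom = Chem.Atom(symbol)
            atom.SetIsAromatic(True)
            if pyrrole and i == 0:
                atom.SetNumExplicitHs(1)
            ring.append(mol.AddAtom(atom))
        for i in range(size):
            bond = mol.AddBond(
                ring[i], ring[(i + 1) % size], Chem.BondType.AROMATIC
            )
        for i, idx in enumerate(ring):
            # ring atoms keep one substitution slot (none for pyrrole N)
            free[idx] = 0 if (pyrrole and i == 0) else 1
    else:
        # start from carbon so growth cannot dead-end immediately
        add_atom("C")

    while mol.GetNumAtoms() < target:
        open_atoms = [i for i, v in free.items() if v > 0]
        if not open_atoms:
            break
        # branch: attach anywhere with open valence; chain: prefer the
        # most recent open atom
        if rng.random() < spec.branch_probability:
            parent = int(rng.choice(open_atoms))
        else:
            parent = open_atoms[-1]
        symbol = str(rng.choice(elements, p=weights))
        child = add_atom(symbol)
        mol.AddBond(parent, child, Chem.BondType.SINGLE)
        free[parent] -= 1
        free[child] -= 1
    # optional aliphatic ring closure between distant open atoms
    if rng.random() < spec.ring_probability:
        open_atoms = [i for i, v in free.items() if v > 0]
        rng.shuffle(open_atoms)
        for a in open_atoms:
            for b in open_atoms:
                if b <= a or mol.GetBondBetweenAtoms(a, b):
                    continue
                path = Chem.GetShortestPath(mol, a, b)
                if len(path) >= 4:  # ring of size >= 4
                    mol.AddBond(a, b, Chem.BondType.SINGLE)
                    free[a] -= 1
                    free[b] -= 1
                    break
            else:
                continue
            break
    if mol.GetNumAtoms() < lo:  # growth dead-ended on terminal atoms
        return ""
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return ""
    smiles = Chem.MolToSmiles(mol)
    return smiles if Chem.MolFromSmiles(smiles) is not None else ""


def generate_fixture_corpus(spec: FixtureSpec) -> list[str]:
    """n valid canonical SMILES, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    attempts = 0
    limit = spec.n_molecules * 50
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > limit:  # pragma: no cover - spec guards this
            raise RuntimeError("fixture generation did not converge")
        smiles = _grow_molecule(spec, rng)
        if smiles:
            assert Chem.MolFromSmiles(smiles) is not None
            out.append(smiles)
    return out


class InapplicableMutation(ValueError):
    """The requested corruption cannot be applied to this SMILES."""


def mutate_to_invalid(
    smiles: str, mode: str, seed: int = 0
) -> str:
    """Corrupt a valid SMILES into a guaranteed-invalid candidate.

    ``drop_ring_digit`` removes one ring-closure digit (leaving its
    partner unmatched); ``unbalance_paren`` removes one parenthesis of
    a matched pair; ``illegal_char`` inserts a character outside the
    SMILES alphabet.
    """
    rng = np.random.default_rng(seed)
    if mode == "drop_ring_digit":
        positions = [
            i
            for i, ch in enumerate(smiles)
            if ch.isdigit() and not _in_brackets(smiles, i)
        ]
        if not positions:
            raise InapplicableMutation("no ring-closure digits")
        pos = int(rng.choice(positions))
        return smiles[:pos] + smiles[pos + 1 :]
    if mode == "unbalance_paren":
        positions = [i for i, ch in enumerate(smiles) if ch in "()"]
        if not positions:
            raise InapplicableMutation("no parentheses")
        pos = int(rng.choice(positions))
        return smiles[:pos] + smiles[pos + 1 :]
    if mode == "illegal_char":
        pos = int(rng.integers(0, len(smiles) + 1))
        return smiles[:pos] + "?" + smiles[pos:]
    raise ValueError(f"unknown mutation mode {mode!r}")


def _in_brackets(smiles: str, pos: int) -> bool:
    open_ = smiles.rfind("[", 0, pos)
    if open_ == -1:
        return False
    close = smiles.find("]", open_)
    return close > pos


class ScriptedMockGenerator:
    """Epoch-scripted stand-in for a trained generator.

    At epoch e it emits a sample where exactly
    ``round(validity_schedule[e] * n)`` strings are valid fixture
    molecules and the remainder are corrupted mutants, letting examiner
    tests control the measured validity exactly. Implements the sampler
    interface ``(n, seed) -> list[str]`` and a ``__call__`` matching
    the training examiner callback's model argument is not needed —
    advance epochs with :meth:`advance`.
    """

    def __init__(
        self,
        validity_schedule: Sequence[float],
        pool: Optional[Sequence[str]] = None,
        seed: int = 0,
    ) -> None:
        if any(not 0.0 <= v <= 1.0 for v in validity_schedule):
            raise ValueError("validity fractions must be in [0, 1]")
        self.schedule = list(validity_schedule)
        self.epoch = 0
        if pool is None:
            pool = generate_fixture_corpus(
                FixtureSpec(n_molecules=400, hac_range=(5, 20), seed=seed)
            )
        # keep only pool entries our mutations can corrupt
        self.pool = [p for p in pool if any(c in p for c in "()123456789")]
        if not self.pool:
            raise ValueError("pool has no mutable SMILES")

    def sample(self, n: int, seed: int = 0) -> list[str]:
        if self.epoch >= len(self.schedule):
            raise IndexError("validity schedule exhausted")
        rng = np.random.default_rng(seed)
        n_valid = round(self.schedule[self.epoch] * n)
        picks = rng.choice(len(self.pool), size=n, replace=True)
        out = []
        for j, pick in enumerate(picks):
            smiles = self.pool[pick]
            if j < n_valid:
                out.append(smiles)
            else:
                mode = (
                    "drop_ring_digit"
                    if any(c.isdigit() for c in smiles)
                    else "unbalance_paren"
                )
                out.append(mutate_to_invalid(smiles, mode, seed=int(pick)))
        return out

    __call__ = sample

    def advance(self) -> None:
        self.epoch += 1
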