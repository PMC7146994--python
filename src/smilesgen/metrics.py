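"""Evaluation suite: validity/uniqueness/training-recall, a 12-property
distribution panel compared by continuous Tanimoto and Jensen–Shannon
divergence, and the chunked novelty / efficiency analysis.

Molecule identity throughout is the full InChIKey string.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

FAILURE_NONE = "none"
FAILURE_RING_BRANCH = "ring_branch_mismatch"
FAILURE_PARSE = "parse_error"
FAILURE_IDENTITY = "identity_failure"

#: The property panel: size, polarity, topology, elemental composition.
PROPERTY_NAMES = (
    "smiles_length",
    "hac",
    "molecular_weight",
    "logp",
    "tpsa",
    "rotatable_bonds",
    "fraction_cyclic",
    "fraction_conjugated",
    "fraction_aromatic",
    "fraction_carbon",
    "fraction_nitrogen",
    "fraction_oxygen",
)

#: Default bin widths; integer-valued properties get unit bins.
DEFAULT_BIN_WIDTHS = {
    "smiles_length": 1.0,
    "hac": 1.0,
    "molecular_weight": 10.0,
    "logp": 0.25,
    "tpsa": 5.0,
    "rotatable_bonds": 1.0,
    "fraction_cyclic": 0.05,
    "fraction_conjugated": 0.05,
    "fraction_aromatic": 0.05,
    "fraction_carbon": 0.05,
    "fraction_nitrogen": 0.05,
    "fraction_oxygen": 0.05,
}


@dataclass(frozen=True)
class ValidityVerdict:
    smiles: str
    is_valid: bool
    identity_key: Optional[str]
    failure_class: str

    def __post_init__(self) -> None:
        assert self.is_valid == (self.identity_key is not None)


_RING_TOKEN = re.compile(r"%\d{2}|\d")


def _ring_branch_mismatch(smiles: str) -> bool:
    """Token-level detection of unbalanced parentheses or ring-closure
    digits opened an odd number of times. Used only to classify
    failures; it never overrides the toolkit verdict."""
    depth = 0
    ring_counts: dict[str, int] = {}
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":  # bracket atoms may contain digits (isotopes, charge)
            end = smiles.find("]", i)
            if end == -1:
                return True
            i = end + 1
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return True
        elif ch == "%":
            m = _RING_TOKEN.match(smiles, i)
            if m is None:
                return True
            token = m.group()
            ring_counts[token] = ring_counts.get(token, 0) + 1
            i += len(token)
            continue
        elif ch.isdigit():
            ring_counts[ch] = ring_counts.get(ch, 0) + 1
        i += 1
    if depth != 0:
        return True
    return any(count % 2 for count in ring_counts.values())


def check_validity(candidate: str) -> ValidityVerdict:
    """Judge one generated candidate.

    A candidate is valid iff the toolkit parses it and converts it to
    an InChIKey. Ring/branch token mismatches are reported as their own
    failure class but candidates are never pre-filtered: every string
    stays in the evaluation denominator.
    """
    mismatch = _ring_branch_mismatch(candidate)
    mol = Chem.MolFromSmiles(candidate) if candidate else None
    if mol is None:
        return ValidityVerdict(
            smiles=candidate,
            is_valid=False,
            identity_key=None,
            failure_class=FAILURE_RING_BRANCH if mismatch else FAILURE_PARSE,
        )
    try:
        key = Chem.MolToInchiKey(mol)
    except Exception:
        key = ""
    if not key:
        return ValidityVerdict(
            smiles=candidate,
            is_valid=False,
            identity_key=None,
            failure_class=FAILURE_IDENTITY,
        )
    return ValidityVerdict(
        smiles=candidate,
        is_valid=True,
        identity_key=key,
        failure_class=FAILURE_NONE,
    )


def validity_percent(candidates: Sequence[str]) -> float:
    """Fraction of candidates that are valid molecules, as a percent."""
    if not candidates:
        raise ValueError("empty candidate list")
    valid = sum(check_validity(s).is_valid for s in candidates)
    return 100.0 * valid / len(candidates)


def summary_rates(
    batch: Sequence[ValidityVerdict], training_keys: set[str]
) -> tuple[float, float, float]:
    """(validity%, uniqueness%, training%).

    validity% = valid / generated; uniqueness% = unique identities /
    valid; training% = unique identities also present in the training
    set / unique identities.
    """
    if not batch:
        raise ValueError("empty batch")
    n_valid = sum(v.is_valid for v in batch)
    unique = {v.identity_key for v in batch if v.is_valid}
    validity = 100.0 * n_valid / len(batch)
    uniqueness = 100.0 * len(unique) / n_valid if n_valid else 0.0
    training = (
        100.0 * len(unique & training_keys) / len(unique) if unique else 0.0
    )
    return validity, uniqueness, training


def compute_properties(mol_or_smiles) -> dict[str, float]:
    """The 12-property vector for one valid molecule.

    SMILES length is the character count of the canonical
    (unsubstituted) SMILES; all fractions are per heavy atom.
    """
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES {mol_or_smiles!r}")
    else:
        mol = mol_or_smiles
    hac = mol.GetNumHeavyAtoms()
    if hac == 0:
        raise ValueError("molecule has no heavy atoms")
    atoms = list(mol.GetAtoms())
    n_cyclic = sum(a.IsInRing() for a in atoms)
    n_aromatic = sum(a.GetIsAromatic() for a in atoms)
    conjugated_atoms = set()
    for bond in mol.GetBonds():
        if bond.GetIsConjugated():
            conjugated_atoms.add(bond.GetBeginAtomIdx())
            conjugated_atoms.add(bond.GetEndAtomIdx())
    counts = {"C": 0, "N": 0, "O": 0}
    for a in atoms:
        if a.GetSymbol() in counts:
            counts[a.GetSymbol()] += 1
    return {
        "smiles_length": float(len(Chem.MolToSmiles(mol))),
        "hac": float(hac),
        "molecular_weight": Descriptors.MolWt(mol),
        "logp": Crippen.MolLogP(mol),
        "tpsa": Descriptors.TPSA(mol),
        "rotatable_bonds": float(Lipinski.NumRotatableBonds(mol)),
        "fraction_cyclic": n_cyclic / hac,
        "fraction_conjugated": len(conjugated_atoms) / hac,
        "fraction_aromatic": n_aromatic / hac,
        "fraction_carbon": counts["C"] / hac,
        "fraction_nitrogen": counts["N"] / hac,
        "fraction_oxygen": counts["O"] / hac,
    }


@dataclass
class PropertyHistogram:
    property_name: str
    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts length must be bins")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.normalized and abs(self.counts.sum() - 1.0) > 1e-9:
            raise ValueError("normalized histogram must sum to 1")

    def normalize(self) -> "PropertyHistogram":
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalize an empty histogram")
        return PropertyHistogram(
            property_name=self.property_name,
            bin_edges=self.bin_edges,
            counts=self.counts / total,
            normalized=True,
        )


def histogram_pair(
    values_a: Sequence[float],
    values_b: Sequence[float],
    property_name: str,
    bin_width: Optional[float] = None,
) -> tuple[PropertyHistogram, PropertyHistogram]:
    """Histogram two value sets on shared edges covering both ranges."""
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(property_name, 1.0)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both value sets must be non-empty")
    lo = math.floor(min(a.min(), b.min()) / bin_width) * bin_width
    hi = math.ceil(max(a.max(), b.max()) / bin_width) * bin_width
    n_bins = max(1, round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi) + 1e-9  # right-inclusive top bin
    counts_a, _ = np.histogram(a, bins=edges)
    counts_b, _ = np.histogram(b, bins=edges)
    return (
        PropertyHistogram(property_name, edges, counts_a, normalized=False),
        PropertyHistogram(property_name, edges, counts_b, normalized=False),
    )


def tanimoto_match(A: PropertyHistogram, B: PropertyHistogram) -> float:
    """Continuous Tanimoto similarity between two histograms on shared
    edges, in percent: ΣAB / (ΣA² + ΣB² − ΣAB) × 100. Scale-invariant
    under joint rescaling of both inputs."""
    if not np.array_equal(A.bin_edges, B.bin_edges):
        raise ValueError("histograms must share bin edges")
    a, b = A.counts, B.counts
    if not a.any() and not b.any():
        raise ValueError("both histograms are all-zero")
    cross = float(np.dot(a, b))
    denom = float(np.dot(a, a) + np.dot(b, b) - cross)
    if denom == 0.0:  # squared counts underflowed to zero
        raise ValueError("histogram counts too small to compare")
    return 100.0 * cross / denom


def _entropy(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def jsd(
    A: PropertyHistogram,
    B: PropertyHistogram,
    weights: tuple[float, float] = (0.5, 0.5),
    base: float = 2.0,
) -> float:
    """Jensen–Shannon divergence between two normalized histograms:
    H(w_a·A + w_b·B) − (w_a·H(A) + w_b·H(B)), log base 2 by default so
    the equal-weight maximum is 1."""
    if not np.array_equal(A.bin_edges, B.bin_edges):
        raise ValueError("histograms must share bin edges")
    if not (A.normalized and B.normalized):
        raise ValueError("jsd requires normalized histograms")
    wa, wb = weights
    if abs(wa + wb - 1.0) > 1e-9 or wa < 0 or wb < 0:
        raise ValueError("weights must be non-negative and sum to 1")
    mixture = wa * A.counts + wb * B.counts
    return _entropy(mixture, base) - (
        wa * _entropy(A.counts, base) + wb * _entropy(B.counts, base)
    )


@dataclass
class NoveltySeries:
    chunk_size: int
    per_chunk_novelty: list[Optional[float]]  # percent; None if no valid
    cumulative_unique: list[int]
    total_generated: int

    @property
    def efficiency(self) -> float:
        """Valid unique molecules / total generated strings, percent."""
        if self.total_generated == 0:
            return 0.0
        last = self.cumulative_unique[-1] if self.cumulative_unique else 0
        return 100.0 * last / self.total_generated


def novelty_analysis(
    stream: Iterable[ValidityVerdict], chunk_size: int = 10_000
) -> NoveltySeries:
    """Chunked novelty of a generation stream.

    Within each chunk, novelty% is the share of valid molecules whose
    identity key has not been seen before (duplicates earlier in the
    same chunk count as seen). Cumulative uniques accumulate across
    chunks; efficiency is final uniques over all generated strings.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    keys = []
    valid_flags = []
    for verdict in stream:
        valid_flags.append(verdict.is_valid)
        keys.append(verdict.identity_key if verdict.is_valid else None)
    total = len(keys)
    # first-occurrence positions of each identity key, vectorized
    valid_idx = [i for i, k in enumerate(keys) if k is not None]
    key_arr = np.array([keys[i] for i in valid_idx])
    first_seen = np.zeros(len(valid_idx), dtype=bool)
    if len(key_arr):
        _, first_positions = np.unique(key_arr, return_index=True)
        first_seen[first_positions] = True
    novel_at = {valid_idx[j]: bool(first_seen[j]) for j in range(len(valid_idx))}
    per_chunk: list[Optional[float]] = []
    cumulative: list[int] = []
    running_unique = 0
    for start in range(0, total, chunk_size):
        chunk_range = range(start, min(start + chunk_size, total))
        n_valid = sum(1 for i in chunk_range if valid_flags[i])
        n_novel = sum(1 for i in chunk_range if novel_at.get(i, False))
        per_chunk.append(100.0 * n_novel / n_valid if n_valid else None)
        running_unique += n_novel
        cumulative.append(running_unique)
    return NoveltySeries(
        chunk_size=chunk_size,
        per_chunk_novelty=per_chunk,
        cumulative_unique=cumulative,
        total_generated=total,
    )


def novelty_by_hac(
    stream: Sequence[ValidityVerdict], chunk_size: int = 10_000
) -> dict[int, NoveltySeries]:
    """Novelty analysis stratified by heavy atom count.

    Each stratum replays the chunked analysis on the substream of
    verdicts whose molecule has that HAC, using the *global* chunk
    boundaries so strata line up across time points. Chunks without
    valid molecules of a given HAC report novelty None.
    """
    hacs: list[Optional[int]] = []
    for verdict in stream:
        if verdict.is_valid:
            mol = Chem.MolFromSmiles(verdict.smiles)
            hacs.append(mol.GetNumHeavyAtoms() if mol else None)
        else:
            hacs.append(None)
    out: dict[int, NoveltySeries] = {}
    for hac in sorted({h for h in hacs if h is not None}):
        seen: set[str] = set()
        per_chunk: list[Optional[float]] = []
        cumulative: list[int] = []
        stratum_total = 0
        for start in range(0, len(hacs), chunk_size):
            n_valid = 0
            n_novel = 0
            for i in range(start, min(start + chunk_size, len(hacs))):
                if hacs[i] != hac:
                    continue
                stratum_total += 1
                n_valid += 1
                key = stream[i].identity_key
                if key not in seen:
                    seen.add(key)
                    n_novel += 1
            per_chunk.append(100.0 * n_novel / n_valid if n_valid else None)
            cumulative.append(len(seen))
        out[hac] = NoveltySeries(
            chunk_size=chunk_size,
            per_chunk_novelty=per_chunk,
            cumulative_unique=cumulative,
            total_generated=stratum_total,
        )
    return out


def property_match_table(
    training_smiles: Sequence[str],
    generated_stages: dict[str, Sequence[str]],
    bin_widths: Optional[dict[str, float]] = None,
) -> list[dict]:
    """Tanimoto and JSD between training and generated property
    distributions, one row per property × stage — the machinery behind
    a distribution-match report."""
    train_props = _property_matrix(training_smiles)
    rows = []
    for stage, smiles in generated_stages.items():
        gen_props = _property_matrix(smiles)
        for name in PROPERTY_NAMES:
            width = (bin_widths or {}).get(name)
            ha, hb = histogram_pair(
                train_props[name], gen_props[name], name, bin_width=width
            )
            rows.append(
                {
                    "property": name,
                    "stage": stage,
                    "tanimoto_percent": tanimoto_match(ha, hb),
                    "jsd": jsd(ha.normalize(), hb.normalize()),
                }
            )
    return rows


def _property_matrix(smiles: Sequence[str]) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {name: [] for name in PROPERTY_NAMES}
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        props = compute_properties(mol)
        for name in PROPERTY_NAMES:
            out[name].append(props[name])
    return out
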