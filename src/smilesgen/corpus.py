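"""Corpus preparation: organic filtering, stereo removal, token
substitution, vocabulary inventory and sliding-window encoding.

The pipeline turns raw one-SMILES-per-line input into a cleaned,
de-duplicated corpus of single-character token strings, from which
fixed-length (context, next-character) training windows are cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements permitted in an "organic" molecule (beyond requiring >=1 C).
ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "S", "Cl", "Br", "I"]
)

#: Multi-character SMILES tokens collapsed to single characters, longest
#: token first so substitution can be done by plain string replacement.
SUBSTITUTIONS: dict[str, str] = {"[nH]": "A", "Cl": "L", "Br": "R"}

#: End-of-molecule symbol. Newline never occurs inside a SMILES string
#: and survives plain-text round trips.
TERMINATOR = "\n"

_STEREO_ATOMS = ["[C@@H]", "[C@H]", "[C@@]", "[C@]"]


class SmilesParseError(ValueError):
    """Raised when a string cannot be parsed as SMILES."""


@dataclass(frozen=True)
class RawMolecule:
    """A cleaned training molecule.

    ``identity_key`` is the InChIKey of ``canonical_smiles`` and is the
    identity used for de-duplication, training-recall and novelty.
    """

    source_smiles: str
    canonical_smiles: str
    identity_key: str


@dataclass
class PrepReport:
    """Bookkeeping for :func:`prepare_corpus`; counts reconcile with the
    number of input fragments (kept + skipped_parse + skipped_organic +
    duplicates == fragments)."""

    input_lines: int = 0
    fragments: int = 0
    kept: int = 0
    skipped_parse: int = 0
    skipped_organic: int = 0
    duplicates: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class Vocabulary:
    """Bidirectional character/index map over the substituted corpus."""

    chars: tuple[str, ...]
    substitutions: dict[str, str] = field(
        default_factory=lambda: dict(SUBSTITUTIONS)
    )
    terminator: str = TERMINATOR

    def __post_init__(self) -> None:
        if self.terminator not in self.chars:
            raise ValueError("terminator must be part of the vocabulary")
        if len(set(self.chars)) != len(self.chars):
            raise ValueError("duplicate characters in vocabulary")

    @property
    def size(self) -> int:
        return len(self.chars)

    @property
    def char_to_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chars)}

    @property
    def index_to_char(self) -> dict[int, str]:
        return {i: c for i, c in enumerate(self.chars)}

    @property
    def terminator_index(self) -> int:
        return self.chars.index(self.terminator)

    def encode(self, text: str) -> np.ndarray:
        table = self.char_to_index
        try:
            return np.array([table[c] for c in text], dtype=np.int16)
        except KeyError as exc:  # pragma: no cover - guarded by callers
            raise KeyError(f"character {exc} not in vocabulary") from exc

    def decode(self, indices: Iterable[int]) -> str:
        return "".join(self.chars[i] for i in indices)

    def to_json(self) -> str:
        return json.dumps(
            {
                "chars": list(self.chars),
                "substitutions": self.substitutions,
                "terminator": self.terminator,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        data = json.loads(text)
        return cls(
            chars=tuple(data["chars"]),
            substitutions=dict(data["substitutions"]),
            terminator=data["terminator"],
        )


@dataclass
class EncodedCorpus:
    """Sliding-window training set: integer contexts of fixed length W
    plus the integer index of the character that follows each context.
    One-hot expansion happens lazily at batch time."""

    contexts: np.ndarray  # (N, W) int16
    labels: np.ndarray  # (N,) int16
    window_length: int
    vocabulary: Vocabulary

    def __len__(self) -> int:
        return len(self.labels)


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def filter_organic(smiles: str) -> bool:
    """True iff the molecule has at least one carbon and all its atoms
    are drawn from the allowed organic element set.

    Raises :class:`SmilesParseError` for unparseable input, which is a
    different condition from "parseable but not organic".
    """
    mol = _parse(smiles)
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    if "C" not in symbols and "c" not in symbols:
        return False
    return all(s in ORGANIC_ELEMENTS for s in symbols)


def strip_stereo(smiles: str) -> str:
    """Remove stereochemistry markers and re-canonicalize.

    Tetrahedral tags [C@@H], [C@H], [C@@], [C@] become plain C and the
    double-bond direction characters ``/`` and ``\\`` are dropped.
    """
    out = smiles
    for token in _STEREO_ATOMS:
        out = out.replace(token, "C")
    out = out.replace("/", "").replace("\\", "")
    mol = Chem.MolFromSmiles(out)
    assert mol is not None, f"stereo stripping broke SMILES: {smiles!r}"
    # belt and braces: clear any remaining stereo flags (e.g. [S@])
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def substitute_tokens(smiles: str) -> str:
    """Collapse the two-character halogens and aromatic [nH] to the
    single characters L, R and A. Input must not already contain those
    characters (the round trip would be ambiguous)."""
    for char in "LRA":
        if char in smiles:
            raise ValueError(
                f"input already contains {char!r}; substitution would be "
                "ambiguous"
            )
    out = smiles
    for token, char in SUBSTITUTIONS.items():  # longest token first
        out = out.replace(token, char)
    return out


def desubstitute_tokens(encoded: str) -> str:
    """Exact inverse of :func:`substitute_tokens`."""
    out = encoded
    for token, char in SUBSTITUTIONS.items():
        out = out.replace(char, token)
    return out


def prepare_corpus(
    raw_smiles: Iterable[str],
) -> tuple[list[RawMolecule], PrepReport]:
    """Clean a raw SMILES list into unique organic molecules.

    Each input line is split into fragments on ".", every fragment is
    parsed, filtered to organic molecules, stereo-stripped and
    canonicalized, then de-duplicated by canonical SMILES keeping input
    order of first occurrence. Unparseable fragments are counted, not
    fatal.
    """
    report = PrepReport()
    seen: set[str] = set()
    kept: list[RawMolecule] = []
    for line in raw_smiles:
        line = line.strip()
        if not line:
            continue
        report.input_lines += 1
        for frag in line.split("."):
            report.fragments += 1
            try:
                if not filter_organic(frag):
                    report.skipped_organic += 1
                    continue
                canonical = strip_stereo(frag)
            except SmilesParseError:
                report.skipped_parse += 1
                continue
            if canonical in seen:
                report.duplicates += 1
                continue
            seen.add(canonical)
            key = Chem.MolToInchiKey(Chem.MolFromSmiles(canonical))
            kept.append(
                RawMolecule(
                    source_smiles=frag,
                    canonical_smiles=canonical,
                    identity_key=key,
                )
            )
    report.kept = len(kept)
    return kept, report


def augment_randomized(
    molecules: Sequence[RawMolecule],
    factor: int,
    seed: int = 42,
    canonical_only: bool = False,
) -> tuple[list[str], float]:
    """Random-atom-order SMILES augmentation, de-duplicated globally.

    For each molecule ``factor`` randomized SMILES are attempted; the
    achieved ("real") augmentation factor is returned alongside and may
    be lower because symmetric molecules yield fewer distinct strings.
    With ``canonical_only`` the canonical strings themselves are
    returned (factor-1 identity augmentation).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out: list[str] = []
    seen: set[str] = set()
    for i, mol in enumerate(molecules):
        if canonical_only:
            candidates = [mol.canonical_smiles]
        else:
            rd = Chem.MolFromSmiles(mol.canonical_smiles)
            candidates = Chem.MolToRandomSmilesVect(
                rd, factor, (seed + i) % 2**31
            )
        for smi in candidates:
            if smi not in seen:
                seen.add(smi)
                out.append(smi)
    real_factor = len(out) / max(len(molecules), 1)
    return out, real_factor


def build_vocabulary(corpus_texts: Sequence[str]) -> Vocabulary:
    """Inventory of characters observed in the substituted corpus plus
    the terminator, sorted for determinism."""
    if not corpus_texts:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    observed = set()
    for text in corpus_texts:
        observed.update(text)
    observed.add(TERMINATOR)
    return Vocabulary(chars=tuple(sorted(observed)))


def encode_windows(
    corpus_texts: Sequence[str],
    vocab: Vocabulary,
    window_length: int,
    step: int = 1,
) -> EncodedCorpus:
    """Cut fixed-length next-character windows out of the corpus.

    The corpus is every text followed by a terminator, prefixed by
    ``window_length`` terminators so generation can start from an empty
    context. Windows start every ``step`` characters; the label is the
    character immediately after the window.
    """
    if window_length < 1 or step < 1:
        raise ValueError("window_length and step must be >= 1")
    content = "".join(t + TERMINATOR for t in corpus_texts)
    if window_length > len(content):
        raise ValueError("window_length exceeds total corpus length")
    joined = TERMINATOR * window_length + content
    indices = vocab.encode(joined)
    n_windows = (len(joined) - window_length - 1) // step + 1
    starts = np.arange(n_windows) * step
    contexts = indices[starts[:, None] + np.arange(window_length)]
    labels = indices[starts + window_length]
    return EncodedCorpus(
        contexts=contexts.astype(np.int16),
        labels=labels.astype(np.int16),
        window_length=window_length,
        vocabulary=vocab,
    )
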