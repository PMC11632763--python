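"""Clique (fragment) decomposition and count-vector featurization.

A molecule is dissected into "cliques": every smallest ring is one
clique (rings sharing more than two atoms are merged into a single
bridged clique), and every bond that belongs to no ring is a two-atom
clique.  The union of clique atom sets covers all heavy atoms and each
bond is owned by exactly one clique.  A dataset-wide vocabulary of the
distinct fragment strings defines feature columns, and a molecule's
descriptor is the sum of one-hot clique indicators — a non-negative
integer count vector.  The descriptor deliberately carries no
information about how the fragments are connected to each other: it is a
coarse-grained picture of a molecule's chemistry, not of its 3-D
structure.

Fragment strings are kekulized (aromatic rings written with explicit
alternating double bonds, e.g. ``C1=CC=CC=C1``), stereo-free, canonical
SMILES with formal charges retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "CliqueOccurrence",
    "CliqueVocabulary",
    "FeatureMatrix",
    "decompose",
    "decompose_dataset",
    "build_vocabulary",
    "featurize",
    "featurize_many",
    "binarize",
]


@dataclass(frozen=True)
class CliqueOccurrence:
    """One clique found in a parent molecule.

    ``atom_indices`` are positions in the parent; ``bond_indices`` are
    the parent bonds this clique *owns* (disjoint across cliques, their
    union is all bonds).  For a ring fused to another ring the shared
    bond is drawn in the fragment string of both rings but owned by only
    one of them.
    """

    atom_indices: frozenset[int]
    fragment_smiles: str
    bond_indices: frozenset[int]


@dataclass
class CliqueVocabulary:
    """Ordered map from fragment string to feature column index.

    Ordering is descending document frequency (number of molecules
    containing the clique at least once), ties broken lexicographically,
    so two builds from the same data yield identical index maps.
    ``occurrence_frequency`` additionally counts total occurrences, for
    abundance reports that weight repeated cliques within one molecule.
    """

    index: dict[str, int] = field(default_factory=dict)
    document_frequency: dict[str, int] = field(default_factory=dict)
    occurrence_frequency: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, fragment: str) -> bool:
        return fragment in self.index

    @property
    def fragments(self) -> list[str]:
        """Fragment strings in column order."""
        out = [""] * len(self.index)
        for frag, j in self.index.items():
            out[j] = frag
        return out

    def to_frame(self) -> pd.DataFrame:
        frags = self.fragments
        return pd.DataFrame(
            {
                "index": np.arange(len(frags)),
                "fragment_smiles": frags,
                "document_frequency": [self.document_frequency[f] for f in frags],
                "occurrence_frequency": [self.occurrence_frequency[f] for f in frags],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CliqueVocabulary":
        vocab = cls()
        for _, row in df.sort_values("index").iterrows():
            frag = row["fragment_smiles"]
            vocab.index[frag] = int(row["index"])
            vocab.document_frequency[frag] = int(row["document_frequency"])
            vocab.occurrence_frequency[frag] = int(row.get("occurrence_frequency", row["document_frequency"]))
        return vocab


@dataclass
class FeatureMatrix:
    """Molecule x clique count matrix with its defining vocabulary."""

    counts: np.ndarray  # (N, V) non-negative integers
    row_ids: np.ndarray  # record indices, length N
    vocab: CliqueVocabulary

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_triplets(self) -> pd.DataFrame:
        """Sparse (row_id, clique_index, count) export."""
        rows, cols = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "row_id": np.asarray(self.row_ids)[rows],
                "clique_index": cols,
                "count": self.counts[rows, cols],
            }
        )


def _merge_bridged(rings: list[set[int]]) -> list[set[int]]:
    # rings sharing > 2 atoms collapse into one bridged clique;
    # fused (2 shared) and spiro (1 shared) rings stay separate
    rings = [set(r) for r in rings]
    merged = True
    while merged:
        merged = False
        for i in range(len(rings)):
            for j in range(i + 1, len(rings)):
                if len(rings[i] & rings[j]) > 2:
                    rings[i] |= rings.pop(j)
                    merged = True
                    break
            if merged:
                break
    return rings


def _fragment_smiles(mol: Chem.Mol, bond_ids: Sequence[int]) -> str:
    sub = Chem.PathToSubmol(mol, list(bond_ids))
    return Chem.MolToSmiles(sub, kekuleSmiles=True)


def decompose(structure: str) -> list[CliqueOccurrence]:
    """Dissect a molecule into ring cliques and non-ring bond cliques.

    Atom and bond indices in the returned occurrences refer to the
    *canonical* atom ordering of the molecule: the input is re-parsed
    from its canonical SMILES before kekulization, because the kekule
    assignment of fused aromatic systems otherwise depends on the atom
    order in which the molecule happens to be written.  This makes the
    decomposition a function of the molecular graph alone.  A
    single-heavy-atom molecule yields one single-atom clique so that no
    molecule is featureless.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparseable or empty SMILES: {structure!r}")
    Chem.RemoveStereochemistry(mol)
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    Chem.Kekulize(mol, clearAromaticFlags=True)

    if mol.GetNumAtoms() == 1:
        atom = mol.GetAtomWithIdx(0)
        # one-atom fragment preserving element and formal charge
        rw = Chem.RWMol()
        a = Chem.Atom(atom.GetAtomicNum())
        a.SetFormalCharge(atom.GetFormalCharge())
        rw.AddAtom(a)
        frag = Chem.MolToSmiles(rw.GetMol())
        return [CliqueOccurrence(frozenset({0}), frag, frozenset())]

    ring_info = mol.GetRingInfo()
    ring_atom_sets = _merge_bridged([set(r) for r in ring_info.AtomRings()])

    cliques: list[CliqueOccurrence] = []
    owned: set[int] = set()
    # deterministic order: by smallest atom index in the ring
    for ring in sorted(ring_atom_sets, key=min):
        bond_ids = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.IsInRing() and b.GetBeginAtomIdx() in ring and b.GetEndAtomIdx() in ring
        ]
        own = frozenset(i for i in bond_ids if i not in owned)
        owned.update(own)
        cliques.append(CliqueOccurrence(frozenset(ring), _fragment_smiles(mol, bond_ids), own))
    for b in mol.GetBonds():
        if not b.IsInRing():
            atoms = frozenset({b.GetBeginAtomIdx(), b.GetEndAtomIdx()})
            cliques.append(
                CliqueOccurrence(atoms, _fragment_smiles(mol, [b.GetIdx()]), frozenset({b.GetIdx()}))
            )
    return cliques


def decompose_dataset(structures: Iterable[str]) -> list[list[CliqueOccurrence]]:
    """Decompose each structure, caching repeated identical strings."""
    cache: dict[str, list[CliqueOccurrence]] = {}
    out = []
    for s in structures:
        if s not in cache:
            cache[s] = decompose(s)
        out.append(cache[s])
    return out


def build_vocabulary(decompositions: Sequence[Sequence[CliqueOccurrence]]) -> CliqueVocabulary:
    """Collect the distinct fragments of a dataset into an ordered vocabulary."""
    if len(decompositions) == 0:
        raise ValueError("cannot build a vocabulary from zero molecules")
    doc: dict[str, int] = {}
    occ: dict[str, int] = {}
    for cliques in decompositions:
        seen = set()
        for c in cliques:
            occ[c.fragment_smiles] = occ.get(c.fragment_smiles, 0) + 1
            if c.fragment_smiles not in seen:
                seen.add(c.fragment_smiles)
                doc[c.fragment_smiles] = doc.get(c.fragment_smiles, 0) + 1
    ordered = sorted(doc, key=lambda f: (-doc[f], f))
    vocab = CliqueVocabulary()
    for j, frag in enumerate(ordered):
        vocab.index[frag] = j
        vocab.document_frequency[frag] = doc[frag]
        vocab.occurrence_frequency[frag] = occ[frag]
    return vocab


def featurize(
    decomposition: Sequence[CliqueOccurrence],
    vocab: CliqueVocabulary,
    oov_policy: str = "drop",
) -> tuple[np.ndarray, int]:
    """Sum the one-hot clique indicators into one integer count vector.

    Fragments absent from the vocabulary are dropped; the returned
    out-of-vocabulary tally counts them (``oov_policy`` is ``"drop"`` or
    ``"tally"`` — both drop, ``"tally"`` is the explicit spelling).
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    if oov_policy not in ("drop", "tally"):
        raise ValueError(f"unknown oov_policy {oov_policy!r}")
    vec = np.zeros(len(vocab), dtype=np.int64)
    oov = 0
    for c in decomposition:
        j = vocab.index.get(c.fragment_smiles)
        if j is None:
            oov += 1
        else:
            vec[j] += 1
    return vec, oov


def featurize_many(
    decompositions: Sequence[Sequence[CliqueOccurrence]],
    vocab: CliqueVocabulary,
    row_ids: Sequence[int] | None = None,
    oov_policy: str = "drop",
) -> tuple[FeatureMatrix, int]:
    """Stack per-molecule count vectors into a :class:`FeatureMatrix`."""
    vecs = []
    total_oov = 0
    for d in decompositions:
        v, oov = featurize(d, vocab, oov_policy)
        vecs.append(v)
        total_oov += oov
    counts = np.vstack(vecs) if vecs else np.zeros((0, len(vocab)), dtype=np.int64)
    if row_ids is None:
        row_ids = np.arange(len(decompositions))
    return FeatureMatrix(counts=counts, row_ids=np.asarray(row_ids), vocab=vocab), total_oov


def binarize(matrix: "FeatureMatrix | np.ndarray") -> np.ndarray:
    """Presence/absence view of a count matrix: entry 1 iff count > 0."""
    counts = matrix.counts if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    return (counts > 0).astype(np.int64)
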