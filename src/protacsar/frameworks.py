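"""Bemis-Murcko frameworks and hashed sphere fingerprints.

The *scaffold* of a molecule is its ring systems plus the direct inter-ring
connections, with atom labels and stereochemistry retained; the *skeleton*
additionally erases atom labels and bond orders, keeping only the graph.
Similarity between molecules is measured with a hashed circular-sphere count
fingerprint: for every atom and every radius up to R, the canonical string
of its r-sphere environment is hashed into a fixed-length count vector twice,
once with full atom/bond labels and once skeleton-abstracted (all atoms
carbon-equivalent, all bonds single-equivalent). This is a reproducible
stand-in for proprietary skeleton-sphere descriptors; all similarity
thresholds in this package refer to it. Count vectors are compared with the
count (min/max) form of the Tanimoto coefficient.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

DEFAULT_RADIUS = 5
DEFAULT_NBITS = 1024


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising ValueError on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol


# ---------------------------------------------------------------------------
# Murcko frameworks
# ---------------------------------------------------------------------------

def murcko_scaffold(mol: Chem.Mol) -> Chem.Mol:
    """Bemis-Murcko scaffold: ring systems plus inter-ring linker atoms.

    Terminal side-chain atoms are pruned iteratively; an exocyclic atom
    double-bonded to a retained atom is itself retained. Acyclic molecules
    yield an empty scaffold. Idempotent.
    """
    return MurckoScaffold.GetScaffoldForMol(mol)


def murcko_skeleton(mol: Chem.Mol) -> Chem.Mol:
    """Murcko skeleton: the scaffold with atom labels and bond orders erased.

    All scaffold atoms become carbon-equivalent and all bonds
    single-equivalent, so e.g. pyridine and benzene share one skeleton.
    """
    scaffold = murcko_scaffold(mol)
    if scaffold.GetNumAtoms() == 0:
        return scaffold
    return MurckoScaffold.MakeScaffoldGeneric(scaffold)


def scaffold_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES of the Murcko scaffold ('' for acyclic input)."""
    return Chem.MolToSmiles(murcko_scaffold(mol))


def skeleton_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES of the Murcko skeleton ('' for acyclic input)."""
    return Chem.MolToSmiles(murcko_skeleton(mol))


# ---------------------------------------------------------------------------
# Sphere fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereFingerprint:
    """Hashed count vector over labeled + skeleton sphere environments."""

    counts: np.ndarray  # shape (nbits,), nonnegative ints
    radius: int
    nbits: int

    def __post_init__(self) -> None:
        if self.counts.shape != (self.nbits,):
            raise ValueError("count vector length must equal nbits")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def to_row(self) -> str:
        return " ".join(str(int(c)) for c in self.counts)


def _stable_hash(text: str) -> int:
    """Platform-stable 64-bit hash of a string (blake2b, 8-byte digest)."""
    return int.from_bytes(hashlib.blake2b(text.encode(), digest_size=8).digest(), "big")


def _atom_invariant(atom: Chem.Atom) -> str:
    # frozen atom-invariant ranking: element, degree, charge, aromaticity, H count
    return (
        f"{atom.GetSymbol()},{atom.GetDegree()},{atom.GetFormalCharge()},"
        f"{int(atom.GetIsAromatic())},{atom.GetTotalNumHs()}"
    )


def _sphere_counts(
    mol: Chem.Mol, radius: int, nbits: int, skeleton: bool
) -> np.ndarray:
    """Morgan-style iterated sphere hashing for one label stream.

    Each atom starts from its invariant (or a degree-only invariant for the
    skeleton stream); at every iteration the invariant absorbs the sorted
    (bond label, neighbour invariant) multiset, so after r rounds it is a
    canonical summary of the atom's r-sphere. Every (atom, radius) sphere
    contributes one count.
    """
    tag = "S" if skeleton else "L"
    if skeleton:
        codes = [f"{tag}|{atom.GetDegree()}" for atom in mol.GetAtoms()]
    else:
        codes = [f"{tag}|{_atom_invariant(atom)}" for atom in mol.GetAtoms()]
    invariants = [_stable_hash(c) for c in codes]
    counts = np.zeros(nbits, dtype=np.int64)
    neighbours = [
        [
            (
                "1" if skeleton else str(bond.GetBondType()),
                bond.GetOtherAtom(atom).GetIdx(),
            )
            for bond in atom.GetBonds()
        ]
        for atom in mol.GetAtoms()
    ]
    for inv in invariants:
        counts[inv % nbits] += 1
    for _ in range(radius):
        new = []
        for idx, atom_nbrs in enumerate(neighbours):
            env = sorted((blabel, invariants[j]) for blabel, j in atom_nbrs)
            text = f"{tag}|{invariants[idx]}|" + "|".join(
                f"{blabel}:{h}" for blabel, h in env
            )
            new.append(_stable_hash(text))
        invariants = new
        for inv in invariants:
            counts[inv % nbits] += 1
    return counts


def skelspheres_fingerprint(
    mol: Chem.Mol, radius: int = DEFAULT_RADIUS, nbits: int = DEFAULT_NBITS
) -> SphereFingerprint:
    """Dual labeled + skeleton-abstracted sphere count fingerprint.

    Deterministic across runs and platforms; the total count equals
    2 * heavy_atoms * (radius + 1).
    """
    counts = _sphere_counts(mol, radius, nbits, skeleton=False)
    counts += _sphere_counts(mol, radius, nbits, skeleton=True)
    return SphereFingerprint(counts=counts, radius=radius, nbits=nbits)


def tanimoto(a: SphereFingerprint, b: SphereFingerprint) -> float:
    """Count Tanimoto similarity: sum(min) / sum(max); 0 for two empty vectors."""
    if a.nbits != b.nbits:
        raise ValueError("fingerprints must share nbits")
    denom = np.maximum(a.counts, b.counts).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(a.counts, b.counts).sum() / denom)


def fingerprint_matrix(fps: list[SphereFingerprint]) -> np.ndarray:
    """Stack fingerprints into an (n, nbits) count matrix."""
    if not fps:
        return np.zeros((0, DEFAULT_NBITS), dtype=np.int64)
    return np.stack([fp.counts for fp in fps])
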