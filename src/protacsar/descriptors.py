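"""Permeability-related 2D descriptors for large, flexible degraders.

Seven descriptors: molecular weight (MW, Da), carbon count (nC), aromatic
ring count (nAR), hydrogen-bond acceptor and donor atom counts (nHAcc,
nHDon), Ertl topological polar surface area (TPSA, A^2, N/O contributions
only) and Kier's molecular flexibility index (PHI, dimensionless).

Counting rules (frozen):
  nHDon  = number of N or O atoms bearing at least one hydrogen.
  nHAcc  = number of N or O atoms, excluding pyrrole-type aromatic nitrogens
           (aromatic N donating its lone pair into the ring: three ring/
           substituent connections or an in-ring NH) and amide/imide
           nitrogens (N single-bonded to a carbonyl carbon). Fluorine and
           sulfur never count.

PHI is computed from Kier's alpha-modified kappa shape indices:
  kappa1a = (A + a)(A + a - 1)^2 / (P1 + a)^2
  kappa2a = (A + a - 1)(A + a - 2)^2 / (P2 + a)^2
  PHI     = kappa1a * kappa2a / A
with A the heavy-atom count, P1 the bond count, P2 the number of two-bond
paths and a the sum of covalent-radius alpha contributions relative to
sp3 carbon. For an unbranched alkane of A atoms PHI equals A - 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RDDescriptors
from rdkit.Chem import rdMolDescriptors

DESCRIPTOR_NAMES = ("MW", "nC", "nAR", "nHAcc", "nHDon", "TPSA", "PHI")

# Kier's alpha contributions: (covalent radius / r(C sp3)) - 1, by element and
# hybridization bucket (aromatic atoms are treated as sp2).
_KIER_ALPHA = {
    ("C", "sp3"): 0.0,
    ("C", "sp2"): -0.13,
    ("C", "sp"): -0.22,
    ("N", "sp3"): -0.04,
    ("N", "sp2"): -0.20,
    ("N", "sp"): -0.29,
    ("O", "sp3"): -0.04,
    ("O", "sp2"): -0.20,
    ("F", "sp3"): -0.07,
    ("Cl", "sp3"): 0.29,
    ("Br", "sp3"): 0.48,
    ("I", "sp3"): 0.73,
    ("P", "sp3"): 0.43,
    ("S", "sp3"): 0.35,
    ("S", "sp2"): 0.22,
}


@dataclass(frozen=True)
class DescriptorVector:
    MW: float
    nC: int
    nAR: int
    nHAcc: int
    nHDon: int
    TPSA: float
    PHI: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.MW, self.nC, self.nAR, self.nHAcc, self.nHDon, self.TPSA, self.PHI)


def tpsa(mol: Chem.Mol) -> float:
    """Ertl fragment-additive topological polar surface area (N/O only)."""
    return float(rdMolDescriptors.CalcTPSA(mol))


def n_aromatic_rings(mol: Chem.Mol) -> int:
    return int(rdMolDescriptors.CalcNumAromaticRings(mol))


def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        if nbr.GetSymbol() != "C" or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        for b2 in nbr.GetBonds():
            if b2.GetBondType() == Chem.BondType.DOUBLE and \
                    b2.GetOtherAtom(nbr).GetSymbol() in ("O", "S"):
                return True
    return False


def _is_pyrrole_type(atom: Chem.Atom) -> bool:
    if not atom.GetIsAromatic():
        return False
    # lone pair in the ring: NH (pyrrole) or three connections (N-substituted)
    return atom.GetTotalNumHs() >= 1 or atom.GetDegree() == 3


def n_hbond_donors(mol: Chem.Mol) -> int:
    """N/O atoms bearing at least one hydrogen."""
    return sum(
        1
        for atom in mol.GetAtoms()
        if atom.GetSymbol() in ("N", "O") and atom.GetTotalNumHs() >= 1
    )


def n_hbond_acceptors(mol: Chem.Mol) -> int:
    """N/O atoms minus pyrrole-type aromatic N and amide N (frozen rule)."""
    count = 0
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol == "O":
            count += 1
        elif symbol == "N":
            if _is_pyrrole_type(atom) or _is_amide_nitrogen(atom):
                continue
            count += 1
    return count


def _kier_alpha(mol: Chem.Mol) -> float:
    total = 0.0
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if atom.GetIsAromatic():
            bucket = "sp2"
        else:
            orders = [b.GetBondTypeAsDouble() for b in atom.GetBonds()]
            if any(o == 3.0 for o in orders):
                bucket = "sp"
            elif any(o == 2.0 for o in orders):
                bucket = "sp2"
            else:
                bucket = "sp3"
        key = (symbol, bucket)
        if key not in _KIER_ALPHA:
            key = (symbol, "sp3")
        total += _KIER_ALPHA.get(key, 0.0)
    return total


def kier_phi(mol: Chem.Mol) -> float:
    """Kier molecular flexibility index from alpha-modified kappa indices."""
    a_count = mol.GetNumHeavyAtoms()
    if a_count < 3:
        raise ValueError("kier_phi requires at least 3 heavy atoms")
    alpha = _kier_alpha(mol)
    p1 = mol.GetNumBonds()
    p2 = sum(
        atom.GetDegree() * (atom.GetDegree() - 1) // 2 for atom in mol.GetAtoms()
    )
    kappa1 = (a_count + alpha) * (a_count + alpha - 1) ** 2 / (p1 + alpha) ** 2
    kappa2 = (a_count + alpha - 1) * (a_count + alpha - 2) ** 2 / (p2 + alpha) ** 2
    return float(kappa1 * kappa2 / a_count)


def compute_descriptors(mol: Chem.Mol) -> DescriptorVector:
    """All seven permeability-related descriptors for one molecule."""
    return DescriptorVector(
        MW=round(float(_RDDescriptors.MolWt(mol)), 2),
        nC=sum(1 for atom in mol.GetAtoms() if atom.GetSymbol() == "C"),
        nAR=n_aromatic_rings(mol),
        nHAcc=n_hbond_acceptors(mol),
        nHDon=n_hbond_donors(mol),
        TPSA=tpsa(mol),
        PHI=kier_phi(mol),
    )


def descriptor_table(
    ids: Sequence[str], mols: Iterable[Chem.Mol]
) -> pd.DataFrame:
    """DataFrame of the seven descriptors, indexed by compound id."""
    rows = [compute_descriptors(mol).as_tuple() for mol in mols]
    return pd.DataFrame(rows, index=list(ids), columns=list(DESCRIPTOR_NAMES))


def descriptor_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the descriptor columns.

    Requires at least 3 molecules. Correlations involving a constant column
    are reported as NaN (undefined), not as numbers.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 molecules for a correlation matrix")
    values = table[list(DESCRIPTOR_NAMES)].astype(float)
    corr = values.corr(method="pearson")
    constant = values.std(ddof=0) == 0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    np.fill_diagonal(corr.values, np.where(constant, np.nan, 1.0))
    return corr
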