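"""Tripartite PROTAC decomposition and linker-degradation relationships.

A PROTAC is warhead--linker--E3-ligand. Given SMARTS anchor patterns for the
two terminal blocks, a molecule is partitioned into the matched warhead
atoms, the matched E3-ligand atoms and the connecting linker (everything
else), joined by exactly two attachment bonds. Linker metrics (carbon count,
topological length, chemical class) feed the linker-degradation relationship
(LDR) analysis: within a matched series (same warhead, same E3 ligand, same
attachment points and linker chemistry, varying only in linker length) the
degradation-vs-length profile is fitted with a quadratic, whose vertex
estimates the optimal linker carbon count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .dataset import DegradationRecord

MIN_SERIES_SIZE = 4
CURVATURE_TOL = 1e-6

ANCHOR_ROLES = ("warhead", "e3_ligand")


class DecompositionError(ValueError):
    """The molecule cannot be partitioned into three blocks."""


class NoAnchorMatch(DecompositionError):
    def __init__(self, role: str):
        self.role = role
        super().__init__(f"no anchor pattern of role {role!r} matches the molecule")


class OverlappingAnchors(DecompositionError):
    def __init__(self) -> None:
        super().__init__("no disjoint warhead/e3 anchor match pair exists")


@dataclass(frozen=True)
class AnchorPattern:
    """A named SMARTS pattern identifying a terminal building block."""

    name: str
    role: str  # "warhead" | "e3_ligand"
    smarts: str

    def __post_init__(self) -> None:
        if self.role not in ANCHOR_ROLES:
            raise ValueError(f"role must be one of {ANCHOR_ROLES}")
        query = Chem.MolFromSmarts(self.smarts)
        if query is None:
            raise ValueError(f"unparsable SMARTS {self.smarts!r}")
        if query.GetNumAtoms() < 3:
            raise ValueError("anchor pattern must cover at least 3 heavy atoms")

    @property
    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.smarts)


@dataclass(frozen=True)
class TripartiteDecomposition:
    """Partition of a PROTAC's heavy atoms into the three building blocks."""

    warhead_atoms: frozenset[int]
    linker_atoms: frozenset[int]
    e3_atoms: frozenset[int]
    # two (linker_atom, anchor_atom) bonds
    attachment_bonds: tuple[tuple[int, int], tuple[int, int]]
    warhead_name: str = ""
    e3_name: str = ""


def load_anchor_library(path: str | Path) -> list[AnchorPattern]:
    """Read an anchor library CSV with columns name, role, smarts."""
    patterns = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            patterns.append(
                AnchorPattern(name=row["name"], role=row["role"], smarts=row["smarts"])
            )
    return patterns


def write_anchor_library(patterns: Sequence[AnchorPattern], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "role", "smarts"])
        for pat in patterns:
            writer.writerow([pat.name, pat.role, pat.smarts])


def _role_matches(
    mol: Chem.Mol, anchors: Sequence[AnchorPattern], role: str
) -> list[tuple[frozenset[int], str]]:
    """All substructure matches of the given role, best-first.

    Ordering is the tie-break rule: largest match first, then lowest
    canonical atom rank of the matched atom set.
    """
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    found: list[tuple[frozenset[int], str]] = []
    seen: set[frozenset[int]] = set()
    for pat in anchors:
        if pat.role != role:
            continue
        for match in mol.GetSubstructMatches(pat.query, uniquify=True):
            atoms = frozenset(match)
            if atoms not in seen:
                seen.add(atoms)
                found.append((atoms, pat.name))
    found.sort(key=lambda am: (-len(am[0]), tuple(sorted(ranks[i] for i in am[0]))))
    return found


def decompose_protac(
    mol: Chem.Mol, anchors: Sequence[AnchorPattern]
) -> TripartiteDecomposition:
    """Partition a PROTAC into warhead / linker / E3-ligand atom sets.

    The best disjoint pair of warhead- and e3-role matches is selected
    (largest match, then lowest canonical atom rank); the linker is the
    complement and must connect the two blocks through exactly two
    attachment bonds.
    """
    w_matches = _role_matches(mol, anchors, "warhead")
    if not w_matches:
        raise NoAnchorMatch("warhead")
    e_matches = _role_matches(mol, anchors, "e3_ligand")
    if not e_matches:
        raise NoAnchorMatch("e3_ligand")

    chosen = None
    for w_atoms, w_name in w_matches:
        for e_atoms, e_name in e_matches:
            if not (w_atoms & e_atoms):
                chosen = (w_atoms, w_name, e_atoms, e_name)
                break
        if chosen:
            break
    if chosen is None:
        raise OverlappingAnchors()
    w_atoms, w_name, e_atoms, e_name = chosen

    all_atoms = frozenset(range(mol.GetNumAtoms()))
    linker = all_atoms - w_atoms - e_atoms
    if not linker:
        raise DecompositionError("anchors leave no linker atoms")

    attachments: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in linker and j in (w_atoms | e_atoms):
            attachments.append((i, j))
        elif j in linker and i in (w_atoms | e_atoms):
            attachments.append((j, i))
    if len(attachments) != 2:
        raise DecompositionError(
            f"expected exactly 2 linker attachment bonds, found {len(attachments)}"
        )
    # linker must induce a connected subgraph
    if len(linker) > 1:
        emol = Chem.RWMol(mol)
        for idx in sorted(all_atoms - linker, reverse=True):
            emol.RemoveAtom(idx)
        if len(Chem.GetMolFrags(emol)) != 1:
            raise DecompositionError("linker atoms do not form a connected subgraph")
    return TripartiteDecomposition(
        warhead_atoms=w_atoms,
        linker_atoms=frozenset(linker),
        e3_atoms=e_atoms,
        attachment_bonds=tuple(sorted(attachments)),  # type: ignore[arg-type]
        warhead_name=w_name,
        e3_name=e_name,
    )


# ---------------------------------------------------------------------------
# Linker metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkerProfile:
    n_carbon: int
    topo_length: int  # bonds on the shortest path between the attachment atoms
    linker_class: str  # alkyl | ether | rigid | mixed


def _fragment_smiles(mol: Chem.Mol, atoms: frozenset[int]) -> str:
    return Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), canonical=True)


def linker_metrics(decomp: TripartiteDecomposition, mol: Chem.Mol) -> LinkerProfile:
    """Carbon count, topological length and chemical class of the linker.

    Ring carbons count toward n_carbon. Class rules: alkyl if every linker
    heavy atom is an acyclic carbon; ether if acyclic C/O with at least one
    oxygen; rigid if any linker atom is in a ring; otherwise mixed.
    """
    linker = decomp.linker_atoms
    n_carbon = sum(1 for i in linker if mol.GetAtomWithIdx(i).GetSymbol() == "C")
    (a1, _), (a2, _) = decomp.attachment_bonds
    if a1 == a2:
        topo = 1
    else:
        topo = max(1, len(Chem.GetShortestPath(mol, a1, a2)) - 1)
    in_ring = any(mol.GetAtomWithIdx(i).IsInRing() for i in linker)
    symbols = {mol.GetAtomWithIdx(i).GetSymbol() for i in linker}
    if in_ring:
        cls = "rigid"
    elif symbols == {"C"}:
        cls = "alkyl"
    elif symbols <= {"C", "O"} and "O" in symbols:
        cls = "ether"
    else:
        cls = "mixed"
    return LinkerProfile(n_carbon=n_carbon, topo_length=topo, linker_class=cls)


# ---------------------------------------------------------------------------
# Matched series and LDR fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdrSeries:
    """A matched series: fixed blocks and linker chemistry, varying length."""

    key: tuple[str, str, str]  # (warhead fragment, e3 fragment, linker class)
    ids: tuple[str, ...]
    lengths: tuple[int, ...]        # linker carbon counts, aligned with ids
    degradations: tuple[float, ...]  # deg_low, aligned with ids
    e3_class: str


@dataclass(frozen=True)
class LdrFit:
    vertex: float       # linker carbon count at maximal degradation
    curvature: float    # signed quadratic coefficient (percent / carbon^2)
    r2: float
    degenerate: bool


def _series_key(
    mol: Chem.Mol, decomp: TripartiteDecomposition, profile: LinkerProfile
) -> tuple[str, str, str]:
    # fragment the two attachment bonds with labeled dummies so the key
    # encodes the attachment points as well as the block structures
    bonds = []
    for la, aa in decomp.attachment_bonds:
        bonds.append(mol.GetBondBetweenAtoms(la, aa).GetIdx())
    frag = Chem.FragmentOnBonds(mol, bonds, addDummies=True, dummyLabels=[(1, 1), (2, 2)])
    pieces = Chem.GetMolFrags(frag, asMols=False)
    piece_smiles = {"warhead": "", "e3": ""}
    for piece in pieces:
        core = {i for i in piece if i < mol.GetNumAtoms()}
        if core <= decomp.warhead_atoms:
            piece_smiles["warhead"] = Chem.MolFragmentToSmiles(frag, atomsToUse=list(piece))
        elif core <= decomp.e3_atoms:
            piece_smiles["e3"] = Chem.MolFragmentToSmiles(frag, atomsToUse=list(piece))
    return (piece_smiles["warhead"], piece_smiles["e3"], profile.linker_class)


def select_matched_series(
    records: Sequence[DegradationRecord],
    decomps: dict[str, TripartiteDecomposition],
    mols: dict[str, Chem.Mol],
    min_size: int = MIN_SERIES_SIZE,
) -> list[LdrSeries]:
    """Group records into matched LDR series.

    Records sharing the warhead fragment, E3 fragment, attachment points and
    linker class — differing only in linker length — form a series; series
    smaller than min_size are discarded.
    """
    groups: dict[tuple[str, str, str], list[DegradationRecord]] = {}
    profiles: dict[str, LinkerProfile] = {}
    for rec in records:
        if rec.id not in decomps:
            raise KeyError(f"no decomposition for record {rec.id!r}")
        mol = mols[rec.id]
        decomp = decomps[rec.id]
        profile = linker_metrics(decomp, mol)
        profiles[rec.id] = profile
        groups.setdefault(_series_key(mol, decomp, profile), []).append(rec)
    series = []
    for key, members in sorted(groups.items()):
        if len(members) < min_size:
            continue
        members = sorted(members, key=lambda r: profiles[r.id].n_carbon)
        series.append(
            LdrSeries(
                key=key,
                ids=tuple(r.id for r in members),
                lengths=tuple(profiles[r.id].n_carbon for r in members),
                degradations=tuple(r.deg_low for r in members),
                e3_class=members[0].e3_class,
            )
        )
    return series


def fit_linker_parabola(
    points: Sequence[tuple[float, float]]
) -> LdrFit:
    """Least-squares quadratic fit of degradation against linker length.

    Needs at least 4 distinct lengths. The fit is flagged degenerate when
    the quadratic coefficient is nonnegative (no interior maximum) or
    negligibly small.
    """
    lengths = np.asarray([p[0] for p in points], dtype=float)
    values = np.asarray([p[1] for p in points], dtype=float)
    if len(set(lengths.tolist())) < 4:
        raise ValueError("need at least 4 distinct linker lengths")
    a, b, c = np.polyfit(lengths, values, 2)
    fitted = np.polyval([a, b, c], lengths)
    ss_res = float(np.sum((values - fitted) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    degenerate = a >= 0 or abs(a) < CURVATURE_TOL
    vertex = float("nan") if abs(a) < CURVATURE_TOL else -b / (2 * a)
    return LdrFit(vertex=float(vertex), curvature=float(a), r2=r2, degenerate=bool(degenerate))


def decomposition_report_row(
    rec_id: str, mol: Chem.Mol, decomp: TripartiteDecomposition
) -> dict[str, object]:
    """One row of the decomposition report CSV."""
    profile = linker_metrics(decomp, mol)
    return {
        "id": rec_id,
        "warhead_smiles": _fragment_smiles(mol, decomp.warhead_atoms),
        "linker_smiles": _fragment_smiles(mol, decomp.linker_atoms),
        "e3_smiles": _fragment_smiles(mol, decomp.e3_atoms),
        "n_carbon": profile.n_carbon,
        "topo_length": profile.topo_length,
        "linker_class": profile.linker_class,
    }
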