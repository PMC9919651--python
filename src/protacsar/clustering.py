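"""Murcko-scaffold clusters merged through matched molecular pairs.

Two molecules are a matched molecular pair (MMP) when a single cut of one
acyclic bond in each exposes a shared core fragment with two different
substituents, each substituent small enough to count as a localized change.
Clusters are the connected components of the graph whose edges join
molecules with identical canonical Murcko scaffolds or an MMP relation; the
same procedure applies at the whole-molecule level or to an extracted
building block (warhead, E3 ligand, linker).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
from rdkit import Chem

from .dataset import DegradationRecord, binarize_activity
from .frameworks import scaffold_smiles

MAX_SUBSTITUENT_ATOMS = 8

CLUSTER_LEVELS = ("full", "warhead", "e3", "linker")


@dataclass(frozen=True)
class MmpPair:
    """Two molecules differing by one localized substituent swap."""

    id_i: str
    id_j: str
    core: str   # canonical core fragment SMILES with attachment dummy
    sub_i: str
    sub_j: str


@dataclass(frozen=True)
class ClusterAssignment:
    level: str
    labels: Mapping[str, str]  # id -> cluster label


@dataclass(frozen=True)
class ClusterSummary:
    label: str
    n: int
    mean: float
    min: float
    max: float
    active_fraction: float


def _single_cut_fragments(
    mol: Chem.Mol, max_sub_atoms: int
) -> set[tuple[str, str]]:
    """All (core, substituent) pairs from single acyclic-single-bond cuts."""
    out: set[tuple[str, str]] = set()
    n_heavy = mol.GetNumAtoms()
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        frag = Chem.FragmentOnBonds(
            mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(1, 1)]
        )
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        if len(pieces) != 2:
            continue
        smiles = []
        sizes = []
        for piece in pieces:
            sizes.append(sum(1 for a in piece.GetAtoms() if a.GetAtomicNum() > 0))
            smiles.append(Chem.MolToSmiles(piece))
        for (core_idx, sub_idx) in ((0, 1), (1, 0)):
            if sizes[sub_idx] <= max_sub_atoms and sizes[core_idx] >= sizes[sub_idx]:
                out.add((smiles[core_idx], smiles[sub_idx]))
    return out


def find_mmp_pairs(
    mols: Mapping[str, Chem.Mol],
    max_sub_atoms: int = MAX_SUBSTITUENT_ATOMS,
) -> list[MmpPair]:
    """All matched molecular pairs among the molecules.

    Every molecule is fragmented at each acyclic single bond; two molecules
    pair when they share a canonical core with different substituents, each
    within max_sub_atoms heavy atoms. Each unordered pair is reported once,
    keyed on its largest shared core.
    """
    if len(mols) < 2:
        return []
    ids = sorted(mols)
    frags = {cid: _single_cut_fragments(mols[cid], max_sub_atoms) for cid in ids}
    by_core: dict[str, dict[str, set[str]]] = {}
    for cid in ids:
        for core, sub in frags[cid]:
            by_core.setdefault(core, {}).setdefault(cid, set()).add(sub)
    best: dict[tuple[str, str], MmpPair] = {}
    for core, members in by_core.items():
        cids = sorted(members)
        for a_pos in range(len(cids)):
            for b_pos in range(a_pos + 1, len(cids)):
                ci, cj = cids[a_pos], cids[b_pos]
                subs_i = members[ci] - members[cj]
                subs_j = members[cj] - members[ci]
                if not subs_i or not subs_j:
                    continue  # substituents must differ
                pair = MmpPair(
                    id_i=ci, id_j=cj, core=core,
                    sub_i=min(subs_i), sub_j=min(subs_j),
                )
                key = (ci, cj)
                prev = best.get(key)
                if prev is None or _core_size(core) > _core_size(prev.core) or (
                    _core_size(core) == _core_size(prev.core) and core < prev.core
                ):
                    best[key] = pair
    return [best[key] for key in sorted(best)]


def _core_size(core_smiles: str) -> int:
    mol = Chem.MolFromSmiles(core_smiles)
    if mol is None:
        return 0
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 0)


def _has_ring(fragment_smiles: str) -> bool:
    mol = Chem.MolFromSmiles(fragment_smiles)
    return mol is not None and mol.GetRingInfo().NumRings() > 0


def murcko_mmp_clusters(
    mols: Mapping[str, Chem.Mol],
    level: str = "full",
    max_sub_atoms: int = MAX_SUBSTITUENT_ATOMS,
    ring_substitutions_only: bool = False,
) -> ClusterAssignment:
    """Connected-component clusters over scaffold-identity and MMP edges.

    For building-block levels pass the extracted fragments as the molecules.
    With ring_substitutions_only, only MMP edges whose differing substituents
    involve a ring merge clusters (the strictest reading of a "ring system
    substitution"); by default any localized substituent swap merges.
    """
    if level not in CLUSTER_LEVELS:
        raise ValueError(f"level must be one of {CLUSTER_LEVELS}")
    graph = nx.Graph()
    graph.add_nodes_from(mols)
    by_scaffold: dict[str, list[str]] = {}
    for cid in sorted(mols):
        by_scaffold.setdefault(scaffold_smiles(mols[cid]), []).append(cid)
    for members in by_scaffold.values():
        for i in range(1, len(members)):
            graph.add_edge(members[0], members[i])
    for pair in find_mmp_pairs(mols, max_sub_atoms=max_sub_atoms):
        if ring_substitutions_only and not (
            _has_ring(pair.sub_i) or _has_ring(pair.sub_j)
        ):
            continue
        graph.add_edge(pair.id_i, pair.id_j)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda comp: comp[0],
    )
    labels: dict[str, str] = {}
    for index, comp in enumerate(components):
        label = _letters(index)
        for cid in comp:
            labels[cid] = label
    return ClusterAssignment(level=level, labels=labels)


def _letters(index: int) -> str:
    # a, b, ..., z, aa, ab, ...
    chars = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        chars = chr(ord("a") + rem) + chars
    return chars


def cluster_activity_summary(
    assignment: ClusterAssignment,
    records: Sequence[DegradationRecord],
    threshold: float = 75.0,
    concentration: str = "low",
) -> list[ClusterSummary]:
    """Per-cluster degradation statistics and active fraction."""
    by_id = {rec.id: rec for rec in records}
    clusters: dict[str, list[float]] = {}
    for cid, label in assignment.labels.items():
        if cid not in by_id:
            raise KeyError(f"clustered id {cid!r} has no degradation record")
        rec = by_id[cid]
        value = rec.deg_low if concentration == "low" else rec.deg_high
        clusters.setdefault(label, []).append(value)
    summaries = []
    for label in sorted(clusters):
        values = clusters[label]
        if not values:
            raise ValueError(f"empty cluster {label!r}")
        active = sum(binarize_activity(v, threshold).active for v in values)
        summaries.append(
            ClusterSummary(
                label=label,
                n=len(values),
                mean=float(sum(values) / len(values)),
                min=float(min(values)),
                max=float(max(values)),
                active_fraction=active / len(values),
            )
        )
    return summaries
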