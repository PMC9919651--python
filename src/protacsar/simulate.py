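"""Synthetic PROTAC dataset generator with planted ground truth.

Emits degradation tables with the statistical structure the analysis
pipeline assumes, so that every downstream result can be checked against a
known truth:

* tripartite molecules assembled from attachment-labeled warhead, linker and
  E3-ligand building blocks (atom maps recorded as ground truth);
* two correlated degradation readouts (the 1 uM value is the 0.1 uM value
  pushed toward saturation);
* a parabolic linker-length dependence with a class-specific optimal carbon
  count (shorter for the cereblon-recruiting class than for the VHL class);
* planted degradation-cliff pairs: a highly active parent and a dead twin
  whose warhead differs by a single in-ring atom edit;
* a planted polarity signal: E3-ligand variants carry increasing numbers of
  hydrogen-bond-accepting decorations, and degradation is penalized above a
  TPSA threshold, which makes activity classifiable from TPSA and nHAcc.

The additive activity model is

    deg_low  = clip(Dmax - a*(L - L*)^2 - p_w - gamma*max(0, TPSA - tau) + eps, 0, 100)
    deg_high = clip(deg_low + delta*(100 - deg_low)/100 + eps', 0, 100)

with L the linker carbon count, L* the class optimum, p_w the warhead
penalty (0 for live warheads, >= 70 for dead variants) and eps Gaussian
noise. Rigid linkers use a near-flat curvature, emulating rigid series that
degrade well almost independently of length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .dataset import DegradationRecord
from .decomposition import AnchorPattern
from .descriptors import tpsa as _tpsa

# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

# warheads: an aryl-nitrile/cycloalkyl-amine family (W1) with dead analogs,
# plus a structurally unrelated benzoxazole family (W2)
_WARHEADS = {
    "W1": ("N#Cc1ccc(C2CCC(CC2)N[*:1])cc1", False),
    # single-atom edit (nitrile N -> CH, i.e. cyano -> ethynyl): loses the key
    # hydrogen-bond-accepting nitrogen; the auto-detectable planted cliff partner
    "W1_deadX": ("C#Cc1ccc(C2CCC(CC2)N[*:1])cc1", True),
    # ring-size edit (6 -> 5): a dead analog of the kind similarity searches miss
    "W1_dead5": ("N#Cc1ccc(C2CCC(C2)N[*:1])cc1", True),
    "W2": ("Clc1ccc2nc(C3CCN(C3)[*:1])oc2c1", False),
}
_DEAD_PARENT = {"W1_deadX": "W1", "W1_dead5": "W1"}
PLANTED_DEAD_WARHEAD = "W1_deadX"

# E3 ligands: a hydroxyproline-amide VHL-like family and a glutarimide/
# phthalimide CRBN-like family; variants add acceptor-only polar decorations
# (methoxy, nitrile, nitro) on an aryl position, raising TPSA and nHAcc
# while leaving the donor count unchanged.
_E3_VARIANTS = {
    "VHL": (
        "OC1CC(c2ccc(-c3scnc3C)cc2)N(C(=O)C(NC(=O)C[*:2])C(C)(C)C)C1",
        "OC1CC(c2ccc(-c3scnc3C)c(OC)c2)N(C(=O)C(NC(=O)C[*:2])C(C)(C)C)C1",
        "OC1CC(c2c(C#N)cc(-c3scnc3C)c(OC)c2C#N)N(C(=O)C(NC(=O)C[*:2])C(C)(C)C)C1",
        "OC1CC(c2c(C(N)=O)cc(-c3scnc3C)c([N+](=O)[O-])c2C#N)N(C(=O)C(NC(=O)C[*:2])C(C)(C)C)C1",
    ),
    "CRBN": (
        "O=C1CCC(N2C(=O)c3ccc(N4CCC(C[*:2])CC4)cc3C2=O)C(=O)N1",
        "O=C1CCC(N2C(=O)c3cc(OC)c(N4CCC(C[*:2])CC4)cc3C2=O)C(=O)N1",
        "O=C1CCC(N2C(=O)c3c(C#N)c(OC)c(N4CCC(C[*:2])CC4)c(C#N)c3C2=O)C(=O)N1",
        "O=C1CCC(N2C(=O)c3c(C(N)=O)c([N+](=O)[O-])c(N4CCC(C[*:2])CC4)c(C#N)c3C2=O)C(=O)N1",
    ),
}

_RIGID_LINKERS = (
    # piperidine-phenylene and piperidine-cyclohexylene
    ("rigid_pip_ph", "[*:1]C1CCN(CC1)c1ccc(C[*:2])cc1"),
    ("rigid_pip_ch", "[*:1]C1CCN(CC1)C1CCC(C[*:2])CC1"),
)


@dataclass(frozen=True)
class Block:
    name: str
    role: str         # warhead | e3_ligand | linker
    smiles: str       # with [*:1] / [*:2] attachment labels
    n_carbon: int = 0  # linker blocks only
    linker_class: str = ""
    penalty: float = 0.0
    is_dead: bool = False
    parent: str = ""
    e3_class: str = ""
    variant: int = 0


@dataclass(frozen=True)
class BlockLibrary:
    warheads: tuple[Block, ...]
    e3_ligands: tuple[Block, ...]
    linkers: tuple[Block, ...]

    def warhead(self, name: str) -> Block:
        return next(b for b in self.warheads if b.name == name)

    def e3(self, e3_class: str, variant: int) -> Block:
        return next(
            b for b in self.e3_ligands if b.e3_class == e3_class and b.variant == variant
        )

    def linker(self, name: str) -> Block:
        return next(b for b in self.linkers if b.name == name)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset."""

    seed: int
    n: int = 200
    vhl_fraction: float = 53 / 92          # the AR dataset's class balance
    linker_length_range: tuple[int, int] = (4, 14)  # alkyl carbon counts
    l_star: Mapping[str, int] = field(
        default_factory=lambda: {"VHL": 10, "CRBN": 6}
    )
    curvature: float = 2.0                 # percent per carbon^2
    rigid_curvature: float = 0.1           # near-flat length penalty for rigid linkers
    dmax: float = 95.0                     # percent
    dead_penalty: float = 90.0             # percent, >= 70 by construction
    cliff_fraction: float = 0.15           # fraction of compounds that are dead twins
    tpsa_tau: float = 135.0                # A^2; polarity penalty threshold
    tpsa_gamma: float = 2.5                # percent per A^2 above tau
    noise_sd: float = 3.0                  # percent
    concentration_gain: float = 20.0       # push toward saturation at 1 uM

    def __post_init__(self) -> None:
        if not (0.0 <= self.vhl_fraction <= 1.0):
            raise ValueError("vhl_fraction must be in [0, 1]")
        if not (0.0 <= self.cliff_fraction <= 0.5):
            raise ValueError("cliff_fraction must be in [0, 0.5]")
        lo, hi = self.linker_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid linker length range")
        if self.dead_penalty < 70.0:
            raise ValueError("dead variants must be penalized by at least 70 points")


def signal_free_config(seed: int, n: int = 200) -> GeneratorConfig:
    """A null configuration: degradation is pure noise around the cutoff.

    All structural effects are switched off and readouts are drawn wide
    around 75%, so activity labels are independent of the descriptors.
    """
    return GeneratorConfig(
        seed=seed,
        n=n,
        curvature=0.0,
        rigid_curvature=0.0,
        dead_penalty=70.0,
        cliff_fraction=0.0,
        tpsa_gamma=0.0,
        dmax=75.0,
        noise_sd=15.0,
    )


# ---------------------------------------------------------------------------
# Block generation and assembly
# ---------------------------------------------------------------------------

def _ether_smiles(n_carbon: int) -> str:
    # PEG-like chain: pairs of carbons separated by ether oxygens
    units, rem = divmod(n_carbon - 2, 2)
    body = "CC" + "OCC" * units + "C" * rem
    return f"[*:1]{body}[*:2]"


def generate_building_blocks(config: GeneratorConfig) -> BlockLibrary:
    """The block library the generator assembles compounds from."""
    warheads = []
    for name, (smiles, is_dead) in _WARHEADS.items():
        warheads.append(
            Block(
                name=name,
                role="warhead",
                smiles=smiles,
                penalty=config.dead_penalty if is_dead else 0.0,
                is_dead=is_dead,
                parent=_DEAD_PARENT.get(name, ""),
            )
        )
    e3s = []
    for e3_class, variants in _E3_VARIANTS.items():
        for variant, smiles in enumerate(variants):
            e3s.append(
                Block(
                    name=f"{e3_class}_v{variant}",
                    role="e3_ligand",
                    smiles=smiles,
                    e3_class=e3_class,
                    variant=variant,
                )
            )
    linkers = []
    lo, hi = config.linker_length_range
    for length in range(lo, hi + 1):
        linkers.append(
            Block(
                name=f"alkyl{length}",
                role="linker",
                smiles="[*:1]" + "C" * length + "[*:2]",
                n_carbon=length,
                linker_class="alkyl",
            )
        )
    for length in range(max(4, lo), min(hi, 6) + 1, 2):
        linkers.append(
            Block(
                name=f"ether{length}",
                role="linker",
                smiles=_ether_smiles(length),
                n_carbon=length,
                linker_class="ether",
            )
        )
    for name, smiles in _RIGID_LINKERS:
        mol = Chem.MolFromSmiles(smiles)
        n_c = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
        linkers.append(
            Block(
                name=name,
                role="linker",
                smiles=smiles,
                n_carbon=n_c,
                linker_class="rigid",
            )
        )
    return BlockLibrary(
        warheads=tuple(warheads), e3_ligands=tuple(e3s), linkers=tuple(linkers)
    )


class AssemblyError(ValueError):
    """The blocks cannot be joined into a valid molecule."""


def _tag_parts(smiles: str, part: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise AssemblyError(f"unparsable block SMILES {smiles!r}")
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 0:
            atom.SetProp("part", part)
    return mol


def _join_map(mol: Chem.RWMol, map_number: int) -> None:
    dummies = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == map_number
    ]
    if len(dummies) != 2:
        raise AssemblyError(f"attachment point *:{map_number} must occur exactly twice")
    nbrs = [mol.GetAtomWithIdx(d).GetNeighbors()[0].GetIdx() for d in dummies]
    mol.AddBond(nbrs[0], nbrs[1], Chem.BondType.SINGLE)
    for d in sorted(dummies, reverse=True):
        mol.RemoveAtom(d)


def assemble_protac_smiles(
    warhead: Block, linker: Block, e3: Block
) -> tuple[str, dict[str, tuple[int, ...]]]:
    """Join the three blocks into one molecule.

    Returns the canonical SMILES and the atom map: for each part (warhead,
    linker, e3) the atom indices *in the canonical SMILES atom order*, i.e.
    valid for the molecule obtained by re-parsing the returned SMILES.
    """
    w = _tag_parts(warhead.smiles, "warhead")
    l = _tag_parts(linker.smiles, "linker")
    e = _tag_parts(e3.smiles, "e3")
    combo = Chem.RWMol(Chem.CombineMols(Chem.CombineMols(w, l), e))
    _join_map(combo, 1)
    _join_map(combo, 2)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # noqa: BLE001 - surface as a domain error
        raise AssemblyError(f"valence violation joining blocks: {exc}") from exc
    smiles = Chem.MolToSmiles(mol)
    order = list(
        map(int, mol.GetProp("_smilesAtomOutputOrder").strip("[]").split(","))
    )
    atom_map: dict[str, list[int]] = {"warhead": [], "linker": [], "e3": []}
    for out_pos, orig_idx in enumerate(order):
        atom_map[mol.GetAtomWithIdx(orig_idx).GetProp("part")].append(out_pos)
    return smiles, {part: tuple(sorted(v)) for part, v in atom_map.items()}


def default_anchor_library(library: BlockLibrary | None = None) -> list[AnchorPattern]:
    """Anchor SMARTS for the generator's warhead and E3 building blocks."""
    if library is None:
        library = generate_building_blocks(GeneratorConfig(seed=0))
    patterns = []
    for block in library.warheads + library.e3_ligands:
        core = Chem.RWMol(Chem.MolFromSmiles(block.smiles))
        dummies = sorted(
            (a.GetIdx() for a in core.GetAtoms() if a.GetAtomicNum() == 0),
            reverse=True,
        )
        for d in dummies:
            core.RemoveAtom(d)
        mol = core.GetMol()
        Chem.SanitizeMol(mol)
        role = "warhead" if block.role == "warhead" else "e3_ligand"
        patterns.append(
            AnchorPattern(name=block.name, role=role, smarts=Chem.MolToSmarts(mol))
        )
    return patterns


# ---------------------------------------------------------------------------
# Activity model
# ---------------------------------------------------------------------------

def simulate_degradation(
    features: Mapping[str, float],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw the two degradation readouts for one compound.

    features must provide: n_carbon, l_star, warhead_penalty, tpsa, and
    rigid (0/1).
    """
    curvature = config.rigid_curvature if features.get("rigid") else config.curvature
    deg_low = (
        config.dmax
        - curvature * (features["n_carbon"] - features["l_star"]) ** 2
        - features["warhead_penalty"]
        - config.tpsa_gamma * max(0.0, features["tpsa"] - config.tpsa_tau)
        + rng.normal(0.0, config.noise_sd)
    )
    deg_low = float(np.clip(deg_low, 0.0, 100.0))
    deg_high = (
        deg_low
        + config.concentration_gain * (100.0 - deg_low) / 100.0
        + rng.normal(0.0, config.noise_sd)
    )
    return deg_low, float(np.clip(deg_high, 0.0, 100.0))


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Planted truth emitted alongside a synthetic dataset."""

    blocks: Mapping[str, tuple[str, str, str]]        # id -> (warhead, linker, e3)
    atom_maps: Mapping[str, Mapping[str, tuple[int, ...]]]
    cliff_pairs: tuple[tuple[str, str], ...]          # (parent id, dead id)
    l_star: Mapping[str, int]
    signal_descriptors: tuple[str, ...]
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "blocks": {k: list(v) for k, v in self.blocks.items()},
            "atom_maps": {
                k: {part: list(v) for part, v in parts.items()}
                for k, parts in self.atom_maps.items()
            },
            "cliff_pairs": [list(p) for p in self.cliff_pairs],
            "l_star": dict(self.l_star),
            "signal_descriptors": list(self.signal_descriptors),
            "config": {
                key: (dict(value) if isinstance(value, Mapping) else value)
                for key, value in asdict(self.config).items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _alkyl_name(length: int) -> str:
    return f"alkyl{length}"


def generate_ldr_series(
    config: GeneratorConfig,
    e3_class: str,
    n_per_length: int = 3,
    lengths: Sequence[int] | None = None,
) -> list[DegradationRecord]:
    """A controlled matched series for linker-length analysis.

    All compounds share the parent warhead and the undecorated E3 ligand and
    differ only in alkyl linker length; lengths default to the class optimum
    +/- 4 carbons (clipped to the configured range), sampled n_per_length
    times each so the series carries enough replication to average out the
    readout noise.
    """
    rng = np.random.default_rng(config.seed)
    library = generate_building_blocks(config)
    lo, hi = config.linker_length_range
    l_star = config.l_star[e3_class]
    if lengths is None:
        lengths = [
            length
            for length in range(max(lo, l_star - 4), min(hi, l_star + 4) + 1)
        ]
    e3 = library.e3(e3_class, 0)
    warhead = library.warhead("W1")
    records = []
    counter = 0
    for length in lengths:
        linker = library.linker(_alkyl_name(int(length)))
        smiles, _ = assemble_protac_smiles(warhead, linker, e3)
        mol = Chem.MolFromSmiles(smiles)
        features = {
            "n_carbon": linker.n_carbon,
            "l_star": l_star,
            "warhead_penalty": 0.0,
            "tpsa": _tpsa(mol),
            "rigid": 0.0,
        }
        for _ in range(n_per_length):
            counter += 1
            deg_low, deg_high = simulate_degradation(features, config, rng)
            records.append(
                DegradationRecord(
                    id=f"s{counter:03d}",
                    smiles=smiles,
                    e3_class=e3_class,
                    deg_low=round(deg_low, 1),
                    deg_high=round(deg_high, 1),
                    cell_line="synthetic",
                    source="ldr_series",
                )
            )
    return records


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[DegradationRecord], GroundTruth]:
    """Generate n records plus the planted ground truth, reproducibly.

    Planted cliff pairs are (parent, dead-twin) couples sharing the linker
    and an undecorated E3 ligand, with the parent at the optimal linker
    length; the remaining compounds draw blocks at random.
    """
    rng = np.random.default_rng(config.seed)
    library = generate_building_blocks(config)
    lo, hi = config.linker_length_range
    n_dead = int(round(config.cliff_fraction * config.n))
    n_random = config.n - 2 * n_dead
    if n_random < 0:
        raise ValueError("cliff_fraction too large for n")

    cliff_pairs: list[tuple[str, str]] = []
    compound_no = 0

    def next_id() -> str:
        nonlocal compound_no
        compound_no += 1
        return f"c{compound_no:03d}"

    rows = []
    for _ in range(n_dead):
        e3_class = "VHL" if rng.random() < config.vhl_fraction else "CRBN"
        l_star = config.l_star[e3_class]
        linker_name = _alkyl_name(int(np.clip(l_star, lo, hi)))
        parent_id, dead_id = next_id(), next_id()
        rows.append((parent_id, "W1", linker_name, e3_class, 0))
        rows.append((dead_id, PLANTED_DEAD_WARHEAD, linker_name, e3_class, 0))
        cliff_pairs.append((parent_id, dead_id))
    for _ in range(n_random):
        e3_class = "VHL" if rng.random() < config.vhl_fraction else "CRBN"
        warhead = "W1" if rng.random() < 0.6 else "W2"
        variant = int(rng.integers(0, 4))
        u = rng.random()
        # lengths are explored around each class's optimum, as a linker
        # optimization campaign would
        l_lo = max(lo, config.l_star[e3_class] - 4)
        l_hi = min(hi, config.l_star[e3_class] + 4)
        if u < 0.5:
            linker_name = _alkyl_name(int(rng.integers(l_lo, l_hi + 1)))
        elif u < 0.8:
            ether_lengths = [b.n_carbon for b in library.linkers if b.linker_class == "ether"]
            linker_name = f"ether{ether_lengths[int(rng.integers(0, len(ether_lengths)))]}"
        else:
            rigid = [b for b in library.linkers if b.linker_class == "rigid"]
            linker_name = rigid[int(rng.integers(0, len(rigid)))].name

        rows.append((next_id(), warhead, linker_name, e3_class, variant))

    records: list[DegradationRecord] = []
    blocks: dict[str, tuple[str, str, str]] = {}
    atom_maps: dict[str, dict[str, tuple[int, ...]]] = {}
    for cid, warhead_name, linker_name, e3_class, variant in rows:
        warhead = library.warhead(warhead_name)
        linker = library.linker(linker_name)
        e3 = library.e3(e3_class, variant)
        smiles, atom_map = assemble_protac_smiles(warhead, linker, e3)
        mol = Chem.MolFromSmiles(smiles)
        features = {
            "n_carbon": linker.n_carbon,
            "l_star": config.l_star[e3_class],
            "warhead_penalty": warhead.penalty,
            "tpsa": _tpsa(mol),
            "rigid": 1.0 if linker.linker_class == "rigid" else 0.0,
        }
        deg_low, deg_high = simulate_degradation(features, config, rng)
        records.append(
            DegradationRecord(
                id=cid,
                smiles=smiles,
                e3_class=e3_class,
                deg_low=round(deg_low, 1),
                deg_high=round(deg_high, 1),
                cell_line="synthetic",
                source="generator",
            )
        )
        blocks[cid] = (warhead.name, linker.name, e3.name)
        atom_maps[cid] = atom_map
    truth = GroundTruth(
        blocks=blocks,
        atom_maps=atom_maps,
        cliff_pairs=tuple(cliff_pairs),
        l_star=dict(config.l_star),
        signal_descriptors=("TPSA", "nHAcc"),
        config=config,
    )
    return records, truth
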