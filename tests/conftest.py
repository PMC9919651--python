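"""Shared fixtures: small molecule sets and synthetic datasets."""

from __future__ import annotations

import pytest
from rdkit import Chem

from protacsar import GeneratorConfig, generate_dataset

# a structurally varied panel of small molecules for oracle comparisons
SMALL_MOLECULES = {
    "toluene": "Cc1ccccc1",
    "ethylbenzene": "CCc1ccccc1",
    "phenol": "Oc1ccccc1",
    "anisole": "COc1ccccc1",
    "pyridine": "c1ccncc1",
    "benzamide": "NC(=O)c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "methylnaphthalene": "Cc1cccc2ccccc12",
    "cyclohexane": "C1CCCCC1",
    "hexane": "CCCCCC",
    "ethanol": "CCO",
    "dimethyl_ether": "COC",
}


@pytest.fixture(scope="session")
def small_mols() -> dict[str, Chem.Mol]:
    return {name: Chem.MolFromSmiles(smi) for name, smi in SMALL_MOLECULES.items()}


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared across tests."""
    config = GeneratorConfig(seed=42)
    records, truth = generate_dataset(config)
    return config, records, truth


@pytest.fixture(scope="session")
def default_mols(default_dataset):
    _, records, _ = default_dataset
    return {r.id: Chem.MolFromSmiles(r.smiles) for r in records}
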