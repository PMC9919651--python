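"""Tripartite decomposition, linker metrics and LDR parabola fits."""

import numpy as np
import pytest
from rdkit import Chem

from protacsar import (
    AnchorPattern,
    GeneratorConfig,
    NoAnchorMatch,
    decompose_protac,
    default_anchor_library,
    fit_linker_parabola,
    generate_building_blocks,
    linker_metrics,
    load_anchor_library,
    select_matched_series,
)
from protacsar.decomposition import write_anchor_library
from protacsar.frameworks import mol_from_smiles
from protacsar.simulate import generate_dataset


@pytest.fixture(scope="module")
def anchors():
    return default_anchor_library()


class TestDecompose:
    def test_recovers_generator_ground_truth(self, default_dataset, default_mols, anchors):
        """Anchor matching reproduces the generator's exact atom partition."""
        _, records, truth = default_dataset
        for rec in records[:60]:
            decomp = decompose_protac(default_mols[rec.id], anchors)
            expected = truth.atom_maps[rec.id]
            assert set(decomp.warhead_atoms) == set(expected["warhead"])
            assert set(decomp.linker_atoms) == set(expected["linker"])
            assert set(decomp.e3_atoms) == set(expected["e3"])

    def test_partition_covers_all_heavy_atoms(self, default_dataset, default_mols, anchors):
        _, records, _ = default_dataset
        for rec in records[:30]:
            mol = default_mols[rec.id]
            d = decompose_protac(mol, anchors)
            union = d.warhead_atoms | d.linker_atoms | d.e3_atoms
            assert union == set(range(mol.GetNumAtoms()))
            assert not (d.warhead_atoms & d.e3_atoms)
            assert len(d.attachment_bonds) == 2

    def test_missing_anchor_names_the_role(self, anchors):
        mol = mol_from_smiles("c1ccccc1CCCCC1CCCCC1")  # matches nothing
        with pytest.raises(NoAnchorMatch, match="warhead"):
            decompose_protac(mol, anchors)

    def test_largest_match_tie_break(self):
        """With nested same-role patterns the larger match wins."""
        mol = mol_from_smiles("Nc1ccc(CCCCCC2CCOC2)cc1")
        anchors = [
            AnchorPattern("small", "warhead", "c1ccccc1"),
            AnchorPattern("large", "warhead", "Nc1ccccc1"),
            AnchorPattern("thf", "e3_ligand", "C1CCOC1"),
        ]
        decomp = decompose_protac(mol, anchors)
        assert decomp.warhead_name == "large"
        assert len(decomp.warhead_atoms) == 7

    def test_anchor_library_roundtrip(self, tmp_path, anchors):
        path = tmp_path / "anchors.csv"
        write_anchor_library(anchors, path)
        loaded = load_anchor_library(path)
        assert [(a.name, a.role, a.smarts) for a in loaded] == [
            (a.name, a.role, a.smarts) for a in anchors
        ]

    def test_invariant_to_atom_reindexing(self, anchors):
        config = GeneratorConfig(seed=5, n=4, cliff_fraction=0.0)
        records, _ = generate_dataset(config)
        for rec in records:
            mol = mol_from_smiles(rec.smiles)
            renum = Chem.RenumberAtoms(mol, list(reversed(range(mol.GetNumAtoms()))))
            p1 = linker_metrics(decompose_protac(mol, anchors), mol)
            p2 = linker_metrics(decompose_protac(renum, anchors), renum)
            assert p1 == p2


class TestLinkerMetrics:
    @pytest.mark.parametrize(
        "linker_name,n_carbon,cls",
        [("alkyl6", 6, "alkyl"), ("ether6", 6, "ether"), ("rigid_pip_ph", 12, "rigid")],
    )
    def test_linker_class_and_carbon_count(self, anchors, linker_name, n_carbon, cls):
        from protacsar.simulate import assemble_protac_smiles

        library = generate_building_blocks(GeneratorConfig(seed=0))
        smiles, _ = assemble_protac_smiles(
            library.warhead("W1"), library.linker(linker_name), library.e3("VHL", 0)
        )
        mol = mol_from_smiles(smiles)
        profile = linker_metrics(decompose_protac(mol, anchors), mol)
        assert profile.n_carbon == n_carbon
        assert profile.linker_class == cls
        assert profile.topo_length >= 1


class TestMatchedSeries:
    def test_series_grouped_by_blocks_and_class(self, anchors):
        from protacsar.simulate import generate_ldr_series

        config = GeneratorConfig(seed=11)
        records = generate_ldr_series(config, "VHL", n_per_length=1)
        mols = {r.id: mol_from_smiles(r.smiles) for r in records}
        decomps = {r.id: decompose_protac(mols[r.id], anchors) for r in records}
        series = select_matched_series(records, decomps, mols)
        assert len(series) == 1
        assert len(series[0].ids) == len(records)

    def test_small_groups_discarded(self, anchors):
        from protacsar.simulate import generate_ldr_series

        config = GeneratorConfig(seed=11)
        records = generate_ldr_series(config, "VHL", n_per_length=1, lengths=[8, 9, 10])
        mols = {r.id: mol_from_smiles(r.smiles) for r in records}
        decomps = {r.id: decompose_protac(mols[r.id], anchors) for r in records}
        assert select_matched_series(records, decomps, mols) == []


class TestParabolaFit:
    def test_noiseless_recovery(self):
        points = [(L, 90 - 2 * (L - 8) ** 2) for L in range(5, 12)]
        fit = fit_linker_parabola(points)
        assert fit.vertex == pytest.approx(8.0)
        assert fit.curvature == pytest.approx(-2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert not fit.degenerate

    def test_noisy_recovery_within_one_carbon(self):
        rng = np.random.default_rng(4)
        points = [
            (L, 90 - 2 * (L - 8) ** 2 + rng.normal(0, 3))
            for L in range(5, 12)
            for _ in range(5)
        ]
        fit = fit_linker_parabola(points)
        assert abs(fit.vertex - 8.0) <= 1.0

    def test_collinear_degenerate(self):
        fit = fit_linker_parabola([(L, 2 * L + 1) for L in range(4, 10)])
        assert fit.degenerate

    def test_too_few_distinct_lengths(self):
        with pytest.raises(ValueError):
            fit_linker_parabola([(1, 5), (2, 6), (3, 5), (3, 5.5)])

    def test_class_specific_optima_ordered(self):
        """CRBN optima sit at shorter linkers than VHL in most replicates."""
        from protacsar.simulate import generate_ldr_series

        ordered = 0
        n_rep = 10
        for seed in range(n_rep):
            config = GeneratorConfig(seed=900 + seed)
            vertices = {}
            for cls in ("CRBN", "VHL"):
                records = generate_ldr_series(config, cls, n_per_length=3)
                lengths = sorted({r.smiles: None for r in records})
                pts = _series_points(records, config, cls)
                vertices[cls] = fit_linker_parabola(pts).vertex
            ordered += vertices["CRBN"] < vertices["VHL"]
        assert ordered >= 0.9 * n_rep


def _series_points(records, config, cls):
    """(linker carbon count, degradation) pairs, lengths recovered by size."""
    by_smiles = {}
    for r in records:
        by_smiles.setdefault(r.smiles, []).append(r.deg_low)
    sizes = sorted(
        (Chem.MolFromSmiles(s).GetNumHeavyAtoms(), s) for s in by_smiles
    )
    lo, hi = config.linker_length_range
    l_star = config.l_star[cls]
    lengths = list(range(max(lo, l_star - 4), min(hi, l_star + 4) + 1))
    return [(L, v) for L, (_, s) in zip(lengths, sizes) for v in by_smiles[s]]
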