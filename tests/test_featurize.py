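"""Graph construction, atomic/global features, and descriptor tables."""

import numpy as np
import pytest
from rdkit import Chem

import semiquant as sq
from semiquant.errors import SchemaError, SmilesParseError
from semiquant.featurize import (
    N_NODE_FEATURES,
    shape_from_coords,
    write_descriptor_table,
)


class TestSmilesToGraph:
    @pytest.mark.parametrize(
        "smiles,n_nodes,edges",
        [
            ("C", 1, []),
            ("CCO", 3, [(0, 1), (1, 2)]),
            ("c1ccccc1", 6, [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (4, 5)]),
        ],
    )
    def test_topology(self, smiles, n_nodes, edges):
        g = sq.smiles_to_graph(smiles)
        assert g.n_nodes == n_nodes
        assert g.edges == edges

    def test_parse_error_names_string(self):
        with pytest.raises(SmilesParseError, match="not_a_smiles"):
            sq.smiles_to_graph("not_a_smiles")

    def test_explicit_hydrogens_normalized(self):
        g = sq.smiles_to_graph("[H]C([H])([H])[H]")
        assert g.n_nodes == 1 and g.edges == []

    def test_disconnected_keeps_largest_fragment(self):
        g = sq.smiles_to_graph("CCO.[Na]")
        assert g.n_nodes == 3

    def test_canonical_and_noncanonical_graphs_isomorphic(self):
        import networkx as nx

        for smi in ["OCC", "c1ccc(O)cc1", "CC(C)N"]:
            canon = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
            g1, g2 = sq.smiles_to_graph(smi), sq.smiles_to_graph(canon)
            assert g1.n_nodes == g2.n_nodes
            assert sorted(g1.degrees()) == sorted(g2.degrees())
            assert nx.is_isomorphic(nx.Graph(g1.edges), nx.Graph(g2.edges)) or g1.n_nodes == 1


class TestAtomFeatures:
    def test_ethanol_oxygen_row(self):
        g = sq.atom_features(sq.smiles_to_graph("CCO"))
        o = g.node_features[2]
        assert o[0] == 8  # atomic number
        assert o[1] == 1  # one hydrogen
        assert o[4] == 0  # formal charge
        assert o[6] == 1  # heavy-atom degree
        assert o[7] == 0 and o[8] == 0  # not in ring, not aromatic

    def test_benzene_ring_flags(self):
        g = sq.atom_features(sq.smiles_to_graph("c1ccccc1"))
        assert np.all(g.node_features[:, 7] == 1)
        assert np.all(g.node_features[:, 8] == 1)
        assert np.all(g.node_features[:, 6] == 2)

    def test_degree_column_matches_edge_list(self, graphs40):
        for g in graphs40:
            np.testing.assert_array_equal(g.node_features[:, 6], g.degrees())

    def test_scaled_columns_in_unit_interval(self, graphs40):
        for g in graphs40:
            scaled = g.node_features[:, 9:12]
            assert np.all(scaled > 0) and np.all(scaled <= 1)


class TestGlobalShape:
    def test_single_heavy_atom(self):
        shape = sq.global_shape("C", conformer_seed=1)
        assert shape.length == shape.width == shape.height == 0.0
        assert shape.volume > 0

    def test_deterministic_for_fixed_seed(self):
        a = sq.global_shape("CC(C)CO", conformer_seed=4)
        b = sq.global_shape("CC(C)CO", conformer_seed=4)
        assert a.as_tuple() == b.as_tuple()

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(8, 3)) * 2.0
        radii = np.full(8, 1.7)
        base = shape_from_coords(coords, radii)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + np.array([5.0, -3.0, 1.0])
        rotated = shape_from_coords(moved, radii)
        assert rotated.volume == pytest.approx(base.volume, abs=1e-6)
        assert rotated.length == pytest.approx(base.length, abs=1e-6)
        assert rotated.width == pytest.approx(base.width, abs=1e-6)
        assert rotated.height == pytest.approx(base.height, abs=1e-6)

    def test_alkane_length_strictly_increasing(self):
        lengths = [sq.global_shape("C" * k, conformer_seed=2).length for k in range(2, 11)]
        assert np.all(np.diff(lengths) > 0)


class TestAssembleNodeMatrix:
    def test_global_columns_constant_within_molecule(self, graphs40):
        for g in graphs40:
            assert g.node_features.shape[1] == N_NODE_FEATURES
            assert np.all(np.ptp(g.node_features[:, 12:], axis=0) == 0)

    def test_rows_differ_only_in_local_columns(self):
        g = sq.featurize_smiles("CCO")
        assert np.ptp(g.node_features[:, 12:], axis=0).max() == 0
        assert np.ptp(g.node_features[:, :12], axis=0).max() > 0

    def test_json_round_trip(self, tmp_path, graphs40):
        from semiquant.featurize import graphs_from_json, graphs_to_json

        path = tmp_path / "graphs.json"
        graphs_to_json(graphs40[:5], path)
        loaded = graphs_from_json(path)
        for a, b in zip(graphs40[:5], loaded):
            assert a.edges == b.edges
            np.testing.assert_allclose(a.node_features, b.node_features)
            assert a.node_order == b.node_order


class TestDescriptorTable:
    def _write(self, tmp_path, text):
        p = tmp_path / "desc.csv"
        p.write_text(text)
        return p

    def test_small_table_round_trip(self, tmp_path):
        table = sq.DescriptorTable(
            ["a", "b", "c"], ["d1", "d2", "d3", "d4", "d5"], np.arange(15.0).reshape(3, 5)
        )
        path = tmp_path / "out.csv"
        write_descriptor_table(table, path)
        loaded = sq.load_descriptor_table(path)
        assert loaded.molecule_ids == table.molecule_ids
        assert loaded.descriptor_names == table.descriptor_names
        np.testing.assert_allclose(loaded.values, table.values)

    def test_na_cell_imputed_and_flagged(self, tmp_path):
        path = self._write(tmp_path, "Name,x,y\na,1.0,2.0\nb,,4.0\nc,3.0,6.0\n")
        table = sq.load_descriptor_table(path)
        assert ("b", "x") in table.imputed_cells
        assert table.values[1, 0] == pytest.approx(2.0)  # column median of {1, 3}

    def test_duplicate_ids_rejected(self, tmp_path):
        path = self._write(tmp_path, "Name,x\na,1\na,2\n")
        with pytest.raises(SchemaError, match="duplicate"):
            sq.load_descriptor_table(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = self._write(tmp_path, "Name,x\na,1\nb,oops\n")
        with pytest.raises(SchemaError, match="oops"):
            sq.load_descriptor_table(path)

    def test_constant_columns_flagged(self, tmp_path):
        path = self._write(tmp_path, "Name,x,y\na,1,2\nb,1,3\n")
        assert sq.load_descriptor_table(path).constant_columns == ["x"]


class TestSelectMainFeatures:
    def test_k_equal_to_descriptor_count_returns_all(self, counts40, targets40):
        names = sq.select_main_features(counts40, targets40, k=len(counts40.descriptor_names), seed=0)
        assert sorted(names) == sorted(counts40.descriptor_names)

    def test_planted_signal_ranked_high(self):
        rng = np.random.default_rng(0)
        n = 120
        X = rng.normal(size=(n, 52))
        y = 3 * X[:, 0] - 2 * X[:, 1] + rng.normal(0, 0.1, n)
        names = [f"x{j:02d}" for j in range(52)]
        table = sq.DescriptorTable([f"m{i}" for i in range(n)], names, X)
        top5 = sq.select_main_features(table, y, k=5, seed=1)
        assert "x00" in top5 and "x01" in top5

    def test_deterministic(self, counts40, targets40):
        a = sq.select_main_features(counts40, targets40, k=4, seed=3)
        b = sq.select_main_features(counts40, targets40, k=4, seed=3)
        assert a == b

    def test_k_too_large_rejected(self, counts40, targets40):
        with pytest.raises(ValueError):
            sq.select_main_features(counts40, targets40, k=99, seed=0)

    def test_pure_noise_importance_near_uniform(self):
        # no descriptor should dominate when targets carry no signal
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 25))
        table = sq.DescriptorTable([f"m{i}" for i in range(60)], [f"x{j}" for j in range(25)], X)
        from semiquant.baselines import BaselineConfig, make_estimator

        total = np.zeros(25)
        n_seeds = 20
        for seed in range(n_seeds):
            y = rng.normal(size=60)
            est = make_estimator(BaselineConfig(model="random_forest", n_estimators=100, seed=seed))
            est.fit(table.values, y)
            total += est.feature_importances_
        mean_imp = total / n_seeds
        assert mean_imp.max() < 5 * mean_imp.mean()
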