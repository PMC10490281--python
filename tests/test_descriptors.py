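"""Descriptor families checked against brute-force and hand-derived oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from qsarwb.descriptors import (
    Atom,
    Conformer,
    MolecularGraph,
    assign_ppp,
    ats,
    atom_pair_freq,
    barysz_balaban,
    cats2d,
    compute_table1_descriptors,
    edge_spectral_moment,
    rdf,
    topo_distances,
)
from qsarwb.exceptions import ConfigError, DisconnectedGraphError, DomainError

# a small pool of real molecules for oracle-equivalence sweeps
MOLECULES = [
    "CCO",
    "CC(=O)O",
    "c1ccccc1O",
    "CCN(CC)CC",
    "CC(=O)Nc1ccccc1",
    "OCCCCCO",
    "NCCCCCCCCO",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",  # ibuprofen
    "c1ccc2[nH]ccc2c1",            # indole
    "CS(=O)(=O)N",                 # methanesulfonamide
    "Clc1ccccc1CN",
    "O=C(O)c1ccccc1O",             # salicylic acid
]


def nx_graph(graph: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in graph.bonds)
    return g


def random_tree(rng, n, elements=("C", "N", "O")) -> MolecularGraph:
    atoms = [Atom(str(rng.choice(elements))) for _ in range(n)]
    bonds = [(int(rng.integers(0, i)), i, 1.0) for i in range(1, n)]
    return MolecularGraph(atoms=atoms, bonds=bonds)


class TestTopoDistances:
    def test_three_atom_chain(self):
        g = MolecularGraph(atoms=[Atom("C")] * 3, bonds=[(0, 1, 1.0), (1, 2, 1.0)])
        D = topo_distances(g)
        assert D[0, 2] == 2 and D[2, 0] == 2

    def test_six_ring_diameter(self):
        g = MolecularGraph.from_smiles("C1CCCCC1")
        D = topo_distances(g)
        oracle = dict(nx.all_pairs_shortest_path_length(nx_graph(g)))
        for i in range(6):
            for j in range(6):
                assert D[i, j] == oracle[i][j]
        assert D.max() == 3

    def test_single_atom(self):
        g = MolecularGraph(atoms=[Atom("C", n_h=4)], bonds=[])
        assert topo_distances(g).shape == (1, 1)
        assert topo_distances(g)[0, 0] == 0

    def test_disconnected_names_fragments(self):
        g = MolecularGraph(atoms=[Atom("C")] * 4, bonds=[(0, 1, 1.0), (2, 3, 1.0)])
        with pytest.raises(DisconnectedGraphError) as err:
            topo_distances(g)
        assert err.value.fragments == [[0, 1], [2, 3]]


class TestATS:
    def test_lag_beyond_diameter_is_zero(self):
        g = MolecularGraph.from_smiles("CCO")
        assert ats(g, 5, "mass") == 0.0

    def test_ethanol_hand_value(self):
        g = MolecularGraph.from_smiles("CCO")
        w_o = 15.999 / 12.011
        assert ats(g, 1, "mass") == pytest.approx(math.log1p(1.0 + w_o), abs=1e-12)
        assert round(ats(g, 1, "mass"), 4) == 1.2036

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(4):
            g = random_tree(rng, int(rng.integers(4, 12)))
            lengths = dict(nx.all_pairs_shortest_path_length(nx_graph(g)))
            w = g.weights("mass")
            for lag in (1, 2, 3):
                total = sum(
                    w[i] * w[j]
                    for i in range(g.n_atoms)
                    for j in range(i + 1, g.n_atoms)
                    if lengths[i][j] == lag
                )
                assert ats(g, lag, "mass") == pytest.approx(math.log1p(total), abs=1e-10)

    def test_nonnegative_and_zero_only_for_empty_sum(self):
        g = MolecularGraph.from_smiles("CC")
        assert ats(g, 1, "mass") > 0
        assert ats(g, 2, "mass") == 0.0

    def test_unknown_weight_rejected(self):
        with pytest.raises(ConfigError):
            ats(MolecularGraph.from_smiles("CC"), 1, "charisma")


def classic_balaban_j(graph: MolecularGraph) -> float:
    """Direct Balaban J from the plain topological distance matrix."""
    D = np.asarray(
        nx.floyd_warshall_numpy(nx_graph(graph)), dtype=float
    )
    s = D.sum(axis=1)
    m = graph.n_bonds
    mu = m - graph.n_atoms + 1
    return m / (mu + 1) * sum(1.0 / math.sqrt(s[i] * s[j]) for i, j, _ in graph.bonds)


class TestBaryszBalaban:
    def test_ethane_closed_form(self):
        g = MolecularGraph.from_smiles("CC")
        for w in ("mass", "polarizability", "vdw_volume"):
            assert barysz_balaban(g, w) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_all_carbon_path_reduces_to_classic_j(self, n):
        g = MolecularGraph(
            atoms=[Atom("C")] * n, bonds=[(i, i + 1, 1.0) for i in range(n - 1)]
        )
        assert barysz_balaban(g, "mass") == pytest.approx(classic_balaban_j(g), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        g = random_tree(rng, 9)
        perm = rng.permutation(9)
        assert barysz_balaban(g.permuted(perm), "polarizability") == pytest.approx(
            barysz_balaban(g, "polarizability"), rel=1e-10
        )

    def test_trivial_graph_rejected(self):
        with pytest.raises(DomainError):
            barysz_balaban(MolecularGraph(atoms=[Atom("C", n_h=4)], bonds=[]), "mass")


class TestCATS2D:
    def test_alkane_has_no_acceptor_pairs(self):
        g = MolecularGraph.from_smiles("CCCCCC")
        for lag in range(10):
            assert cats2d(g, lag, ("A", "A")) == 0

    def test_diol_single_pair_at_lag_six(self):
        g = MolecularGraph.from_smiles("OCCCCCO")
        assert cats2d(g, 6, ("A", "A")) == 1
        assert cats2d(g, 5, ("A", "A")) == 0

    @pytest.mark.parametrize("smiles", MOLECULES)
    def test_brute_force_equivalence(self, smiles):
        g = MolecularGraph.from_smiles(smiles)
        labels = assign_ppp(g)
        lengths = dict(nx.all_pairs_shortest_path_length(nx_graph(g)))
        for lag in (1, 3, 5, 7):
            for pair in (("A", "A"), ("A", "D"), ("N", "L"), ("D", "L")):
                t1, t2 = pair
                expected = sum(
                    1
                    for i in range(g.n_atoms)
                    for j in range(i + 1, g.n_atoms)
                    if lengths[i].get(j) == lag
                    and (
                        (t1 in labels[i] and t2 in labels[j])
                        or (t2 in labels[i] and t1 in labels[j])
                    )
                )
                assert cats2d(g, lag, pair) == expected

    def test_pair_budget_invariant(self):
        """Summed A-A counts over all lags can't exceed C(n_A, 2)."""
        for smiles in MOLECULES:
            g = MolecularGraph.from_smiles(smiles)
            n_a = sum("A" in s for s in assign_ppp(g))
            total = sum(cats2d(g, lag, ("A", "A")) for lag in range(10))
            assert total <= n_a * (n_a - 1) // 2

    def test_invalid_type_code(self):
        with pytest.raises(ConfigError):
            cats2d(MolecularGraph.from_smiles("CC"), 1, ("A", "Z"))


class TestAtomPairFreq:
    def test_no_nitrogen_gives_zero(self):
        g = MolecularGraph.from_smiles("OCCCCCO")
        assert atom_pair_freq(g, "N", "O", 9) == 0

    def test_nine_bond_chain(self):
        g = MolecularGraph.from_smiles("NCCCCCCCCO")
        assert atom_pair_freq(g, "N", "O", 9) == 1

    @pytest.mark.parametrize("smiles", MOLECULES[:6])
    def test_argument_symmetry(self, smiles):
        g = MolecularGraph.from_smiles(smiles)
        for d in (1, 2, 3):
            assert atom_pair_freq(g, "N", "O", d) == atom_pair_freq(g, "O", "N", d)


class TestEdgeSpectralMoment:
    def test_single_bond_closed_form(self):
        g = MolecularGraph(atoms=[Atom("C"), Atom("O")], bonds=[(0, 1, 1.0)])
        for k in (1, 3, 14):
            assert edge_spectral_moment(g, k, {"C-O:1": 0.74}) == pytest.approx(
                math.log1p(0.74**k), rel=1e-12
            )

    def test_three_bond_chain_order_two(self):
        g = MolecularGraph(
            atoms=[Atom("C")] * 4, bonds=[(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)]
        )
        assert edge_spectral_moment(g, 2, {"C-C:1": 0.0}) == pytest.approx(
            math.log(5.0), abs=1e-12
        )

    @pytest.mark.parametrize("smiles", ["CC(=O)O", "c1ccccc1O", "CCN(CC)CC"])
    def test_eigenvalue_oracle(self, smiles):
        from qsarwb.descriptors.table1 import bond_dipoles, _dipole_key

        g = MolecularGraph.from_smiles(smiles)
        lookup = bond_dipoles()
        m = g.n_bonds
        B = np.zeros((m, m))
        for e, (i, j, bo) in enumerate(g.bonds):
            B[e, e] = lookup[_dipole_key(g.atoms[i].element, g.atoms[j].element, bo)]
        for e in range(m):
            for f in range(e + 1, m):
                if set(g.bonds[e][:2]) & set(g.bonds[f][:2]):
                    B[e, f] = B[f, e] = 1.0
        lam = np.linalg.eigvalsh(B)
        for k in (2, 5, 14):
            assert edge_spectral_moment(g, k) == pytest.approx(
                math.log1p(float(np.sum(lam**k))), rel=1e-8
            )

    def test_missing_bond_type_is_config_error(self):
        g = MolecularGraph(atoms=[Atom("C"), Atom("Se")], bonds=[(0, 1, 1.0)])
        with pytest.raises(ConfigError, match="C-Se"):
            edge_spectral_moment(g, 2)


class TestRDF:
    probe = MolecularGraph(
        atoms=[Atom("C", n_h=3), Atom("C", n_h=3)], bonds=[(0, 1, 1.0)]
    )

    def test_two_carbons_at_probe_radius(self):
        conf = Conformer(np.array([[0.0, 0.0, 0.0], [14.0, 0.0, 0.0]]))
        assert rdf(conf, self.probe, 14.0, "vdw_volume") == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_decay_bound(self):
        conf = Conformer(np.array([[0.0, 0.0, 0.0], [13.0, 0.0, 0.0]]))
        assert rdf(conf, self.probe, 14.0, "vdw_volume", beta=100.0) < 1e-40

    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        g = random_tree(rng, n)
        coords = rng.uniform(-5, 5, size=(n, 3))
        w = g.weights("vdw_volume")
        R, beta = 3.0, 100.0
        expected = sum(
            w[i] * w[j] * math.exp(-beta * (R - np.linalg.norm(coords[i] - coords[j])) ** 2)
            for i in range(n)
            for j in range(i + 1, n)
        )
        assert rdf(Conformer(coords), g, R, "vdw_volume", beta) == pytest.approx(
            expected, rel=1e-10
        )

    def test_missing_conformer(self):
        with pytest.raises(DomainError, match="3D"):
            rdf(None, self.probe, 14.0, "vdw_volume")


class TestTable1Vector:
    def test_hexane_zero_pharmacophore_terms(self):
        g = MolecularGraph.from_smiles("CCCCCC")
        v = compute_table1_descriptors(g)
        assert v["CATS2D_07_AA"] == 0 and v["CATS2D_05_AA"] == 0
        assert v["CATS2D_03_NL"] == 0 and v["F09[N-O]"] == 0

    def test_schema(self):
        v = compute_table1_descriptors(MolecularGraph.from_smiles("CC(=O)Nc1ccccc1"))
        assert list(v) == [
            "ATS6m",
            "J_Dz(p)",
            "CATS2D_07_AA",
            "CATS2D_03_NL",
            "CATS2D_05_AA",
            "SM14_AEA(dm)",
            "F09[N-O]",
            "RDF140v",
        ]
        assert math.isnan(v["RDF140v"])  # no conformer supplied

    @pytest.mark.parametrize("seed", range(3))
    def test_atom_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        g = MolecularGraph.from_smiles("CC(=O)Nc1ccc(O)cc1")
        perm = rng.permutation(g.n_atoms)
        gp = g.permuted(perm)
        a = compute_table1_descriptors(g)
        b = compute_table1_descriptors(gp)
        for key in a:
            if math.isnan(a[key]):
                assert math.isnan(b[key])
            else:
                assert a[key] == pytest.approx(b[key], rel=1e-9), key
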