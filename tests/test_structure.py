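"""Structure parsing, ligand placement and network construction."""

import numpy as np
import pytest

from allonet.structure import (
    BuildConfig,
    LigationState,
    SpringEdit,
    StructureModel,
    apply_spring_edit,
    build_network,
    place_ligand_nodes,
    read_structure,
)
from allonet.synthetic import ToyDimerConfig, toy_dimer, write_model_pdb

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.500   0.000   0.000  1.00  0.00           C
END
"""

CAMP_GROUP = """\
HETATM    5  C1  CMP A 101       2.000   3.000   0.000  1.00  0.00           C
HETATM    6  O1  CMP A 101       2.500   3.500   0.000  1.00  0.00           O
HETATM    7  P   CMP A 101       3.000   3.000   1.000  1.00  0.00           P
"""


def _write(tmp_path, text, name="mini.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadStructure:
    def test_minimal_fixture_has_three_calpha_nodes(self, tmp_path):
        model = read_structure(_write(tmp_path, MINIMAL_PDB), ligand_names=())
        assert len(model.nodes) == 3
        assert model.ligand_atoms == ()
        chains = {n[0] for n in model.nodes}
        assert chains == {"A"}

    def test_camp_group_collected_as_one_instance(self, tmp_path):
        text = MINIMAL_PDB.replace("END\n", CAMP_GROUP + "END\n")
        model = read_structure(_write(tmp_path, text), ligand_names={"CMP"})
        assert len(model.ligand_instances) == 1
        assert len(model.ligand_atoms) == 3
        elements = sorted(a[1] for a in model.ligand_atoms)
        assert elements == ["C", "O", "P"]

    def test_missing_ligand_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="no ligand"):
            read_structure(_write(tmp_path, MINIMAL_PDB), ligand_names={"CMP"})

    def test_missing_chain_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="chains"):
            read_structure(_write(tmp_path, MINIMAL_PDB), chains=["B"],
                           ligand_names=())

    def test_node_count_matches_record_scan(self, tmp_path):
        """Independent oracle: count CA ATOM records as text."""
        model = toy_dimer(ToyDimerConfig(seed=4))
        path = tmp_path / "toy.pdb"
        write_model_pdb(model, path)
        n_ca = sum(
            1 for line in path.read_text().splitlines()
            if line.startswith("ATOM") and line[12:16].strip() == "CA"
        )
        parsed = read_structure(path, ligand_names={"LIG"})
        assert len(parsed.nodes) == n_ca
        assert len(parsed.ligand_instances) == 2


class TestPlaceLigandNodes:
    def test_mass_weighted_mean(self):
        model = StructureModel(
            (("A", 1, "GLY", np.zeros(3)),),
            (("L1", "C", 12.0, np.array([0.0, 0.0, 0.0])),
             ("L1", "O", 16.0, np.array([1.0, 0.0, 0.0]))),
        )
        [(inst, xyz)] = place_ligand_nodes(model)
        assert inst == "L1"
        np.testing.assert_allclose(xyz, [16.0 / 28.0, 0, 0], rtol=1e-12)

    def test_equal_masses_give_centroid(self):
        coords = np.array([[0.0, 0, 0], [1, 1, 0], [2, 0, 1]])
        model = StructureModel(
            (("A", 1, "GLY", np.zeros(3)),),
            tuple(("L1", "C", 12.0, c) for c in coords),
        )
        [(_, xyz)] = place_ligand_nodes(model)
        np.testing.assert_allclose(xyz, coords.mean(axis=0), rtol=1e-12)

    def test_matches_brute_force_oracle(self, dimer_model):
        placed = dict(place_ligand_nodes(dimer_model))
        for inst in dimer_model.ligand_instances:
            num = np.zeros(3)
            den = 0.0
            for i, el, m, xyz in dimer_model.ligand_atoms:
                if i == inst:
                    num += m * np.asarray(xyz)
                    den += m
            np.testing.assert_allclose(placed[inst], num / den, rtol=1e-12)


def _line_model(xs):
    return StructureModel(
        tuple(("A", i + 1, "GLY", np.array([x, 0.0, 0.0]))
              for i, x in enumerate(xs)),
        (),
    )


class TestBuildNetwork:
    def test_collinear_chain_springs(self):
        net = build_network(_line_model([0.0, 5.0, 10.0]), BuildConfig(),
                            LigationState.apo())
        assert set(net.springs) == {(0, 1), (1, 2)}

    def test_cutoff_boundary_is_inclusive(self):
        net = build_network(_line_model([0.0, 8.0]), BuildConfig(),
                            LigationState.apo())
        assert set(net.springs) == {(0, 1)}

    def test_holo2_minus_ligand_nodes_is_apo(self, dimer_model, config):
        apo = build_network(dimer_model, config, LigationState.apo())
        holo2 = build_network(dimer_model, config, LigationState.holo2())
        n_ca = apo.n_nodes
        ca_springs = {p for p in holo2.springs if max(p) < n_ca}
        assert ca_springs == set(apo.springs)
        assert holo2.n_nodes == n_ca + 2

    def test_disconnected_network_raises_with_components(self):
        with pytest.raises(ValueError, match="disconnected"):
            build_network(_line_model([0.0, 5.0, 50.0, 55.0]), BuildConfig(),
                          LigationState.apo())

    def test_duplicate_positions_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_network(_line_model([0.0, 0.0]), BuildConfig(),
                          LigationState.apo())

    def test_spring_set_invariant_under_rigid_motion(self, dimer_model, config):
        rng = np.random.default_rng(0)
        # random rotation (QR of a Gaussian matrix) plus translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3) * 10
        moved = StructureModel(
            tuple((c, r, n, Q @ xyz + t) for c, r, n, xyz in dimer_model.nodes),
            tuple((i, e, m, Q @ xyz + t)
                  for i, e, m, xyz in dimer_model.ligand_atoms),
        )
        a = build_network(dimer_model, config, LigationState.holo2())
        b = build_network(moved, config, LigationState.holo2())
        assert set(a.springs) == set(b.springs)

    def test_c2_symmetry_relates_the_two_holo1_networks(self, dimer_networks):
        a = dimer_networks["holo1A"]
        b = dimer_networks["holo1B"]
        # permutation swapping chains A<->B maps one spring set to the other
        n_per_chain = sum(1 for lab in a.labels if lab.chain == "A")
        n_ca = 2 * n_per_chain

        def swap(i):
            if i >= n_ca:
                return i
            return i + n_per_chain if i < n_per_chain else i - n_per_chain

        mapped = {tuple(sorted((swap(i), swap(j)))) for i, j in a.springs}
        assert mapped == set(b.springs)


class TestSpringEdit:
    def test_scale_one_is_identity(self, dimer_networks):
        net = dimer_networks["holo2"]
        edited = apply_spring_edit(net, SpringEdit(scale=1.0, residue=3))
        assert edited.springs == dict(net.springs)

    def test_pair_edit_touches_exactly_one_spring(self, dimer_networks):
        net = dimer_networks["holo2"]
        (i, j) = min(
            p for p in net.springs
            if net.labels[p[0]].kind == "calpha"
            and net.labels[p[1]].kind == "calpha"
        )
        la, lb = net.labels[i], net.labels[j]
        edit = SpringEdit(scale=4.0, pair=((la.chain, la.resnum),
                                           (lb.chain, lb.resnum)))
        edited = apply_spring_edit(net, edit)
        changed = [p for p in net.springs
                   if edited.springs[p] != net.springs[p]]
        assert changed == [(i, j)]
        assert edited.springs[(i, j)] == pytest.approx(4.0)

    def test_residue_edit_touches_all_incident_springs_in_both_chains(
        self, dimer_networks
    ):
        net = dimer_networks["holo2"]
        resnum = 5
        targets = {i for i, lab in enumerate(net.labels)
                   if lab.kind == "calpha" and lab.resnum == resnum}
        expected = {p for p in net.springs if targets & set(p)}
        edited = apply_spring_edit(net, SpringEdit(scale=0.25, residue=resnum))
        changed = {p for p in net.springs
                   if edited.springs[p] != net.springs[p]}
        assert changed == expected
        # C2 symmetry: same incident count in each chain
        per_chain = {}
        for i in targets:
            per_chain[net.labels[i].chain] = len(net.incident(i))
        assert per_chain["A"] == per_chain["B"]

    def test_edits_compose_multiplicatively(self, dimer_networks):
        net = dimer_networks["holo2"]
        ab = apply_spring_edit(
            apply_spring_edit(net, SpringEdit(scale=2.0, residue=7)),
            SpringEdit(scale=3.0, residue=7),
        )
        direct = apply_spring_edit(net, SpringEdit(scale=6.0, residue=7))
        for p in net.springs:
            assert ab.springs[p] == pytest.approx(direct.springs[p], rel=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            SpringEdit(scale=0.0, residue=1)

    def test_unresolvable_residue_raises(self, dimer_networks):
        with pytest.raises(ValueError, match="resolves to no springs"):
            apply_spring_edit(dimer_networks["apo"],
                              SpringEdit(scale=2.0, residue=999))


class TestConfigAndExports:
    def test_build_config_from_yaml(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("spring_constant: 2.0\ncutoff: 10.0\n"
                     "ligand_names: [CMP, FAD]\n")
        cfg, ligands = BuildConfig.from_file(p)
        assert cfg.spring_constant == 2.0
        assert cfg.cutoff == 10.0
        assert cfg.temperature == 300.0
        assert ligands == ("CMP", "FAD")
        bad = tmp_path / "bad.yaml"
        bad.write_text("sprng: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            BuildConfig.from_file(bad)

    def test_edge_list_round_trips_spring_count(self, dimer_networks, tmp_path):
        net = dimer_networks["holo2"]
        path = tmp_path / "edges.csv"
        net.to_edge_csv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) - 1 == len(net.springs)
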