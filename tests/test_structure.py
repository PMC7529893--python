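"""Structure reading, Kabsch superposition and interface-contact mapping."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from magekit import structure
from magekit.structure import interface_contacts, kabsch, read_structure, superpose_ca


def pdb_atom(serial, name, resname, chain, resseq, xyz, occ=1.0, element="C",
             altloc=" ", record="ATOM  "):
    x, y, z = xyz
    return (
        f"{record}{serial:5d}  {name:<3s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def ca_trace_pdb(chains):
    """PDB text with one CA atom per residue for each chain's coordinate list."""
    lines = []
    serial = 1
    for chain_id, coords in chains.items():
        for i, xyz in enumerate(coords, start=1):
            lines.append(pdb_atom(serial, "CA", "ALA", chain_id, i, xyz))
            serial += 1
    return "\n".join(lines) + "\nEND\n"


def helix_coords(n, seed=0):
    """A jittered helical CA trace: realistic, non-degenerate geometry."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * 100.0 * np.pi / 180.0
    coords = np.c_[2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)]
    return coords + rng.normal(0, 0.05, coords.shape)


class TestReadStructure:
    def test_minimal_two_atom_pdb(self):
        text = "\n".join(
            [
                pdb_atom(1, "N", "GLY", "A", 1, (1.0, 2.0, 3.0), element="N"),
                pdb_atom(2, "CA", "GLY", "A", 1, (2.5, 3.5, 4.5)),
            ]
        ) + "\nEND\n"
        model = read_structure(text)
        atoms = list(model.atoms())
        assert len(atoms) == 2
        assert atoms[0].atom_name == "N"
        assert np.allclose(atoms[1].xyz, [2.5, 3.5, 4.5])
        assert atoms[0].res_name == "GLY" and atoms[0].res_seq == 1

    def test_altloc_highest_occupancy_selected(self):
        text = "\n".join(
            [
                pdb_atom(1, "CA", "SER", "A", 1, (0.0, 0.0, 0.0), occ=0.4, altloc="A"),
                pdb_atom(2, "CA", "SER", "A", 1, (9.0, 9.0, 9.0), occ=0.6, altloc="B"),
            ]
        ) + "\nEND\n"
        model = read_structure(text)
        atoms = list(model.atoms())
        assert len(atoms) == 1
        assert np.allclose(atoms[0].xyz, [9.0, 9.0, 9.0])

    def test_missing_chain_lookup(self):
        model = read_structure(ca_trace_pdb({"A": helix_coords(5)}))
        with pytest.raises(KeyError):
            model.chain("Z")


class TestSuperposition:
    def test_identical_chains_identity_transform(self):
        coords = helix_coords(20)
        model = read_structure(ca_trace_pdb({"A": coords, "B": coords}))
        res = superpose_ca(model, "B", "A")
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-6)
        assert res.n_atoms == 20

    def test_rigidly_rotated_copy_superposes_exactly(self):
        coords = helix_coords(25, seed=1)
        rot = Rotation.from_euler("xyz", [40, -25, 100], degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 8.0])
        # exact identity on raw coordinates
        _, _, rmsd = kabsch(moved, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        # via the PDB round trip, limited only by the format's 3-decimal precision
        model = read_structure(ca_trace_pdb({"A": coords, "B": moved}))
        res = superpose_ca(model, "B", "A")
        assert res.rmsd == pytest.approx(0.0, abs=5e-3)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(2)
        a = helix_coords(15, seed=2)
        b = a + rng.normal(0, 0.2, a.shape)
        model = read_structure(ca_trace_pdb({"A": a, "B": b}))
        fwd = superpose_ca(model, "B", "A").rmsd
        rev = superpose_ca(model, "A", "B").rmsd
        assert fwd == pytest.approx(rev, abs=1e-6)

    def test_kabsch_matches_independent_least_squares(self):
        # independent oracle: scipy's closed-form alignment on the same pairs
        rng = np.random.default_rng(3)
        p = rng.normal(0, 5, (10, 3))
        q = p @ Rotation.random(random_state=4).as_matrix().T + rng.normal(0, 0.3, (10, 3))
        _, _, rmsd = kabsch(p, q)
        rot, ssd = Rotation.align_vectors(q - q.mean(0), p - p.mean(0))
        oracle = np.sqrt(
            np.mean(np.sum((rot.apply(p - p.mean(0)) - (q - q.mean(0))) ** 2, axis=1))
        )
        assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_kabsch_beats_sampled_rotations(self):
        # brute-force sanity: no sampled rigid motion does better
        rng = np.random.default_rng(5)
        p = rng.normal(0, 5, (10, 3))
        q = p @ Rotation.random(random_state=6).as_matrix().T + rng.normal(0, 0.5, (10, 3))
        _, _, rmsd = kabsch(p, q)
        pc, qc = p - p.mean(0), q - q.mean(0)
        sampled = Rotation.random(2000, random_state=7)
        best = min(
            np.sqrt(np.mean(np.sum((r.apply(pc) - qc) ** 2, axis=1))) for r in sampled
        )
        assert rmsd <= best + 1e-12

    def test_unpaired_residues_excluded_and_counted(self):
        a = helix_coords(20, seed=8)
        model = read_structure(ca_trace_pdb({"A": a, "B": a[:15]}))
        res = superpose_ca(model, "B", "A")
        assert res.n_atoms == 15
        assert res.n_unpaired == 5

    def test_too_few_pairs_rejected(self):
        model = read_structure(ca_trace_pdb({"A": helix_coords(2), "B": helix_coords(2)}))
        with pytest.raises(ValueError):
            superpose_ca(model, "B", "A")

    def test_four_protomer_model_all_under_point_four(self):
        # a synthetic asymmetric unit: protomer A plus three perturbed rigid copies,
        # perturbation scaled so every pairwise C-alpha RMSD stays below 0.4 A
        a = helix_coords(180, seed=9)
        rng = np.random.default_rng(10)
        chains = {"A": a}
        for i, cid in enumerate("BCD"):
            rot = Rotation.random(random_state=20 + i).as_matrix()
            chains[cid] = (a + rng.normal(0, 0.18, a.shape)) @ rot.T + rng.normal(0, 30, 3)
        model = read_structure(ca_trace_pdb(chains))
        for cid in "BCD":
            res = superpose_ca(model, cid, "A")
            assert 0.0 < res.rmsd < 0.4


def toy_cleft():
    """12 atoms forming a planted cleft: two facing walls 4-6 A apart."""
    rng = np.random.default_rng(11)
    wall_a = np.c_[np.linspace(0, 10, 6), np.zeros(6), np.zeros(6)]
    wall_b = np.c_[np.linspace(0, 10, 6), np.full(6, 4.5) + rng.uniform(-1.0, 1.5, 6), np.zeros(6)]
    return wall_a, wall_b


class TestInterfaceContacts:
    def model_from_walls(self, wall_a, wall_b):
        return read_structure(ca_trace_pdb({"A": wall_a, "B": wall_b}))

    def sel(self, model, chain):
        return structure.select_atoms(model, chain)

    def test_pair_inside_cutoff(self):
        model = self.model_from_walls(np.array([[0.0, 0, 0]]), np.array([[4.9, 0, 0]]))
        contacts, summary = interface_contacts(self.sel(model, "A"), self.sel(model, "B"))
        assert len(contacts) == 1
        assert contacts["distance"].iloc[0] == pytest.approx(4.9)
        assert len(summary) == 1

    def test_pair_outside_cutoff(self):
        model = self.model_from_walls(np.array([[0.0, 0, 0]]), np.array([[5.1, 0, 0]]))
        contacts, _ = interface_contacts(self.sel(model, "A"), self.sel(model, "B"))
        assert contacts.empty

    def test_matches_brute_force_oracle(self):
        wall_a, wall_b = toy_cleft()
        model = self.model_from_walls(wall_a, wall_b)
        contacts, _ = interface_contacts(self.sel(model, "A"), self.sel(model, "B"), cutoff=5.0)
        expected = set()
        for i, xa in enumerate(wall_a, start=1):       # O(n^2) oracle
            for j, xb in enumerate(wall_b, start=1):
                if np.linalg.norm(xa - xb) <= 5.0:
                    expected.add((i, j))
        got = set(zip(contacts["res_seq_a"], contacts["res_seq_b"]))
        assert got == expected
        assert len(expected) > 0

    def test_invariant_under_rigid_motion(self):
        wall_a, wall_b = toy_cleft()
        rot = Rotation.from_euler("zyx", [30, 60, -45], degrees=True).as_matrix()
        shift = np.array([100.0, -50.0, 20.0])
        m1 = self.model_from_walls(wall_a, wall_b)
        m2 = self.model_from_walls(wall_a @ rot.T + shift, wall_b @ rot.T + shift)
        c1, _ = interface_contacts(self.sel(m1, "A"), self.sel(m1, "B"))
        c2, _ = interface_contacts(self.sel(m2, "A"), self.sel(m2, "B"))
        assert len(c1) == len(c2)
        # distances agree to the PDB format's coordinate precision
        assert np.allclose(np.sort(c1["distance"]), np.sort(c2["distance"]), atol=5e-3)

    def test_overlapping_selections_rejected(self):
        model = self.model_from_walls(*toy_cleft())
        sel = self.sel(model, "A")
        with pytest.raises(ValueError, match="overlap"):
            interface_contacts(sel, sel)

    def test_waters_excluded_by_default(self):
        lines = [
            pdb_atom(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
            pdb_atom(2, "CA", "ALA", "B", 1, (3.0, 0.0, 0.0)),
            pdb_atom(3, "O", "HOH", "B", 2, (1.0, 0.0, 0.0), element="O", record="HETATM"),
        ]
        model = read_structure("\n".join(lines) + "\nEND\n")
        sel_b = structure.select_atoms(model, "B")
        assert all(a.res_name != "HOH" for a in sel_b)
        sel_b_wet = structure.select_atoms(model, "B", include_waters=True)
        assert any(a.res_name == "HOH" for a in sel_b_wet)
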