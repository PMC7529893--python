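"""Structure reading, Kabsch C-alpha superposition, and interface-contact mapping.

Coordinate files (PDB or mmCIF, via gemmi) are flattened to per-chain atom
records.  Chains are superposed by least-squares rigid alignment of C-alpha
atoms paired by residue number, and binding interfaces are mapped as all atom
pairs within a distance cutoff (default 5 A) between two disjoint selections —
the convention used to delineate a substrate binding cleft.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class AtomRecord:
    chain: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    hetero: bool = False

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.res_seq, self.icode)


@dataclass
class Model:
    """First model of a coordinate file: chains mapped to atom records."""

    chains: dict = field(default_factory=dict)

    def atoms(self):
        for atoms in self.chains.values():
            yield from atoms

    def chain(self, chain_id: str) -> list:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r}; have {sorted(self.chains)}")
        return self.chains[chain_id]


def _looks_like_path(source) -> bool:
    if isinstance(source, os.PathLike):
        return True
    return isinstance(source, str) and "\n" not in source and os.path.exists(source)


def read_structure(source) -> Model:
    """Read a PDB or mmCIF file (path or text) into a :class:`Model`.

    Only the first model of multi-model files is kept.  Alternate conformers
    are resolved to the highest-occupancy copy of each atom.  All ATOM and
    HETATM records are retained with their chain/residue metadata.
    """
    if _looks_like_path(source):
        st = gemmi.read_structure(str(source))
    else:
        text = str(source)
        if text.lstrip().startswith("data_"):
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("no models in structure")
    st.setup_entities()
    model = st[0]

    chains: dict[str, list[AtomRecord]] = {}
    for chain in model:
        records = chains.setdefault(chain.name, [])
        for residue in chain:
            # resolve altlocs: highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            het = residue.het_flag == "H"
            for atom in best.values():
                records.append(
                    AtomRecord(
                        chain=chain.name,
                        res_seq=residue.seqid.num,
                        icode=residue.seqid.icode.strip(),
                        res_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        hetero=het,
                    )
                )
    return Model(chains=chains)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, det +1
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_atoms: int
    n_unpaired: int
    atom_selection: str
    degenerate: bool = False


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of paired point sets.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` with a
    proper rotation (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cr - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose_ca(
    model: Model,
    mobile: str,
    reference: str,
) -> SuperpositionResult:
    """Superpose one chain's C-alpha trace onto another's, paired by residue number.

    Residues present in only one chain are excluded and counted as unpaired.
    Requires at least 3 paired C-alpha atoms; a (near-)collinear selection is
    flagged degenerate.
    """
    def ca_map(chain_id: str) -> dict:
        return {
            (a.res_seq, a.icode): a.xyz
            for a in model.chain(chain_id)
            if a.atom_name == "CA" and not a.hetero
        }

    mob = ca_map(mobile)
    ref = ca_map(reference)
    shared = sorted(set(mob) & set(ref))
    n_unpaired = len(set(mob) ^ set(ref))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} paired C-alpha atoms; need at least 3")
    p = np.array([mob[k] for k in shared])
    q = np.array([ref[k] for k in shared])

    # collinearity check on the mobile selection
    centered = p - p.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    degenerate = bool(svals[1] < 1e-6 * max(svals[0], 1e-12))

    rot, trans, rmsd = kabsch(p, q)
    return SuperpositionResult(
        rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(shared),
        n_unpaired=n_unpaired, atom_selection=f"CA {mobile}->{reference}",
        degenerate=degenerate,
    )


def select_atoms(
    model: Model,
    chain: str,
    residues=None,
    include_het: bool = False,
    include_waters: bool = False,
) -> list:
    """Atoms of ``chain``, optionally restricted to a residue-number collection."""
    out = []
    for a in model.chain(chain):
        if not include_waters and a.res_name in WATER_NAMES:
            continue
        if not include_het and a.hetero and a.res_name not in WATER_NAMES:
            continue
        if residues is not None and a.res_seq not in residues:
            continue
        out.append(a)
    return out


def interface_contacts(
    selection_a: list,
    selection_b: list,
    cutoff: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All atom pairs between two disjoint selections within ``cutoff`` A (inclusive).

    Returns the contact table and a summary of the unique selection-a residues
    in contact — with selection_a the adapter protein and selection_b the
    substrate peptide, the summary delineates the substrate binding cleft.
    """
    keys_a = {(a.chain, a.res_seq, a.icode, a.atom_name) for a in selection_a}
    keys_b = {(b.chain, b.res_seq, b.icode, b.atom_name) for b in selection_b}
    if keys_a & keys_b:
        raise ValueError("selections overlap")
    if not selection_a or not selection_b:
        return (
            pd.DataFrame(columns=_CONTACT_COLS),
            pd.DataFrame(columns=["chain", "res_seq", "res_name", "n_contacts"]),
        )

    xa = np.array([a.xyz for a in selection_a])
    xb = np.array([b.xyz for b in selection_b])
    tree_b = cKDTree(xb)
    pairs = cKDTree(xa).query_ball_tree(tree_b, r=cutoff)
    rows = []
    for i, js in enumerate(pairs):
        a = selection_a[i]
        for j in js:
            b = selection_b[j]
            dist = float(np.linalg.norm(a.xyz - b.xyz))
            rows.append(
                {
                    "chain_a": a.chain, "res_seq_a": a.res_seq, "res_name_a": a.res_name,
                    "atom_a": a.atom_name,
                    "chain_b": b.chain, "res_seq_b": b.res_seq, "res_name_b": b.res_name,
                    "atom_b": b.atom_name,
                    "distance": dist,
                }
            )
    contacts = pd.DataFrame(rows, columns=_CONTACT_COLS).sort_values(
        ["chain_a", "res_seq_a", "atom_a", "distance"], kind="stable"
    ).reset_index(drop=True)
    if contacts.empty:
        summary = pd.DataFrame(columns=["chain", "res_seq", "res_name", "n_contacts"])
    else:
        summary = (
            contacts.groupby(["chain_a", "res_seq_a", "res_name_a"], as_index=False)
            .size()
            .rename(
                columns={
                    "chain_a": "chain", "res_seq_a": "res_seq",
                    "res_name_a": "res_name", "size": "n_contacts",
                }
            )
            .sort_values(["chain", "res_seq"], kind="stable")
            .reset_index(drop=True)
        )
    return contacts, summary


_CONTACT_COLS = [
    "chain_a", "res_seq_a", "res_name_a", "atom_a",
    "chain_b", "res_seq_b", "res_name_b", "atom_b",
    "distance",
]
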