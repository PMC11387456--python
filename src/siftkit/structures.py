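"""Receptor/ligand structure handling for contact-fingerprint analysis.

Receptors are read from PDB (via Biotite), ligand poses from SDF (via RDKit)
or extracted from HETATM records by residue name. Residues carry optional
GPCRdb-style generic numbers ("3x32" = helix 3, position 32) supplied as a
mapping table — generic numbering is data, not something computed here.
Trajectories are exchanged as multi-model PDB files (one model per frame).

All coordinates are in Angstroms throughout.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from rdkit import Chem

__all__ = [
    "Atom",
    "Residue",
    "ReceptorStructure",
    "LigandPose",
    "Complex",
    "load_receptor",
    "load_ligand",
    "load_complex",
    "load_trajectory",
    "write_trajectory",
    "read_generic_mapping",
    "map_generic_numbers",
    "pocket_panel",
    "pose_rmsd",
    "superpose_frames",
]

# backbone atom names; everything else on a residue is side chain
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
                   "P": 1.07, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass
class Residue:
    """One amino-acid residue keyed by (chain, auth number, insertion code)."""

    chain: str
    number: int
    aa_code: str
    atoms: list[Atom]
    icode: str = ""
    generic_number: str | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def label(self) -> str:
        """Generic number when annotated, else chain:number."""
        return self.generic_number or f"{self.chain}:{self.number}{self.icode}"

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.element != "H"], dtype=float)

    def atom_coords(self, names: Iterable[str]) -> np.ndarray:
        wanted = set(names)
        return np.array([a.coord for a in self.atoms if a.name in wanted], dtype=float)


@dataclass
class ReceptorStructure:
    residues: list[Residue]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys in receptor")

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain, number, icode):
                return r
        raise KeyError(f"no residue {chain}/{number}{icode}")

    def by_generic(self, generic_number: str) -> Residue:
        for r in self.residues:
            if r.generic_number == generic_number:
                return r
        raise KeyError(f"no residue with generic number {generic_number}")

    def alpha_carbons(self) -> np.ndarray:
        return np.array([a.coord for r in self.residues for a in r.atoms
                         if a.name == "CA"], dtype=float)


@dataclass
class LigandPose:
    """Small-molecule pose: elements, coordinates, formal charges and bonds."""

    elements: list[str]
    coords: np.ndarray                       # (n, 3) float
    formal_charges: list[int]
    bonds: list[tuple[int, int, int]]        # (i, j, order); order 12 = aromatic
    pose_id: str = "pose"
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if len(self.formal_charges) != n:
            raise ValueError("formal_charges length mismatch")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"invalid bond ({i}, {j})")

    def heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(np.array(self.elements) != "H")

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices()]

    def translated(self, shift: np.ndarray) -> "LigandPose":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))

    def bond_graph(self, heavy_only: bool = True) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            if heavy_only and el == "H":
                continue
            g.add_node(i, element=el)
        for i, j, order in self.bonds:
            if i in g and j in g:
                g.add_edge(i, j, order=order)
        return g

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        """Build an RDKit molecule (with coordinates) from the pose."""
        rw = Chem.RWMol()
        for el, q in zip(self.elements, self.formal_charges):
            atom = Chem.Atom(el)
            atom.SetFormalCharge(int(q))
            rw.AddAtom(atom)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE, 12: Chem.BondType.AROMATIC}
        for i, j, order in self.bonds:
            rw.AddBond(int(i), int(j), order_map.get(order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, [float(c) for c in xyz])
        mol.AddConformer(conf)
        if sanitize:
            Chem.SanitizeMol(mol)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, pose_id: str = "pose",
                   conf_id: int = 0) -> "LigandPose":
        conf = mol.GetConformer(conf_id)
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
        coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
        order_map = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                     Chem.BondType.TRIPLE: 3, Chem.BondType.AROMATIC: 12}
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                  order_map.get(b.GetBondType(), 1)) for b in mol.GetBonds()]
        return cls(elements, coords, charges, bonds, pose_id=pose_id)


@dataclass
class Complex:
    """A receptor and one ligand pose sharing a Cartesian frame."""

    receptor: ReceptorStructure
    ligand: LigandPose
    complex_id: str = "complex"


# ---------------------------------------------------------------------------
# I/O

def _atom_array_to_residues(array: "struc.AtomArray",
                            hetero: bool = False) -> list[Residue]:
    mask = array.hetero if hetero else ~array.hetero
    sub = array[mask]
    residues: list[Residue] = []
    for start in struc.get_residue_starts(sub):
        rmask = (
            (sub.chain_id == sub.chain_id[start])
            & (sub.res_id == sub.res_id[start])
            & (sub.ins_code == sub.ins_code[start])
        )
        atoms_arr = sub[rmask]
        atoms = [Atom(name=str(atoms_arr.atom_name[i]),
                      element=str(atoms_arr.element[i]).capitalize(),
                      coord=tuple(float(x) for x in atoms_arr.coord[i]))
                 for i in range(atoms_arr.array_length())]
        residues.append(Residue(chain=str(sub.chain_id[start]),
                                number=int(sub.res_id[start]),
                                aa_code=str(sub.res_name[start]),
                                icode=str(sub.ins_code[start]).strip(),
                                atoms=atoms))
    # deduplicate while preserving order (residue starts can repeat per chain scan)
    seen: set = set()
    uniq = []
    for r in residues:
        if r.key not in seen:
            seen.add(r.key)
            uniq.append(r)
    return uniq


def load_receptor(path: str | Path, model: int = 1) -> ReceptorStructure:
    """Read the polymer part of a PDB file into a ReceptorStructure."""
    pdb = pdbio.PDBFile.read(str(path))
    array = pdb.get_structure(model=model)
    residues = _atom_array_to_residues(array, hetero=False)
    if not residues:
        raise IOError(f"no polymer residues found in {path}")
    return ReceptorStructure(residues, metadata={"path": str(path)})


def _perceive_bonds(elements: Sequence[str], coords: np.ndarray,
                    tolerance: float = 0.45) -> list[tuple[int, int, int]]:
    """Distance-based single-bond perception from covalent radii."""
    bonds = []
    n = len(elements)
    for i in range(n):
        for j in range(i + 1, n):
            ri = _COVALENT_RADII.get(elements[i].upper(), 0.77)
            rj = _COVALENT_RADII.get(elements[j].upper(), 0.77)
            if np.linalg.norm(coords[i] - coords[j]) <= ri + rj + tolerance:
                bonds.append((i, j, 1))
    return bonds


def load_ligand(path: str | Path, format: str | None = None,
                residue_name: str = "LIG") -> LigandPose:
    """Read a ligand pose from SDF, or extract a HETATM residue from a PDB.

    For the PDB route, bonds are perceived from interatomic distances (orders
    are not recoverable from PDB); formal charges default to the file's charge
    column when present, else zero.
    """
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".mol", ".sd"} else "pdb"
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mol = next((m for m in supplier if m is not None), None)
        if mol is None:
            raise IOError(f"no parseable molecule in {path}")
        return LigandPose.from_rdkit(mol, pose_id=path.stem)
    if format == "pdb":
        pdb = pdbio.PDBFile.read(str(path))
        array = pdb.get_structure(model=1)
        mask = array.hetero & (array.res_name == residue_name)
        if not mask.any():
            raise ValueError(f"no HETATM residue named {residue_name!r} in {path}")
        sub = array[mask]
        elements = [str(e).capitalize() for e in sub.element]
        coords = np.asarray(sub.coord, dtype=float)
        charges = [int(c) for c in sub.charge] if "charge" in sub.get_annotation_categories() \
            else [0] * len(elements)
        bonds = _perceive_bonds(elements, coords)
        return LigandPose(elements, coords, charges, bonds, pose_id=path.stem)
    raise ValueError(f"unknown ligand format {format!r}")


def load_complex(receptor_path: str | Path, ligand_path: str | Path | None = None,
                 ligand_residue: str = "LIG") -> Complex:
    """Load a receptor and a ligand pose into one Complex.

    The ligand comes from a separate SDF/PDB file, or — when ``ligand_path``
    is None — from the HETATM residue named ``ligand_residue`` inside the
    receptor file itself.
    """
    receptor = load_receptor(receptor_path)
    if ligand_path is None:
        ligand = load_ligand(receptor_path, format="pdb", residue_name=ligand_residue)
    else:
        ligand = load_ligand(ligand_path)
    cid = Path(receptor_path).stem
    return Complex(receptor, ligand, complex_id=cid)


def load_trajectory(path: str | Path, ligand_residue: str = "LIG") -> list[Complex]:
    """Read a multi-model PDB (model = frame) into a list of Complexes."""
    pdb = pdbio.PDBFile.read(str(path))
    stack = pdb.get_structure()
    frames = []
    for t in range(stack.stack_depth()):
        array = stack[t]
        residues = _atom_array_to_residues(array, hetero=False)
        mask = array.hetero & (array.res_name == ligand_residue)
        sub = array[mask]
        elements = [str(e).capitalize() for e in sub.element]
        coords = np.asarray(sub.coord, dtype=float)
        bonds = _perceive_bonds(elements, coords)
        ligand = LigandPose(elements, coords, [0] * len(elements), bonds,
                            pose_id=f"frame{t}", frame_index=t)
        frames.append(Complex(ReceptorStructure(residues), ligand,
                              complex_id=f"{Path(path).stem}:frame{t}"))
    return frames


def _complex_to_atom_array(cx: Complex, ligand_residue: str = "LIG") -> "struc.AtomArray":
    n_rec = sum(len(r.atoms) for r in cx.receptor.residues)
    n = n_rec + len(cx.ligand.elements)
    array = struc.AtomArray(n)
    idx = 0
    for r in cx.receptor.residues:
        for a in r.atoms:
            array.chain_id[idx] = r.chain
            array.res_id[idx] = r.number
            array.ins_code[idx] = r.icode
            array.res_name[idx] = r.aa_code
            array.atom_name[idx] = a.name
            array.element[idx] = a.element.upper()
            array.coord[idx] = a.coord
            array.hetero[idx] = False
            idx += 1
    for i, el in enumerate(cx.ligand.elements):
        array.chain_id[idx] = "X"
        array.res_id[idx] = 900
        array.res_name[idx] = ligand_residue
        array.atom_name[idx] = f"{el.upper()}{i + 1}"[:4]
        array.element[idx] = el.upper()
        array.coord[idx] = cx.ligand.coords[i]
        array.hetero[idx] = True
        idx += 1
    return array


def write_trajectory(frames: Sequence[Complex], path: str | Path,
                     ligand_residue: str = "LIG") -> None:
    """Write frames as a multi-model PDB."""
    arrays = [_complex_to_atom_array(cx, ligand_residue) for cx in frames]
    stack = struc.stack(arrays)
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_complex(cx: Complex, path: str | Path, ligand_residue: str = "LIG") -> None:
    pdb = pdbio.PDBFile()
    pdb.set_structure(_complex_to_atom_array(cx, ligand_residue))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Generic numbering

def _valid_generic(label: str) -> bool:
    parts = label.split("x")
    return (len(parts) == 2 and all(parts)
            and all(c in string.digits for c in parts[0])
            and all(c in string.digits for c in parts[1]))


def read_generic_mapping(path: str | Path) -> dict[tuple[str, int], str]:
    """Read a chain,resnum,generic CSV into a mapping dict."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("chain", "resnum", "generic"):
        if need not in cols:
            raise KeyError(f"mapping CSV needs columns chain,resnum,generic; got {list(df.columns)}")
    return {(str(r[cols["chain"]]), int(r[cols["resnum"]])): str(r[cols["generic"]])
            for _, r in df.iterrows()}


def map_generic_numbers(
    receptor: ReceptorStructure,
    mapping: dict[tuple[str, int], str],
) -> tuple[ReceptorStructure, list[tuple[str, int]]]:
    """Annotate residues with GPCRdb generic numbers.

    Returns the annotated receptor and a report of mapping rows that matched
    no residue. Duplicate generic labels in the mapping are a configuration
    error; unmapped residues are simply left unannotated.
    """
    labels = list(mapping.values())
    for label in labels:
        if not _valid_generic(label):
            raise ValueError(f"invalid generic label {label!r} (expected '<seg>x<pos>')")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate generic labels in mapping: {dupes}")
    unmatched = []
    by_key = {(r.chain, r.number): r for r in receptor.residues}
    for (chain, number), label in mapping.items():
        res = by_key.get((chain, number))
        if res is None:
            unmatched.append((chain, number))
        else:
            res.generic_number = label
    return receptor, unmatched


# ---------------------------------------------------------------------------
# Geometry

def pocket_panel(cx: Complex, cutoff_A: float = 6.0) -> list[Residue]:
    """Binding-pocket residue panel: residues with any heavy atom within
    ``cutoff_A`` of any ligand heavy atom, ordered by (chain, number, icode)."""
    if cutoff_A <= 0:
        return []
    lig = cx.ligand.heavy_coords()
    if len(lig) == 0:
        return []
    tree = cKDTree(lig)
    panel = []
    for r in cx.receptor.residues:
        coords = r.heavy_coords()
        if len(coords) and np.any(tree.query(coords, k=1)[0] <= cutoff_A):
            panel.append(r)
    return sorted(panel, key=lambda r: r.key)


def _automorphisms(graph: nx.Graph, cap: int):
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        graph, graph,
        node_match=lambda a, b: a["element"] == b["element"])
    out = []
    for mapping in matcher.isomorphisms_iter():
        out.append(mapping)
        if len(out) >= cap:
            return out, True
    return out, False


def pose_rmsd(pose_a: LigandPose, pose_b: LigandPose,
              symmetry_aware: bool = False, automorphism_cap: int = 10_000) -> float:
    """Heavy-atom RMSD between two poses of the same molecule, in place.

    No superposition is performed — the poses must already share a frame
    (the use case is comparing docked and crystallographic poses within one
    receptor frame). With ``symmetry_aware``, the minimum over bond-graph
    automorphisms is returned, so chemically equivalent atoms (e.g. the two
    ortho carbons of a phenyl) can swap; enumeration is capped at
    ``automorphism_cap`` mappings, beyond which the identity matching is used.
    """
    ha = pose_a.heavy_indices()
    hb = pose_b.heavy_indices()
    ea = [pose_a.elements[i] for i in ha]
    eb = [pose_b.elements[i] for i in hb]
    if sorted(ea) != sorted(eb):
        raise ValueError("poses are not the same molecule (heavy-atom multiset differs)")
    ga = pose_a.bond_graph(heavy_only=True)
    gb = pose_b.bond_graph(heavy_only=True)
    if sorted(d for _, d in ga.degree) != sorted(d for _, d in gb.degree):
        raise ValueError("poses are not the same molecule (bond graph differs)")
    if ea != eb or list(ha) != list(hb):
        raise ValueError("atom ordering differs between poses; reorder first")
    xa = pose_a.coords[ha]
    xb = pose_b.coords[hb]
    naive = float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    if not symmetry_aware:
        return naive
    autos, capped = _automorphisms(ga, automorphism_cap)
    if capped:
        import warnings
        warnings.warn(f"automorphism count exceeds cap ({automorphism_cap}); "
                      "falling back to identity matching")
        return naive
    pos = {node: k for k, node in enumerate(ha)}
    best = naive
    for mapping in autos:
        perm = np.array([pos[mapping[node]] for node in ha])
        rmsd = float(np.sqrt(np.mean(np.sum((xa - xb[perm]) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def _default_selection(cx: Complex) -> np.ndarray:
    return cx.receptor.alpha_carbons()


def superpose_frames(
    frames: Sequence[Complex],
    reference_selection: Callable[[Complex], np.ndarray] | None = None,
) -> tuple[list[Complex], list[tuple[np.ndarray, np.ndarray]]]:
    """Rigid-body (Kabsch) superposition of every frame onto frame 0.

    The least-squares fit uses the reference selection (default: receptor
    alpha-carbons); the resulting proper rotation + translation is applied to
    all atoms of the frame, ligand included. Returns aligned frames and the
    per-frame (rotation matrix, translation) pairs, with frame 0 mapped by
    the identity.
    """
    if reference_selection is None:
        reference_selection = _default_selection
    if not frames:
        return [], []
    ref = np.asarray(reference_selection(frames[0]), dtype=float)
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 reference atoms for superposition")
    ref_centroid = ref.mean(axis=0)
    aligned = []
    transforms = []
    for cx in frames:
        sel = np.asarray(reference_selection(cx), dtype=float)
        if sel.shape != ref.shape:
            raise ValueError("frame selection shape differs from reference")
        centroid = sel.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref - ref_centroid, sel - centroid)
        R = rot.as_matrix()
        t = ref_centroid - R @ centroid
        transforms.append((R, t))
        aligned.append(_transform_complex(cx, R, t))
    return aligned, transforms


def _transform_complex(cx: Complex, R: np.ndarray, t: np.ndarray) -> Complex:
    new_residues = []
    for r in cx.receptor.residues:
        atoms = [Atom(a.name, a.element, tuple(R @ np.asarray(a.coord) + t))
                 for a in r.atoms]
        new_residues.append(Residue(r.chain, r.number, r.aa_code, atoms,
                                    r.icode, r.generic_number))
    receptor = ReceptorStructure(new_residues, metadata=dict(cx.receptor.metadata))
    ligand = replace(cx.ligand, coords=cx.ligand.coords @ R.T + t)
    return Complex(receptor, ligand, complex_id=cx.complex_id)
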