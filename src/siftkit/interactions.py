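"""Typed ligand-residue interaction detection and SIFt encoding.

A structural interaction fingerprint (SIFt) summarises one ligand-receptor
complex as a binary matrix: binding-site residues on one axis, interaction
types on the other.  The classic nine-type scheme is used — contact,
backbone contact, side-chain contact, polar, hydrophobic, hydrogen bond with
the protein as acceptor, hydrogen bond with the protein as donor, aromatic,
and charged — with a hierarchy rule: any typed interaction at a residue
implies the plain contact bit, and hydrogen bonds / salt bridges imply the
polar bit.

Detection is purely geometric, driven by a configurable cutoff set (defaults
are literature-standard values, recorded in every output).  Ligand chemical
features are perceived from the bond graph (via RDKit aromaticity and
valence); residue features come from a built-in per-amino-acid atom-name
lookup covering the 20 standard residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from rdkit import Chem

from .structures import BACKBONE_ATOMS, Complex, LigandPose, Residue

__all__ = [
    "DEFAULT_SCHEME",
    "InteractionCutoffs",
    "FeatureSet",
    "InteractionEvent",
    "SIFt",
    "perceive_features",
    "residue_features",
    "detect_interactions",
    "encode_sift",
    "sift_per_frame",
    "sift_for_complex",
]

#: classic nine-type SIFt column scheme, in canonical order
DEFAULT_SCHEME: tuple[str, ...] = (
    "contact", "backbone_contact", "sidechain_contact", "polar", "hydrophobic",
    "hb_protein_acceptor", "hb_protein_donor", "aromatic", "charged",
)

# typed bits that imply other bits when encoding (besides contact, which
# every typed event implies)
_IMPLIES: dict[str, tuple[str, ...]] = {
    "hb_protein_acceptor": ("polar",),
    "hb_protein_donor": ("polar",),
    "charged": ("polar",),
}


@dataclass(frozen=True)
class InteractionCutoffs:
    """Geometric cutoffs (Angstroms / degrees) defining each interaction type."""

    contact_A: float = 4.5
    hydrophobic_A: float = 4.5
    polar_A: float = 4.0
    hbond_A: float = 3.5
    hbond_angle_deg: float = 120.0
    charged_A: float = 4.0
    aromatic_A: float = 5.5

    def max_cutoff(self) -> float:
        return max(self.contact_A, self.hydrophobic_A, self.polar_A,
                   self.hbond_A, self.charged_A, self.aromatic_A)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FeatureSet:
    """Chemical feature atoms of a molecule (atom indices into its atom list)."""

    donors: frozenset[int] = frozenset()
    acceptors: frozenset[int] = frozenset()
    cations: tuple[tuple[int, ...], ...] = ()       # charge groups (atom tuples)
    anions: tuple[tuple[int, ...], ...] = ()
    hydrophobes: frozenset[int] = frozenset()
    aromatic_rings: tuple[tuple[int, ...], ...] = ()
    polars: frozenset[int] = frozenset()            # all N/O/S heavy atoms


@dataclass(frozen=True)
class InteractionEvent:
    """One typed geometric contact between the ligand and a residue."""

    residue: str                       # generic label or chain:number
    itype: str
    ligand_atoms: tuple[int, ...]
    residue_atoms: tuple[str, ...]
    geometry: tuple[tuple[str, float], ...]   # e.g. (("distance_A", 3.2),)

    @property
    def distance_A(self) -> float:
        return dict(self.geometry)["distance_A"]


@dataclass
class SIFt:
    """Binary panel x scheme interaction matrix for one complex."""

    panel: list[str]
    scheme: list[str]
    bits: np.ndarray                   # (len(panel), len(scheme)) bool
    complex_id: str = "complex"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (len(self.panel), len(self.scheme)):
            raise ValueError("bits shape must be (len(panel), len(scheme))")

    def bit(self, residue: str, itype: str) -> bool:
        return bool(self.bits[self.panel.index(residue), self.scheme.index(itype)])

    def any_contact(self) -> np.ndarray:
        """Per-residue collapsed any-interaction vector."""
        return self.bits.any(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits.astype(int), index=self.panel,
                            columns=self.scheme)


# ---------------------------------------------------------------------------
# Ligand feature perception

def perceive_features(ligand: LigandPose) -> FeatureSet:
    """Perceive donor/acceptor/charge/hydrophobe/aromatic features on a ligand.

    Donors are N/O/S bearing at least one hydrogen (explicit or implicit by
    valence); acceptors are N/O with an available lone pair (positively
    charged, pyrrole-type and amide nitrogens excluded); charge groups come
    from formal charges plus chargeable-group rules — amidinium/guanidinium
    and aliphatic amines count as cations, carboxylates as anions; hydrophobes
    are carbons with no N/O/S neighbour; aromatic rings use RDKit aromaticity.
    """
    try:
        mol = ligand.to_rdkit(sanitize=True)
    except Exception as exc:
        raise ValueError(f"feature perception failed (valence/sanitisation): {exc}")

    donors, acceptors, hydrophobes, polars = set(), set(), set(), set()
    cations: list[tuple[int, ...]] = []
    anions: list[tuple[int, ...]] = []

    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym == "H":
            continue
        neigh = [n.GetSymbol() for n in atom.GetNeighbors()]
        if sym in ("N", "O", "S"):
            polars.add(i)
            if atom.GetTotalNumHs() >= 1 and atom.GetFormalCharge() >= 0:
                donors.add(i)
        if sym == "O" and atom.GetFormalCharge() <= 0:
            acceptors.add(i)
        if sym == "N" and atom.GetFormalCharge() <= 0 and atom.GetTotalValence() < 4:
            pyrrole_like = atom.GetIsAromatic() and atom.GetTotalNumHs() > 0
            amide = any(_is_carbonyl_carbon(n) for n in atom.GetNeighbors())
            if not pyrrole_like and not amide:
                acceptors.add(i)
        if sym == "C" and not any(s in ("N", "O", "S") for s in neigh):
            hydrophobes.add(i)
        if atom.GetFormalCharge() > 0:
            cations.append((i,))
        if atom.GetFormalCharge() < 0 and sym != "O":
            anions.append((i,))

    # chargeable groups on neutral molecules
    guanidinium = Chem.MolFromSmarts("[CX3](=[NX2])([NX3])[NX3,NX2]")
    amidinium = Chem.MolFromSmarts("[CX3](=[NX2])[NX3]")
    for pat in (guanidinium, amidinium):
        for match in mol.GetSubstructMatches(pat):
            if not any(mol.GetAtomWithIdx(i).GetFormalCharge() != 0 for i in match):
                group = tuple(sorted(match))
                if not any(set(group) <= set(g) or set(g) <= set(group) for g in cations):
                    cations.append(group)
    amine = Chem.MolFromSmarts("[NX3;!$(N-C=O);!$(N-a);!$(N=*);H0,H1,H2,H3;+0]")
    for match in mol.GetSubstructMatches(amine):
        i = match[0]
        if mol.GetAtomWithIdx(i).GetIsAromatic():
            continue
        if not any(i in g for g in cations):
            cations.append((i,))
    carboxylate = Chem.MolFromSmarts("[CX3](=O)[OX1H0-,OX2H1]")
    for match in mol.GetSubstructMatches(carboxylate):
        group = tuple(sorted(match))
        if not any(set(group) & set(g) for g in anions):
            anions.append(group)

    rings = []
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(tuple(ring))

    return FeatureSet(
        donors=frozenset(donors), acceptors=frozenset(acceptors),
        cations=tuple(cations), anions=tuple(anions),
        hydrophobes=frozenset(hydrophobes), aromatic_rings=tuple(rings),
        polars=frozenset(polars),
    )


def _is_carbonyl_carbon(atom: "Chem.Atom") -> bool:
    if atom.GetSymbol() != "C":
        return False
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetSymbol() == "O" and bond.GetBondTypeAsDouble() == 2.0:
            return True
    return False


# ---------------------------------------------------------------------------
# Residue feature lookup (atom names per standard amino acid)

_RING1 = {"PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
          "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
          "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
          "TRP": ("CG", "CD1", "NE1", "CE2", "CD2")}
_RING2 = {"TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")}

# side-chain feature atoms; backbone N (donor) and O/OXT (acceptor) are added
# for every residue except the proline donor
_SIDECHAIN = {
    "ALA": dict(hydrophobes=("CB",)),
    "ARG": dict(donors=("NE", "NH1", "NH2"), cations=(("NE", "NH1", "NH2", "CZ"),),
                hydrophobes=("CB", "CG")),
    "ASN": dict(donors=("ND2",), acceptors=("OD1",), hydrophobes=("CB",)),
    "ASP": dict(acceptors=("OD1", "OD2"), anions=(("OD1", "OD2"),), hydrophobes=("CB",)),
    "CYS": dict(donors=("SG",)),
    "GLN": dict(donors=("NE2",), acceptors=("OE1",), hydrophobes=("CB", "CG")),
    "GLU": dict(acceptors=("OE1", "OE2"), anions=(("OE1", "OE2"),),
                hydrophobes=("CB", "CG")),
    "GLY": dict(),
    "HIS": dict(donors=("ND1", "NE2"), acceptors=("ND1", "NE2"), hydrophobes=("CB",)),
    "ILE": dict(hydrophobes=("CB", "CG1", "CG2", "CD1")),
    "LEU": dict(hydrophobes=("CB", "CG", "CD1", "CD2")),
    "LYS": dict(donors=("NZ",), cations=(("NZ",),), hydrophobes=("CB", "CG", "CD")),
    "MET": dict(hydrophobes=("CB",)),
    "PHE": dict(hydrophobes=("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "PRO": dict(hydrophobes=("CB", "CG")),
    "SER": dict(donors=("OG",), acceptors=("OG",)),
    "THR": dict(donors=("OG1",), acceptors=("OG1",), hydrophobes=("CG2",)),
    "TRP": dict(donors=("NE1",),
                hydrophobes=("CB", "CE3", "CZ2", "CZ3", "CH2")),
    "TYR": dict(donors=("OH",), acceptors=("OH",),
                hydrophobes=("CB", "CG", "CD1", "CD2", "CE1", "CE2")),
    "VAL": dict(hydrophobes=("CB", "CG1", "CG2")),
}

STANDARD_RESIDUES = frozenset(_SIDECHAIN)


def residue_features(residue: Residue) -> dict:
    """Feature atoms of a residue, as name sets keyed by feature kind.

    Raises KeyError for nonstandard residues.
    """
    aa = residue.aa_code.upper()
    if aa not in _SIDECHAIN:
        raise KeyError(f"nonstandard residue {aa}")
    spec = _SIDECHAIN[aa]
    present = {a.name for a in residue.atoms}
    feats = {
        "donors": {n for n in spec.get("donors", ()) if n in present},
        "acceptors": {n for n in spec.get("acceptors", ()) if n in present},
        "cations": [tuple(n for n in grp if n in present)
                    for grp in spec.get("cations", ()) if any(n in present for n in grp)],
        "anions": [tuple(n for n in grp if n in present)
                   for grp in spec.get("anions", ()) if any(n in present for n in grp)],
        "hydrophobes": {n for n in spec.get("hydrophobes", ()) if n in present},
        "rings": [],
        "polars": {a.name for a in residue.atoms
                   if a.element in ("N", "O", "S")},
    }
    if "N" in present and aa != "PRO":
        feats["donors"].add("N")
    for n in ("O", "OXT"):
        if n in present:
            feats["acceptors"].add(n)
    for table in (_RING1, _RING2):
        ring = table.get(aa)
        if ring and all(n in present for n in ring):
            feats["rings"].append(ring)
    return feats


def _ring_centroid_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


# ---------------------------------------------------------------------------
# Detection

def detect_interactions(
    cx: Complex,
    cutoffs: InteractionCutoffs | None = None,
    method: str = "grid",
    nonstandard: str = "warn",
) -> list[InteractionEvent]:
    """Detect all typed ligand-residue interactions in a complex.

    ``method="grid"`` prunes candidate residues with a k-d tree on ligand
    heavy atoms before the exact per-pair geometry test; ``method="brute"``
    scans every residue unconditionally. Both return identical event lists —
    the brute route exists as an independent check of the pruning.

    Events are emitted in (residue panel order, type order) and are invariant
    to atom ordering within the inputs. Hydrogen-bond detection uses the
    donor-heavy/acceptor-heavy distance criterion; when explicit hydrogens
    are present on the donor, the D-H...A angle must also exceed the angular
    cutoff, otherwise the event is flagged "no_H_mode".
    """
    if cutoffs is None:
        cutoffs = InteractionCutoffs()
    if method not in ("grid", "brute"):
        raise ValueError("method must be 'grid' or 'brute'")
    feats = perceive_features(cx.ligand)
    lig_heavy = cx.ligand.heavy_indices()
    lig_coords = cx.ligand.coords

    if len(lig_heavy) == 0:
        return []
    candidates: list[Residue]
    if method == "grid":
        tree = cKDTree(lig_coords[lig_heavy])
        reach = cutoffs.max_cutoff() + 3.0   # margin covers group-center offsets
        candidates = []
        for r in cx.receptor.residues:
            coords = r.heavy_coords()
            if len(coords) and np.any(tree.query(coords, k=1)[0] <= reach):
                candidates.append(r)
    else:
        candidates = list(cx.receptor.residues)

    events: list[InteractionEvent] = []
    for residue in sorted(candidates, key=lambda r: r.key):
        try:
            rfeats = residue_features(residue)
        except KeyError:
            if nonstandard == "error":
                raise ValueError(f"nonstandard residue {residue.aa_code}")
            import warnings
            warnings.warn(f"skipping nonstandard residue {residue.aa_code} "
                          f"{residue.chain}/{residue.number}")
            continue
        events.extend(_residue_events(cx.ligand, feats, residue, rfeats, cutoffs))
    return events


def _residue_events(ligand: LigandPose, lf: FeatureSet, residue: Residue,
                    rf: dict, cutoffs: InteractionCutoffs) -> list[InteractionEvent]:
    events: list[InteractionEvent] = []
    label = residue.label
    ratoms = [a for a in residue.atoms if a.element != "H"]
    rnames = [a.name for a in ratoms]
    rcoords = np.array([a.coord for a in ratoms], dtype=float) \
        if ratoms else np.zeros((0, 3))
    lig_heavy = ligand.heavy_indices()
    if len(ratoms) == 0 or len(lig_heavy) == 0:
        return events
    lcoords = ligand.coords[lig_heavy]
    dists = np.linalg.norm(lcoords[:, None, :] - rcoords[None, :, :], axis=2)

    def emit(itype, lig_idx, res_names, geometry):
        events.append(InteractionEvent(
            residue=label, itype=itype,
            ligand_atoms=tuple(sorted(int(i) for i in lig_idx)),
            residue_atoms=tuple(sorted(res_names)),
            geometry=tuple(geometry)))

    # plain contact + backbone/side-chain split
    close = np.argwhere(dists <= cutoffs.contact_A)
    if len(close):
        pairs_l = {int(lig_heavy[i]) for i, _ in close}
        pairs_r = {rnames[j] for _, j in close}
        dmin = float(dists.min())
        emit("contact", pairs_l, pairs_r, [("distance_A", dmin)])
        bb = {rnames[j] for _, j in close if rnames[j] in BACKBONE_ATOMS}
        sc = pairs_r - BACKBONE_ATOMS
        if bb:
            dbb = float(min(dists[i, j] for i, j in close if rnames[j] in BACKBONE_ATOMS))
            emit("backbone_contact",
                 {int(lig_heavy[i]) for i, j in close if rnames[j] in BACKBONE_ATOMS},
                 bb, [("distance_A", dbb)])
        if sc:
            dsc = float(min(dists[i, j] for i, j in close if rnames[j] not in BACKBONE_ATOMS))
            emit("sidechain_contact",
                 {int(lig_heavy[i]) for i, j in close if rnames[j] not in BACKBONE_ATOMS},
                 sc, [("distance_A", dsc)])

    name_to_col = {n: j for j, n in enumerate(rnames)}
    lig_row = {int(a): i for i, a in enumerate(lig_heavy)}

    def pair_dist(lig_atom: int, res_name: str) -> float:
        return float(dists[lig_row[lig_atom], name_to_col[res_name]])

    # polar
    polar_pairs = [(a, n) for a in sorted(lf.polars) for n in sorted(rf["polars"])
                   if n in name_to_col and pair_dist(a, n) <= cutoffs.polar_A]
    if polar_pairs:
        d = min(pair_dist(a, n) for a, n in polar_pairs)
        emit("polar", {a for a, _ in polar_pairs}, {n for _, n in polar_pairs},
             [("distance_A", d)])

    # hydrophobic
    hyd_pairs = [(a, n) for a in sorted(lf.hydrophobes) for n in sorted(rf["hydrophobes"])
                 if n in name_to_col and pair_dist(a, n) <= cutoffs.hydrophobic_A]
    if hyd_pairs:
        d = min(pair_dist(a, n) for a, n in hyd_pairs)
        emit("hydrophobic", {a for a, _ in hyd_pairs}, {n for _, n in hyd_pairs},
             [("distance_A", d)])

    # hydrogen bonds (ligand donor -> protein acceptor)
    explicit_h = "H" in ligand.elements
    hba = [(a, n) for a in sorted(lf.donors) for n in sorted(rf["acceptors"])
           if n in name_to_col and pair_dist(a, n) <= cutoffs.hbond_A
           and _hb_angle_ok(ligand, a, np.array(
               [at.coord for at in residue.atoms if at.name == n][0]),
               cutoffs.hbond_angle_deg)]
    if hba:
        d = min(pair_dist(a, n) for a, n in hba)
        geom = [("distance_A", d)] + ([] if explicit_h else [("no_H_mode", 1.0)])
        emit("hb_protein_acceptor", {a for a, _ in hba}, {n for _, n in hba}, geom)

    # hydrogen bonds (protein donor -> ligand acceptor)
    hbd = [(a, n) for a in sorted(lf.acceptors) for n in sorted(rf["donors"])
           if n in name_to_col and pair_dist(a, n) <= cutoffs.hbond_A]
    if hbd:
        d = min(pair_dist(a, n) for a, n in hbd)
        emit("hb_protein_donor", {a for a, _ in hbd}, {n for _, n in hbd},
             [("distance_A", d), ("no_H_mode", 1.0)])

    # charged (opposite charge-group centers)
    charged_hits = []
    for lgroup in lf.cations:
        for rgroup in rf["anions"]:
            d = _group_center_distance(ligand, lgroup, residue, rgroup)
            if d is not None and d <= cutoffs.charged_A:
                charged_hits.append((lgroup, rgroup, d))
    for lgroup in lf.anions:
        for rgroup in rf["cations"]:
            d = _group_center_distance(ligand, lgroup, residue, rgroup)
            if d is not None and d <= cutoffs.charged_A:
                charged_hits.append((lgroup, rgroup, d))
    if charged_hits:
        d = min(h[2] for h in charged_hits)
        emit("charged", {a for h in charged_hits for a in h[0]},
             {n for h in charged_hits for n in h[1]}, [("distance_A", d)])

    # aromatic (ring centroid - ring centroid)
    aro_hits = []
    for lring in lf.aromatic_rings:
        lcen, _ = _ring_centroid_normal(ligand.coords[list(lring)])
        for rring in rf["rings"]:
            rc = residue.atom_coords(rring)
            if len(rc) != len(rring):
                continue
            rcen, _ = _ring_centroid_normal(rc)
            d = float(np.linalg.norm(lcen - rcen))
            if d <= cutoffs.aromatic_A:
                aro_hits.append((lring, rring, d))
    if aro_hits:
        d = min(h[2] for h in aro_hits)
        emit("aromatic", {a for h in aro_hits for a in h[0]},
             {n for h in aro_hits for n in h[1]}, [("distance_A", d)])

    return events


def _hb_angle_ok(ligand: LigandPose, donor_idx: int, acceptor_coord: np.ndarray,
                 min_angle_deg: float) -> bool:
    """D-H...A angle test; passes trivially when the donor has no explicit H."""
    h_idx = [j for i, j, _ in ligand.bonds if i == donor_idx and ligand.elements[j] == "H"]
    h_idx += [i for i, j, _ in ligand.bonds if j == donor_idx and ligand.elements[i] == "H"]
    if not h_idx:
        return True
    d = ligand.coords[donor_idx]
    for h in h_idx:
        hv = ligand.coords[h]
        v1 = d - hv
        v2 = acceptor_coord - hv
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= min_angle_deg:
            return True
    return False


def _group_center_distance(ligand: LigandPose, lgroup: Sequence[int],
                           residue: Residue, rgroup: Sequence[str]) -> float | None:
    rc = residue.atom_coords(rgroup)
    if len(rc) == 0:
        return None
    lcen = ligand.coords[list(lgroup)].mean(axis=0)
    return float(np.linalg.norm(lcen - rc.mean(axis=0)))


# ---------------------------------------------------------------------------
# Encoding

def encode_sift(
    events: Iterable[InteractionEvent],
    panel: Sequence[Residue | str],
    scheme: Sequence[str] = DEFAULT_SCHEME,
    complex_id: str = "complex",
    cutoffs: InteractionCutoffs | None = None,
) -> tuple[SIFt, list[InteractionEvent]]:
    """Encode an event list as a SIFt over an ordered residue panel.

    The hierarchy rule is enforced here: every typed bit sets the contact bit
    for its residue, and hydrogen-bond / charged bits set the polar bit.
    Events at residues outside the panel are returned in the second element,
    never silently dropped.
    """
    if not len(panel):
        raise ValueError("panel must be nonempty")
    labels = [p if isinstance(p, str) else p.label for p in panel]
    scheme = list(scheme)
    col = {t: k for k, t in enumerate(scheme)}
    bits = np.zeros((len(labels), len(scheme)), dtype=bool)
    row = {lab: r for r, lab in enumerate(labels)}
    outside = []
    for ev in events:
        r = row.get(ev.residue)
        if r is None:
            outside.append(ev)
            continue
        if ev.itype in col:
            bits[r, col[ev.itype]] = True
        for implied in _IMPLIES.get(ev.itype, ()):
            if implied in col:
                bits[r, col[implied]] = True
        if "contact" in col:
            bits[r, col["contact"]] = True
    meta = {"cutoffs": cutoffs.to_dict() if cutoffs else InteractionCutoffs().to_dict()}
    return SIFt(labels, scheme, bits, complex_id=complex_id, metadata=meta), outside


def sift_for_complex(cx: Complex, panel: Sequence[Residue | str],
                     scheme: Sequence[str] = DEFAULT_SCHEME,
                     cutoffs: InteractionCutoffs | None = None) -> SIFt:
    """Detect interactions and encode the SIFt in one step."""
    events = detect_interactions(cx, cutoffs=cutoffs)
    sift, _ = encode_sift(events, panel, scheme, complex_id=cx.complex_id,
                          cutoffs=cutoffs)
    return sift


def sift_per_frame(frames: Sequence[Complex], panel: Sequence[Residue | str],
                   scheme: Sequence[str] = DEFAULT_SCHEME,
                   cutoffs: InteractionCutoffs | None = None) -> list[SIFt]:
    """One SIFt per trajectory frame, frame order preserved."""
    return [sift_for_complex(cx, panel, scheme, cutoffs) for cx in frames]
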