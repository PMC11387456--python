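"""Synthetic inputs for every pipeline stage, with ground truth attached.

Docked complexes and MD trajectories from commercial engines cannot be
redistributed or regenerated here, so this module produces statistical twins
of each analysis input:

* activity tables — log-normal nM values split by parameter type, compounds
  built by decorating named chemotype scaffolds so the substructure rules
  recover the planted class;
* SIFt panels — Bernoulli contact matrices with planted active/inactive
  frequency differences over a null firing rate;
* toy 3D complexes — one-to-few-residue pseudo-pockets built from ideal
  amino-acid side-chain geometry, with a small rigid ligand placed so a
  chosen interaction archetype (hydrogen bond, salt bridge, aromatic
  stacking, hydrophobic contact, or none) is realised under the default
  cutoffs;
* trajectories — per-frame ligand placement with tunable contact persistence
  plus Gaussian coordinate jitter.

Every generator is seed-deterministic and returns its ground truth alongside
the data. Random streams are split per generator component, so adding a new
generator does not shift existing fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .interactions import DEFAULT_SCHEME, SIFt
from .ligand_db import ActivityRecord, Parameter, Relation
from .structures import Atom, Complex, LigandPose, ReceptorStructure, Residue

__all__ = [
    "SyntheticSpec",
    "simulate_activity_table",
    "simulate_sift_panel",
    "simulate_complex",
    "simulate_trajectory",
    "ARCHETYPES",
]

_STREAMS = {"activity": 0, "panel": 1, "complex": 2, "trajectory": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass
class SyntheticSpec:
    """Parameters controlling all synthetic generators.

    Defaults emulate a mid-sized receptor-ligand SAR collection: nM activity
    values log-normally spread over ~3 orders of magnitude around 100 nM,
    balanced active/inactive groups of 50, a 30% background contact rate with
    a planted 0.4 frequency difference at one residue, and 0.2 A coordinate
    jitter per trajectory frame.
    """

    seed: int = 0
    n_active: int = 50
    n_inactive: int = 50
    planted_deltas: dict[str, float] = field(default_factory=lambda: {"p000": 0.4})
    null_p: float = 0.3
    jitter_sigma_A: float = 0.2
    persistence: dict[str, float] = field(default_factory=dict)
    lognormal_mu: float = math.log(100.0)      # natural-log nM
    lognormal_sigma: float = 1.5
    chemotype_mix: dict[str, float] = field(default_factory=lambda: {
        "acylguanidine": 0.5, "2-aminoquinoline": 0.5})
    duplicate_fraction: float = 0.2

    def validate(self) -> None:
        if abs(sum(self.chemotype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("chemotype_mix proportions must sum to 1")
        for residue, delta in self.planted_deltas.items():
            if not -1.0 <= delta <= 1.0:
                raise ValueError(f"planted delta for {residue} outside [-1, 1]")
            if not 0.0 <= self.null_p + max(delta, 0.0) <= 1.0 or self.null_p + min(delta, 0.0) < 0:
                raise ValueError(f"null_p + delta for {residue} outside [0, 1]")
        if not 0.0 <= self.null_p <= 1.0:
            raise ValueError("null_p must lie in [0, 1]")
        if self.jitter_sigma_A < 0:
            raise ValueError("jitter_sigma_A must be nonnegative")
        for residue, p in self.persistence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"persistence for {residue} outside [0, 1]")


# ---------------------------------------------------------------------------
# Activity tables

# decoration templates per chemotype: "{R}" is replaced by a substituent
# fragment (possibly empty); every decorated product must still match its
# own chemotype rule, which the tests enforce
_SCAFFOLD_TEMPLATES: dict[str, str] = {
    "acylguanidine": "C({R}[H])C(=O)NC(=N)N",
    "2-aminoquinoline": "Nc1ccc2cc({R}[H])ccc2n1",
    "benzoxazine": "C1COc2cc({R}[H])ccc2N1",
    "arylpiperazine": "c1cc({R}[H])ccc1N1CCNCC1",
    "tryptamine": "NCCc1c[nH]c2ccc({R}[H])cc12",
}


def _random_substituent(rng: np.random.Generator) -> str:
    """A random linear C/O chain with optional terminal halogen (may be empty)."""
    length = int(rng.integers(0, 7))
    tokens: list[str] = []
    last = ""
    for _ in range(length):
        tok = "O" if (last != "O" and rng.random() < 0.25) else "C"
        tokens.append(tok)
        last = tok
    if tokens and tokens[-1] == "C" and rng.random() < 0.3:
        tokens.append(str(rng.choice(["F", "Cl"])))
    return "".join(tokens)


def _decorate(chemotype: str, rng: np.random.Generator) -> str:
    template = _SCAFFOLD_TEMPLATES[chemotype]
    sub = _random_substituent(rng)
    smiles = template.replace("{R}", sub)
    # "(...[H])" with empty R leaves an explicit-H branch; drop the branch
    return smiles.replace("([H])", "") if sub == "" else smiles.replace("[H])", ")")


def simulate_activity_table(
    spec: SyntheticSpec,
    parameter: Parameter | str = Parameter.Ki,
    threshold_nM: float = 1000.0,
) -> tuple[list[ActivityRecord], dict]:
    """Generate activity records with known class labels and chemotypes.

    ``n_active`` compounds get values below ``threshold_nM`` and
    ``n_inactive`` at or above it (log-normal draws, rejected-resampled into
    the correct side). A ``duplicate_fraction`` of compounds receive a second
    measurement (same structure, slightly perturbed value) to exercise
    deduplication. Ground truth maps each canonical SMILES to its planted
    chemotype and activity class, so it joins directly against the entries
    produced by ``ligand_db.merge_compounds``.
    """
    from .ligand_db import canonical_smiles
    spec.validate()
    parameter = Parameter(parameter)
    rng = _rng(spec.seed, "activity")
    names = sorted(spec.chemotype_mix)
    probs = np.array([spec.chemotype_mix[n] for n in names])
    unknown = [n for n in names if n not in _SCAFFOLD_TEMPLATES]
    if unknown:
        raise ValueError(f"no scaffold template for chemotypes: {unknown}")

    records: list[ActivityRecord] = []
    truth: dict = {"chemotype": {}, "activity_class": {}, "n_unique": 0,
                   "parameter": parameter.value, "threshold_nM": threshold_nM}
    seen: set[str] = set()
    made = 0
    for active in (True, False):
        n_group = spec.n_active if active else spec.n_inactive
        for _ in range(n_group):
            chemotype = str(rng.choice(names, p=probs))
            for attempt in range(200):       # decorate until structure is fresh
                smiles = _decorate(chemotype, rng)
                key = canonical_smiles(smiles)
                if key is not None and key not in seen:
                    break
            else:
                raise RuntimeError("substituent vocabulary exhausted; "
                                   "reduce group sizes")
            seen.add(key)
            value = _draw_value(rng, spec, active, threshold_nM)
            records.append(ActivityRecord(
                record_id=f"syn:{made}", structure=smiles, parameter=parameter,
                relation=Relation.EQ, value_nM=value, source="other",
                compound_label=f"SYN{made:04d}"))
            if rng.random() < spec.duplicate_fraction:
                dup = value * math.exp(0.1 * rng.standard_normal())
                # keep the duplicate on the same side of the threshold
                dup = _clip_side(dup, active, threshold_nM)
                records.append(ActivityRecord(
                    record_id=f"syn:{made}:dup", structure=smiles,
                    parameter=parameter, relation=Relation.EQ, value_nM=dup,
                    source="other", compound_label=f"SYN{made:04d}"))
            truth["chemotype"][key] = chemotype
            truth["activity_class"][key] = "active" if active else "inactive"
            made += 1
    truth["n_unique"] = len(seen)
    return records, truth


def _draw_value(rng, spec: SyntheticSpec, active: bool, threshold: float) -> float:
    if spec.lognormal_sigma == 0:
        value = math.exp(spec.lognormal_mu)
        return _clip_side(value, active, threshold)
    for _ in range(1000):
        value = float(np.exp(spec.lognormal_mu
                             + spec.lognormal_sigma * rng.standard_normal()))
        if (value < threshold) == active:
            return value
    return _clip_side(value, active, threshold)


def _clip_side(value: float, active: bool, threshold: float) -> float:
    if active and value >= threshold:
        return threshold * 0.5
    if not active and value < threshold:
        return threshold * 2.0
    return value


# ---------------------------------------------------------------------------
# SIFt panels

def simulate_sift_panel(
    spec: SyntheticSpec,
    panel_size: int = 31,
) -> tuple[list[SIFt], list[SIFt], dict]:
    """Bernoulli contact panels with planted active/inactive differences.

    Null residues fire with probability ``null_p`` in both groups; each
    planted residue fires with ``null_p + delta`` in the active group and
    ``null_p`` in the inactive group. Residue labels are ``p000``,
    ``p001``, ...; planted deltas keyed by int are taken as panel indices.

    Returns (active SIFts, inactive SIFts, ground truth).
    """
    spec.validate()
    rng = _rng(spec.seed, "panel")
    panel = [f"p{i:03d}" for i in range(panel_size)]
    planted: dict[str, float] = {}
    for key, delta in spec.planted_deltas.items():
        label = panel[key] if isinstance(key, int) else key
        if label not in panel:
            raise ValueError(f"planted residue {label!r} outside panel of size {panel_size}")
        planted[label] = delta

    p_active = np.full(panel_size, spec.null_p)
    p_inactive = np.full(panel_size, spec.null_p)
    for label, delta in planted.items():
        p_active[panel.index(label)] = spec.null_p + delta

    def draw(n: int, p: np.ndarray, tag: str) -> list[SIFt]:
        sifts = []
        for i in range(n):
            fire = rng.random(panel_size) < p
            bits = np.zeros((panel_size, 1), dtype=bool)
            bits[:, 0] = fire
            sifts.append(SIFt(panel=list(panel), scheme=["contact"], bits=bits,
                              complex_id=f"{tag}{i:03d}"))
        return sifts

    active = draw(spec.n_active, p_active, "act")
    inactive = draw(spec.n_inactive, p_inactive, "inact")
    truth = {"panel": panel, "planted": planted, "null_p": spec.null_p,
             "p_active": p_active.tolist(), "p_inactive": p_inactive.tolist()}
    return active, inactive, truth


# ---------------------------------------------------------------------------
# Toy 3D complexes

ARCHETYPES = ("hbond", "ionic", "aromatic", "hydrophobic", "no_contact")

# side-chain axis of the templates below (unit vector away from the backbone)
_AXIS = np.array([0.36, -0.50, 0.78])
_PERP = np.array([0.8115, 0.5710, -0.0085])   # unit, orthogonal to _AXIS


def _backbone(origin: np.ndarray) -> list[Atom]:
    o = np.asarray(origin, dtype=float)
    return [Atom("N", "N", tuple(o + [-1.46, 0.0, 0.0])),
            Atom("CA", "C", tuple(o)),
            Atom("C", "C", tuple(o + [0.55, 1.36, 0.0])),
            Atom("O", "O", tuple(o + [1.77, 1.50, 0.0]))]


def _cb(origin: np.ndarray) -> np.ndarray:
    return np.asarray(origin) + np.array([0.55, -0.77, 1.20])


def make_residue(aa: str, chain: str, number: int,
                 origin: Sequence[float] = (0.0, 0.0, 0.0)) -> Residue:
    """Build one residue with idealised geometry at the given CA origin.

    Supported templates: GLY, ALA, SER, ASP, LEU, PHE. Side chains extend
    along a fixed axis away from the backbone; aromatic rings are exact
    regular hexagons (coplanar by construction).
    """
    o = np.asarray(origin, dtype=float)
    atoms = _backbone(o)
    aa = aa.upper()
    if aa == "GLY":
        pass
    elif aa == "ALA":
        atoms.append(Atom("CB", "C", tuple(_cb(o))))
    elif aa == "SER":
        cb = _cb(o)
        atoms.append(Atom("CB", "C", tuple(cb)))
        atoms.append(Atom("OG", "O", tuple(cb + 1.41 * _AXIS)))
    elif aa == "ASP":
        cb = _cb(o)
        cg = cb + 1.52 * _AXIS
        atoms.append(Atom("CB", "C", tuple(cb)))
        atoms.append(Atom("CG", "C", tuple(cg)))
        atoms.append(Atom("OD1", "O", tuple(cg + 0.60 * _AXIS + 1.10 * _PERP)))
        atoms.append(Atom("OD2", "O", tuple(cg + 0.60 * _AXIS - 1.10 * _PERP)))
    elif aa == "LEU":
        cb = _cb(o)
        cg = cb + 1.52 * _AXIS
        d1 = (_AXIS + 0.8 * _PERP)
        d2 = (_AXIS - 0.8 * _PERP)
        atoms.append(Atom("CB", "C", tuple(cb)))
        atoms.append(Atom("CG", "C", tuple(cg)))
        atoms.append(Atom("CD1", "C", tuple(cg + 1.52 * d1 / np.linalg.norm(d1))))
        atoms.append(Atom("CD2", "C", tuple(cg + 1.52 * d2 / np.linalg.norm(d2))))
    elif aa == "PHE":
        cb = _cb(o)
        cg = cb + 1.50 * _AXIS
        center = cg + 1.39 * _AXIS
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        atoms.append(Atom("CB", "C", tuple(cb)))
        for k, name in enumerate(ring_names):
            theta = math.pi + k * math.pi / 3.0   # CG sits at theta = pi
            pos = center + 1.39 * (math.cos(theta) * _AXIS + math.sin(theta) * _PERP)
            atoms.append(Atom(name, "C", tuple(pos)))
    else:
        raise ValueError(f"no template for residue {aa!r}")
    return Residue(chain=chain, number=number, aa_code=aa, atoms=atoms)


def _spectators() -> list[Residue]:
    return [make_residue("GLY", "A", 90, origin=(-9.0, 2.0, -3.0)),
            make_residue("ALA", "A", 91, origin=(8.0, -6.0, -5.0))]


def _phe_ring_geometry(res: Residue) -> tuple[np.ndarray, np.ndarray]:
    ring = res.atom_coords(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"))
    center = ring.mean(axis=0)
    centered = ring - center
    _, _, vt = np.linalg.svd(centered)
    return center, vt[2] / np.linalg.norm(vt[2])


def simulate_complex(archetype: str, seed: int = 0,
                     aromatic_centroid_A: float = 5.0) -> tuple[Complex, list[str]]:
    """A pseudo-pocket realising exactly one interaction archetype.

    Returns the Complex and the expected interaction-event types at the
    target residue (empty for ``no_contact``); no other residue interacts.
    The seed applies a small random rigid rotation/translation to the whole
    scene so repeated fixtures are not axis-aligned.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; choose from {ARCHETYPES}")
    rng = _rng(seed, "complex")

    if archetype in ("hbond", "no_contact"):
        target = make_residue("SER", "A", 10)
        og = np.array(target.atom_coords(("OG",))[0])
        if archetype == "hbond":
            o_pos = og + 2.9 * _AXIS
            expected = ["contact", "sidechain_contact", "polar",
                        "hb_protein_acceptor", "hb_protein_donor"]
        else:
            o_pos = og + 20.0 * _AXIS
            expected = []
        c_pos = o_pos + 1.43 * _AXIS
        ligand = LigandPose(["O", "C"], np.stack([o_pos, c_pos]), [0, 0],
                            [(0, 1, 1)], pose_id=archetype)
    elif archetype == "ionic":
        target = make_residue("ASP", "A", 10)
        od = target.atom_coords(("OD1", "OD2"))
        center = od.mean(axis=0)
        n_pos = center + 3.5 * _AXIS
        c_pos = n_pos + 1.49 * _AXIS
        ligand = LigandPose(["N", "C"], np.stack([n_pos, c_pos]), [1, 0],
                            [(0, 1, 1)], pose_id=archetype)
        expected = ["contact", "sidechain_contact", "polar", "charged"]
    elif archetype == "aromatic":
        target = make_residue("PHE", "A", 10)
        center, normal = _phe_ring_geometry(target)
        if np.dot(normal, _AXIS) < 0:
            normal = -normal
        bcen = center + aromatic_centroid_A * normal
        hexagon = []
        for k in range(6):
            theta = k * math.pi / 3.0
            hexagon.append(bcen + 1.39 * (math.cos(theta) * _AXIS
                                          + math.sin(theta) * _PERP))
        ligand = LigandPose(["C"] * 6, np.stack(hexagon), [0] * 6,
                            [(i, (i + 1) % 6, 12) for i in range(6)],
                            pose_id=archetype)
        expected = ["aromatic"] if aromatic_centroid_A <= 5.5 else []
    else:  # hydrophobic
        target = make_residue("LEU", "A", 10)
        cg = np.array(target.atom_coords(("CG",))[0])
        c2 = cg + 4.0 * _AXIS
        c1 = c2 + 1.53 * _PERP
        c3 = c2 - 1.53 * _PERP
        ligand = LigandPose(["C", "C", "C"], np.stack([c1, c2, c3]), [0, 0, 0],
                            [(0, 1, 1), (1, 2, 1)], pose_id=archetype)
        expected = ["contact", "sidechain_contact", "hydrophobic"]

    receptor = ReceptorStructure([target] + _spectators())
    cx = Complex(receptor, ligand, complex_id=f"{archetype}:{seed}")
    cx = _random_rigid(cx, rng)
    return cx, expected


def _random_rigid(cx: Complex, rng: np.random.Generator) -> Complex:
    from scipy.spatial.transform import Rotation
    quat = rng.standard_normal(4)
    R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    t = rng.uniform(-5, 5, size=3)
    from .structures import _transform_complex
    return _transform_complex(cx, R, t)


# ---------------------------------------------------------------------------
# Trajectories

def simulate_trajectory(base: Complex, spec: SyntheticSpec,
                        n_frames: int = 500) -> tuple[list[Complex], dict]:
    """Jittered trajectory frames with planted contact persistence.

    The receptor is fixed; each frame keeps the ligand in the base (contact)
    pose with probability ``persistence`` (the value for the pocket's target
    residue; default 1.0) or displaces it 12 A along the pocket axis, far
    outside every cutoff. Gaussian jitter of ``jitter_sigma_A`` per
    coordinate is then added to the ligand.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    spec.validate()
    rng = _rng(spec.seed, "trajectory")
    p_contact = min(spec.persistence.values()) if spec.persistence else 1.0
    # displacement along the pocket axis: away from the receptor centroid
    rec_centroid = np.concatenate(
        [r.heavy_coords() for r in base.receptor.residues]).mean(axis=0)
    lig_centroid = base.ligand.coords.mean(axis=0)
    axis = lig_centroid - rec_centroid
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    frames = []
    in_contact = np.zeros(n_frames, dtype=bool)
    for t in range(n_frames):
        contact = bool(rng.random() < p_contact)
        in_contact[t] = contact
        coords = base.ligand.coords.copy()
        if not contact:
            coords = coords + 12.0 * axis
        if spec.jitter_sigma_A > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sigma_A, size=coords.shape)
        ligand = replace(base.ligand, coords=coords,
                         pose_id=f"frame{t}", frame_index=t)
        frames.append(Complex(base.receptor, ligand,
                              complex_id=f"{base.complex_id}:frame{t}"))
    truth = {"persistence": p_contact, "in_contact": in_contact,
             "jitter_sigma_A": spec.jitter_sigma_A}
    return frames, truth
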