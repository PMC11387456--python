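"""Chemotype assignment and similarity clustering of a ligand collection.

Two complementary routes group compounds into chemical classes:

* a curated, ordered SMARTS rule library naming the recurring scaffolds of
  serotonin-receptor medicinal chemistry (acylguanidines, 2-aminoquinolines,
  benzoxazines, ergolines, ...) — the primary route, because named classes are
  the unit the SAR literature reports on; and
* leader-style (Butina) clustering on Morgan-fingerprint Tanimoto similarity —
  the fallback for compounds no rule covers, standing in for interactive
  clustering tools.

Rule order encodes priority: the first matching rule wins, so specific
scaffolds (e.g. the ergoline tetracycle) must precede the generic fragments
they embed (e.g. tryptamine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .ligand_db import CompoundEntry, Parameter

__all__ = [
    "ChemotypeRule",
    "ClusterAssignment",
    "default_rules",
    "load_rules",
    "assign_chemotype",
    "assign_all",
    "cluster_compounds",
    "cluster_summary",
]


@dataclass(frozen=True)
class ChemotypeRule:
    """A named substructure rule; lower priority number = matched first."""

    name: str
    smarts: str
    priority: int

    def pattern(self) -> Chem.Mol:
        pat = Chem.MolFromSmarts(self.smarts)
        if pat is None:
            raise ValueError(f"SMARTS for rule {self.name!r} does not compile")
        return pat


# (name, SMARTS, exemplar scaffold SMILES). The exemplar is the plain scaffold
# the rule is designed around; each exemplar matches its own rule and no other,
# which the test suite enforces as an all-pairs identity matrix.
_RULE_TABLE: list[tuple[str, str, str]] = [
    ("lysergic acid derivative", "C1~C2c3cccc4[nH]cc(c34)CC2NCC1",
     "CN1CC(C(=O)O)C=C2c3cccc4[nH]cc(c34)CC21"),
    ("N'-benzyl-N-(pyridin-2-yl)guanidine", "[NX3](Cc1ccccc1)C(=[NX2])[NX3]c1ccccn1",
     "N(Cc1ccccc1)C(=N)Nc1ccccn1"),
    ("acylguanidine", "[CX3](=O)[NX3][CX3](=[NX2])[NX3]", "CC(=O)NC(=N)N"),
    ("carboline", "c1ccc2c(c1)[nH]c1cnccc12", "c1ccc2c(c1)[nH]c1cnccc12"),
    ("2-amino-dihydroquinazoline", "[NX3]C1=Nc2ccccc2CN1", "NC1=Nc2ccccc2CN1"),
    ("2-aminoquinoline", "[NX3;!$(N-C=O)]c1ccc2ccccc2n1", "Nc1ccc2ccccc2n1"),
    ("1-(quinolin-8-yl)methanamine", "[NX3][CH2]c1cccc2cccnc12", "NCc1cccc2cccnc12"),
    ("isoquinoline amide", "O=C([NX3])c1cc2ccccc2cn1", "NC(=O)c1cc2ccccc2cn1"),
    ("quinazoline", "c1ccc2ncncc2c1", "c1ccc2ncncc2c1"),
    ("benzoxazine", "C1COc2ccccc2N1", "C1COc2ccccc2N1"),
    ("benzimidazole", "c1ccc2[nH]cnc2c1", "c1ccc2[nH]cnc2c1"),
    ("aminoimidazole", "[NX3]c1ncc[nH]1", "Nc1ncc[nH]1"),
    ("biarylmethylamine", "[NX3][CH2]c1ccccc1-c1ccccc1", "NCc1ccccc1-c1ccccc1"),
    ("arylpiperazine", "c1ccc(cc1)N1CC[NX3]CC1", "c1ccc(cc1)N1CCNCC1"),
    ("tryptamine", "[NX3;!R][CH2;!R][CH2;!R]c1c[nH]c2ccccc12", "NCCc1c[nH]c2ccccc12"),
]

#: exemplar scaffold SMILES per rule name (used by tests and the generator)
EXEMPLAR_SCAFFOLDS: dict[str, str] = {name: smi for name, _, smi in _RULE_TABLE}


def default_rules() -> list[ChemotypeRule]:
    """The built-in rule library, in priority order."""
    return [ChemotypeRule(name, smarts, i)
            for i, (name, smarts, _) in enumerate(_RULE_TABLE)]


def load_rules(path: str | Path) -> list[ChemotypeRule]:
    """Load an editable rule table (CSV with name, smarts, priority columns)."""
    df = pd.read_csv(path)
    rules = [ChemotypeRule(str(r["name"]), str(r["smarts"]), int(r["priority"]))
             for _, r in df.iterrows()]
    rules.sort(key=lambda r: r.priority)
    if len({r.name for r in rules}) != len(rules):
        raise ValueError("rule names must be unique")
    if len({r.priority for r in rules}) != len(rules):
        raise ValueError("rule priorities must be distinct")
    for r in rules:
        r.pattern()  # compile check
    return rules


def assign_chemotype(
    entry: CompoundEntry | str,
    rules: Sequence[ChemotypeRule] | None = None,
) -> str | None:
    """Name of the first (highest-priority) rule matching the compound, or None.

    Accepts a CompoundEntry or a bare SMILES string. Deterministic: rule
    priority fully resolves multi-match cases.
    """
    if rules is None:
        rules = default_rules()
    smiles = entry if isinstance(entry, str) else entry.canonical_key
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    for rule in sorted(rules, key=lambda r: r.priority):
        if mol.HasSubstructMatch(rule.pattern()):
            return rule.name
    return None


def assign_all(entries: Iterable[CompoundEntry],
               rules: Sequence[ChemotypeRule] | None = None) -> list[CompoundEntry]:
    """Annotate entries in place with their chemotype; returns the same list."""
    entries = list(entries)
    for e in entries:
        e.chemotype = assign_chemotype(e, rules)
    return entries


@dataclass
class ClusterAssignment:
    """A partition of compounds into clusters with designated centroids."""

    labels: dict[str, int]                   # compound key -> cluster id
    members: dict[int, list[str]] = field(default_factory=dict)
    centroids: dict[int, str] = field(default_factory=dict)
    method: str = "similarity"

    def __post_init__(self) -> None:
        if not self.members:
            members: dict[int, list[str]] = {}
            for key, cid in self.labels.items():
                members.setdefault(cid, []).append(key)
            self.members = members


def _morgan_fps(smiles_list: Sequence[str]):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    fps = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable structure: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def tanimoto_matrix(smiles_list: Sequence[str]) -> np.ndarray:
    """Pairwise Tanimoto similarity on Morgan (radius 2, 2048-bit) fingerprints."""
    fps = _morgan_fps(smiles_list)
    n = len(fps)
    sim = np.eye(n)
    for i in range(1, n):
        row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        sim[i, :i] = row
        sim[:i, i] = row
    return sim


def cluster_compounds(
    entries: Sequence[CompoundEntry | str],
    similarity_cutoff: float = 0.4,
) -> ClusterAssignment:
    """Leader-style (Butina) sphere-exclusion clustering of a compound set.

    Two compounds are neighbours when their Morgan-fingerprint Tanimoto
    similarity is >= ``similarity_cutoff``. Cluster leaders are picked in
    descending neighbour count, ties broken by ascending canonical key, so the
    partition is deterministic and independent of input order up to relabeling.
    Every compound is assigned; the leader is the cluster centroid.
    """
    if not 0 < similarity_cutoff < 1:
        raise ValueError("similarity_cutoff must lie in (0, 1)")
    keys = [e if isinstance(e, str) else e.canonical_key for e in entries]
    if not keys:
        raise ValueError("need at least one entry")
    # duplicates collapse onto one representative
    uniq = sorted(set(keys))
    sim = tanimoto_matrix(uniq)
    neighbours = [set(np.flatnonzero(sim[i] >= similarity_cutoff)) for i in range(len(uniq))]
    order = sorted(range(len(uniq)),
                   key=lambda i: (-len(neighbours[i]), uniq[i]))
    assigned: dict[int, int] = {}
    centroids: dict[int, str] = {}
    next_id = 0
    for i in order:
        if i in assigned:
            continue
        centroids[next_id] = uniq[i]
        for j in sorted(neighbours[i]):
            if j not in assigned:
                assigned[j] = next_id
        next_id += 1
    index = {k: i for i, k in enumerate(uniq)}
    labels = {key: assigned[index[key]] for key in keys}
    # members keep input multiplicity (duplicate structures count separately)
    members: dict[int, list[str]] = {cid: [] for cid in centroids}
    for key in keys:
        members[labels[key]].append(key)
    return ClusterAssignment(labels=labels, members=members,
                             centroids=centroids, method="similarity")


def cluster_summary(
    assignment: ClusterAssignment,
    entries: Sequence[CompoundEntry],
    parameter: Parameter | str = Parameter.Ki,
) -> pd.DataFrame:
    """Per-cluster size and potency statistics (median best value, counts < 50/100 nM)."""
    parameter = Parameter(parameter)
    by_key = {e.canonical_key: e for e in entries}
    missing = set(assignment.labels) - set(by_key)
    if missing:
        raise ValueError(f"assignment covers compounds absent from entries: {sorted(missing)[:3]}")
    rows = []
    for cid in sorted(assignment.members):
        members = assignment.members[cid]
        values = [by_key[k].best_value_nM[parameter] for k in members
                  if parameter in by_key[k].best_value_nM]
        rows.append({
            "cluster_id": cid,
            "size": len(members),
            "centroid": assignment.centroids.get(cid),
            f"median_{parameter.value}_nM": float(np.median(values)) if values else np.nan,
            "below_50nM": sum(1 for v in values if v < 50.0),
            "below_100nM": sum(1 for v in values if v < 100.0),
        })
    return pd.DataFrame(rows)
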