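"""Curation of multi-source bioactivity collections for a single receptor target.

This module turns heterogeneous activity tables (ChEMBL exports, hand-extracted
patent data, PDSP entries) into a deduplicated, activity-labelled compound
collection.  Records carry a parameter type (Ki / IC50 / EC50, all in nM), a
relation (``=``, ``<``, ``>``) and a SMILES structure; compounds are keyed by
RDKit canonical SMILES so that different depictions of the same molecule merge
into one entry.  Activity classes follow the potency-threshold convention used
throughout serotonin-receptor SAR work: a compound is *active* for a parameter
when its best (lowest) determined value falls below the threshold
(1000 nM by default) and *inactive* otherwise.
"""

from __future__ import annotations

import enum
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Parameter",
    "Relation",
    "ActivityClass",
    "ActivityRecord",
    "CompoundEntry",
    "VennCounts",
    "RejectedRecord",
    "read_activity_table",
    "canonical_smiles",
    "merge_compounds",
    "classify_activity",
    "parameter_overlap",
    "threshold_count",
    "activity_distribution",
    "collection_summary",
]


class Parameter(str, enum.Enum):
    """Activity parameter type; values are nM concentrations."""

    Ki = "Ki"
    IC50 = "IC50"
    EC50 = "EC50"


class Relation(str, enum.Enum):
    EQ = "="
    LT = "<"
    GT = ">"


class ActivityClass(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    UNDETERMINED = "undetermined"


#: default potency threshold separating actives from inactives, in nM
DEFAULT_THRESHOLD_NM = 1000.0

# column-name aliases for reading third-party tables; keys are canonical names
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "structure": ("structure", "smiles", "canonical_smiles", "Smiles", "SMILES"),
    "parameter": ("parameter", "standard_type", "type", "param"),
    "relation": ("relation", "standard_relation", "rel"),
    "value": ("value", "standard_value", "value_nm", "value_nM", "activity"),
    "source": ("source", "src", "data_source", "origin"),
    "compound_label": ("compound_label", "label", "name", "molecule_chembl_id", "id"),
    "units": ("units", "standard_units", "unit"),
}

_UNIT_TO_NM = {"nM": 1.0, "nm": 1.0, "uM": 1000.0, "um": 1000.0, "µM": 1000.0,
               "mM": 1e6, "mm": 1e6, "M": 1e9, "pM": 1e-3, "pm": 1e-3}

_KNOWN_SOURCES = ("chembl", "patent", "pdsp", "other")


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement for one structure."""

    record_id: str
    structure: str
    parameter: Parameter
    relation: Relation
    value_nM: float
    source: str = "other"
    compound_label: str | None = None

    def __post_init__(self) -> None:
        if not self.value_nM > 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")


@dataclass
class RejectedRecord:
    """An input row that failed validation, with the reason it was rejected."""

    row: Mapping
    reason: str


@dataclass
class CompoundEntry:
    """Per-compound aggregate of all records sharing one canonical structure."""

    canonical_key: str
    records: list[ActivityRecord] = field(default_factory=list)
    best_value_nM: dict[Parameter, float] = field(default_factory=dict)
    chemotype: str | None = None

    @property
    def activity_class(self) -> dict[Parameter, ActivityClass]:
        return {p: classify_activity(self, p) for p in Parameter}

    def determined_parameters(self) -> frozenset[Parameter]:
        """Parameters with at least one '='-relation measurement."""
        return frozenset(self.best_value_nM)


@dataclass
class VennCounts:
    """Counts of compounds by the exact subset of parameters determined for them."""

    counts: dict[frozenset, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def marginal(self, parameter: Parameter) -> int:
        """Number of compounds for which *parameter* is determined."""
        return sum(n for subset, n in self.counts.items() if parameter in subset)


def canonical_smiles(smiles: str) -> str | None:
    """RDKit canonical SMILES, or None when the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _resolve_columns(columns: Sequence[str],
                     aliases: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canonical, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                resolved[canonical] = lower[name.lower()]
                break
    return resolved


def read_activity_table(
    path: str | Path,
    format: str | None = None,
    column_aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> tuple[list[ActivityRecord], list[RejectedRecord]]:
    """Read an XLSX/CSV activity table into validated records.

    Rows failing validation (unparseable structure, nonpositive value, unknown
    parameter or relation) are returned in the rejects list with a reason, never
    silently dropped.  Values are normalised to nM at read time when a units
    column is present.

    Parameters
    ----------
    path : file path
    format : "xlsx" or "csv"; inferred from the extension when omitted
    column_aliases : overrides for column-name resolution

    Returns
    -------
    (records, rejects)
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"activity table not found: {path}")
    if format is None:
        format = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    if format == "xlsx":
        df = pd.read_excel(path)
    elif format == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_aliases:
        aliases.update(column_aliases)
    cols = _resolve_columns(df.columns, aliases)
    required = ("structure", "parameter", "relation", "value", "source")
    missing = [c for c in required if c not in cols]
    if missing:
        raise KeyError(f"required columns missing from {path.name}: {missing} "
                       f"(resolvable aliases: { {m: aliases[m] for m in missing} })")

    records: list[ActivityRecord] = []
    rejects: list[RejectedRecord] = []
    for i, row in df.iterrows():
        raw = row.to_dict()
        try:
            record = _row_to_record(raw, cols, record_id=f"{path.stem}:{i}")
        except ValueError as exc:
            rejects.append(RejectedRecord(raw, str(exc)))
            continue
        records.append(record)
    return records, rejects


def _row_to_record(raw: Mapping, cols: Mapping[str, str], record_id: str) -> ActivityRecord:
    smiles = str(raw[cols["structure"]]).strip()
    if canonical_smiles(smiles) is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    try:
        parameter = Parameter(str(raw[cols["parameter"]]).strip())
    except ValueError:
        raise ValueError(f"unknown parameter: {raw[cols['parameter']]!r}")
    try:
        relation = Relation(str(raw[cols["relation"]]).strip())
    except ValueError:
        raise ValueError(f"unknown relation: {raw[cols['relation']]!r}")
    try:
        value = float(raw[cols["value"]])
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric value: {raw[cols['value']]!r}")
    if "units" in cols and not pd.isna(raw.get(cols["units"], np.nan)):
        unit = str(raw[cols["units"]]).strip()
        if unit not in _UNIT_TO_NM:
            raise ValueError(f"unknown unit: {unit!r}")
        value *= _UNIT_TO_NM[unit]
    if not value > 0:
        raise ValueError("nonpositive value")
    source = str(raw[cols["source"]]).strip().lower()
    if source not in _KNOWN_SOURCES:
        source = "other"
    label = None
    if "compound_label" in cols and not pd.isna(raw.get(cols["compound_label"], np.nan)):
        label = str(raw[cols["compound_label"]])
    return ActivityRecord(record_id, smiles, parameter, relation, value, source, label)


def merge_compounds(
    records: Iterable[ActivityRecord],
    best_value: str = "min",
) -> tuple[list[CompoundEntry], list[RejectedRecord]]:
    """Group records by canonical structure into per-compound entries.

    ``best_value_nM[p]`` aggregates the '='-relation measurements of parameter
    *p* for the compound (minimum by default, configurable to median).  The
    operation is idempotent: merging the output's own records reproduces the
    same entries.

    Records whose structure fails canonicalization go to the rejects list.
    """
    if best_value not in {"min", "median"}:
        raise ValueError("best_value must be 'min' or 'median'")
    by_key: dict[str, list[ActivityRecord]] = defaultdict(list)
    rejects: list[RejectedRecord] = []
    for record in records:
        key = canonical_smiles(record.structure)
        if key is None:
            rejects.append(RejectedRecord({"record_id": record.record_id,
                                           "structure": record.structure},
                                          "canonicalization failure"))
            continue
        by_key[key].append(record)

    entries = []
    for key in sorted(by_key):
        recs = by_key[key]
        best: dict[Parameter, float] = {}
        for p in Parameter:
            values = [r.value_nM for r in recs
                      if r.parameter == p and r.relation == Relation.EQ]
            if values:
                best[p] = float(min(values) if best_value == "min"
                                else np.median(values))
        entries.append(CompoundEntry(canonical_key=key, records=recs,
                                     best_value_nM=best))
    return entries, rejects


def classify_activity(
    entry: CompoundEntry,
    parameter: Parameter | str,
    threshold_nM: float = DEFAULT_THRESHOLD_NM,
) -> ActivityClass:
    """Label a compound active/inactive/undetermined for one parameter.

    Active iff the best determined value is strictly below the threshold;
    a value at the threshold exactly is inactive.  Bound-type records
    contribute evidence without a determined value: a '<'-record whose bound
    is below the threshold is active evidence, a '>'-record whose bound is at
    or above it is inactive evidence; bounds straddling the threshold leave
    the compound undetermined.
    """
    if not threshold_nM > 0:
        raise ValueError("threshold_nM must be positive")
    parameter = Parameter(parameter)
    if parameter in entry.best_value_nM:
        value = entry.best_value_nM[parameter]
        return ActivityClass.ACTIVE if value < threshold_nM else ActivityClass.INACTIVE
    lt_bounds = [r.value_nM for r in entry.records
                 if r.parameter == parameter and r.relation == Relation.LT]
    if lt_bounds and min(lt_bounds) < threshold_nM:
        return ActivityClass.ACTIVE
    gt_bounds = [r.value_nM for r in entry.records
                 if r.parameter == parameter and r.relation == Relation.GT]
    if gt_bounds and max(gt_bounds) >= threshold_nM:
        return ActivityClass.INACTIVE
    return ActivityClass.UNDETERMINED


def parameter_overlap(entries: Sequence[CompoundEntry]) -> VennCounts:
    """Venn-style counts of compounds by which parameters are determined.

    Each compound with at least one determined parameter is counted in exactly
    one subset cell; compounds with no determined parameter are not counted.
    """
    counts: dict[frozenset, int] = defaultdict(int)
    for entry in entries:
        subset = entry.determined_parameters()
        if subset:
            counts[subset] += 1
    return VennCounts(dict(counts))


def threshold_count(
    entries: Sequence[CompoundEntry],
    parameter: Parameter | str,
    cutoff_nM: float,
    chemotype: str | None = None,
    source: str | None = None,
) -> int:
    """Compounds whose best value for *parameter* is strictly below *cutoff_nM*.

    Optionally restricted to one chemotype class and/or to compounds with at
    least one record from the given source.
    """
    parameter = Parameter(parameter)
    n = 0
    for entry in entries:
        if chemotype is not None and entry.chemotype != chemotype:
            continue
        if source is not None and not any(r.source == source for r in entry.records):
            continue
        value = entry.best_value_nM.get(parameter)
        if value is not None and value < cutoff_nM:
            n += 1
    return n


def activity_distribution(
    entries: Sequence[CompoundEntry],
    parameter: Parameter | str,
    bin_edges_nM: Sequence[float],
) -> np.ndarray:
    """Histogram of best values over left-closed, right-open bins.

    Values outside [edges[0], edges[-1]) are not counted; use open-ended
    edges (0, inf) to capture everything.
    """
    edges = np.asarray(bin_edges_nM, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 values")
    parameter = Parameter(parameter)
    values = np.array([e.best_value_nM[parameter] for e in entries
                       if parameter in e.best_value_nM], dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    if len(values):
        idx = np.searchsorted(edges, values, side="right") - 1
        ok = (idx >= 0) & (idx < len(counts)) & (values < edges[-1])
        np.add.at(counts, idx[ok], 1)
    return counts


def collection_summary(
    entries: Sequence[CompoundEntry],
    threshold_nM: float = DEFAULT_THRESHOLD_NM,
) -> dict:
    """JSON-serialisable summary of a curated collection (counts, Venn, classes)."""
    venn = parameter_overlap(entries)
    summary: dict = {
        "n_compounds": len(entries),
        "n_records": sum(len(e.records) for e in entries),
        "venn": {"+".join(sorted(p.value for p in subset)): n
                 for subset, n in sorted(venn.counts.items(),
                                         key=lambda kv: sorted(p.value for p in kv[0]))},
    }
    for p in Parameter:
        classes = [classify_activity(e, p, threshold_nM) for e in entries]
        summary[p.value] = {
            "n_records": sum(1 for e in entries for r in e.records if r.parameter == p),
            "n_determined": venn.marginal(p),
            "n_active": sum(1 for c in classes if c == ActivityClass.ACTIVE),
            "n_inactive": sum(1 for c in classes if c == ActivityClass.INACTIVE),
            "below_100nM": threshold_count(entries, p, 100.0),
            "min_value_nM": min((e.best_value_nM[p] for e in entries
                                 if p in e.best_value_nM), default=None),
        }
    return summary


def write_collection(entries: Sequence[CompoundEntry], out_dir: str | Path,
                     threshold_nM: float = DEFAULT_THRESHOLD_NM) -> None:
    """Write curated collection CSV plus a JSON summary to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in entries:
        row = {"canonical_smiles": e.canonical_key, "n_records": len(e.records),
               "chemotype": e.chemotype}
        for p in Parameter:
            row[f"best_{p.value}_nM"] = e.best_value_nM.get(p)
            row[f"class_{p.value}"] = classify_activity(e, p, threshold_nM).value
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "collection.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(collection_summary(entries, threshold_nM), fh, indent=2)
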