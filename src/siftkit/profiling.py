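"""Group-level statistics on structural interaction fingerprints.

Given per-complex (or per-frame) SIFts this module computes the quantities a
contact-profiling study reports:

* per-residue contact frequencies within a compound group, and the
  frequent-contact positions rule (residues contacted by more than 60% of
  compounds in at least one group);
* the active-vs-inactive differential: the absolute difference between the
  fraction of interacting active compounds and the fraction of interacting
  inactive compounds, ranked per residue;
* the agonist-exclusion variant, which keeps only positions the reference
  agonist pose does not itself contact;
* per-residue Spearman rank correlation between per-compound interaction
  frequency (over trajectory frames) and the experimental activity value,
  with exact +/-1 sets reported;
* ligand RMSF over aligned trajectory frames;
* a descriptive concordance join against published mutagenesis effects.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interactions import SIFt
from .structures import Complex

__all__ = [
    "ContactProfile",
    "DifferentialResult",
    "CorrelationResult",
    "RmsfResult",
    "MutationEffect",
    "MutationRecord",
    "contact_frequency",
    "frequent_positions",
    "differential_contacts",
    "agonist_exclusion",
    "spearman_contact_activity",
    "ligand_rmsf",
    "mutagenesis_concordance",
    "read_mutation_table",
]


def _check_shared_panel(sifts: Sequence[SIFt]) -> list[str]:
    if not sifts:
        raise ValueError("need at least one SIFt (group frequency undefined for n=0)")
    panel = sifts[0].panel
    for s in sifts[1:]:
        if s.panel != panel:
            raise ValueError("SIFts do not share a residue panel")
        if s.scheme != sifts[0].scheme:
            raise ValueError("SIFts do not share an interaction-type scheme")
    return list(panel)


@dataclass
class ContactProfile:
    """Per-residue interaction frequencies for one group of compounds."""

    panel: list[str]
    frequencies: np.ndarray            # (len(panel),) collapsed, or (panel, types)
    n: int
    group_label: str = ""
    scheme: list[str] | None = None    # set when per-type

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies < 0) or np.any(self.frequencies > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        if self.frequencies.ndim != 1:
            raise ValueError("per-type profile; use to_dataframe()")
        return pd.Series(self.frequencies, index=self.panel, name=self.group_label)

    def to_dataframe(self) -> pd.DataFrame:
        if self.frequencies.ndim == 1:
            return self.to_series().to_frame()
        return pd.DataFrame(self.frequencies, index=self.panel, columns=self.scheme)


def contact_frequency(sifts: Sequence[SIFt], collapse_types: bool = True,
                      group_label: str = "") -> ContactProfile:
    """Fraction of SIFts with an interaction at each panel residue.

    With ``collapse_types`` (the default, matching residue-level reporting)
    a residue counts as contacted when any bit in its row is set; otherwise
    per-type frequencies are returned.
    """
    panel = _check_shared_panel(sifts)
    n = len(sifts)
    if collapse_types:
        stackv = np.stack([s.any_contact() for s in sifts])   # (n, panel)
        f = stackv.mean(axis=0)
        return ContactProfile(panel, f, n, group_label)
    stackm = np.stack([s.bits for s in sifts])                # (n, panel, types)
    return ContactProfile(panel, stackm.mean(axis=0), n, group_label,
                          scheme=list(sifts[0].scheme))


def frequent_positions(profiles: Sequence[ContactProfile],
                       threshold: float = 0.60) -> list[str]:
    """Residues whose frequency strictly exceeds ``threshold`` in >= 1 profile.

    The strict inequality follows the "more than 60% of compounds from at
    least one of the considered groups" convention; a residue at exactly the
    threshold is excluded.
    """
    if not profiles:
        return []
    panel = profiles[0].panel
    for p in profiles[1:]:
        if p.panel != panel:
            raise ValueError("profiles do not share a panel")
    hits = []
    for i, residue in enumerate(panel):
        if any(np.atleast_1d(p.frequencies[i]).max() > threshold for p in profiles):
            hits.append(residue)
    return hits


@dataclass(frozen=True)
class DifferentialResult:
    """Active-vs-inactive contact-frequency difference at one residue."""

    residue: str
    f_active: float
    f_inactive: float

    @property
    def delta(self) -> float:
        return self.f_active - self.f_inactive

    @property
    def abs_delta(self) -> float:
        return abs(self.delta)


def differential_contacts(active: Sequence[SIFt], inactive: Sequence[SIFt],
                          top_k: int | None = None) -> list[DifferentialResult]:
    """Per-residue |f_active - f_inactive|, ranked descending.

    Frequencies use the collapsed any-contact bit. Ties in |delta| are broken
    by panel order. ``top_k`` truncates the ranked list; the full table is
    always recoverable by omitting it.
    """
    if not active or not inactive:
        raise ValueError("both groups must be nonempty")
    fa = contact_frequency(active, group_label="active")
    fi = contact_frequency(inactive, group_label="inactive")
    if fa.panel != fi.panel:
        raise ValueError("groups do not share a residue panel")
    order = {r: i for i, r in enumerate(fa.panel)}
    results = [DifferentialResult(r, float(fa.frequencies[i]), float(fi.frequencies[i]))
               for i, r in enumerate(fa.panel)]
    results.sort(key=lambda d: (-d.abs_delta, order[d.residue]))
    return results[:top_k] if top_k is not None else results


def agonist_exclusion(diff: Sequence[DifferentialResult],
                      agonist_sift: SIFt) -> list[DifferentialResult]:
    """Drop differential positions the reference agonist itself contacts.

    Used when comparing agonists against inactives: a position only
    discriminates if the known agonist makes no contact there. Ranking order
    of the surviving entries is preserved.
    """
    contacted = {r for r, hit in zip(agonist_sift.panel, agonist_sift.any_contact())
                 if hit}
    return [d for d in diff if d.residue not in contacted]


class SignSet(str, enum.Enum):
    PLUS_ONE = "+1"
    MINUS_ONE = "-1"
    OTHER = "other"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation of contact frequency vs activity at one residue."""

    residue: str
    rho: float                  # NaN when undefined (constant frequency)
    n: int

    @property
    def sign_set(self) -> SignSet:
        if np.isnan(self.rho):
            return SignSet.UNDEFINED
        if self.rho == 1.0:
            return SignSet.PLUS_ONE
        if self.rho == -1.0:
            return SignSet.MINUS_ONE
        return SignSet.OTHER


def spearman_contact_activity(
    per_compound_freqs: Mapping[str, Mapping[str, float] | pd.Series],
    activities: Mapping[str, float],
) -> list[CorrelationResult]:
    """Per-residue Spearman rho between interaction frequency and activity.

    Compounds are matched by key; every compound needs an activity value and
    frequencies over a shared panel. Ties receive average ranks. Residues
    whose frequency is constant across compounds have no defined rank
    correlation and are reported with rho = NaN rather than zero, so the
    exact +/-1 sets are not polluted.
    """
    compounds = sorted(per_compound_freqs)
    if len(compounds) < 3:
        raise ValueError("need at least 3 compounds for a rank correlation")
    missing = [c for c in compounds if c not in activities]
    if missing:
        raise ValueError(f"compounds without activity values: {missing}")
    freq_df = pd.DataFrame({c: pd.Series(dict(per_compound_freqs[c]))
                            for c in compounds}).T
    if freq_df.isna().any().any():
        raise ValueError("per-compound frequencies do not share a panel")
    act = np.array([float(activities[c]) for c in compounds])
    results = []
    for residue in freq_df.columns:
        f = freq_df[residue].to_numpy(dtype=float)
        if np.all(f == f[0]) or np.all(act == act[0]):
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(f, act).statistic)
        results.append(CorrelationResult(str(residue), rho, len(compounds)))
    return results


@dataclass
class RmsfResult:
    """Ligand heavy-atom fluctuation over aligned trajectory frames."""

    per_atom_rmsf: np.ndarray
    n_frames: int

    @property
    def ligand_mean_rmsf(self) -> float:
        return float(np.mean(self.per_atom_rmsf))


def ligand_rmsf(aligned_frames: Sequence[Complex]) -> RmsfResult:
    """Per-atom RMSF of the ligand's heavy atoms about their mean positions.

    Frames must already be superposed on a receptor reference
    (``structures.superpose_frames``); RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2).
    """
    if len(aligned_frames) < 2:
        raise ValueError("need at least 2 frames for an RMSF")
    coords = np.stack([cx.ligand.heavy_coords() for cx in aligned_frames])
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    return RmsfResult(per_atom_rmsf=rmsf, n_frames=len(aligned_frames))


class MutationEffect(str, enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    LOSS = "loss"
    NO_CHANGE = "no_change"
    MIXED = "mixed"


#: effects counting as a consistent directional change in ligand binding
EFFECTFUL = frozenset({MutationEffect.INCREASE, MutationEffect.DECREASE,
                       MutationEffect.LOSS})


@dataclass(frozen=True)
class MutationRecord:
    """One published mutagenesis observation at a generic position."""

    residue: str                  # generic label, e.g. "3x32"
    substitution: str             # e.g. "D3x32A"
    effect: MutationEffect
    ligand_context: str | None = None

    def __post_init__(self) -> None:
        parts = self.residue.split("x")
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            raise ValueError(f"residue must be a generic label, got {self.residue!r}")


def read_mutation_table(path) -> list[MutationRecord]:
    """Read a mutagenesis CSV (generic_label, substitution, effect[, ligand])."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    records = []
    for _, row in df.iterrows():
        records.append(MutationRecord(
            residue=str(row[cols["generic_label"]]),
            substitution=str(row[cols["substitution"]]),
            effect=MutationEffect(str(row[cols["effect"]]).strip()),
            ligand_context=str(row[cols["ligand"]]) if "ligand" in cols else None))
    return records


@dataclass
class ConcordanceReport:
    """Descriptive join of flagged positions against mutagenesis effects."""

    per_residue: dict[str, str] = field(default_factory=dict)   # residue -> category
    flagged_effectful: list[str] = field(default_factory=list)
    flagged_no_data: list[str] = field(default_factory=list)
    effectful_unflagged: list[str] = field(default_factory=list)

    def summary_counts(self) -> dict[str, int]:
        return {"flagged_effectful": len(self.flagged_effectful),
                "flagged_no_data": len(self.flagged_no_data),
                "effectful_unflagged": len(self.effectful_unflagged)}


def mutagenesis_concordance(flagged: Sequence[str],
                            mutations: Sequence[MutationRecord]) -> ConcordanceReport:
    """Confront computationally flagged positions with mutagenesis outcomes.

    Purely descriptive (no significance test). A position is *effect-bearing*
    when at least one mutation there shows a consistent directional effect
    (increase, decrease or loss); positions with only mixed or no-change
    records are categorised as such. Generic labels are compared after
    stripping any amino-acid prefix (``D3x32`` and ``3x32`` are equal).
    """
    def norm(label: str) -> str:
        return label.lstrip("ABCDEFGHIKLMNPQRSTVWY") if "x" in label else label

    by_residue: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        by_residue.setdefault(norm(m.residue), []).append(m)

    report = ConcordanceReport()
    flagged_norm = [norm(r) for r in flagged]
    for raw, residue in zip(flagged, flagged_norm):
        recs = by_residue.get(residue)
        if not recs:
            report.per_residue[raw] = "no_data"
            report.flagged_no_data.append(raw)
        elif any(m.effect in EFFECTFUL for m in recs):
            effects = sorted({m.effect.value for m in recs})
            report.per_residue[raw] = "+".join(effects)
            report.flagged_effectful.append(raw)
        else:
            report.per_residue[raw] = "+".join(sorted({m.effect.value for m in recs}))
    flagged_set = set(flagged_norm)
    for residue, recs in sorted(by_residue.items()):
        if residue not in flagged_set and any(m.effect in EFFECTFUL for m in recs):
            report.effectful_unflagged.append(residue)
    return report


def plot_contact_profiles(profiles: Sequence[ContactProfile], path) -> None:
    """Grouped per-residue frequency bars (one colour per group) to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not profiles:
        raise ValueError("need at least one profile")
    panel = profiles[0].panel
    x = np.arange(len(panel))
    width = 0.8 / len(profiles)
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(panel)), 4))
    for k, p in enumerate(profiles):
        f = p.frequencies if p.frequencies.ndim == 1 else p.frequencies.max(axis=1)
        ax.bar(x + k * width, f, width, label=p.group_label or f"group {k}")
    ax.axhline(0.60, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(panel, rotation=90, fontsize=7)
    ax.set_ylabel("contact frequency")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_differential(diff: Sequence[DifferentialResult], path,
                      top_k: int = 15) -> None:
    """Ranked |delta| bars for the top differential positions, to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = list(diff)[:top_k]
    fig, ax = plt.subplots(figsize=(max(5, 0.5 * len(top)), 4))
    ax.bar([d.residue for d in top], [d.abs_delta for d in top],
           color=["tab:blue" if d.delta >= 0 else "tab:red" for d in top])
    ax.set_ylabel("|f_active - f_inactive|")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def differential_table(diff: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([{"residue": d.residue, "f_active": d.f_active,
                          "f_inactive": d.f_inactive, "delta": d.delta,
                          "abs_delta": d.abs_delta} for d in diff])


def correlation_table(corr: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{"residue": c.residue, "rho": c.rho, "n": c.n,
                          "sign_set": c.sign_set.value} for c in corr])
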