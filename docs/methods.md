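# Methods

This note records the models, conventions and numerical choices behind
siftkit, and what the synthetic generators do and do not emulate.

## Activity curation

A record is one measurement: SMILES, parameter ∈ {Ki, IC50, EC50}, relation
∈ {=, <, >}, value in nM, source. Values are normalised to nM at read time
(µM → ×1000 etc.). Compounds are keyed by RDKit canonical SMILES; a
compound's *best value* per parameter is the minimum over its `=`-relation
records (configurable to the median — the minimum matches the common
practice of quoting a compound by its best reported potency).

Activity classes use a potency threshold, default 1000 nM:

* active ⇔ best value **strictly below** the threshold;
* inactive ⇔ best value at or above it. The boundary case (exactly
  1000 nM) is classified inactive; the literature convention ("below
  1000 nM active, above inactive") leaves it open, and a strict `<` makes
  the rule reproducible.
* Bound-type records contribute evidence without a point value: a
  `< b` record with b below the threshold is active evidence, a `> b`
  record with b at or above it is inactive evidence; anything else leaves
  the compound undetermined. Patent series reported only as, e.g.,
  "Ki below 600 nM" are stored as `<`-relation records.

Histograms are left-closed/right-open; Venn counts place each compound in
exactly one subset cell of the parameters determined for it.

## Chemotype rules and clustering

Named chemical classes are the unit SAR papers report on, so the primary
classifier is an ordered SMARTS library (15 rules). Rule order encodes
priority and resolves embeddings — the ergoline tetracycle precedes the
tryptamine fragment it contains; acyl-substituted guanidines precede plain
guanidine patterns. Each rule is unit-tested to match its exemplar scaffold
and no other (an all-pairs identity matrix), which is the strongest
structural guarantee available: the original class memberships were assigned
manually, and rule priorities encode one defensible reading of classes with
overlapping chemistry, not the original authors' intent.

Similarity clustering is the fallback for unlabelled chemistry: Morgan
fingerprints (radius 2, 2048 bits), Tanimoto similarity, and a Butina
(leader/sphere-exclusion) loop with a fully specified tie-break — leaders
are chosen by descending neighbour count, then ascending canonical key — so
the partition is deterministic and input-order independent.

## Structures and geometry

* Coordinates are Å throughout; residues are keyed by (chain, author
  number, insertion code); trajectories are exchanged as multi-model PDB.
* GPCRdb generic numbers are **supplied as data** (chain,resnum,generic
  CSV), never computed: deriving them needs curated alignments. The bundled
  mapping file uses *synthetic* residue numbering (see its docstring) and
  exists for panel construction and tests. It includes position 5x46, which
  appears in the source literature in a typographically doubtful form
  ("5x461"); it is shipped but flagged, not vouched for.
* Pose RMSD is computed in place (no refit), because re-docking
  comparisons live in a single receptor frame. Symmetry-aware RMSD
  minimises over bond-graph automorphisms (element-labelled VF2),
  enumeration capped at 10,000 mappings; past the cap the identity matching
  is used with a warning. Benzene's 12 ring symmetries are the canonical
  test.
* Frame superposition is a least-squares rigid fit (Kabsch, via SciPy's
  rotation alignment) of each frame's reference selection — default
  receptor Cα — onto frame 0; the proper rotation plus translation is then
  applied to all atoms including the ligand.
* Ligand RMSF: RMSF_i = √(mean_t |x_i(t) − ⟨x_i⟩|²) over heavy atoms, on
  aligned frames; the reported per-ligand value is the mean over atoms.
  Under isotropic per-coordinate jitter σ the closed-form expectation is
  σ√3, used as a test oracle.

## Interaction typing and SIFt

The nine-type scheme is: contact, backbone_contact, sidechain_contact,
polar, hydrophobic, hb_protein_acceptor, hb_protein_donor, aromatic,
charged. Which variant the original SIFt studies used is not recoverable;
this classic set is adopted, and every output records the full cutoff
configuration so comparisons are explicit. Default cutoffs
(literature-standard, all configurable):

| type | criterion | default |
|---|---|---|
| contact | heavy–heavy distance | ≤ 4.5 Å |
| hydrophobic | apolar C···C | ≤ 4.5 Å |
| polar | N/O/S ··· N/O/S | ≤ 4.0 Å |
| hydrogen bond | donor-heavy ··· acceptor-heavy | ≤ 3.5 Å |
| (with explicit H) | D–H···A angle | ≥ 120° |
| charged | opposite charge-group centres | ≤ 4.0 Å |
| aromatic | ring centroid ··· centroid | ≤ 5.5 Å |

Docked poses commonly lack hydrogens; H-bond detection then degrades to the
distance criterion and the event carries a `no_H_mode` flag. Backbone =
{N, CA, C, O, OXT}. Tryptophan contributes both rings to aromatic
detection. Ligand features come from the bond graph: donors are N/O/S with
≥ 1 hydrogen (explicit or implicit by valence); acceptors are N/O with an
available lone pair (pyrrole-type and amide N excluded); charge groups come
from formal charges plus chargeable-group rules (guanidinium/amidinium and
aliphatic amines positive, carboxylates negative — the physiological-pH
reading); hydrophobes are carbons without N/O/S neighbours. Residue
features are a fixed atom-name table over the 20 standard amino acids;
nonstandard residues are skipped with a warning (configurable to error).

Encoding enforces a hierarchy: any typed event sets the residue's contact
bit, and H-bond/charged bits set the polar bit. Detection prunes candidate
residues with a k-d tree; the exhaustive all-pairs scan is kept as an
independent route (`method="brute"`) and the two are asserted equal in
tests — the pruning margin (max cutoff + 3 Å) covers group-centre offsets.

## Group statistics

Frequencies compare the collapsed any-contact bit by default, matching
residue-level reporting; per-type analysis is a flag. The frequent-contact
rule uses strict `>` 0.60. The differential report has no published cut for
"highest difference", so the default presentation is top-10 by |Δ| with the
full table always available. Spearman ρ is computed on raw activity values
(rank-based, so any strictly monotone transform — nM vs log-nM — gives the
same ρ; property-tested). Residues with constant frequency across compounds
have no defined rank correlation and are reported as NaN, never silently
zero, so the exact ±1 sets stay clean. With only three compounds ρ is
confined to {±1, ±0.5}, which is why the ±1 sets of small MD panels are
exact rather than approximate. The mutagenesis join is purely descriptive
(no significance test): a flagged position is *effect-bearing* when at
least one mutation there shows a consistent directional effect
(increase/decrease/loss); positions with only mixed or no-change records
are reported in their own category.

## Synthetic generators

What they emulate, and what they do not:

* **Activity tables** — log-normal nM values (defaults μ = ln 100,
  σ = 1.5 on the natural-log scale, spanning ~3 orders of magnitude as
  receptor SAR collections do), balanced 50/50 active/inactive groups by
  rejected resampling around the 1000 nM threshold, a 20% duplicate-record
  rate to exercise deduplication, and compounds built by decorating
  chemotype scaffold templates with random C/O/halogen substituents so the
  SMARTS rules recover the planted class. Not emulated: assay noise
  structure, inter-source systematic shifts, stereochemistry.
* **SIFt panels** — independent Bernoulli contacts: null residues at rate
  `null_p` (default 0.3) in both groups, planted residues at
  `null_p + Δ` (default Δ = 0.4 at one residue) in actives only, over a
  31-residue panel (the size of a typical annotated binding-site panel).
  Real contact panels are correlated across residues; independence makes
  the noise analysis exact but optimistic.
* **Pocket archetypes** — 1–3 residue pseudo-pockets from ideal-geometry
  side-chain templates (SER/ASP/LEU/PHE plus spectators), with a minimal
  rigid ligand placed so exactly one interaction archetype holds under the
  default cutoffs (H-bond at 2.9 Å, salt bridge at 3.5 Å group centres,
  ring stacking at 5.0 Å centroids, hydrophobic at 4.0 Å); a seeded random
  rigid motion de-aligns the scene from the axes. Real templates (not
  abstract spheres) are used so feature perception is exercised genuinely.
* **Trajectories** — receptor fixed; per frame the ligand stays in the
  contact pose with the planted persistence probability or is displaced
  12 Å along the pocket axis (beyond every cutoff), then Gaussian jitter
  (default σ = 0.2 Å per coordinate) is added. Not emulated: correlated
  frame-to-frame motion, receptor flexibility, solvent.

All generators split their random streams per component (seed sequences
keyed by a fixed component id), so adding a generator cannot shift existing
fixtures, and all return ground truth with the data.

Passing tests on these twins demonstrate that the statistics, geometry and
bookkeeping are correct — not that the pipeline's biological conclusions
transfer to any particular receptor; that depends on the quality of the
poses and trajectories supplied.

## Problem sizes and known limitations

Test and script problem sizes (200 random complexes for the detection
oracle, 100 replicates of the recovery experiment, 2000 frames for the RMSF
closed form) were chosen so each check's sampling error is far below its
assertion tolerance while the whole suite stays fast.

A note on the planted-recovery experiment: at Δ = 0.4, background 0.3 and
n = 50 per group over a 31-residue panel, the per-replicate probability
that the planted residue outranks all 30 null residues is ≈ 0.967 (the
planted |Δ| estimate has s.e. ≈ 0.09 while the maximum null |Δ| is
typically ≈ 0.2), so recovery rates of 94–97/100 are the expected outcome
of a correct implementation, not a defect; at n = 200 per group recovery
is 100/100. The acceptance script reports both rates.

Other limitations: no water-mediated or metal contacts, no halogen-bond or
cation-π typing (the scheme is the classic nine types), no protonation-state
assignment, no docking or force-field dynamics, and PDB-embedded ligands
get distance-perceived single bonds only (bond orders are not recoverable
from PDB).
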