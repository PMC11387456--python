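# siftkit

Tools for asking a structure-based SAR question about a G protein-coupled
receptor: **which binding-site residues distinguish active from inactive
ligands?** The package was built around the serotonin 5-HT5A receptor — a
target whose ligand collection spans ChEMBL records, hand-extracted patent
series and PDSP entries — but every component is generic over receptor and
ligand set.

The pipeline has four stages:

1. **Curation** (`siftkit.ligand_db`). Multi-source activity tables
   (Ki / IC50 / EC50 in nM, with `=`, `<`, `>` relations) are validated,
   normalised, and deduplicated on RDKit canonical SMILES. A compound is
   *active* for a parameter when its best value is strictly below a potency
   threshold (default 1000 nM) and *inactive* at or above it; bound-type
   records (`Ki < 600 nM`, common in patents) contribute class evidence
   without a point value. Summaries cover per-parameter Venn overlaps,
   threshold counts and value histograms.
2. **Chemotypes** (`siftkit.chemotypes`). An ordered SMARTS rule library
   names the recurring scaffolds of serotonergic medicinal chemistry
   (acylguanidines, 2-aminoquinolines, benzoxazines, ergolines, ...);
   Butina (sphere-exclusion) clustering on Morgan-fingerprint Tanimoto
   similarity groups whatever the rules do not cover.
3. **SIFt encoding** (`siftkit.structures`, `siftkit.interactions`).
   Receptor PDB files and ligand poses are combined into complexes, residues
   carry GPCRdb generic numbers ("3x32" = helix 3, position 32), and each
   complex is encoded as a structural interaction fingerprint: a binary
   residue × interaction-type matrix over the classic nine types (contact,
   backbone/side-chain contact, polar, hydrophobic, H-bond in either
   direction, aromatic, charged) under explicit geometric cutoffs.
4. **Profiling** (`siftkit.profiling`). Group statistics on SIFts:
   per-residue contact frequencies *f*; the frequent-contact rule
   (*f* > 0.60 in at least one group); the differential
   Δ(r) = f_active(r) − f_inactive(r) ranked by |Δ|; an agonist-exclusion
   filter; per-residue Spearman ρ between per-compound contact frequency and
   activity; ligand RMSF over Kabsch-superposed trajectory frames; and a
   descriptive concordance join against published mutagenesis effects.

Because docked poses and MD trajectories from commercial engines cannot be
shipped, `siftkit.synthetic_data` generates statistical twins of every input
— decorated-scaffold activity tables, Bernoulli contact panels with planted
frequency differences, toy 3D pockets built from ideal side-chain geometry,
and jittered trajectories with planted contact persistence — each returning
its ground truth so the whole pipeline is testable end to end.

## Worked example

Plant a 0.4 contact-frequency difference at residue `p004` of a 10-residue
panel (background rate 0.3, 50 compounds per group) and recover it:

```python
from siftkit.synthetic_data import SyntheticSpec, simulate_sift_panel
from siftkit.profiling import differential_contacts, differential_table

spec = SyntheticSpec(seed=7, n_active=50, n_inactive=50,
                     planted_deltas={"p004": 0.4}, null_p=0.3)
active, inactive, truth = simulate_sift_panel(spec, panel_size=10)
diff = differential_contacts(active, inactive, top_k=5)
print(differential_table(diff).to_string(index=False))
```

```
residue  f_active  f_inactive  delta  abs_delta
   p004      0.64        0.26   0.38       0.38
   p008      0.36        0.20   0.16       0.16
   p009      0.32        0.24   0.08       0.08
   p001      0.30        0.36  -0.06       0.06
   p006      0.26        0.20   0.06       0.06
```

The planted residue tops the ranking with an estimated |Δ| of 0.38 against
a true 0.4; the remaining rows are binomial noise around the shared 0.3
background rate (two-sample s.e. ≈ 0.09 at n = 50), which is why unplanted
residues can show differences up to ~0.2.

A shell session covering the same ground:

```bash
siftkit curate --input activity.csv --threshold 1000 --out curated/
siftkit sift --receptor complex.pdb --mapping mapping.csv --out sift.csv
siftkit profile --active a1.csv --active a2.csv --inactive i1.csv --out diff.csv
siftkit simulate --archetype ionic --seed 4 --n-frames 100 --out fixtures/
```

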