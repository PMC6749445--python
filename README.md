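# strainscope

Geometric-strain analysis for ultrahigh-resolution protein structures.

Very high resolution X-ray structures resolve real deviations from textbook
geometry: bent aromatic rings, twisted arginine guanidinium groups,
non-planar peptide bonds, weak C–H…O hydrogen bonds and strongly anisotropic
atomic displacements. `strainscope` turns those observations into a reusable,
testable pipeline applicable to any PDB/mmCIF coordinate file:

* **Bending angles** — residue-type-specific planarity metrics:
  * Arg: signed torsion Cδ–Nε–Cζ–Nη1 (ideal 0°), with automatic
    normalization of swapped η-nitrogen names;
  * Phe: 180° − angle(Cβ, Cγ, Cζ) (ideal 0°);
  * Trp: signed pseudo-torsion Cβ–Cγ–Cε2–Cζ3 (ideal 0°);
  * Tyr: [180° − angle(Cβ,Cγ,Cζ)] + [180° − angle(Cβ,Cζ,Oη)] (ideal 0°).
* **ω scan** — peptide-bond torsion CA(i)–C(i)–N(i+1)–CA(i+1), reported as a
  signed deviation from the nearest ideal (trans 180° / cis 0°).
* **Weak hydrogen bonds** — riding-hydrogen placement (C–H 1.09 Å,
  N–H 1.01 Å), N–H…O and C–H…O detection, H-bond-based secondary-structure
  assignment, and capping-motif classification (sheet extension, β-turn
  i→i+3 side-chain caps, helix i+3/i+4 caps).
* **ADP anisotropy** — eigen-analysis of ANISOU tensors; per-atom anisotropy
  (smallest/largest eigenvalue, 1 = isotropic), group means over
  protein/ligand/solvent, and a principal-axis field export for visualizing
  concerted motions.
* **Synthetic fixtures** — a generator that builds residues and
  secondary-structure elements with *exactly known* geometry (prescribed
  twists, bends, ω values and anisotropy ratios), so every metric is
  validated by construction closure.

Default outlier thresholds (ours, configurable): |arg twist| ≥ 6°,
Phe bend ≥ 5°, |Trp bend| ≥ 5°, Tyr bend ≥ 6°, |ω deviation| ≥ 10°.
Default H-bond criteria (ours, configurable): C–H…O d(H…O) ≤ 2.8 Å,
d(C…O) ≤ 3.8 Å, θ ≥ 110°; N–H…O d(H…O) ≤ 2.5 Å, d(N…O) ≤ 3.5 Å, θ ≥ 120°.
Deuterium is treated as hydrogen throughout; geometry uses one conformer per
residue (highest-occupancy altloc); group ADP statistics exclude H/D and
non-positive-definite tensors by default (counts reported).

## Command line

```sh
strainscope fixtures --out fixtures/ --seed 0      # synthetic test suite + manifest
strainscope bend    INPUT.pdb ...                  # bending-angle report (TSV)
strainscope omega   INPUT.cif ...                  # omega-deviation report
strainscope chbonds INPUT.pdb ...                  # H-bond report + motif counts
strainscope aniso   INPUT.cif --axes axes.pml      # ADP group means + axis export
strainscope all     INPUT... --config cfg.txt --out reports/
```

`all` writes per-structure TSV/JSON reports plus a cross-structure outlier
summary sorted by |value|. Configuration is a plain `key = value` file; see
`strainscope.config.AnalysisConfig` for every setting and its default.
Reports are deterministic (fixed sort orders, no timestamps).

## Library example

```python
from strainscope import read_structure, scan_structure, flag_outliers

model = read_structure("data/6s2m.cif")
measurements, counts = flag_outliers(scan_structure(model))
for m in measurements:
    if m.is_outlier:
        print(m.residue_label, m.metric, round(m.value, 1))
```
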