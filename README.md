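# alphasheet

Design and characterization toolkit for **α-sheet hairpin peptides** —
non-standard secondary structure in which the backbone (φ, ψ) dihedrals
alternate between the right-handed (α_R, lower-left Ramachandran quadrant)
and left-handed (α_L, upper-right quadrant) helical conformations. Unlike a
β-strand, whose carbonyls alternate faces, an α-strand aligns **all N–H
groups on one face and all C=O groups on the other**, giving the sheet a
molecular dipole. α-sheet is hypothesized to be the structure of the toxic
soluble oligomers formed early in amyloid aggregation, and peptides designed
to adopt it (using alternating L- and D-amino acids to stabilize the
alternating α_R/α_L backbone) act as aggregation inhibitors.

The package is aimed at structural bioinformaticians and peptide designers
who need to:

- **build** idealized α-sheet and β-sheet hairpin backbones (linear
  single-turn or cyclic two-turn) from internal coordinates, with D-residue
  chirality, amide and α protons, and exact dihedral round-trips;
- **detect** α-strand conformation: Ramachandran quadrant classification,
  maximal alternating α_L/α_R runs, carbonyl/amide alignment order
  parameters in [0, 1];
- **score** designs over conformational ensembles by hydrogen-bond
  occupancy — the fraction of frames in which each template hydrogen bond
  satisfies the geometric criteria — with mean Cα RMSD (Kabsch) as
  tie-breaker;
- **rank** candidate sequences by summed log conformational propensity
  (with D-amino-acid tables obtained from L tables by the mirror rule
  P_D(region) = P_L(mirror(region))) under polar/nonpolar composition
  constraints;
- **predict NOE patterns** via ensemble-averaged effective distances
  d_eff = ⟨r⁻⁶⟩⁻¹ᐟ⁶: short sequential d_NN is the α-sheet signature, short
  sequential d_αN the β-sheet signature;
- **quantify assays and spectra**: Congo red relative binding
  rCb = A₅₄₀/25295 − A₄₇₇/46306, ThT percent inhibition, Beer–Lambert
  concentrations, Savitzky–Golay smoothing/second derivatives, amide-I band
  assignment (α-sheet = paired ~1640 and 1675–1680 cm⁻¹ minima), CD molar
  ellipticity conversion.

A `fixtures` module generates every input synthetically (jittered-dihedral
ensembles, sigmoidal aggregation kinetics, Gaussian-band spectra), so the
whole pipeline runs without external data.

## Worked example

```python
import numpy as np
from alphasheet import (TemplateSpec, make_ideal_template, classify_chain,
                        detect_alpha_strands, predict_pattern,
                        ConformationalEnsemble, JitterSpec, generate_ensemble,
                        find_hbonds, score_design)
from alphasheet.design import ALPHA_SHEET, BETA_SHEET

alpha = make_ideal_template(TemplateSpec(conformation=ALPHA_SHEET))   # 14 residues
beta  = make_ideal_template(TemplateSpec(conformation=BETA_SHEET))

print(alpha.sequence)                       # AaAaAaGGAaAaAa  (lowercase = D)
print(len(detect_alpha_strands(classify_chain(alpha))))   # 2
print(len(detect_alpha_strands(classify_chain(beta))))    # 0

va = predict_pattern(ConformationalEnsemble(frames=[alpha]))
vb = predict_pattern(ConformationalEnsemble(frames=[beta]))
print(va.verdict, round(va.median_dnn, 2))  # ALPHA_SHEET_LIKE 2.74
print(vb.verdict, round(vb.median_dnn, 2))  # BETA_SHEET_LIKE 4.41

ens = generate_ensemble(JitterSpec(template=TemplateSpec(), sigma=5.0,
                                   n_frames=100, seed=1))
print(round(score_design(ens, alpha).mean_template_occupancy, 2))  # 0.65
```

The α template's sequential amide–amide distance (2.74 Å, a strong NOE)
versus the β template's (4.41 Å, unobservable) is the quantitative core of
the α/β discrimination: α-sheet gives strong sequential d_NN crosspeaks,
β-sheet does not.

A CLI mirrors the library (`alphasheet build|detect|score|design|noe|assay|spectra|fixtures`):

```bash
alphasheet build --spec alpha --strand-len 6 --out alpha.pdb
alphasheet noe --in alpha.pdb
```

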