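# Methods

## The α-sheet model

An α-strand is a backbone whose (φ, ψ) dihedrals alternate strictly between
the α_R conformation (φ < 0, ψ < 0) and the α_L conformation (φ ≥ 0, ψ ≥ 0).
Although each residue is locally helical, the alternation produces an
extended chain whose peptide carbonyls all point to one face and whose amide
N–H groups all point to the other — the opposite of a β-strand, where these
groups alternate. The toolkit operationalizes this picture three ways:

1. **Classification.** The Ramachandran map is partitioned into the four
   sign quadrants — β (φ<0, ψ≥0), α_R (φ<0, ψ<0), α_L (φ≥0, ψ≥0) and
   mirror-β (φ≥0, ψ<0) — half-open at 0° (boundaries belong to the
   nonnegative side). Undefined or non-finite angles map to UNDEFINED,
   never raise. Arbitrary polygonal regions can be substituted when finer
   boundaries are needed. Because the quadrant boundaries form an
   inversion-invariant set while their labels must swap under inversion,
   the mirror law classify(−φ,−ψ) = mirror(classify(φ,ψ)) holds everywhere
   *except* exactly on a boundary; grids used to verify the law are placed
   at half-degree offsets.
2. **Strand detection.** Maximal runs of strictly alternating α_L/α_R
   labels of length ≥ 4 (configurable). In a linear idealized hairpin the
   first and last residues have undefined φ or ψ, so a terminal strand of
   n residues is detected over its n−1 classifiable residues; cyclic chains
   have no such truncation.
3. **Alignment order parameters.** The norm of the mean unit C→O (and N→H)
   vector over a segment: 1 for perfect alignment (α-strand ≈ 0.94 for the
   default template), ≈ 0 for alternating β carbonyls.

## Backbone construction

Chains are built by sequential internal-coordinate (NeRF-style) placement
from per-residue (φ, ψ, ω), with Engh–Huber-style constants (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, C–O 1.231 Å, N–H 1.010 Å, CA–CB 1.530 Å;
standard backbone angles), all configurable. ω defaults to 180° (trans) and
is never silently bent; cis bonds must be requested explicitly. Torsions
follow the IUPAC sign convention in (−180, 180], validated against
biotite's dihedral implementation; round-trips measure-after-build agree to
≈ 1e-13°.

Chirality lives in a per-residue L/D flag (glycine is achiral) *and* in the
dihedral signs; the backbone build itself is chirality-agnostic, and only
CB/Hα placement consults the flag. CB sits at the two-cone intersection
(∠N–CA–CB = 110.5°, ∠C–CA–CB = 110.1°) on the side of the N/CA/C plane
matching CCD ideal alanine; D residues take the mirror side. Hα completes
the tetrahedron opposite CB; glycine carries both completions (HA2/HA3).
The amide H is placed in the peptide plane at ∠C–N–H = 119°, trans to the
preceding carbonyl O. Building a chain with all chirality flags flipped and
all dihedrals negated reproduces the point inversion of the original to
≈ 1e-14 Å RMSD.

Cα RMSD uses Kabsch superposition (SVD with determinant correction, no
reflections), implemented directly because the generic quaternion aligner
leaves ~1e-7 Å residuals on exactly congruent sets where this application
wants true zeros.

## Idealized templates

The default ideal dihedrals are α_R (−60, −45), α_L (60, 45), β (−120, 130)
— points chosen inside the respective quadrants; the literature specifies
the regions, not numeric values, so these are library defaults, not
published constants. Hairpins are strand–turn–strand (single turn, linear)
or strand–turn–strand–turn (cyclic); strand parity puts α_R (L residues) at
odd positions and α_L (D residues) at even ones. β-hairpins close with a
type I′ turn, (60, 30) and (90, 0). For the α-hairpin no turn type is
established; the default, (50, −10) and (170, −10), was selected once by a
coarse 20°-grid search over the β/mirror-β quadrants (so turn residues can
never extend a detected strand) for the two-residue turn that closes the
idealized α-hairpin best — six cross-strand hydrogen bonds and the most
compact strand pairing. Cyclic closure is *reported* (the C-terminal→
N-terminal gap in `metadata['closure_gap']`), never optimized: cyclization
through a non-ideal turn is a known source of distortion and no closure
algorithm is part of the model.

## Hydrogen-bond occupancy scoring

Default criteria (angle mode): H···O ≤ 2.6 Å and ∠N–H···O ≥ 120°;
a distance-only mode (N···O ≤ 3.5 Å) serves proton-free structures. Both
are common conventions; no specific cutoff is canonical for this system, so
they are explicit configuration. The design score is the mean, over the
hydrogen bonds detected in the candidate's own idealized template, of the
fraction of ensemble frames (frame weight) in which the bond still holds,
plus the weighted mean per-frame Cα RMSD to the template. Ranking is
lexicographic — higher occupancy first, lower RMSD on ties — rather than a
weighted sum, because RMSD is a qualitative monitor, not a calibrated
energy. Uniform-weight ensembles use exact integer counting so occupancies
are exact rationals.

## Sequence ranking

Candidates are enumerated from per-position residue sets; chirality is
imposed by the template (D at α_L positions, L at α_R/β positions, glycine
free), the composition constraint keeps the strand polar fraction within
[0.4, 0.6] by default (polar set S,T,N,Q,D,E,K,R,H,Y), and the score is
Σ log P(code, chirality → target region) from a propensity table.
Zero-probability entries score −∞ and rank last; ties break
lexicographically. D-residue tables derive from L tables by the mirror rule
P_D(code, region) = P_L(code, mirror(region)) — an involution that fixes
glycine. Refinement is deliberately manual (rank → evaluate → edit →
re-rank); no automated mutation search is provided.

## NOE effective distances

For a proton pair, d_eff = (Σ_f w_f r_f⁻⁶)⁻¹ᐟ⁶ over ensemble frames — the
quantity proportional to NOE intensity, dominated by the shortest
conformers, and bounded between the minimum and the arithmetic-mean frame
distance (power-mean inequality, enforced as an invariant). Glycine Hα
pairs yield two measurements (HA2, HA3). Intensity buckets: strong < 2.7 Å,
medium < 3.5 Å, weak < 5.5 Å, else none (half-open at each edge; standard
qualitative NOE classes).

The pattern verdict over strand residues is:
ALPHA_SHEET_LIKE iff median sequential d_NN ≤ 3.0 Å and the median
sequential d_αN is not shorter than the median intraresidue d_αN;
BETA_SHEET_LIKE iff median sequential d_αN ≤ 2.6 Å and median sequential
d_NN ≥ 4.0 Å; otherwise MIXED_OTHER. The long-range census lists all HN/Hα
pairs with |i−j| ≥ 3 under 5.5 Å as evidence. **Calibration caveat:** an
α-helix also has short sequential d_NN; the rule discriminates the two
sheet types (D/L-alternating designs cannot be helical) and is documented
as out-of-calibration for helical input rather than silently extended.
On the default templates the medians are d_NN 2.74 Å (α) vs 4.41 Å (β) and
sequential d_αN 3.58 Å (α) vs 2.16 Å (β), matching the canonical NMR
fingerprints.

## Assay quantification

- Congo red: rCb = A₅₄₀/25295 − A₄₇₇/46306 (constants configurable);
  negative values are reported, not clipped. Curves are normalized by the
  reference value at an anchor time (48 h for the TTR protocol), linearly
  interpolated if needed; both divide-then-anchor and subtract-then-anchor
  orders are expressible since baseline handling is explicit.
- Percent inhibition: 100·(1 − (treated(t)−b)/(control(t)−b)) at an anchor
  time (12 h for the ThT protocol is a config default). The baseline b
  defaults to the control's value at the treatment start, which also
  supports the pre-aggregated "remaining aggregation" variant via an
  explicit b. With the synthetic sigmoid fixtures the injected inhibition
  is recovered exactly when b is the generator's true baseline; the
  sigmoid's small tail at t = 0 makes the default-baseline estimate high by
  a few tenths of a point.
- Beer–Lambert: c = A/(ε·l)·dilution, with ε₂₂₀ = 50 000 cm⁻¹·M⁻¹ as the
  Aβ default.
- Savitzky–Golay: least-squares convolution (scipy coefficients), window
  odd and > order, uniform grid required; derivatives scaled by spacing.
  Output is truncated to the valid interior — instrument-style, no
  padding (a flag can re-enable padding in future; none is default). A
  12-point request is rejected with guidance to use 13.
- Amide-I assignment: local minima of the second derivative deeper than
  3× the MAD of the out-of-band signal become bands; windows are β
  1620–1640, helix 1650–1658, turn 1666–1674, α-sheet-low 1636–1644,
  α-sheet-high 1675–1680 cm⁻¹ (all configurable). The verdict is
  ALPHA_SHEET only when *both* signature minima (≈1640 and 1675–1680) are
  present — the 1640 window alone overlaps β and is not diagnostic.
- CD: [θ] = θ_mdeg/(10·c·l), optionally per-residue; the molar vs
  mean-residue ambiguity is resolved by an explicit mode flag.

## Synthetic fixtures: what they do and do not emulate

`generate_ensemble` jitters template φ/ψ with independent Gaussian noise
(sd σ) and rebuilds the chain, so every frame is a geometrically valid
peptide — the property MD frames share. ω is held at its template value
(peptide bonds are far stiffer than φ/ψ). The model has **no** energetics:
no correlated motions, no side chains beyond CB, no solvent, no rare-event
transitions between basins. Tests passing on these fixtures demonstrate
the *analysis* machinery (counting, averaging, ranking, discrimination),
not that any particular sequence folds. Kinetics fixtures are logistic
sigmoids, signal = baseline + amplitude·(1−inhibition)·σ((t−t50)/τ), with
optional Gaussian noise — they emulate the shape of dye-binding aggregation
curves, not nucleation-growth mechanism. Spectra are sums of negative
Gaussians on a 1 cm⁻¹ grid (second-derivative-like) plus noise. All
generators are pure functions of (spec, seed). Default fixture conditions:
σ ∈ {0, 5, 15, 30}°, 100 frames, 5 seeds for the occupancy–jitter curve;
kinetics baseline 0.05, amplitude 1.0, t50 12 h, τ 2.5 h, noise sd 0.01
(1% of amplitude); spectral noise sd 0.005–0.01 of band depth.

## Numerical choices

- Angles: degrees, (−180, 180], wrap at ±180 mapped to +180.
- Modal-label ties break by the fixed order α_R < α_L < β < mirror-β <
  UNDEFINED; ranking ties break lexicographically on the sequence string.
- PDB coordinates are written at the format's 1e-3 Å precision; D residues
  are written with standard L names plus a chirality sidecar TSV for
  maximal reader compatibility (D names like DAL are honored on read).
- Superposition requires ≥ 3 points; ensembles require topology-identical
  frames and weights normalized to 1 (nonnegative).
- Problem sizes in the test-suite and acceptance script (14-residue
  hairpins, 100-frame ensembles, 5 seeds, 1000-sample sandwich checks,
  1°-grid mirror checks) were chosen as the smallest sizes at which each
  property is sharply decided.

## Known limitations

- No MD engine, force field or water model: ensembles are inputs or
  synthetic.
- No NOESY spectrum simulation (mixing time, spin diffusion), chemical
  shifts, or solution-structure calculation.
- No side chains beyond CB, no energy minimization, no cyclic-closure
  optimization.
- The pattern rule is uncalibrated against α-helix (see above), and the
  wet-lab inhibition percentages of real peptide/protein systems depend on
  physical samples that arithmetic cannot reproduce.
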