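# Methods

This note documents the models, defaults and numerical choices behind
`fgtools`, and what the synthetic generators do and do not emulate.

## Structural data model and I/O

Structures are read with gemmi (PDB v3.3 and mmCIF) into a plain
chain → residue → atom hierarchy.  Only model 1 of multi-model files is
kept, waters are dropped, and alternate locations are collapsed to a single
conformer (highest occupancy; ties broken by altloc letter) so that all
downstream energetics are single-conformer and deterministic.  Hydrogens are
parsed and flagged but excluded from accessibility and energy calculations:
deposited fibril models are heavy-atom models, and the solvation-parameter
formalism is defined on heavy atoms.

Author residue numbering is preserved verbatim and all intervals are 1-based
inclusive; BED output converts to 0-based half-open only at the writer.

Van der Waals radii never come from coordinate files; they are assigned from
named tables shipped with the package (default `bondi1964`: H 1.20, C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80 Å).  Missing elements raise an error naming
the atom rather than silently defaulting.

## Sequence features

Motif patterns are fixed letters plus `X` wildcards; matches may overlap,
which matters in repeat-dense low-complexity sequences (`FGFGFG` contains
three FG motifs).  The census distinguishes canonical GLFG from "GLFG-like"
motifs, whose default definition is XLFX (any residue, Leu, Phe, any
residue) — chosen because naturally occurring variants such as SLFS behave
like GLFG motifs; the pattern is a configurable argument, not a claim about
any particular published counting rule.

Composition profiles use ten residue classes (ILVM hydrophobic, FYW
aromatic, KRH positive, ED negative, QN amide-polar, ST hydroxyl-polar, and
G/P/A/C singletons).  Windows are centred and truncated at the edges; per
position the class fractions are normalised by the number of classified
letters in the window, so rows sum to 1 wherever any classified residue is
present.

## Soluble fraction and peptide tiling

The soluble fraction of a condition is the ratio of its amide-region
spectral integral to a fully soluble reference.  The only uncertainty
statement available for such integrals is a signal-to-noise ratio, so the
relative error of an integral is taken as 1/SNR and the ratio error follows
by quadrature: σ_f = f·sqrt(SNR_c⁻² + SNR_r⁻²).  Ratios above 1 (possible
under noise) are clipped to 1 with a warning; the uncertainty is kept from
the unclipped value.

Per-residue aggregation propensity is the **unweighted mean** of the
aggregated fractions of all peptides covering the position — no length or
coverage weighting, matching the plain-averaging definition of the assay.
Positions covered by no peptide carry an explicit undefined marker, never 0,
since 0 is a valid propensity.  The standard error at a position is the
standard error of the covering values (0 for a single peptide); percentile
bootstrap over peptides (seeded, deterministic) provides confidence bands.

Because the covering-peptide set is constant over runs of ~step residues,
the estimated profile is piecewise constant and a raw argmax can sit
anywhere on a plateau.  Peak positions are therefore reported as the
centroid of positions weighted by their excess over the half-maximum level
within a search window (`peak_center`), which is robust to plateaus and to
tie-breaking noise.

### Resolution of the tiling estimator

With 40-residue peptides stepping by 20, averaging over covering peptides is
a smoothing operator with an effective window of ~60 residues.  A planted
truth must vary slowly on that scale for the estimator to be nearly
unbiased: for two Gaussian bumps, the zero-noise bias RMSE is 0.050 at bump
sd 35 but 0.035 at sd 55.  The synthetic-assay default truth therefore uses
bumps of sd 55 at residues 100 and 310 (amplitudes 0.55 and 0.65 over a 0.15
baseline, the C-terminal region stronger), for which recovery at the assay's
σ = 0.02 noise is comfortably within an RMSE of 0.05 on covered positions.
This is a statement about the estimator's resolution, not about any real
domain's propensity landscape.

## Helical geometry

A fibril is modelled as layers related by a screw motion (rise Δz, twist Δφ
about the fibril axis).  Conventions: rise > 0 along the layer-ascending
axis; twist signed, negative = left-handed; crossover is the half-turn
length, `crossover = 180 × rise / |twist|`, because a cross-β fibril's
projected appearance repeats every 180° (e.g. 715 Å at 4.75 Å rise ↔
|twist| 1.20°).  An untwisted stack reports an infinite crossover.

**Layer detection.**  Chain centroids are projected onto each principal axis
of the Cα cloud; an axis is accepted when the projections split into groups
whose median spacing lies in the cross-β stacking range (default 3.0–6.5 Å)
and scored by the ratio of the smallest between-group gap to the largest
within-group spread.  The rise prior resolves the geometric ambiguity
between the stacking direction (~4.7 Å repeat) and the in-plane sheet-packing
direction (~9–10 Å between chain axes); when no direction qualifies, the
model is one layer whose axis is the thin direction of the Cα cloud.  Both
the gap threshold and the rise range are parameters for unusual geometries.

**Orientation.**  A chain's direction is its Cα end-to-end vector; chains are
parallel/antiparallel by the sign of the projection onto the first chain's
direction.  Chains with fewer than 4 Cα get an explicit `undefined` label
with a warning.

**Rise/twist estimation.**  Chains of consecutive layers are matched by
in-plane centroid proximity (greedy nearest-neighbour, ties by chain id);
matched chains contribute Cα pairs for residues present in both.  The
least-squares rigid transform (Kabsch, SVD with determinant correction) of
layer *i* onto *i+1* is screw-decomposed: the rotation axis comes from the
rotation vector, oriented along the layer-ascending fibril axis; twist is
the signed angle and rise the translation component along that axis (which
is invariant to the choice of axis point).  The mean ± sd over all
consecutive pairs is reported.  Handedness is preserved under any rigid
transformation of the whole model.  Depositions with a single layer cannot
be superposed; helical parameters are then read from mmCIF
`_em_helical_entity` metadata and flagged `source="metadata"`.

## SASA and solvation energetics

SASA uses the Shrake–Rupley construction: points on the expanded sphere
(vdW + probe, default probe 1.4 Å) are tested against neighbours' expanded
spheres; the accessible area is the exposed fraction times the expanded
sphere's area.  The point set is a spherical Fibonacci grid — deterministic,
no RNG — rotated per atom by a Kronecker sequence of Euler angles so that
quadrature errors of neighbouring atoms are decorrelated and summed areas
converge faster (total area changes by <0.5 % between 960 and 3840 points on
the test fixtures; 960 is the default).  Isolated-atom areas match
4π(r+probe)² to quadrature accuracy, and two-sphere configurations match the
analytic spherical-cap formula.

Energies follow the atomic-solvation-parameter model: ΔG(atom) =
ASP(class) × SASA(atom), classes carbon / neutral N / neutral O / charged O
(Asp, Glu carboxylates, OXT) / charged N (Lys NZ, Arg guanidinium) / sulfur.
The default parameter set is Eisenberg & McLachlan (1986): 16, −6, −6, −24,
−50, 21 cal·mol⁻¹·Å⁻², stored as a provenance-labelled data file; other sets
can be dropped in.  Histidine is treated as neutral.  Parameters are stored
in cal·mol⁻¹·Å⁻² and converted to kcal/mol at exactly one place.

**Stabilization energy.**  For an odd N-layer context (5 for planar-layer
fibrils, 9 when layers are less planar and reach further), the per-residue
stabilization energy is ΔΔG = G_solv(residue in the N-layer assembly) −
G_solv(residue in a reference state), evaluated for every chain of the
middle layer; the headline number is the arithmetic mean over those
residues.  Two reference states are implemented because published
solvation-energy pipelines differ here and the exact choice is often
unstated:

* `isolated_conformer` (default) — the residue's whole chain alone in its
  fibril conformation; ΔΔG then measures stabilization by *assembly*.
* `tripeptide` — the residue with only its two chain neighbours, excised in
  conformation; a near-fully-exposed reference that also counts burial by
  the chain's own distant residues.

On the synthetic fibril both modes agree to ~0.01 kcal/mol per residue; on
real, side-chain-complete models they can differ more, so both are reported
by the analysis driver.  Stabilizing patches are maximal runs of positions
(means over the middle-layer chains) at or below a threshold, merged across
single-position gaps; a 25th-percentile threshold reproduces planted dips on
constructed profiles.

## Synthetic generators

All generators take explicit seeds, use `numpy.random.default_rng`, and are
byte-deterministic; no global RNG state is touched.

* **β-stack**: extended pseudo-chains (N, Cα, C, O, Cβ; no Cβ for Gly; 3.4 Å
  per residue along the strand, alternating Cβ pleat) placed side by side at
  9.5 Å within a layer — the sheet-to-sheet zipper distance, deliberately
  distinct from the 4.7 Å stacking repeat so that layer detection faces the
  same anisotropy as real fibrils.  Layer k is layer 0 rotated by k·twist
  and translated k·rise along z, so helical-parameter estimation has an
  exact ground truth.  Antiparallel chains run in the reverse strand
  direction.  Optional Gaussian coordinate jitter.  Not emulated: real
  side-chain geometry, hydrogen bonding, backbone dihedrals — so absolute
  energy values from these fixtures characterise the method, not any real
  fibril.
* **Peptide tiling**: 40-mers stepping by 20 over 384 residues (18
  peptides; the last 4 positions stay uncovered, exercising the undefined
  marker); per-peptide value = interval mean of the truth + N(0, σ), clipped
  to [0,1], σ = 0.02 by default.  Not emulated: peptide-specific kinetics,
  sequence-dependent noise.
* **1D spectra**: sums of Lorentzian lines in the 6–10 ppm amide region
  scaled by a known soluble fraction plus white noise; the integration
  helper estimates the noise floor from a signal-free region and reports
  SNR = integral/σ_integral, so 1/SNR is exactly the relative integral
  error assumed by the quadrature propagation.  Not emulated: J-couplings,
  relaxation, baseline/phase artefacts.

## Known limitations

* Stabilization energies ignore electrostatics, conformational strain and
  entropy; they are surface-burial scores in the ASP sense.
* Published per-residue stability values for deposited fibril models were
  produced by software whose parameter set and reference state are not
  public; with the Eisenberg–McLachlan defaults this implementation
  reproduces sign and ordering robustly, while absolute agreement depends on
  the reference mode (both are provided, and the deposited-model tests
  accept either within a documented band).
* Layer detection assumes a roughly straight fibril axis over the deposited
  segment and a cross-β stacking repeat; exotic symmetries need the
  `gap_threshold`/`rise_range` overrides.
* F→S and similar mutants are analysed at sequence level only; no structural
  remodelling is attempted.
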