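# fgtools

Quantitative analysis of FG-nucleoporin self-association: amyloid-fibril
energetics, helical fibril geometry, and FG-repeat sequence/assay profiling.

Intrinsically disordered FG-repeat domains of nucleoporins such as human
Nup98 form the permeability barrier of the nuclear pore complex, and their
cohesive FG–FG interactions drive hydrogel and amyloid formation.  This
package implements the analyses used to characterise that self-association
at residue resolution:

* **Sequence features** — scanning for FG dipeptides, canonical GLFG and
  GLFG-like (XLFX) motifs, and sliding-window residue-class composition
  profiles of low-complexity sequences.
* **Peptide tiling → per-residue propensity** — a domain is dissected into
  overlapping peptides whose aggregated fraction is measured (1D amide-proton
  NMR: soluble fraction = amide-region integral ratio to a soluble reference,
  with 1/SNR relative errors combined in quadrature).  The propensity of
  residue *i* is the unweighted mean of the aggregated fractions of all
  peptides containing *i*; uncovered positions are explicitly undefined.
  Bootstrap resampling of peptides gives confidence bands.
* **Helical fibril geometry** — layers (rungs) of a fibril model are detected
  along the principal axis compatible with the cross-β stacking repeat;
  chain orientations (parallel/antiparallel) are labelled from Cα end-to-end
  vectors; rise and twist follow from the screw decomposition of the
  least-squares (Kabsch) superposition of consecutive layers, and
  `crossover = 180 × rise / |twist|` converts between the half-turn crossover
  distance and the per-layer twist (negative twist = left-handed).
* **Stabilization (solvation) energetics** — Shrake–Rupley solvent-accessible
  surface areas on a deterministic Fibonacci sphere grid, combined with
  atomic solvation parameters (default: Eisenberg–McLachlan 1986, shipped
  with provenance):  ΔG_solv(atom) = ASP(class) × SASA(atom).  The per-residue
  stabilization energy of a fibril is ΔΔG between the middle layer of an
  N-layer context and a reference state (isolated chain conformer by
  default); negative values mean burial stabilizes.  Contiguous low-energy
  runs identify zipper-like stabilizing patches.
* **Synthetic data** — deterministic generators for layered β-stacks with
  known rise/twist/orientations, tiled-peptide assays with a known
  per-residue truth, and Lorentzian amide-region spectra with a known soluble
  fraction, so every stage is testable offline.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/03_tiling_profile.py
python analysis/04_fibril_geometry.py
python analysis/05_solvation_energy.py
```

The drivers print, among other things:

```
worked example: crossover 715 Å at rise 4.75 Å -> twist -1.20°/layer
geometry summary: ... "chains_per_layer": [5, 5, 5, 5, 5],
  "orientations": {"parallel": 20, "antiparallel": 5},
  "rise_A": 4.71, "twist_deg": -1.19, "crossover_A": 712.4 ...
tiling summary: ... "recovered_peaks": [99.1, 309.6],
  "rmse_vs_truth_covered": 0.036,
  "soluble_fraction": 0.3299, "aggregated_fraction": 0.6701 ...
solvation summary: ... "mean_per_residue_kcal_mol": -0.512 ...
```

Reading these: a fibril whose projection repeats every 715 Å while climbing
4.75 Å per layer twists −1.20° per layer (left-handed).  The synthetic
5×5-chain stack built at rise 4.71 Å / twist −1.19° is recovered exactly by
layer superposition, with four parallel chains and one antiparallel edge
chain per layer.  The 18-peptide tiling assay with σ = 0.02 noise recovers
the planted propensity peaks at residues ~100 and ~310 within a residue, at
RMSE 0.036; the synthetic condition spectrum integrates to a soluble
fraction of 0.33, i.e. 67 % aggregated.  The middle layer of the synthetic
fibril is stabilized by −0.51 kcal/mol per residue relative to its isolated
chains.

The same machinery is exposed as a small CLI (`fgtools motifs|tile|crossover|
helix|stability|simulate ...`); see `fgtools --help`.

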