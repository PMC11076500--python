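#!/usr/bin/env python
"""Generate the synthetic inputs used by the downstream analysis steps.

Writes to results/synthetic/:
  * fibril.pdb / fibril.cif — a 5-layer, 5-chains-per-layer β-stack at
    rise 4.71 Å / twist −1.19°, four parallel chains and one antiparallel
    edge chain per layer;
  * peptides.tsv — 18 overlapping 40-mers tiling a 384-residue sequence,
    aggregated fractions = interval means of a two-peak truth + σ=0.02 noise;
  * truth.tsv — the planted per-residue truth;
  * spectra: reference (fully soluble) and condition (33% soluble) 1D spectra.
"""

from pathlib import Path

import pandas as pd

from fgtools import structio as io
from fgtools import synthetic_data as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20240507


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    stack = syn.make_beta_stack(syn.StackSpec(
        orientation_pattern=["parallel"] * 4 + ["antiparallel"], seed=SEED))
    io.write_structure(stack, OUT / "fibril.pdb")
    io.write_structure(stack, OUT / "fibril.cif")
    print(f"fibril: {len(stack.chains)} chains, {stack.n_atoms} atoms -> {OUT/'fibril.pdb'}")

    tiling = syn.TilingSpec(seed=SEED)
    assays = syn.make_tiling_dataset(tiling)
    pd.DataFrame(
        [(a.peptide_id, a.start, a.end, a.aggregated_fraction, a.error) for a in assays],
        columns=["peptide_id", "start", "end", "aggregated_fraction", "error"],
    ).to_csv(OUT / "peptides.tsv", sep="\t", index=False)
    pd.DataFrame({"position": range(1, 385), "truth": tiling.truth_vector()}).to_csv(
        OUT / "truth.tsv", sep="\t", index=False)
    print(f"tiling: {len(assays)} peptides -> {OUT/'peptides.tsv'}")

    for label, frac, seed in (("reference", 1.0, SEED + 1), ("condition", 0.33, SEED + 2)):
        sp = syn.make_spectrum(syn.SpectrumSpec(soluble_fraction_truth=frac, seed=seed))
        pd.DataFrame({"ppm": sp.ppm, "intensity": sp.intensity}).to_csv(
            OUT / f"spectrum_{label}.tsv", sep="\t", index=False)
    print(f"spectra: reference + condition -> {OUT}")


if __name__ == "__main__":
    main()
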