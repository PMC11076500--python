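"""Synthetic generators for every input the analysis stages consume.

Three generators emulate the statistical/geometric structure of the real
inputs so that the whole pipeline runs and is tested without downloads:

* :func:`make_beta_stack` — an idealized cross-β fibril: layers of extended
  chains related by a known helical rise and twist, with per-chain
  parallel/antiparallel orientations.  Chains carry only N, Cα, C, O and Cβ
  pseudo-atoms (no Cβ for glycine) — enough for geometry and solvent-
  accessibility work without a rotamer library.
* :func:`make_tiling_dataset` — an overlapping-peptide aggregation assay whose
  per-peptide value is the mean of a known per-residue truth over the peptide
  interval plus clipped Gaussian noise.
* :func:`make_spectrum` — an amide-region 1D NMR spectrum as a sum of
  Lorentzian lines scaled by a known soluble fraction, plus white noise, with
  a window-integration helper for soluble-fraction quantification.

All generators take explicit seeds and are deterministic; no global RNG state
is touched.  Default parameter values are the study conditions the rest of
the package is tested under (five chains per layer, four parallel and one
antiparallel edge chain, rise 4.71 Å / twist −1.19°; 18 peptides tiling 384
residues with truth peaks near residues 100 and 310 and noise σ = 0.02).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio.SeqUtils import seq3

from .structio import Atom, Chain, Residue, StructureModel
from .tiling_profile import IntegralMeasurement, PeptideAssay

__all__ = [
    "StackSpec",
    "TilingSpec",
    "SpectrumSpec",
    "Spectrum1D",
    "make_beta_stack",
    "make_tiling_dataset",
    "make_spectrum",
    "integrate_window",
    "two_peak_truth",
]

#: generic FG-repeat-like 30-mer used for synthetic fibril chains (synthetic
#: sequence, not a natural nucleoporin fragment)
DEFAULT_STACK_SEQUENCE = "GGLFGQSTNPAGGLFGSTNKFGQSSGGLFG"

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


@dataclass
class StackSpec:
    n_layers: int = 5
    chains_per_layer: int = 5
    rise: float = 4.71              # Å per layer
    twist: float = -1.19            # degrees per layer, negative = left-handed
    strand_spacing: float = 9.5     # Å between chain axes within a layer
    residue_sequence: str = DEFAULT_STACK_SEQUENCE
    orientation_pattern: Sequence[str] | None = None  # per chain in a layer
    start_number: int = 1
    jitter_sd: float = 0.0          # Å, optional coordinate noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.chains_per_layer < 1:
            raise ValueError("n_layers and chains_per_layer must be >= 1")
        if self.orientation_pattern is not None:
            pat = list(self.orientation_pattern)
            if len(pat) != self.chains_per_layer:
                raise ValueError("orientation_pattern length must equal chains_per_layer")
            if not set(pat) <= {"parallel", "antiparallel"}:
                raise ValueError("orientation_pattern entries must be parallel/antiparallel")


def _rotation_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _extended_chain(sequence: str, antiparallel: bool) -> list[tuple[str, str, np.ndarray]]:
    """(res_name3, atom_name, coord) triples for one extended pseudo-chain.

    The strand runs along x (3.4 Å per residue), pleats along z via
    alternating Cβ, and is centred at the origin.
    """
    n = len(sequence)
    out: list[tuple[str, str, np.ndarray]] = []
    for j, aa in enumerate(sequence):
        x = 3.4 * ((n - 1 - j) if antiparallel else j) - 3.4 * (n - 1) / 2.0
        sign = 1.0 if j % 2 == 0 else -1.0
        res3 = seq3(aa).upper()
        atoms = [
            ("N", np.array([x - 1.2, 0.8, 0.0])),
            ("CA", np.array([x, 0.0, 0.0])),
            ("C", np.array([x + 1.2, 0.8, 0.0])),
            ("O", np.array([x + 1.6, 1.9, 0.4])),
        ]
        if aa != "G":
            atoms.append(("CB", np.array([x, -0.7, sign * 1.3])))
        for name, coord in atoms:
            out.append((res3, name, coord))
    return out


def make_beta_stack(spec: StackSpec) -> StructureModel:
    """Idealized layered β-stack with exactly known helical parameters.

    Layer k is layer 0 rotated by k·twist about the z axis and translated by
    k·rise along z, so rigid superposition of consecutive layers recovers
    (rise, twist) exactly (up to ``jitter_sd``).  Antiparallel chains run in
    the reverse strand direction.  Deterministic under ``spec.seed``.
    """
    total = spec.n_layers * spec.chains_per_layer
    if total > len(_CHAIN_IDS):
        raise ValueError(f"too many chains ({total}) for single-character chain ids")
    rng = np.random.default_rng(spec.seed)
    pattern = list(spec.orientation_pattern or ["parallel"] * spec.chains_per_layer)
    n_res = len(spec.residue_sequence)

    base_chains: list[list[tuple[str, str, np.ndarray]]] = []
    for c, orient in enumerate(pattern):
        y_off = spec.strand_spacing * (c - (spec.chains_per_layer - 1) / 2.0)
        triples = _extended_chain(spec.residue_sequence, orient == "antiparallel")
        base_chains.append([(r, a, xyz + np.array([0.0, y_off, 0.0])) for r, a, xyz in triples])

    chains: list[Chain] = []
    serial = 0
    idx = 0
    for k in range(spec.n_layers):
        R = _rotation_z(k * spec.twist)
        shift = np.array([0.0, 0.0, k * spec.rise])
        for c in range(spec.chains_per_layer):
            cid = _CHAIN_IDS[idx]
            idx += 1
            residues: list[Residue] = []
            current: Residue | None = None
            res_index = -1
            for res3, aname, xyz in base_chains[c]:
                if aname == "N":
                    res_index += 1
                    current = Residue(
                        chain_id=cid,
                        seq_id=spec.start_number + res_index,
                        res_name=res3,
                        atoms=[],
                    )
                    residues.append(current)
                serial += 1
                coord = R @ xyz + shift
                if spec.jitter_sd > 0:
                    coord = coord + rng.normal(0.0, spec.jitter_sd, 3)
                assert current is not None
                current.atoms.append(
                    Atom(serial=serial, name=aname, element=aname[0], coord=coord)
                )
            chains.append(Chain(chain_id=cid, residues=residues))
    return StructureModel(id=f"beta_stack_{spec.n_layers}x{spec.chains_per_layer}", chains=chains)


# ---------------------------------------------------------------------------
# peptide tiling
# ---------------------------------------------------------------------------


def two_peak_truth(
    seq_length: int = 384,
    centers: tuple[float, float] = (100.0, 310.0),
    amplitudes: tuple[float, float] = (0.55, 0.65),
    width: float = 55.0,
    baseline: float = 0.15,
) -> np.ndarray:
    """Smooth two-peak per-residue propensity truth on positions 1..L.

    Defaults mimic an FG domain with two aggregation-prone regions, the
    C-terminal one slightly stronger.  The default width keeps the truth
    slowly varying relative to the 40-residue peptide window, which is the
    regime in which averaging over covering peptides is a nearly unbiased
    per-residue estimator (the window smoothing alone otherwise dominates the
    recovery error); see the methods note for the bias analysis.
    """
    pos = np.arange(1, seq_length + 1, dtype=float)
    t = baseline
    for c, a in zip(centers, amplitudes):
        t = t + a * np.exp(-((pos - c) ** 2) / (2.0 * width**2))
    return np.clip(t, 0.0, 1.0)


@dataclass
class TilingSpec:
    seq_length: int = 384
    truth: np.ndarray | Callable[[int], np.ndarray] | None = None  # default: two_peak_truth
    peptide_length: int = 40
    step: int = 20
    noise_sd: float = 0.02
    seed: int = 0

    def truth_vector(self) -> np.ndarray:
        if self.truth is None:
            t = two_peak_truth(self.seq_length)
        elif callable(self.truth):
            t = np.asarray(self.truth(self.seq_length), dtype=float)
        else:
            t = np.asarray(self.truth, dtype=float)
        if t.shape != (self.seq_length,):
            raise ValueError("truth vector length must equal seq_length")
        if t.min() < 0 or t.max() > 1:
            raise ValueError("truth values must lie in [0, 1]")
        return t

    def __post_init__(self) -> None:
        if self.peptide_length > self.seq_length:
            raise ValueError("peptide_length exceeds seq_length")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_tiling_dataset(spec: TilingSpec) -> list[PeptideAssay]:
    """Overlapping peptides whose aggregated fraction is the interval mean of
    the truth plus clipped Gaussian noise.  With the defaults (length 384,
    40-mers stepping by 20) exactly 18 peptides are produced.
    """
    truth = spec.truth_vector()
    rng = np.random.default_rng(spec.seed)
    assays: list[PeptideAssay] = []
    start = 1
    k = 0
    while start + spec.peptide_length - 1 <= spec.seq_length:
        end = start + spec.peptide_length - 1
        mean_truth = float(truth[start - 1 : end].mean())
        value = mean_truth + float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else mean_truth
        k += 1
        assays.append(
            PeptideAssay(
                peptide_id=f"pep{k:02d}",
                start=start,
                end=end,
                aggregated_fraction=float(np.clip(value, 0.0, 1.0)),
                error=spec.noise_sd,
            )
        )
        start += spec.step
    return assays


# ---------------------------------------------------------------------------
# 1D spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectrumSpec:
    ppm_min: float = 6.0
    ppm_max: float = 10.0
    n_points: int = 2048
    peaks: Sequence[tuple[float, float, float]] = (
        # (center ppm, half-width ppm, amplitude) — amide-proton region
        (7.70, 0.03, 0.8),
        (7.95, 0.025, 1.0),
        (8.10, 0.03, 1.2),
        (8.25, 0.02, 0.9),
        (8.45, 0.03, 1.1),
        (8.65, 0.025, 0.7),
    )
    soluble_fraction_truth: float = 1.0
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.soluble_fraction_truth <= 1.0:
            raise ValueError("soluble_fraction_truth must lie in [0, 1]")
        for _, width, _ in self.peaks:
            if width <= 0:
                raise ValueError("peak widths must be > 0")


@dataclass
class Spectrum1D:
    ppm: np.ndarray
    intensity: np.ndarray
    noise_sd: float  # generative noise level (per point)


def make_spectrum(spec: SpectrumSpec) -> Spectrum1D:
    """Sum of Lorentzian lines scaled by the soluble fraction, plus noise."""
    ppm = np.linspace(spec.ppm_min, spec.ppm_max, spec.n_points)
    signal = np.zeros_like(ppm)
    for center, width, amp in spec.peaks:
        signal += amp * width**2 / ((ppm - center) ** 2 + width**2)
    rng = np.random.default_rng(spec.seed)
    intensity = spec.soluble_fraction_truth * signal
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, spec.n_points)
    return Spectrum1D(ppm=ppm, intensity=intensity, noise_sd=spec.noise_sd)


def integrate_window(
    spectrum: Spectrum1D,
    window: tuple[float, float] = (7.4, 9.0),
    label: str = "amide",
    noise_region: tuple[float, float] | None = (6.0, 6.6),
) -> IntegralMeasurement:
    """Integrate the spectrum over a ppm window (trapezoid rule).

    The SNR reported is integral / σ_integral, where σ_integral is the noise
    standard deviation of the window sum estimated from a signal-free region
    (falling back to the generative noise level when the estimate is zero),
    so 1/SNR is directly the relative uncertainty of the integral.
    """
    lo, hi = sorted(window)
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if mask.sum() < 2:
        raise ValueError("integration window contains fewer than 2 points")
    integral = float(np.trapezoid(spectrum.intensity[mask], spectrum.ppm[mask]))
    dppm = float(np.mean(np.diff(spectrum.ppm)))
    if noise_region is not None:
        nlo, nhi = sorted(noise_region)
        nmask = (spectrum.ppm >= nlo) & (spectrum.ppm <= nhi)
        noise_sd = float(np.std(spectrum.intensity[nmask])) if nmask.sum() > 3 else spectrum.noise_sd
    else:
        noise_sd = spectrum.noise_sd
    noise_sd = max(noise_sd, 1e-12)
    sigma_integral = noise_sd * dppm * math.sqrt(int(mask.sum()))
    snr = max(abs(integral) / sigma_integral, 1e-9)
    return IntegralMeasurement(condition_label=label, integral=max(integral, 0.0), snr=snr)
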