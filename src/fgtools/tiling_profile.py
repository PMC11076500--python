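"""Per-residue aggregation propensity from overlapping-peptide assays.

An FG-repeat domain is dissected into overlapping peptides; each peptide's
aggregated fraction is measured (e.g. by 1D amide-proton NMR: the soluble
fraction is the ratio of the amide-region integral to a fully soluble
reference, and aggregated = 1 − soluble).  The per-residue propensity is the
unweighted mean of the aggregated fractions of all peptides covering that
residue; positions covered by no peptide are explicitly undefined (``None``),
never zero.

Peptide intervals are 1-based inclusive in the parent-sequence numbering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideAssay",
    "ResidueProfile",
    "IntegralMeasurement",
    "SolubleFraction",
    "soluble_fraction",
    "residue_propensity",
    "bootstrap_profile",
    "peak_center",
    "read_peptide_table",
    "write_residue_profile",
    "profile_to_frame",
]


@dataclass(frozen=True)
class PeptideAssay:
    peptide_id: str
    start: int
    end: int
    aggregated_fraction: float
    error: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.peptide_id}: start {self.start} > end {self.end}")
        if not 0.0 <= self.aggregated_fraction <= 1.0:
            raise ValueError(f"{self.peptide_id}: aggregated_fraction outside [0, 1]")
        if self.error < 0:
            raise ValueError(f"{self.peptide_id}: negative error")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ResidueProfile:
    position: int
    propensity: float | None   # None where no peptide covers the position
    n_covering: int
    stderr: float | None


@dataclass(frozen=True)
class IntegralMeasurement:
    condition_label: str
    integral: float
    snr: float

    def __post_init__(self) -> None:
        if self.integral < 0:
            raise ValueError(f"{self.condition_label}: negative integral")
        if self.snr <= 0:
            raise ValueError(f"{self.condition_label}: snr must be > 0")


@dataclass(frozen=True)
class SolubleFraction:
    value: float
    stderr: float
    clipped: bool = False

    @property
    def aggregated(self) -> float:
        return 1.0 - self.value


def soluble_fraction(cond: IntegralMeasurement, ref: IntegralMeasurement) -> SolubleFraction:
    """Soluble fraction = condition integral / reference integral.

    The relative error of each integral is taken as 1/SNR and the two are
    combined in quadrature:  σ_f = f·sqrt(snr_c⁻² + snr_r⁻²).  Ratios above 1
    are clipped to 1 with a warning (the uncertainty is kept from the
    unclipped ratio).
    """
    if ref.integral == 0:
        raise ZeroDivisionError(f"reference integral of {ref.condition_label!r} is zero")
    f = cond.integral / ref.integral
    err = f * float(np.hypot(1.0 / cond.snr, 1.0 / ref.snr))
    clipped = False
    if f > 1.0:
        warnings.warn(
            f"soluble fraction {f:.3f} > 1 for {cond.condition_label!r}; clipping to 1",
            stacklevel=2,
        )
        f, clipped = 1.0, True
    return SolubleFraction(value=f, stderr=err, clipped=clipped)


def _validate_assays(assays: Sequence[PeptideAssay], seq_length: int) -> None:
    for a in assays:
        if a.start < 1 or a.end > seq_length:
            raise ValueError(
                f"peptide {a.peptide_id} interval [{a.start}, {a.end}] outside sequence 1..{seq_length}"
            )


def residue_propensity(assays: Sequence[PeptideAssay], seq_length: int) -> list[ResidueProfile]:
    """Unweighted mean aggregated fraction over the peptides covering each
    position.  ``stderr`` is the standard error of the covering values (0 for
    a single covering peptide); uncovered positions have ``propensity=None``.
    """
    _validate_assays(assays, seq_length)
    out: list[ResidueProfile] = []
    for pos in range(1, seq_length + 1):
        vals = [a.aggregated_fraction for a in assays if a.covers(pos)]
        if not vals:
            out.append(ResidueProfile(pos, None, 0, None))
        elif len(vals) == 1:
            out.append(ResidueProfile(pos, vals[0], 1, 0.0))
        else:
            arr = np.asarray(vals)
            out.append(
                ResidueProfile(
                    pos,
                    float(arr.mean()),
                    len(vals),
                    float(arr.std(ddof=1) / np.sqrt(len(vals))),
                )
            )
    return out


def bootstrap_profile(
    assays: Sequence[PeptideAssay],
    seq_length: int,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap confidence band for the per-residue profile.

    Peptides are resampled with replacement; per position the percentile
    interval is taken over resamples in which the position was covered.
    Positions never covered get NaN bounds.  Deterministic under *seed*.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    _validate_assays(assays, seq_length)
    rng = np.random.default_rng(seed)
    n = len(assays)
    samples = np.full((n_boot, seq_length), np.nan)
    starts = np.array([a.start for a in assays])
    ends = np.array([a.end for a in assays])
    fracs = np.array([a.aggregated_fraction for a in assays])
    positions = np.arange(1, seq_length + 1)
    cover = (starts[:, None] <= positions) & (positions <= ends[:, None])  # (n, L)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cov = cover[idx]            # (n, L)
        vals = fracs[idx][:, None]  # (n, 1)
        counts = cov.sum(axis=0)
        sums = np.where(cov, vals, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            samples[b] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    alpha = (1.0 - ci) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        lo = np.nanpercentile(samples, 100 * alpha, axis=0)
        hi = np.nanpercentile(samples, 100 * (1 - alpha), axis=0)
    return pd.DataFrame({"position": positions, "ci_low": lo, "ci_high": hi}).set_index("position")


def peak_center(
    profile: Sequence[ResidueProfile],
    window: tuple[int, int],
    level: float = 0.5,
) -> float:
    """Half-maximum-weighted peak position inside a position window.

    The tiling estimator is piecewise constant over runs with identical
    peptide coverage, so a raw argmax can sit anywhere on a ~step-sized
    plateau.  The centroid of positions weighted by their excess over
    ``level`` of the window's (max − min) range is a plateau-robust peak
    location.  Returns NaN when the window has no defined values.
    """
    lo, hi = window
    pos = np.array([p.position for p in profile if lo <= p.position <= hi and p.propensity is not None])
    val = np.array([p.propensity for p in profile if lo <= p.position <= hi and p.propensity is not None])
    if len(val) == 0:
        return math.nan
    cut = val.min() + level * (val.max() - val.min())
    w = np.clip(val - cut, 0.0, None)
    if w.sum() == 0:
        return float(pos[int(np.argmax(val))])
    return float((pos * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_peptide_table(path: str | Path) -> list[PeptideAssay]:
    """TSV with columns peptide_id, start, end, aggregated_fraction[, error]."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "start", "end", "aggregated_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PeptideAssay(
            peptide_id=str(row.peptide_id),
            start=int(row.start),
            end=int(row.end),
            aggregated_fraction=float(row.aggregated_fraction),
            error=float(getattr(row, "error", 0.0) or 0.0),
        )
        for row in df.itertuples(index=False)
    ]


def read_integral_table(path: str | Path) -> list[IntegralMeasurement]:
    """TSV with columns condition_label, integral, snr."""
    df = pd.read_csv(path, sep="\t")
    return [
        IntegralMeasurement(str(r.condition_label), float(r.integral), float(r.snr))
        for r in df.itertuples(index=False)
    ]


def profile_to_frame(profile: list[ResidueProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.position, p.propensity, p.n_covering, p.stderr) for p in profile],
        columns=["position", "propensity", "n_covering", "stderr"],
    ).set_index("position")


def write_residue_profile(profile: list[ResidueProfile], path: str | Path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", na_rep="NA")
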