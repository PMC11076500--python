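"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the motif
oracle is a naive O(n·m) scan, and the SASA oracles are closed-form sphere
formulas plus a brute-force Monte Carlo estimator with its own RNG-based
point sampling (the implementation uses a deterministic Fibonacci grid).
"""

from __future__ import annotations

import math

import numpy as np


def naive_motif_starts(sequence: str, pattern: str) -> list[int]:
    """All (overlapping) match start indices, 0-based, by direct comparison."""
    n, m = len(sequence), len(pattern)
    starts = []
    for i in range(n - m + 1):
        ok = True
        for j, p in enumerate(pattern):
            if p != "X" and sequence[i + j] != p:
                ok = False
                break
        if ok:
            starts.append(i)
    return starts


def sphere_area(radius: float, probe: float) -> float:
    """Accessible area of an isolated atom: the full expanded sphere."""
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_area(radius: float, probe: float, distance: float) -> float:
    """Accessible area of each of two identical atoms a given distance apart.

    Each expanded sphere (radius R = r + probe) loses the spherical cap cut
    off by the bisecting plane: cap area = 2πR(R − d/2).
    """
    R = radius + probe
    if distance >= 2 * R:
        return 4.0 * math.pi * R * R
    cap = 2.0 * math.pi * R * (R - distance / 2.0)
    return 4.0 * math.pi * R * R - cap


def mc_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_per_atom: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Brute-force Monte Carlo per-atom accessible areas.

    Uniform random points on each atom's expanded sphere are tested for
    inclusion in any other expanded sphere.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    rng = np.random.default_rng(seed)
    expanded = radii + probe
    n = len(coords)
    areas = np.empty(n)
    for i in range(n):
        v = rng.normal(size=(n_per_atom, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        buried = np.zeros(n_per_atom, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= expanded[i] + expanded[j]:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            buried |= d2 < expanded[j] ** 2
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * (~buried).mean()
    return areas
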