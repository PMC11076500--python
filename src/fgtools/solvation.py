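"""Solvent accessibility and atomic-solvation-parameter energetics.

Solvent-accessible surface area (SASA) is computed with the Shrake–Rupley
rolling-probe method using a deterministic spherical Fibonacci point set (no
random numbers), so results are exactly reproducible.  The per-atom area is
the area of the sphere of radius (vdW + probe) around the atom centre that is
not inside any neighbour's expanded sphere.

Solvation free energies follow the atomic-solvation-parameter (ASP) model:
each heavy atom is assigned a chemistry class (carbon, neutral N, neutral O,
charged N, charged O, sulfur) and its energy is the class parameter
(cal·mol⁻¹·Å⁻²) times its accessible area; residue energies are atom sums.
Parameters live in provenance-labelled data files (default: the
Eisenberg–McLachlan 1986 set) and are converted to kcal/mol at exactly one
boundary.

The per-residue stabilization energy of a fibril is the difference in
solvation free energy of each middle-layer residue between the assembled
N-layer context and a reference state (the isolated chain in its fibril
conformation by default): negative values mean burial in the fibril is
stabilizing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .fibril_geometry import LayerSet, detect_layers
from .structio import Atom, Residue, StructureModel, subset_chains

__all__ = [
    "SASAResult",
    "ASPSet",
    "EnergyProfile",
    "fibonacci_sphere",
    "compute_sasa",
    "load_asp_set",
    "available_asp_sets",
    "solvation_free_energy",
    "stabilization_energy",
    "identify_stabilizing_patches",
    "position_means",
]

CAL_PER_KCAL = 1000.0


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden-angle spiral)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n_points, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _grid_rotation(index: int) -> np.ndarray:
    """Deterministic per-atom rotation of the sphere grid.

    A Kronecker (additive-recurrence) sequence of Euler angles decorrelates
    the quadrature error of neighbouring atoms so that summed areas converge
    faster, while keeping the computation free of random state.
    """
    a = 2.0 * math.pi * ((index * 0.7548776662466927) % 1.0)
    b = math.acos(1.0 - 2.0 * ((index * 0.5698402909980532) % 1.0))
    ca, sa, cb, sb = math.cos(a), math.sin(a), math.cos(b), math.sin(b)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    return rz @ ry


@dataclass
class SASAResult:
    """Per-atom accessible areas for the heavy atoms of a model.

    ``entries[i]`` is the (residue, atom) pair whose accessible area is
    ``per_atom_area[i]``.
    """

    entries: list[tuple[Residue, Atom]]
    per_atom_area: np.ndarray  # Å², aligned with entries
    probe_radius: float
    n_points: int

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())

    def residue_areas(self) -> dict[tuple[str, int], float]:
        out: dict[tuple[str, int], float] = {}
        for (res, _), area in zip(self.entries, self.per_atom_area):
            key = (res.chain_id, res.seq_id)
            out[key] = out.get(key, 0.0) + float(area)
        return out


def compute_sasa(model: StructureModel, probe: float = 1.4, n_points: int = 960) -> SASAResult:
    """Shrake–Rupley SASA over the model's heavy atoms.

    Radii must have been assigned (:func:`fgtools.structio.assign_radii`);
    hydrogens are excluded.  Deterministic for a given ``n_points``.
    """
    if n_points < 32:
        warnings.warn(f"n_points={n_points} is very coarse; areas will be noisy", stacklevel=2)
    entries: list[tuple[Residue, Atom]] = []
    for res, atom in model.iter_atoms():
        if atom.is_hydrogen:
            continue
        if atom.vdw_radius is None:
            raise ValueError(
                f"atom {atom.name} in {res.chain_id}/{res.res_name}{res.seq_id} has no vdW radius; "
                "run assign_radii first"
            )
        entries.append((res, atom))
    if not entries:
        raise ValueError("model has no heavy atoms")
    coords = np.array([a.coord for _, a in entries])
    radii = np.array([a.vdw_radius for _, a in entries])
    expanded = radii + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = float(expanded.max())
    areas = np.empty(len(entries))
    for i in range(len(entries)):
        Ri = expanded[i]
        nb = tree.query_ball_point(coords[i], Ri + max_reach)
        nb = [j for j in nb if j != i and np.linalg.norm(coords[j] - coords[i]) < Ri + expanded[j]]
        pts = coords[i] + Ri * (sphere @ _grid_rotation(i).T)
        if nb:
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        areas[i] = 4.0 * math.pi * Ri * Ri * exposed / n_points
    return SASAResult(entries=entries, per_atom_area=areas, probe_radius=probe, n_points=n_points)


# ---------------------------------------------------------------------------
# atomic solvation parameters
# ---------------------------------------------------------------------------

#: side-chain atoms carrying formal charge at neutral pH
_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}

DEFAULT_ASP_SET = "eisenberg_mclachlan_1986"


@dataclass(frozen=True)
class ASPSet:
    """Named atom-class → solvation parameter (cal·mol⁻¹·Å⁻²) mapping."""

    name: str
    mapping: dict[str, float]

    def classify(self, res_name: str, atom_name: str, element: str) -> str:
        element = element.upper()
        if element == "C":
            return "carbon"
        if element == "S":
            return "sulfur"
        key = (res_name.upper(), atom_name.upper())
        if element == "O":
            return "charged_O" if (key in _CHARGED_O or atom_name.upper() == "OXT") else "neutral_O"
        if element == "N":
            return "charged_N" if key in _CHARGED_N else "neutral_N"
        raise KeyError(
            f"cannot classify atom {atom_name} ({element}) of {res_name} under ASP set {self.name!r}"
        )

    def parameter(self, res_name: str, atom_name: str, element: str) -> float:
        return self.mapping[self.classify(res_name, atom_name, element)]

    def scaled(self, factor: float) -> "ASPSet":
        return ASPSet(name=f"{self.name}*{factor}", mapping={k: v * factor for k, v in self.mapping.items()})


def available_asp_sets() -> list[str]:
    base = resources.files("fgtools.data") / "asp"
    return sorted(p.name.removesuffix(".tsv") for p in base.iterdir() if p.name.endswith(".tsv"))


def load_asp_set(name: str = DEFAULT_ASP_SET) -> ASPSet:
    name = name.replace("-", "_")
    res = resources.files("fgtools.data") / "asp" / f"{name}.tsv"
    if not res.is_file():
        raise KeyError(f"unknown ASP set {name!r}; have {available_asp_sets()}")
    mapping: dict[str, float] = {}
    for line in res.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, value = line.split("\t")
        mapping[cls] = float(value)
    return ASPSet(name=name, mapping=mapping)


def solvation_free_energy(
    sasa: SASAResult, asp: ASPSet
) -> tuple[np.ndarray, dict[tuple[str, int], float]]:
    """Per-atom and per-residue solvation free energies in kcal/mol.

    energy(atom) = ASP(class) × area(atom) / 1000; residue energies are sums
    over their atoms.
    """
    atom_e = np.empty(len(sasa.entries))
    residue_e: dict[tuple[str, int], float] = {}
    for i, ((res, atom), area) in enumerate(zip(sasa.entries, sasa.per_atom_area)):
        p = asp.parameter(res.res_name, atom.name, atom.element)
        e = p * float(area) / CAL_PER_KCAL
        atom_e[i] = e
        key = (res.chain_id, res.seq_id)
        residue_e[key] = residue_e.get(key, 0.0) + e
    return atom_e, residue_e


# ---------------------------------------------------------------------------
# fibril stabilization energy
# ---------------------------------------------------------------------------


@dataclass
class EnergyProfile:
    """Per-residue stabilization energies of a fibril's middle layer."""

    per_residue_energy: dict[tuple[str, int], float]
    context_layers: int
    reference_mode: str
    middle_chain_ids: list[str]
    middle_layer_index: int  # 0-based within the selected context window

    @property
    def mean_per_residue(self) -> float:
        vals = list(self.per_residue_energy.values())
        return float(np.mean(vals)) if vals else math.nan


def middle_index(context: int) -> int:
    """0-based middle of a 1..context window (context must be odd)."""
    if context % 2 == 0:
        raise ValueError(f"context must be odd, got {context}")
    return context // 2


def _single_residue_context(chain_residues: list[Residue], idx: int) -> list[Residue]:
    lo = max(0, idx - 1)
    return chain_residues[lo : idx + 2]


def stabilization_energy(
    model: StructureModel,
    layers: LayerSet | None = None,
    context: int = 5,
    reference_mode: str = "isolated_conformer",
    asp: ASPSet | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> EnergyProfile:
    """ΔΔG_solv per residue of the middle layer of a *context*-layer assembly.

    ΔΔG(residue) = G_solv(residue in assembly) − G_solv(residue in reference):

    * ``isolated_conformer`` — the residue's whole chain alone, in its fibril
      conformation (default);
    * ``tripeptide`` — the residue plus its two chain neighbours excised in
      their fibril conformation, a near-fully-exposed reference.

    The profile covers every residue of every middle-layer chain; the mean is
    the arithmetic mean over those residues (negative = stabilizing).
    """
    if context % 2 == 0:
        raise ValueError(f"context must be odd, got {context}")
    if reference_mode not in {"isolated_conformer", "tripeptide"}:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if asp is None:
        asp = load_asp_set()
    if layers is None:
        layers = detect_layers(model)
    if layers.n_layers < context:
        raise ValueError(f"model has {layers.n_layers} layers < context {context}")
    start = (layers.n_layers - context) // 2
    window = layers.layers[start : start + context]
    mid = middle_index(context)
    middle_chains = window[mid]

    assembly = subset_chains(model, [cid for layer in window for cid in layer], new_id=f"{model.id}:context{context}")
    _, res_e_assembly = solvation_free_energy(compute_sasa(assembly, probe, n_points), asp)

    per_residue: dict[tuple[str, int], float] = {}
    for cid in middle_chains:
        chain = model.get_chain(cid)
        if reference_mode == "isolated_conformer":
            single = subset_chains(model, [cid], new_id=f"{model.id}:{cid}")
            _, res_e_ref = solvation_free_energy(compute_sasa(single, probe, n_points), asp)
            for res in chain.residues:
                key = (cid, res.seq_id)
                per_residue[key] = res_e_assembly[key] - res_e_ref[key]
        else:  # tripeptide
            for idx, res in enumerate(chain.residues):
                ctx_res = _single_residue_context(chain.residues, idx)
                sub = StructureModel(id=f"{model.id}:{cid}:{res.seq_id}", chains=[
                    type(chain)(chain_id=cid, residues=ctx_res)
                ])
                _, res_e_ref = solvation_free_energy(compute_sasa(sub, probe, n_points), asp)
                key = (cid, res.seq_id)
                per_residue[key] = res_e_assembly[key] - res_e_ref[key]

    return EnergyProfile(
        per_residue_energy=per_residue,
        context_layers=context,
        reference_mode=reference_mode,
        middle_chain_ids=list(middle_chains),
        middle_layer_index=mid,
    )


def position_means(profile: EnergyProfile) -> dict[int, float]:
    """Mean energy per residue number across the middle-layer chains."""
    acc: dict[int, list[float]] = {}
    for (_, seq_id), e in profile.per_residue_energy.items():
        acc.setdefault(seq_id, []).append(e)
    return {pos: float(np.mean(v)) for pos, v in sorted(acc.items())}


def identify_stabilizing_patches(
    profile: EnergyProfile | dict[int, float], threshold: float
) -> list[tuple[int, int]]:
    """Maximal runs of residue positions with energy ≤ *threshold*.

    Runs separated by a gap of at most one position (a single above-threshold
    or missing residue) are merged.  Operates on per-position means when given
    a full profile.
    """
    means = position_means(profile) if isinstance(profile, EnergyProfile) else profile
    if not means:
        return []
    qualifying = sorted(pos for pos, e in means.items() if e <= threshold)
    if not qualifying:
        return []
    patches: list[list[int]] = [[qualifying[0], qualifying[0]]]
    for pos in qualifying[1:]:
        if pos - patches[-1][1] <= 2:  # gap of <= 1 position
            patches[-1][1] = pos
        else:
            patches.append([pos, pos])
    return [(a, b) for a, b in patches]
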