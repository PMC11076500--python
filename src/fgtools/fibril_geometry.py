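"""Helical geometry of amyloid fibrils.

A fibril is a stack of layers (rungs) related by a screw motion: a rise (Å)
along the fibril axis plus a twist (degrees) about it.  Twist is signed:
negative = left-handed, the common convention for amyloid helical
reconstruction.  The crossover distance is the axial length over which the
projected fibril repeats; because a β-sheet cross-section looks the same
after half a turn, crossover corresponds to 180°:

    crossover = 180 × rise / |twist|

Layer detection, chain-orientation labelling (parallel/antiparallel) and
rise/twist estimation by least-squares superposition of consecutive layers
operate on the Cα trace of a :class:`~fgtools.structio.StructureModel`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Chain, StructureModel

__all__ = [
    "HelicalParams",
    "LayerSet",
    "crossover_to_twist",
    "twist_to_crossover",
    "detect_layers",
    "estimate_helical_params",
    "kabsch",
    "read_helical_metadata",
    "SingleLayerError",
]


class SingleLayerError(ValueError):
    """Raised when fewer than two layers are available for superposition."""


@dataclass(frozen=True)
class HelicalParams:
    rise: float            # Å per layer, > 0
    twist: float           # degrees per layer, signed (negative = left-handed)
    rise_sd: float = 0.0
    twist_sd: float = 0.0
    n_pairs: int = 0
    source: str = "superposition"  # or "metadata"

    @property
    def crossover(self) -> float:
        """Half-turn (180°) axial length in Å; inf for an untwisted stack."""
        return twist_to_crossover(self.twist, self.rise)


@dataclass
class LayerSet:
    axis: np.ndarray                        # unit fibril axis
    layers: list[list[str]]                 # chain ids per layer, ordered along +axis
    orientations: dict[str, str]            # chain id -> parallel|antiparallel|undefined
    axial_coords: dict[str, float] = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def chains_per_layer(self) -> list[int]:
        return [len(layer) for layer in self.layers]


# ---------------------------------------------------------------------------
# crossover <-> twist
# ---------------------------------------------------------------------------


def crossover_to_twist(crossover: float, rise: float, handedness: str = "left") -> float:
    """Twist per layer (degrees, signed) from the half-turn crossover length."""
    if crossover <= 0 or rise <= 0:
        raise ValueError("crossover and rise must be positive")
    twist = 180.0 * rise / crossover
    if handedness == "left":
        return -twist
    if handedness == "right":
        return twist
    raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")


def twist_to_crossover(twist: float, rise: float) -> float:
    """Half-turn crossover length (Å); inf when twist is zero."""
    if rise <= 0:
        raise ValueError("rise must be positive")
    if twist == 0:
        return math.inf
    return 180.0 * rise / abs(twist)


# ---------------------------------------------------------------------------
# layers and orientations
# ---------------------------------------------------------------------------


def _chain_centroid(chain: Chain) -> np.ndarray:
    ca = chain.ca_coords()
    if len(ca):
        return ca.mean(axis=0)
    coords = np.array([a.coord for r in chain.residues for a in r.atoms])
    return coords.mean(axis=0)


def _cluster_1d(values: np.ndarray, gap_threshold: float) -> list[list[int]]:
    """Group indices whose sorted values are separated by gaps <= threshold."""
    order = np.argsort(values, kind="stable")
    groups: list[list[int]] = [[int(order[0])]]
    for prev, cur in zip(order[:-1], order[1:]):
        if values[cur] - values[prev] > gap_threshold:
            groups.append([])
        groups[-1].append(int(cur))
    return groups


def _direction(chain: Chain) -> np.ndarray | None:
    ca = chain.ca_coords()
    if len(ca) < 4:
        return None
    return ca[-1] - ca[0]


def detect_layers(
    model: StructureModel,
    gap_threshold: float | None = None,
    rise_range: tuple[float, float] = (3.0, 6.5),
) -> LayerSet:
    """Partition chains into layers stacked along the fibril axis.

    The axis is chosen among the principal axes of the full Cα cloud as the
    one along which chain centroids separate most cleanly into groups (largest
    ratio of smallest between-group gap to largest within-group spread) *and*
    whose median between-group spacing is compatible with the cross-β stacking
    repeat (``rise_range``, default 3.0–6.5 Å).  The rise prior breaks the
    ambiguity between the stacking direction and the in-plane sheet-packing
    direction (typically ~9–10 Å apart); without a compatible direction the
    model is treated as a single layer, whose axis is the thin direction of
    the Cα cloud.  Chain orientation is the sign of its Cα end-to-end vector
    projected onto the first chain's; chains with fewer than 4 Cα are
    labelled undefined with a warning.
    """
    if not model.chains:
        raise ValueError("model has no chains")
    centroids = np.array([_chain_centroid(c) for c in model.chains])
    all_ca = np.vstack([c.ca_coords() for c in model.chains if len(c.ca_coords())])
    if len(all_ca) < 3:
        all_ca = np.vstack([np.array([a.coord for r in c.residues for a in r.atoms]) for c in model.chains])
    cov = np.cov((all_ca - all_ca.mean(axis=0)).T)
    _, eigvecs = np.linalg.eigh(cov)  # ascending eigenvalues: column 0 = thin direction

    best: tuple[float, np.ndarray, list[list[int]]] | None = None
    for k in range(3):
        axis = eigvecs[:, k]
        proj = centroids @ axis
        if len(proj) < 2:
            continue
        gaps = np.diff(np.sort(proj))
        thr = gap_threshold if gap_threshold is not None else max(float(gaps.max()) / 2.0, 1e-6)
        groups = _cluster_1d(proj, thr)
        if len(groups) < 2:
            continue
        spreads = [proj[g].max() - proj[g].min() for g in groups]
        mids = sorted(float(np.mean(proj[g])) for g in groups)
        between = np.diff(mids)
        if not (rise_range[0] <= float(np.median(between)) <= rise_range[1]):
            continue
        score = float(between.min()) / (max(spreads) + 0.1)
        if best is None or score > best[0]:
            best = (score, axis, groups)
    if best is None:
        # no stacking direction compatible with the cross-β repeat: one layer
        axis, groups = eigvecs[:, 0], [list(range(len(model.chains)))]
    else:
        _, axis, groups = best
    # deterministic axis sign: largest-magnitude component positive
    lead = int(np.argmax(np.abs(axis)))
    if axis[lead] < 0:
        axis = -axis
    proj = centroids @ axis
    groups = sorted(groups, key=lambda g: float(np.mean(proj[g])))

    layers = [[model.chains[i].chain_id for i in sorted(g, key=lambda i: model.chains[i].chain_id)] for g in groups]

    ref_dir = None
    orientations: dict[str, str] = {}
    ordered_ids = [cid for layer in layers for cid in layer]
    for cid in ordered_ids:
        d = _direction(model.get_chain(cid))
        if d is None:
            warnings.warn(f"chain {cid}: fewer than 4 Cα atoms, orientation undefined", stacklevel=2)
            orientations[cid] = "undefined"
            continue
        if ref_dir is None:
            ref_dir = d
            orientations[cid] = "parallel"
        else:
            orientations[cid] = "parallel" if float(d @ ref_dir) >= 0 else "antiparallel"

    axial = {model.chains[i].chain_id: float(proj[i]) for i in range(len(model.chains))}
    return LayerSet(axis=axis, layers=layers, orientations=orientations, axial_coords=axial)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with x → R·x + t mapping X onto Y."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or len(X) < 3:
        raise ValueError("need two matched (n>=3, 3) coordinate sets")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    return R, t


def _match_chains(model: StructureModel, layer_a: list[str], layer_b: list[str], axis: np.ndarray) -> list[tuple[str, str]]:
    """Pair chains of consecutive layers by in-plane centroid proximity."""
    if len(layer_a) != len(layer_b):
        raise ValueError(f"layers have different chain counts: {len(layer_a)} vs {len(layer_b)}")
    P = np.eye(3) - np.outer(axis, axis)  # project out the axial component
    ca = {cid: P @ _chain_centroid(model.get_chain(cid)) for cid in layer_a}
    cb = {cid: P @ _chain_centroid(model.get_chain(cid)) for cid in layer_b}
    pairs: list[tuple[str, str]] = []
    candidates = sorted(
        ((float(np.linalg.norm(ca[i] - cb[j])), i, j) for i in layer_a for j in layer_b),
        key=lambda x: (x[0], x[1], x[2]),
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


def _paired_ca(model: StructureModel, pairs: list[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
    X, Y = [], []
    for a_id, b_id in pairs:
        a, b = model.get_chain(a_id), model.get_chain(b_id)
        res_a = {r.seq_id: r.get_atom("CA") for r in a.residues if r.get_atom("CA")}
        res_b = {r.seq_id: r.get_atom("CA") for r in b.residues if r.get_atom("CA")}
        common = sorted(set(res_a) & set(res_b))
        if not common:
            raise ValueError(f"chains {a_id} and {b_id} share no residue numbers")
        X.extend(res_a[s].coord for s in common)
        Y.extend(res_b[s].coord for s in common)
    return np.array(X), np.array(Y)


def estimate_helical_params(model: StructureModel, layers: LayerSet | None = None) -> HelicalParams:
    """Rise and twist from rigid superposition of each consecutive layer pair.

    For each pair, the screw decomposition of the fitted transform gives the
    twist (rotation angle about the screw axis, sign relative to the layer-
    ascending fibril axis) and the rise (translation component along that
    axis).  The mean ± sd over pairs is reported.
    """
    if layers is None:
        layers = detect_layers(model)
    if layers.n_layers < 2:
        raise SingleLayerError(
            "fewer than two layers: cannot superpose; read helical parameters "
            "from deposition metadata instead (read_helical_metadata)"
        )
    rises, twists = [], []
    for la, lb in zip(layers.layers[:-1], layers.layers[1:]):
        pairs = _match_chains(model, la, lb, layers.axis)
        X, Y = _paired_ca(model, pairs)
        R, t = kabsch(X, Y)
        assert abs(np.linalg.det(R) - 1.0) < 1e-6
        rotvec = Rotation.from_matrix(R).as_rotvec()
        angle = float(np.linalg.norm(rotvec))
        if angle < 1e-12:
            u = layers.axis
            theta = 0.0
        else:
            u = rotvec / angle
            theta = angle
            if float(u @ layers.axis) < 0:
                u, theta = -u, -theta
        rises.append(float(u @ t))
        twists.append(math.degrees(theta))
    rises_a = np.asarray(rises)
    twists_a = np.asarray(twists)
    return HelicalParams(
        rise=float(rises_a.mean()),
        twist=float(twists_a.mean()),
        rise_sd=float(rises_a.std(ddof=1)) if len(rises_a) > 1 else 0.0,
        twist_sd=float(twists_a.std(ddof=1)) if len(twists_a) > 1 else 0.0,
        n_pairs=len(rises_a),
        source="superposition",
    )


def read_helical_metadata(path: str | Path) -> HelicalParams:
    """Fallback: helical rise/twist from mmCIF deposition metadata
    (``_em_helical_entity``).  Used when a deposition contains a single layer
    so superposition is impossible; ``source`` is set to ``"metadata"``.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    twist = block.find_value("_em_helical_entity.angular_rotation_per_subunit")
    rise = block.find_value("_em_helical_entity.axial_rise_per_subunit")
    if twist is None or rise is None:
        raise ValueError(f"{path}: no _em_helical_entity rise/twist metadata")
    return HelicalParams(rise=float(rise), twist=float(twist), source="metadata")
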