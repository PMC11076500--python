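"""Atomic-structure and sequence I/O plus the shared structural data model.

Structures (PDB v3.3 / mmCIF) are parsed with :mod:`gemmi` and converted into
a small chain → residue → atom hierarchy that the geometry and solvation
modules operate on.  Van der Waals radii are assigned from named, provenance-
labelled tables shipped with the package; they are never taken from the
coordinate file.

Conventions
-----------
* Residue numbering is the author numbering of the file, 1-based, inclusive.
* Alternate locations are collapsed to a single conformer: highest occupancy
  wins, ties broken by altloc letter order.
* Hydrogens are parsed and flagged but excluded from solvent-accessibility
  and energy calculations downstream.
* Only the first model of a multi-model file is read; waters are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.SeqUtils import seq3

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "SequenceRecord",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "RadiusLookupError",
    "SequenceValidationError",
    "read_structure",
    "write_structure",
    "assign_radii",
    "load_radius_table",
    "available_radius_tables",
    "read_fasta",
    "subset_chains",
]

AMINO_ACIDS_1 = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_RES3 = {seq3(a).upper() for a in AMINO_ACIDS_1}


class StructureError(Exception):
    """Base class for structural I/O errors."""


class FormatError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class RadiusLookupError(StructureError, KeyError):
    pass


class SequenceValidationError(ValueError):
    pass


@dataclass
class Atom:
    """One atom of a residue.

    ``vdw_radius`` is ``None`` until :func:`assign_radii` is applied; it never
    comes from the coordinate file.
    """

    serial: int
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float | None = None
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.res_name.upper() in STANDARD_RES3

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates in residue order, shape (n, 3)."""
        coords = [r.get_atom("CA").coord for r in self.residues if r.get_atom("CA")]
        return np.array(coords, dtype=float).reshape(-1, 3)

    @property
    def seq_ids(self) -> list[int]:
        return [r.seq_id for r in self.residues]


@dataclass
class StructureModel:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in model {self.id!r}")

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.iter_residues():
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


@dataclass
class SequenceRecord:
    """A protein sequence with its author numbering offset.

    ``start_number`` is the author number of the first residue, so residue
    ``i`` (0-based index) carries number ``start_number + i``.
    """

    id: str
    residues: str
    start_number: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.residues):
            if ch not in AMINO_ACIDS_1 + "X":
                raise SequenceValidationError(
                    f"record {self.id!r}: illegal character {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def number_of(self, index: int) -> int:
        return self.start_number + index


# ---------------------------------------------------------------------------
# structure reading / writing
# ---------------------------------------------------------------------------

_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}


def _detect_format(path: Path) -> gemmi.CoorFormat:
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return gemmi.CoorFormat.Pdb
    if suffix in {".cif", ".mmcif"}:
        return gemmi.CoorFormat.Mmcif
    return gemmi.CoorFormat.Detect


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    # Keep one conformer per atom name: max occupancy, ties by altloc order.
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
        out.append(group[0])
    return out


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only model 1 is used; waters are dropped; alternate locations are
    collapsed (highest occupancy, ties by altloc letter).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        fmt = _detect_format(path)
    elif format in _FORMATS:
        fmt = _FORMATS[format]
    else:
        raise FormatError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.is_water():
                continue
            atoms: list[Atom] = []
            for ga in gres:
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=ga.altloc if ga.altloc != "\0" else "",
                        is_hydrogen=ga.is_hydrogen(),
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if atoms:
                residues.append(
                    Residue(
                        chain_id=gchain.name,
                        seq_id=gres.seqid.num,
                        res_name=gres.name,
                        atoms=atoms,
                    )
                )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    out = StructureModel(id=st.name or path.stem, chains=chains, source_path=str(path))
    if out.n_atoms == 0:
        raise EmptyStructureError(f"{path}: no polymer atoms")
    return out


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (chosen by extension when ``auto``)."""
    path = Path(path)
    if format == "auto":
        fmt = _detect_format(path)
        if fmt == gemmi.CoorFormat.Detect:
            raise FormatError(f"cannot infer format from extension of {path}")
        format = "pdb" if fmt == gemmi.CoorFormat.Pdb else "mmcif"
    if format not in _FORMATS:
        raise FormatError(f"unknown structure format {format!r}")

    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    serial = 0
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            for a in res.atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                ga.serial = serial
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def subset_chains(model: StructureModel, chain_ids: Iterable[str], new_id: str | None = None) -> StructureModel:
    """New model containing only the named chains (shared atom objects)."""
    wanted = list(chain_ids)
    chains = [c for cid in wanted for c in model.chains if c.chain_id == cid]
    if len(chains) != len(wanted):
        missing = set(wanted) - {c.chain_id for c in chains}
        raise KeyError(f"chains not in model: {sorted(missing)}")
    return StructureModel(id=new_id or model.id, chains=chains, source_path=model.source_path)


# ---------------------------------------------------------------------------
# radii
# ---------------------------------------------------------------------------

DEFAULT_RADIUS_TABLE = "bondi1964"


def available_radius_tables() -> list[str]:
    base = resources.files("fgtools.data") / "radii"
    return sorted(p.name.removesuffix(".tsv") for p in base.iterdir() if p.name.endswith(".tsv"))


def load_radius_table(name: str = DEFAULT_RADIUS_TABLE) -> dict[str, float]:
    """Load a named element → vdW radius (Å) table shipped with the package."""
    res = resources.files("fgtools.data") / "radii" / f"{name}.tsv"
    if not res.is_file():
        raise KeyError(f"unknown radius table {name!r}; have {available_radius_tables()}")
    table: dict[str, float] = {}
    for line in res.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, radius = line.split("\t")
        table[element] = float(radius)
    return table


def assign_radii(model: StructureModel, radius_set: str | dict[str, float] = DEFAULT_RADIUS_TABLE) -> StructureModel:
    """Assign vdW radii to every atom of *model* in place (and return it).

    Raises :class:`RadiusLookupError` naming the first non-hydrogen atom whose
    element is absent from the table.  Hydrogens with no table entry are left
    unassigned (they are excluded from accessibility calculations anyway).
    """
    table = load_radius_table(radius_set) if isinstance(radius_set, str) else radius_set
    for res, atom in model.iter_atoms():
        if not atom.element:
            raise RadiusLookupError(
                f"atom {atom.name} in {res.chain_id}/{res.res_name}{res.seq_id} has no element"
            )
        radius = table.get(atom.element)
        if radius is None:
            if atom.is_hydrogen:
                continue
            raise RadiusLookupError(
                f"element {atom.element!r} of atom {atom.name} in "
                f"{res.chain_id}/{res.res_name}{res.seq_id} not in radius table"
            )
        atom.vdw_radius = radius
    return model


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, start_number: int = 1) -> list[SequenceRecord]:
    """Read FASTA records; whitespace is stripped and letters uppercased."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        records.append(SequenceRecord(id=rec.id, residues=seq, start_number=start_number))
    if not records:
        raise SequenceValidationError(f"{path}: no FASTA records")
    return records
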