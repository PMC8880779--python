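"""Macromolecular structure and sequence I/O.

Reads wwPDB-format coordinate files into a light in-memory model
(:class:`StructureModel`), assigns van der Waals radii, and writes FASTA and
PDB output.  Parsing and serialization are delegated to :mod:`biotite`;
this module fixes the conventions the rest of the package relies on:

* hydrogens and waters are excluded from all surface mathematics,
* metal ions (HETATM) are retained and assigned to their chain, so that
  Ca2+-loaded calcium-sensor proteins remain analyzable,
* residue numbering is the author numbering from the file, never re-indexed,
* for NMR ensembles, model 1 is the default conformer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .errors import ModelIndexError, PDBParseError, SequenceError

logger = logging.getLogger(__name__)

#: Solvent residue names dropped on read.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: One-letter codes of the 20 canonical amino acids.
AA1 = "ACDEFGHIKLMNPQRSTVWY"

#: Bondi-style van der Waals radii (Angstrom).  The PISA-comparable default
#: set; user-overridable through :class:`RadiiTable`.
DEFAULT_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "CA": 1.37,  # calcium ion
    "MG": 1.73,
    "ZN": 1.39,
    "K": 2.75,
    "NA": 2.27,
    "CL": 1.75,
    "F": 1.47,
    "SE": 1.90,
}


@dataclass(frozen=True)
class Atom:
    """A single atom with author numbering and an optional vdW radius."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float | None = None

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)


@dataclass(frozen=True)
class RadiiTable:
    """Element -> van der Waals radius mapping with a fallback default."""

    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    default_radius: float = 1.70

    def __post_init__(self) -> None:
        for elem, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius for {elem!r} out of range (0.5, 3.0): {r}")
        if not 0.5 < self.default_radius < 3.0:
            raise ValueError(f"default radius out of range: {self.default_radius}")

    def lookup(self, element: str) -> tuple[float, bool]:
        """Return (radius, known); unknown elements get the default radius."""
        key = element.strip().upper()
        if key in self.radii:
            return self.radii[key], True
        return self.default_radius, False

    @classmethod
    def from_file(cls, path: str | Path, default_radius: float = 1.70) -> "RadiiTable":
        """Read a two-column text config: element, radius (Angstrom)."""
        radii: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            elem, value = line.split()
            radii[elem.upper()] = float(value)
        return cls(radii=radii, default_radius=default_radius)


class StructureModel:
    """Ordered atom collection partitioned into chains.

    Residue identity is the triple ``(chain_id, residue_number, residue_name)``
    and must be unique within the model.
    """

    def __init__(self, atoms: list[Atom], title: str = ""):
        self.atoms = list(atoms)
        self.title = title
        self._check_residue_uniqueness()

    def _check_residue_uniqueness(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_number)
            if key in seen and seen[key] != a.residue_name:
                raise ValueError(
                    f"residue identity clash at chain {a.chain_id} "
                    f"{a.residue_number}: {seen[key]} vs {a.residue_name}"
                )
            seen[key] = a.residue_name

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> dict[str, list[tuple[int, str]]]:
        """chain_id -> ordered list of (residue_number, residue_name)."""
        out: dict[str, list[tuple[int, str]]] = {}
        for a in self.atoms:
            residues = out.setdefault(a.chain_id, [])
            entry = (a.residue_number, a.residue_name)
            if not residues or residues[-1] != entry:
                if entry not in residues:
                    residues.append(entry)
        return out

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains.keys())

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        vals = [a.vdw_radius for a in self.atoms]
        if any(v is None for v in vals):
            raise ValueError("radii not assigned; call assign_radii first")
        return np.array(vals, dtype=float)

    def subset(self, chain_ids: set[str] | frozenset[str]) -> "StructureModel":
        missing = set(chain_ids) - set(self.chain_ids)
        if missing:
            from .errors import ChainLookupError

            raise ChainLookupError(f"chains not in structure: {sorted(missing)}")
        return StructureModel(
            [a for a in self.atoms if a.chain_id in chain_ids], title=self.title
        )

    def residue_atoms(self) -> dict[tuple[str, int, str], list[Atom]]:
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out


def _scan_for_malformed_line(path: str | Path) -> None:
    """Raise PDBParseError naming the first malformed ATOM/HETATM line."""
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"truncated coordinate record at line {lineno}")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(
                f"malformed coordinate field at line {lineno}: {exc}"
            ) from exc


def read_pdb(
    path: str | Path,
    model_index: int = 1,
    *,
    keep_hydrogens: bool = False,
    keep_waters: bool = False,
) -> StructureModel:
    """Read one model of a PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        PDB-format file with at least one ATOM record.
    model_index:
        1-based model number; NMR ensembles (e.g. solution structures of
        intrinsically disordered peptides) contain many models.
    keep_hydrogens, keep_waters:
        Both default to False: crystal and NMR files are inconsistent about
        hydrogens, and waters are not part of the binding-interface math.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if "ATOM" not in text and "HETATM" not in text:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    try:
        pdb_file = PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        if not 1 <= model_index <= n_models:
            raise ModelIndexError(
                f"model_index {model_index} out of range 1..{n_models}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = pdb_file.get_structure(model=model_index)
    except ModelIndexError:
        raise
    except Exception as exc:  # locate the offending line for the message
        _scan_for_malformed_line(path)
        raise PDBParseError(f"{path}: {exc}") from exc

    mask = np.ones(arr.array_length(), dtype=bool)
    if not keep_hydrogens:
        mask &= ~np.isin(arr.element, ("H", "D"))
    if not keep_waters:
        mask &= ~np.isin(arr.res_name, tuple(WATER_NAMES))
    arr = arr[mask]

    atoms = [
        Atom(
            serial=i + 1,
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]) or "A",
            residue_number=int(arr.res_id[i]),
            position=np.asarray(arr.coord[i], dtype=float),
        )
        for i in range(arr.array_length())
    ]
    title = ""
    for line in text.splitlines():
        if line.startswith("TITLE"):
            title = line[10:].strip()
            break
    return StructureModel(atoms, title=title)


def assign_radii(
    s: StructureModel, table: RadiiTable | None = None
) -> StructureModel:
    """Return a copy of *s* with every atom carrying a vdW radius.

    Unknown elements receive ``table.default_radius`` and a logged warning;
    this never fails.
    """
    table = table or RadiiTable()
    unknown: set[str] = set()
    atoms = []
    for a in s.atoms:
        r, known = table.lookup(a.element)
        if not known:
            unknown.add(a.element)
        atoms.append(replace(a, vdw_radius=r))
    for elem in sorted(unknown):
        logger.warning(
            "element %r not in radii table; using default %.2f A",
            elem,
            table.default_radius,
        )
    return StructureModel(atoms, title=s.title)


def write_pdb(s: StructureModel, path: str | Path) -> None:
    """Write *s* as a wwPDB v3.3 coordinate file (single model)."""
    n = len(s.atoms)
    arr = AtomArray(n)
    arr.coord = s.coords().astype(np.float32)
    for i, a in enumerate(s.atoms):
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.residue_number
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.hetero[i] = a.name == a.element and len(a.residue_name) <= 2
    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def write_fasta(
    seq: str, header: str, path: str | Path, *, amidated: bool = False
) -> None:
    """Write a single-record FASTA file.

    The sequence is normalized to uppercase one-letter codes; a C-terminal
    amidation is noted in the header free text (FASTA carries no chemistry).
    """
    seq = seq.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    bad = sorted(set(seq) - set(AA1))
    if bad:
        raise SequenceError(f"illegal residue codes: {bad}")
    description = header.strip()
    if amidated and "amidated" not in description.lower():
        description += " | C-terminus amidated"
    record = SeqRecord(Seq(seq), id=description.split()[0], description=description)
    with open(path, "w") as fh:
        seqio_write([record], fh, "fasta")
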