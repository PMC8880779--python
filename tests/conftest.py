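"""Shared fixtures: hand-written PDB snippets and fixture interface reports."""

import numpy as np
import pytest

from bindsurf.structure_io import Atom, RadiiTable, StructureModel, assign_radii
from bindsurf.surface import InterfaceReport, ResidueBurial


def pdb_atom_line(serial, name, res_name, chain, res_id, x, y, z, element, record="ATOM"):
    return (
        f"{record:<6}{serial:>5} {name:^4} {res_name:<3} {chain}{res_id:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
    )


@pytest.fixture
def three_atom_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C"),
        pdb_atom_line(3, "C", "ALA", "A", 1, 2.2, 1.2, 0.0, "C"),
        "TER",
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    lines = [
        "MODEL        1",
        pdb_atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        "ENDMDL",
        "MODEL        2",
        pdb_atom_line(1, "CA", "GLY", "A", 1, 5.0, 5.0, 5.0, "C"),
        "ENDMDL",
        "END",
    ]
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_structure(specs, radii=True):
    """specs: list of (name, element, chain, res_id, res_name, xyz[, radius])."""
    atoms = []
    for i, spec in enumerate(specs):
        name, element, chain, res_id, res_name, xyz = spec[:6]
        atoms.append(
            Atom(
                serial=i + 1,
                name=name,
                element=element,
                residue_name=res_name,
                chain_id=chain,
                residue_number=res_id,
                position=np.asarray(xyz, dtype=float),
                vdw_radius=spec[6] if len(spec) > 6 else None,
            )
        )
    s = StructureModel(atoms)
    if radii and any(a.vdw_radius is None for a in atoms):
        s = assign_radii(s, RadiiTable())
    return s


def report_from_rows(ligand_rows=(), receptor_rows=(), threshold=0.5):
    """Build an InterfaceReport from (name, number, ratio) rows.

    Absolute areas are synthesized from the ratio with a 100 A^2 free-state
    area, which is all the burial-based operations consume.
    """
    burials = []
    for side, chain, rows in (
        ("receptor", "A", receptor_rows),
        ("ligand", "B", ligand_rows),
    ):
        for name, number, ratio in rows:
            burials.append(
                ResidueBurial(
                    residue=(chain, number, name),
                    side=side,
                    asa_free=100.0,
                    asa_complex=100.0 * (1.0 - ratio),
                    bsa=100.0 * ratio,
                    ratio=ratio,
                )
            )
    return InterfaceReport(
        receptor_chains=frozenset({"A"}),
        ligand_chains=frozenset({"B"}),
        burials=burials,
        threshold_used=threshold,
    )
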