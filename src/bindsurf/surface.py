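"""Solvent-accessible surface area and per-residue interface burial.

The engine is a deterministic Shrake–Rupley implementation: each atom is
covered with a fixed Fibonacci-spiral lattice of points on its probe-expanded
sphere, and its accessible area is the exposed-point fraction times the full
sphere area.  Interface burial follows the PISA convention: a residue's ASA
is computed in the complex and in its own binding partner alone (the other
partner removed), BSA = ASA_free - ASA_complex, and the BSA/ASA ratio is the
fractional burial used to call interface hot spots.

Because the same point lattice is used in the complex and in the isolated
partners, removing atoms can only expose points, so BSA >= 0 holds exactly,
not merely within tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ChainLookupError, DegenerateGeometryError
from .structure_io import StructureModel

#: Default probe radius (water) and sphere-point count; PISA-comparable.
DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960

#: Residue-class partition used for hot-spot filtering.  The design protocol
#: works with hydrophobic/uncharged residues; the partition is explicit and
#: configurable rather than hard-wired.
HYDROPHOBIC = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY", "CYS"}
)
CHARGED = frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"})
POLAR = frozenset({"SER", "THR", "ASN", "GLN", "TYR"})

#: Below this free-state area (A^2) the burial ratio is reported as 0 to
#: avoid a 0/0.
MIN_FREE_AREA = 0.1

ResidueId = tuple[str, int, str]


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (n, 3) on the sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and per-residue accessible areas (A^2)."""

    per_atom_area: dict[int, float]
    per_residue_area: dict[ResidueId, float]
    probe_radius: float
    n_sphere_points: int

    @property
    def total_area(self) -> float:
        return float(sum(self.per_atom_area.values()))


@dataclass(frozen=True)
class ResidueBurial:
    """Interface burial of one residue.

    ``asa_free`` is the residue's ASA with the *other* binding partner
    removed (its own side intact); ``ratio`` = BSA/ASA_free clipped to [0,1].
    """

    residue: ResidueId
    side: str  # "receptor" | "ligand"
    asa_free: float
    asa_complex: float
    bsa: float
    ratio: float

    @property
    def residue_class(self) -> str:
        if self.residue[2] in HYDROPHOBIC:
            return "hydrophobic"
        if self.residue[2] in CHARGED:
            return "charged"
        return "polar"


@dataclass(frozen=True)
class InterfaceReport:
    """Burial of every residue on both sides of a two-body interface."""

    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]
    burials: list[ResidueBurial]
    threshold_used: float = 0.5
    probe_radius: float = DEFAULT_PROBE
    n_sphere_points: int = DEFAULT_POINTS

    def side(self, which: str) -> list[ResidueBurial]:
        return [b for b in self.burials if b.side == which]

    def to_records(self) -> list[dict]:
        return [
            {
                "side": b.side,
                "chain": b.residue[0],
                "residue_number": b.residue[1],
                "residue_name": b.residue[2],
                "asa_free": round(b.asa_free, 3),
                "asa_complex": round(b.asa_complex, 3),
                "bsa": round(b.bsa, 3),
                "ratio": round(b.ratio, 4),
            }
            for b in self.burials
        ]


def _atom_exposure(
    coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int
) -> np.ndarray:
    """Exposed-point count per atom on the probe-expanded spheres."""
    n_atoms = coords.shape[0]
    expanded = radii + probe
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)

    # Identical-position atoms of equal radius make occlusion ill-defined.
    close = tree.query_pairs(r=1e-9)
    for i, j in close:
        if abs(radii[i] - radii[j]) < 1e-9:
            raise DegenerateGeometryError(
                f"atoms {i} and {j} coincide with equal radius"
            )

    max_expanded = float(expanded.max())
    exposed = np.empty(n_atoms, dtype=int)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        neighbors = tree.query_ball_point(coords[i], expanded[i] + max_expanded)
        neighbors = [j for j in neighbors if j != i]
        if not neighbors:
            exposed[i] = n_points
            continue
        nb = np.asarray(neighbors, dtype=int)
        # point buried if strictly inside a neighbor's expanded sphere
        d2 = np.sum(
            (pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2
        )
        buried = np.any(d2 < (expanded[nb] ** 2)[None, :], axis=1)
        exposed[i] = int(n_points - buried.sum())
    return exposed


def compute_sasa(
    s: StructureModel,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> SasaResult:
    """Shrake–Rupley SASA of every atom, aggregated per residue.

    The point lattice is a deterministic Fibonacci spiral, so repeated runs
    are bit-identical; per-residue areas are exact sums of atom areas.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60")
    if len(s) == 0:
        return SasaResult({}, {}, probe_radius, n_points)
    coords = s.coords()
    radii = s.radii()
    exposed = _atom_exposure(coords, radii, probe_radius, n_points)
    expanded = radii + probe_radius
    areas = (exposed / n_points) * 4.0 * np.pi * expanded**2

    per_atom = {a.serial: float(areas[i]) for i, a in enumerate(s.atoms)}
    per_res: dict[ResidueId, float] = {}
    for i, a in enumerate(s.atoms):
        per_res[a.residue_id] = per_res.get(a.residue_id, 0.0) + float(areas[i])
    return SasaResult(per_atom, per_res, probe_radius, n_points)


def interface_burial(
    complex_s: StructureModel,
    receptor_chains: set[str],
    ligand_chains: set[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    threshold: float = 0.5,
) -> InterfaceReport:
    """Per-residue BSA/ASA across a two-body interface.

    ASA is computed three times with identical parameters: once for the
    complex and once for each isolated side.  Residues whose BSA falls below
    numerical tolerance (or whose free-state ASA is negligible) report a
    ratio of 0.
    """
    receptor_chains = set(receptor_chains)
    ligand_chains = set(ligand_chains)
    if not receptor_chains or not ligand_chains:
        raise ValueError("both chain sets must be non-empty")
    if receptor_chains & ligand_chains:
        raise ValueError("receptor and ligand chain sets must be disjoint")
    present = set(complex_s.chain_ids)
    missing = (receptor_chains | ligand_chains) - present
    if missing:
        raise ChainLookupError(f"chains not in structure: {sorted(missing)}")

    sasa_complex = compute_sasa(complex_s, probe, n_points)
    burials: list[ResidueBurial] = []
    for side_name, side_chains in (
        ("receptor", receptor_chains),
        ("ligand", ligand_chains),
    ):
        isolated = complex_s.subset(side_chains)
        sasa_free = compute_sasa(isolated, probe, n_points)
        for res_id, free_area in sasa_free.per_residue_area.items():
            complex_area = sasa_complex.per_residue_area.get(res_id, 0.0)
            bsa = free_area - complex_area
            if free_area < MIN_FREE_AREA or bsa < 1e-6:
                ratio = 0.0
            else:
                ratio = float(np.clip(bsa / free_area, 0.0, 1.0))
            burials.append(
                ResidueBurial(
                    residue=res_id,
                    side=side_name,
                    asa_free=free_area,
                    asa_complex=complex_area,
                    bsa=bsa,
                    ratio=ratio,
                )
            )
    return InterfaceReport(
        receptor_chains=frozenset(receptor_chains),
        ligand_chains=frozenset(ligand_chains),
        burials=burials,
        threshold_used=threshold,
        probe_radius=probe,
        n_sphere_points=n_points,
    )


def select_hot_spots(
    report: InterfaceReport,
    threshold: float = 0.5,
    side: str = "receptor",
    classes: frozenset[str] | set[str] | None = None,
) -> list[ResidueBurial]:
    """Residues of one side with burial ratio >= threshold.

    ``classes`` restricts by residue class name ("hydrophobic", "charged",
    "polar"); None admits any class.  Sorted by descending ratio, ties by
    ascending residue number.  A threshold above 1 simply selects nothing.
    """
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    picked = [
        b
        for b in report.side(side)
        if b.ratio >= threshold
        and (classes is None or b.residue_class in classes)
    ]
    return sorted(picked, key=lambda b: (-b.ratio, b.residue[1]))


def report_to_tsv(report: InterfaceReport) -> str:
    """Serialize an :class:`InterfaceReport` as TSV text."""
    import pandas as pd

    return pd.DataFrame(report.to_records()).to_csv(sep="\t", index=False)
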