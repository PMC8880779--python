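"""Synthetic inputs for every pipeline stage.

Real inputs to the analysis — fluorescence recordings, inhibitor
titrations, and docked pose coordinate files — are not publicly deposited,
so this module generates desk-scale stand-ins with known ground truth:

* first-order rise/decay fluorescence traces with an optional lag phase and
  seeded Gaussian noise (the generator and the kinetics fitters are mutual
  oracles);
* one-site hyperbolic inhibition titrations;
* toy two-helix complexes with a planted buried-residue set, written as
  valid PDB, standing in for the unreleased docked poses;
* the published burial tables, parsed (see :mod:`bindsurf.tables`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from .errors import DataError
from .kinetics import KineticTrace
from .structure_io import Atom, StructureModel


@dataclass
class TraceSpec:
    """Parameters of a simulated first-order fluorescence trace.

    Defaults emulate the published assay conditions: 1 s sampling over
    2000 s (rise) or 3000 s (decay) and low-noise recordings (noise about
    1% of the amplitude).
    """

    kind: str  # "rise" | "decay"
    k: float  # s^-1
    f_start: float
    f_end: float
    lag: float = 0.0
    duration: float | None = None
    dt: float = 1.0
    noise_sd: float | None = None  # a.u.; None -> 1% of amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rise", "decay"):
            raise DataError(f"kind must be 'rise' or 'decay', got {self.kind!r}")
        if self.kind == "rise" and self.f_end <= self.f_start:
            raise DataError("rise requires f_end > f_start")
        if self.kind == "decay" and self.f_end >= self.f_start:
            raise DataError("decay requires f_end < f_start")
        if self.k <= 0 or self.dt <= 0 or self.lag < 0:
            raise DataError("k and dt must be positive, lag non-negative")
        if self.duration is None:
            self.duration = 2000.0 if self.kind == "rise" else 3000.0
        if self.noise_sd is None:
            self.noise_sd = 0.01 * abs(self.f_end - self.f_start)


def simulate_trace(spec: TraceSpec) -> KineticTrace:
    """F(t) = f_end - (f_end - f_start) * exp(-k (t - lag)) for t >= lag,
    f_start before the lag, plus i.i.d. Gaussian noise (seeded)."""
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    amplitude = spec.f_end - spec.f_start
    f = np.where(
        t < spec.lag,
        spec.f_start,
        spec.f_end - amplitude * np.exp(-spec.k * np.clip(t - spec.lag, 0.0, None)),
    )
    if spec.noise_sd and spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return KineticTrace(time=t, fluorescence=f, label=f"synthetic-{spec.kind}")


def simulate_titration(
    y0: float,
    qmax: float,
    ic50: float,
    concentrations: list[float] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One-site inhibition responses Y = y0 - qmax*x/(ic50+x) plus noise.

    Returns a DataFrame with columns ``conc_nM`` and ``pct_increase``.
    """
    x = np.asarray(concentrations, dtype=float)
    if np.any(x < 0):
        raise DataError("concentrations must be non-negative")
    if ic50 <= 0:
        raise DataError("ic50 must be positive")
    y = y0 - qmax * x / (ic50 + x)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return pd.DataFrame({"conc_nM": x, "pct_increase": y})


@dataclass
class ToyComplexSpec:
    """Two ideal poly-alanine helices with a planted buried-residue set.

    Chain A is an ideal helix (rise 1.5 Å, twist 100 deg per residue) whose
    phase is rotated so the planted residues' Cβ point toward the partner;
    chain B is its mirror image across the inter-axial midplane at
    ``inter_axial_distance``.  The planted set must respect helix
    periodicity (an i, i+3, i+7 face by default) for all members to face
    the partner.
    """

    n_residues: int = 12
    inter_axial_distance: float = 9.0
    rise_per_residue: float = 1.5
    twist_deg: float = 100.0
    ca_radius: float = 2.3
    planted_buried: frozenset[int] = frozenset({3, 6, 10})
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.planted_buried) - set(range(1, self.n_residues + 1))
        if bad:
            raise DataError(f"planted residues outside 1..{self.n_residues}: {bad}")
        if not self.planted_buried:
            raise DataError("planted_buried must be non-empty")


def _helix_atoms(
    spec: ToyComplexSpec, chain_id: str, mirror_x: float | None, serial0: int
) -> list[Atom]:
    atoms: list[Atom] = []
    twist = math.radians(spec.twist_deg)
    # rotate the helix so the planted residues' mean phase points along +x
    planted = sorted(spec.planted_buried)
    mean_phase = np.angle(
        np.mean([np.exp(1j * twist * (n - 1)) for n in planted])
    )
    phase0 = -mean_phase
    serial = serial0
    for n in range(1, spec.n_residues + 1):
        theta = phase0 + twist * (n - 1)
        z = spec.rise_per_residue * (n - 1)
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        ca = spec.ca_radius * radial + np.array([0.0, 0.0, z])
        # idealized backbone pseudo-positions flanking the Cα
        tang = math.radians(50.0)
        n_dir = np.array(
            [math.cos(theta - tang), math.sin(theta - tang), 0.0]
        )
        c_dir = np.array(
            [math.cos(theta + tang), math.sin(theta + tang), 0.0]
        )
        positions = {
            "N": 1.6 * n_dir + np.array([0.0, 0.0, z - 0.75]),
            "CA": ca,
            "C": 1.6 * c_dir + np.array([0.0, 0.0, z + 0.75]),
            "O": 2.6 * c_dir + np.array([0.0, 0.0, z + 0.9]),
            "CB": (spec.ca_radius + 1.5) * radial + np.array([0.0, 0.0, z]),
        }
        for name, pos in positions.items():
            if mirror_x is not None:
                pos = np.array([2.0 * mirror_x - pos[0], pos[1], pos[2]])
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name="ALA",
                    chain_id=chain_id,
                    residue_number=n,
                    position=pos,
                )
            )
            serial += 1
    return atoms


def make_toy_complex(
    spec: ToyComplexSpec | None = None,
) -> tuple[StructureModel, dict[str, frozenset[int]]]:
    """Build the two-chain toy complex and its ground-truth burial labels.

    Returns the structure (chains A and B; radii not yet assigned) and a
    mapping chain id -> planted buried residue numbers.  With the default
    geometry the planted residues bury above ratio 0.3 at 9 Å inter-axial
    distance and nothing is buried at large separations.
    """
    spec = spec or ToyComplexSpec()
    atoms_a = _helix_atoms(spec, "A", mirror_x=None, serial0=1)
    atoms_b = _helix_atoms(
        spec, "B", mirror_x=spec.inter_axial_distance / 2.0, serial0=len(atoms_a) + 1
    )
    atoms = atoms_a + atoms_b
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        atoms = [
            Atom(
                serial=a.serial,
                name=a.name,
                element=a.element,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                residue_number=a.residue_number,
                position=a.position + rng.normal(0.0, spec.jitter_sd, size=3),
            )
            for a in atoms
        ]
    model = StructureModel(atoms, title="synthetic two-helix toy complex")
    truth = {
        "A": frozenset(spec.planted_buried),
        "B": frozenset(spec.planted_buried),
    }
    return model, truth


def table_fixtures() -> dict:
    """The published burial tables as tidy DataFrames, plus design constants.

    Keys: ``abeta_cam`` and ``abeta_calbindin`` (columns: structure, side,
    residue_name, residue_number, ratio), ``delta_g_cam``,
    ``delta_g_calbindin``, ``cam_calcium_sites`` and
    ``reference_geometry`` (the synthetic Cα stand-in used by the
    mimetic-design calibration).
    """

    def tidy(table: dict, side_names: tuple[str, str]) -> pd.DataFrame:
        rows = []
        for structure, sides in table.items():
            for side_key, records in sides.items():
                side = side_names[0] if side_key == "abeta" else side_names[1]
                for name, number, ratio in records:
                    rows.append(
                        {
                            "structure": structure,
                            "side": side,
                            "residue_name": name,
                            "residue_number": number,
                            "ratio": ratio,
                        }
                    )
        return pd.DataFrame(rows)

    return {
        "abeta_cam": tidy(tables.ABETA_CAM, ("abeta", "cam")),
        "abeta_calbindin": tidy(
            tables.ABETA_CALBINDIN, ("abeta", "calbindin")
        ),
        "delta_g_cam": dict(tables.DELTA_G_CAM),
        "delta_g_calbindin": dict(tables.DELTA_G_CALBINDIN),
        "cam_calcium_sites": tables.CAM_CALCIUM_SITE_RESIDUES,
        "reference_geometry": dict(tables.REFERENCE_CA_GEOMETRY),
    }
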