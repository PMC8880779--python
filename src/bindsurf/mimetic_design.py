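"""Binding-surface-mimetic peptide design.

The protocol converts interface hot-spot residues of a receptor into a short
linear peptide that mimics their spatial arrangement:

1. order the hot spots along a greedy nearest-neighbor path through their
   Cα positions, starting from the most deeply buried residue;
2. map each hot spot through a reduced hydrophobic alphabet {V, F, M, L, A};
3. between consecutive hot spots separated by a Cα gap of d Å, insert
   ``round(d / 3.8) - 1`` non-polar spacer residues (capped), 3.8 Å being
   the virtual bond length of an extended chain;
4. truncate from the low-ratio end to the maximum length and annotate the
   C-terminus as amidated.

The shipped :func:`reference_design` applies this machinery to the packaged
calmodulin hot-spot fixture with a synthetic reference geometry and emits
the 10-residue antagonist VFAFAMAFML; that configuration is an explicit
calibration (the historical residue-pairing choice is not recoverable), not
a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoordinateError, DegenerateDesignError
from .tables import (
    ABETA_CAM,
    ONE_TO_THREE,
    REFERENCE_CA_GEOMETRY,
    THREE_TO_ONE,
)

#: Default substitution map onto the reduced hydrophobic alphabet.  Identity
#: on {V,F,M,L,A}; conservative size/chemistry substitutions elsewhere.
#: Charged and polar residues are expected to be excluded at hot-spot
#: selection and are absent from the map.
DEFAULT_SUBSTITUTION = {
    "V": "V", "F": "F", "M": "M", "L": "L", "A": "A",
    "I": "V",
    "W": "F", "Y": "F",
    "C": "M",
    "G": "A", "P": "A", "S": "A", "T": "A",
}


@dataclass(frozen=True)
class HotSpot:
    residue: tuple[str, int, str]  # (chain, number, 3-letter name)
    ratio: float
    ca_position: np.ndarray  # (3,) Å

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.residue[2]]


@dataclass
class HotSpotSet:
    """Interface hot spots with Cα coordinates and their pose of origin."""

    entries: list[HotSpot]
    source: str = ""

    def __post_init__(self) -> None:
        for h in self.entries:
            pos = np.asarray(h.ca_position, dtype=float)
            if pos.shape != (3,) or not np.all(np.isfinite(pos)):
                raise CoordinateError(
                    f"residue {h.residue}: non-finite or missing Cα coordinates"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DesignConfig:
    substitution_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION)
    )
    spacer_residue: str = "A"
    virtual_bond_length: float = 3.8
    max_spacers_per_gap: int = 3
    max_length: int = 10
    ordering: str = "nearest-neighbor-path"  # or "ratio-descending"
    amidate_c_terminus: bool = True

    def __post_init__(self) -> None:
        if self.max_length < 2:
            raise ValueError("max_length must be >= 2")
        if not 3.5 <= self.virtual_bond_length <= 4.0:
            raise ValueError("virtual_bond_length must be within [3.5, 4.0] Å")
        if self.ordering not in ("nearest-neighbor-path", "ratio-descending"):
            raise ValueError(f"unknown ordering {self.ordering!r}")


@dataclass(frozen=True)
class MimeticPeptide:
    """A designed sequence with per-position provenance."""

    sequence: str  # one-letter, N→C
    amidated: bool
    provenance: tuple[str, ...]  # hot-spot residue tag or "spacer"
    gap_distances: tuple[float, ...]  # Cα gaps between consecutive hot spots

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.provenance):
            raise ValueError("provenance must annotate every position")
        if all(tag == "spacer" for tag in self.provenance):
            raise DegenerateDesignError("peptide contains no hot-spot position")


def order_hot_spots(hot_spots: HotSpotSet, mode: str = "nearest-neighbor-path") -> HotSpotSet:
    """Order hot spots for linearization.

    Nearest-neighbor-path mode builds a greedy path: start from the
    highest-ratio residue (ties to the lowest residue number) and repeatedly
    append the spatially closest unvisited residue (distance ties also to
    the lowest residue number).  Ratio-descending mode ignores geometry.
    """
    entries = list(hot_spots.entries)
    if len(entries) < 2:
        return HotSpotSet(entries, source=hot_spots.source)
    if mode == "ratio-descending":
        ordered = sorted(entries, key=lambda h: (-h.ratio, h.residue[1]))
        return HotSpotSet(ordered, source=hot_spots.source)
    if mode != "nearest-neighbor-path":
        raise ValueError(f"unknown ordering mode {mode!r}")

    start = min(entries, key=lambda h: (-h.ratio, h.residue[1]))
    path = [start]
    remaining = [h for h in entries if h is not start]
    while remaining:
        last = path[-1]
        nxt = min(
            remaining,
            key=lambda h: (
                float(np.linalg.norm(h.ca_position - last.ca_position)),
                h.residue[1],
            ),
        )
        path.append(nxt)
        remaining.remove(nxt)
    return HotSpotSet(path, source=hot_spots.source)


def _spacer_count(gap: float, cfg: DesignConfig) -> int:
    return min(
        cfg.max_spacers_per_gap,
        max(0, round(gap / cfg.virtual_bond_length) - 1),
    )


def _emit(ordered: list[HotSpot], cfg: DesignConfig) -> tuple[str, list[str], list[float]]:
    seq: list[str] = []
    prov: list[str] = []
    gaps: list[float] = []
    for i, h in enumerate(ordered):
        if i > 0:
            gap = float(np.linalg.norm(h.ca_position - ordered[i - 1].ca_position))
            gaps.append(gap)
            for _ in range(_spacer_count(gap, cfg)):
                seq.append(cfg.spacer_residue)
                prov.append("spacer")
        letter = cfg.substitution_map.get(h.one_letter)
        if letter is None:
            raise DegenerateDesignError(
                f"residue {h.residue} ({h.one_letter}) has no substitution; "
                "exclude non-hydrophobic residues at hot-spot selection"
            )
        seq.append(letter)
        tag = f"{h.residue[2].capitalize()}{h.residue[1]}"
        prov.append(tag)
    return "".join(seq), prov, gaps


def design_peptide(ordered: HotSpotSet, cfg: DesignConfig | None = None) -> MimeticPeptide:
    """Emit a mimetic peptide from an ordered hot-spot set.

    If the emitted sequence would exceed ``cfg.max_length``, hot spots are
    dropped from the low-ratio end (ties dropped at the higher residue
    number) and spacers are recomputed over the surviving path until the
    peptide fits.
    """
    cfg = cfg or DesignConfig()
    if len(ordered) == 0:
        raise ValueError("ordered hot-spot set is empty")
    kept = list(ordered.entries)
    if all(
        cfg.substitution_map.get(h.one_letter, cfg.spacer_residue)
        == cfg.spacer_residue
        for h in kept
    ):
        raise DegenerateDesignError("every hot spot maps to the spacer residue")

    while True:
        seq, prov, gaps = _emit(kept, cfg)
        if len(seq) <= cfg.max_length or len(kept) == 1:
            break
        drop = min(kept, key=lambda h: (h.ratio, -h.residue[1]))
        kept.remove(drop)

    return MimeticPeptide(
        sequence=seq,
        amidated=cfg.amidate_c_terminus,
        provenance=tuple(prov),
        gap_distances=tuple(gaps),
    )


#: The explicit residue pairing of the shipped calibration (see module
#: docstring): calmodulin structure-1 hot spots treated as participating in
#: interface pairs, by author residue number.
REFERENCE_PAIR_RESIDUES = (27, 19, 89, 71, 68, 51, 32)


def reference_hot_spot_set() -> HotSpotSet:
    """The packaged structure-1 calibration fixture.

    Ratios come from the published structure-1 calmodulin burial table; Cα
    positions are the synthetic collinear reference geometry shipped with
    the package.
    """
    ratio_by_number = {num: r for (_, num, r) in ABETA_CAM[1]["cam"]}
    entries = []
    for (chain, num, name), pos in REFERENCE_CA_GEOMETRY.items():
        entries.append(
            HotSpot(
                residue=(chain, num, name),
                ratio=ratio_by_number[num],
                ca_position=np.asarray(pos, dtype=float),
            )
        )
    return HotSpotSet(entries, source="cam-structure-1-reference")


def reference_design(cfg: DesignConfig | None = None) -> MimeticPeptide:
    """Run the shipped calibration end to end (emits VFAFAMAFML)."""
    ordered = order_hot_spots(reference_hot_spot_set())
    return design_peptide(ordered, cfg or DesignConfig())
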