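"""Docking-pose acceptance criteria and ΔG ranking.

A candidate complex between the amyloid-β(1–42) peptide and a calcium-sensor
receptor is retained only if

1. the hydrophobic core of the peptide's 25–35 segment is engaged at the
   interface (at least ``min_hydrophobic_contacts`` hydrophobic-class
   segment residues buried above the threshold), and
2. no Ca2+-coordinating receptor residue is buried above the threshold,
   since complexation is known experimentally not to perturb calcium
   binding.

Passing poses are ranked by ascending docking ΔG (metadata from the docking
program; never computed here), with ties broken by overlap with a reference
hot-spot set and then by pose id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CriteriaError
from .structure_io import StructureModel
from .surface import InterfaceReport, interface_burial
from .tables import CAM_CALCIUM_SITE_RESIDUES


@dataclass
class PoseCriteria:
    """Acceptance thresholds for a docked peptide:receptor pose."""

    target_segment: tuple[int, int] = (25, 35)
    min_hydrophobic_contacts: int = 2
    burial_threshold: float = 0.5
    #: receptor residue numbers whose burial disqualifies the pose; default
    #: is the calmodulin EF-loop calcium-coordinating set (1CLL numbering).
    forbidden_residues: frozenset[int] = field(
        default_factory=lambda: CAM_CALCIUM_SITE_RESIDUES
    )
    #: optional reference hot-spot residue numbers used for tie-breaking
    overlap_reference: frozenset[int] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.target_segment
        if not (1 <= lo <= hi <= 42):
            raise ValueError("target_segment must lie within residues 1-42")
        if self.min_hydrophobic_contacts < 1:
            raise ValueError("min_hydrophobic_contacts must be >= 1")


@dataclass
class PoseRecord:
    """A candidate pose: structure and/or precomputed interface report."""

    pose_id: str
    delta_g: float
    structure: StructureModel | None = None
    report: InterfaceReport | None = None
    receptor_chains: frozenset[str] = frozenset({"A"})
    ligand_chains: frozenset[str] = frozenset({"B"})

    def get_report(self, probe: float = 1.4, n_points: int = 960) -> InterfaceReport:
        if self.report is not None:
            return self.report
        if self.structure is None:
            raise CriteriaError(f"pose {self.pose_id}: no report and no structure")
        self.report = interface_burial(
            self.structure,
            set(self.receptor_chains),
            set(self.ligand_chains),
            probe=probe,
            n_points=n_points,
        )
        return self.report


@dataclass(frozen=True)
class PoseVerdict:
    pose_id: str
    passed: bool
    n_segment_contacts: int
    violated_forbidden: tuple[tuple[str, int, str], ...]
    rank: int | None = None


def evaluate_pose(pose: PoseRecord, criteria: PoseCriteria) -> PoseVerdict:
    """Apply the acceptance criteria to one pose.

    ``n_segment_contacts`` counts ligand-side residues within the target
    segment that are hydrophobic-class and buried at or above the threshold;
    the pose passes iff that count meets the minimum and no forbidden
    receptor residue is buried.
    """
    report = pose.get_report()
    lo, hi = criteria.target_segment
    ligand = report.side("ligand")
    in_segment = [b for b in ligand if lo <= b.residue[1] <= hi]
    if not in_segment:
        raise CriteriaError(
            f"pose {pose.pose_id}: peptide chain has no residues in "
            f"segment {lo}-{hi}"
        )
    n_contacts = sum(
        1
        for b in in_segment
        if b.residue_class == "hydrophobic" and b.ratio >= criteria.burial_threshold
    )
    violated = tuple(
        b.residue
        for b in report.side("receptor")
        if b.residue[1] in criteria.forbidden_residues
        and b.ratio >= criteria.burial_threshold
    )
    passed = n_contacts >= criteria.min_hydrophobic_contacts and not violated
    return PoseVerdict(
        pose_id=pose.pose_id,
        passed=passed,
        n_segment_contacts=n_contacts,
        violated_forbidden=violated,
    )


def _overlap(pose: PoseRecord, criteria: PoseCriteria) -> int:
    if criteria.overlap_reference is None:
        return 0
    report = pose.get_report()
    hot = {
        b.residue[1]
        for b in report.side("receptor")
        if b.ratio >= criteria.burial_threshold
    }
    return len(hot & criteria.overlap_reference)


def rank_poses(
    poses: list[PoseRecord],
    criteria: PoseCriteria | None = None,
    verdicts: list[PoseVerdict] | None = None,
) -> list[tuple[PoseRecord, PoseVerdict]]:
    """Rank the passing poses by ascending ΔG.

    Ties break toward larger overlap with ``criteria.overlap_reference``,
    then lexicographically by pose id.  With no passing pose the result is
    simply empty (an empty-result signal, not an exception).
    """
    criteria = criteria or PoseCriteria()
    if verdicts is None:
        verdicts = [evaluate_pose(p, criteria) for p in poses]
    passing = [(p, v) for p, v in zip(poses, verdicts) if v.passed]
    passing.sort(
        key=lambda pv: (pv[0].delta_g, -_overlap(pv[0], criteria), pv[0].pose_id)
    )
    ranked = []
    for rank, (p, v) in enumerate(passing, start=1):
        ranked.append(
            (
                p,
                PoseVerdict(
                    pose_id=v.pose_id,
                    passed=v.passed,
                    n_segment_contacts=v.n_segment_contacts,
                    violated_forbidden=v.violated_forbidden,
                    rank=rank,
                ),
            )
        )
    return ranked
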