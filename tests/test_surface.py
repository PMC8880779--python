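import math

import numpy as np
import pytest

from bindsurf.errors import ChainLookupError, DegenerateGeometryError
from bindsurf.surface import (
    compute_sasa,
    fibonacci_sphere,
    interface_burial,
    select_hot_spots,
)
from bindsurf.synthetic_data import ToyComplexSpec, make_toy_complex, table_fixtures
from bindsurf.structure_io import assign_radii

from conftest import make_structure, report_from_rows

PROBE = 1.4


def random_cluster(n, seed, box=8.0):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, box, size=(n, 3))
    return make_structure(
        [("C", "C", "A", i + 1, "UNK", coords[i]) for i in range(n)]
    )


def monte_carlo_sasa(s, probe, n_points=100_000, seed=0):
    """Independent rejection-sampling oracle for per-atom accessible area."""
    rng = np.random.default_rng(seed)
    coords = s.coords()
    radii = s.radii()
    expanded = radii + probe
    out = {}
    for i, atom in enumerate(s.atoms):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(s.atoms)):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= expanded[j] ** 2
        out[atom.serial] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out


class TestSphereLattice:
    def test_points_on_unit_sphere(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_centroid_near_origin(self):
        assert np.linalg.norm(fibonacci_sphere(960).mean(axis=0)) < 1e-3


class TestSasaClosedForms:
    def test_isolated_sphere(self):
        s = make_structure([("C", "C", "A", 1, "UNK", (0, 0, 0))])
        result = compute_sasa(s, PROBE, 960)
        expected = 4.0 * np.pi * (1.70 + PROBE) ** 2
        assert result.total_area == pytest.approx(expected, rel=1e-12)

    def test_two_spheres_spherical_cap(self):
        # equal expanded spheres at distance equal to their radius: each
        # loses a cap of height R - d/2
        s = make_structure(
            [
                ("C", "C", "A", 1, "UNK", (0, 0, 0)),
                ("C", "C", "A", 2, "UNK", (3.10, 0, 0)),
            ]
        )
        result = compute_sasa(s, PROBE, 960)
        R = 3.10
        expected = 4.0 * np.pi * R**2 - 2.0 * np.pi * R * (R - R / 2.0)
        for area in result.per_atom_area.values():
            assert area == pytest.approx(expected, rel=5e-3)

    def test_full_occlusion(self):
        s = make_structure(
            [
                ("S1", "C", "A", 1, "UNK", (0, 0, 0), 0.6),
                ("S2", "C", "A", 2, "UNK", (0.1, 0, 0), 2.5),
            ]
        )
        result = compute_sasa(s, PROBE, 960)
        assert result.per_atom_area[1] == 0.0

    def test_coinciding_atoms_rejected(self):
        s = make_structure(
            [
                ("C", "C", "A", 1, "UNK", (1, 1, 1)),
                ("C", "C", "A", 2, "UNK", (1, 1, 1)),
            ]
        )
        with pytest.raises(DegenerateGeometryError):
            compute_sasa(s, PROBE, 960)


class TestSasaProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_point_count_convergence(self, seed):
        s = random_cluster(20, seed)
        coarse = compute_sasa(s, PROBE, 960).total_area
        fine = compute_sasa(s, PROBE, 3840).total_area
        assert abs(coarse - fine) / fine < 0.02

    @pytest.mark.parametrize("seed", [0, 1])
    def test_monte_carlo_oracle_agreement(self, seed):
        s = random_cluster(8, seed, box=6.0)
        result = compute_sasa(s, PROBE, 960)
        oracle = monte_carlo_sasa(s, PROBE, n_points=100_000, seed=seed)
        for serial, area in result.per_atom_area.items():
            ref = oracle[serial]
            if ref < 1.0:  # fully or nearly occluded: compare absolutely
                assert abs(area - ref) < 1.0
            else:
                assert abs(area - ref) / ref < 0.03

    def test_additivity_exact(self):
        s = random_cluster(15, 3)
        result = compute_sasa(s, PROBE, 960)
        assert sum(result.per_atom_area.values()) == pytest.approx(
            sum(result.per_residue_area.values()), rel=1e-12
        )

    def test_library_cross_check(self):
        # independent Shrake-Rupley implementation from biotite
        import biotite.structure as bst

        s = random_cluster(20, 4)
        mine = compute_sasa(s, PROBE, 960)
        arr = bst.AtomArray(len(s))
        arr.coord = s.coords().astype(np.float32)
        for i, a in enumerate(s.atoms):
            arr.chain_id[i] = a.chain_id
            arr.res_id[i] = a.residue_number
            arr.res_name[i] = a.residue_name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        ref = bst.sasa(arr, probe_radius=PROBE, point_number=960,
                       vdw_radii=s.radii())
        for i, a in enumerate(s.atoms):
            assert mine.per_atom_area[a.serial] == pytest.approx(
                float(ref[i]), rel=1e-4, abs=1e-4
            )


@pytest.fixture(scope="module")
def toy():
    model, truth = make_toy_complex(ToyComplexSpec())
    return assign_radii(model), truth


class TestInterfaceBurial:
    def test_bsa_non_negative(self, toy):
        model, _ = toy
        report = interface_burial(model, {"A"}, {"B"})
        for b in report.burials:
            assert b.asa_complex <= b.asa_free + 1e-6
            assert b.ratio >= 0.0

    def test_planted_residues_buried(self, toy):
        model, truth = toy
        report = interface_burial(model, {"A"}, {"B"})
        for b in report.side("ligand"):
            if b.residue[1] in truth["B"]:
                assert b.ratio > 0.3

    def test_separated_partners_have_zero_burial(self):
        model, _ = make_toy_complex(ToyComplexSpec(inter_axial_distance=100.0))
        report = interface_burial(assign_radii(model), {"A"}, {"B"})
        assert all(b.ratio == 0.0 for b in report.burials)

    def test_label_swap_symmetry(self, toy):
        model, _ = toy
        fwd = interface_burial(model, {"A"}, {"B"})
        rev = interface_burial(model, {"B"}, {"A"})
        fwd_ratios = {b.residue: b.ratio for b in fwd.burials}
        rev_ratios = {b.residue: b.ratio for b in rev.burials}
        assert fwd_ratios == rev_ratios

    def test_sandwiched_residue_fully_buried(self):
        # one ligand atom enclosed between receptor atoms on all sides
        shell = []
        for i, (dx, dy, dz) in enumerate(
            [(3, 0, 0), (-3, 0, 0), (0, 3, 0), (0, -3, 0), (0, 0, 3), (0, 0, -3)]
        ):
            shell.append(("C", "C", "A", i + 1, "GLY", (dx, dy, dz), 2.2))
        shell.append(("C", "C", "B", 1, "GLY", (0, 0, 0), 1.7))
        s = make_structure(shell)
        report = interface_burial(s, {"A"}, {"B"})
        (buried,) = report.side("ligand")
        assert buried.ratio == pytest.approx(1.0)

    def test_missing_chain_raises(self, toy):
        model, _ = toy
        with pytest.raises(ChainLookupError):
            interface_burial(model, {"A"}, {"Z"})

    def test_disjoint_chain_sets_required(self, toy):
        model, _ = toy
        with pytest.raises(ValueError):
            interface_burial(model, {"A"}, {"A", "B"})


class TestHotSpots:
    def test_published_high_burial_residues(self):
        rows = table_fixtures()["abeta_cam"]
        cam = rows[(rows.structure == 1) & (rows.side == "cam")]
        report = report_from_rows(
            receptor_rows=[
                (r.residue_name, r.residue_number, r.ratio) for r in cam.itertuples()
            ]
        )
        hot = select_hot_spots(report, threshold=0.9, side="receptor")
        numbers = {b.residue[1] for b in hot}
        assert numbers == {27, 32, 52, 63, 68, 71, 19, 89, 98}
        ratios = [b.ratio for b in hot]
        assert ratios == sorted(ratios, reverse=True)

    def test_threshold_above_one_selects_nothing(self):
        report = report_from_rows(receptor_rows=[("ILE", 1, 1.0)])
        assert select_hot_spots(report, threshold=1.01) == []

    def test_class_filter(self):
        report = report_from_rows(
            receptor_rows=[
                ("LEU", 1, 0.9),
                ("ASP", 2, 0.9),
                ("SER", 3, 0.9),
                ("PHE", 4, 0.6),
            ]
        )
        hot = select_hot_spots(
            report, threshold=0.5, side="receptor", classes={"hydrophobic"}
        )
        assert [b.residue[2] for b in hot] == ["LEU", "PHE"]

    def test_tie_break_by_residue_number(self):
        report = report_from_rows(
            receptor_rows=[("LEU", 9, 0.8), ("ILE", 2, 0.8), ("VAL", 5, 0.9)]
        )
        hot = select_hot_spots(report, threshold=0.5)
        assert [b.residue[1] for b in hot] == [5, 2, 9]
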