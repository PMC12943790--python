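"""Ternary assembly: triangulation, liquidus surface, domain maps."""

import numpy as np
import pytest

from saltscreen import (
    CrystallinePhase,
    Role,
    assemble,
    solve_simple_eutectic,
    ternary_eutectic,
    triangulate,
)
from saltscreen.datasets import generate_synthetic_system
from saltscreen.ternary import SubTernary
from tests.conftest import make_phase, scan_ternary_eutectic


def corner_phases(t_fus=400.0, dh_fus=25000.0):
    return [
        make_phase("A", Role.ENANTIOMER, (1, 0, 0), t_fus, dh_fus),
        make_phase("B", Role.ENANTIOMER, (0, 1, 0), t_fus, dh_fus),
        make_phase("C", Role.RESOLVING_AGENT, (0, 0, 1), t_fus, dh_fus),
    ]


class TestTriangulate:
    def test_three_corner_phases_give_one_subtriangle(self):
        subs = triangulate(corner_phases())
        assert len(subs) == 1
        assert set(subs[0].names) == {"A", "B", "C"}

    def test_pregabalin_case_has_four_subtriangles(self, case3):
        subs = triangulate(case3.phases, case3.explicit_triplets)
        assert len(subs) == 4
        for p in case3.phases:
            assert any(p.name in s.names for s in subs)

    def test_pregabalin_case_delaunay_agrees_with_curated_triplets(self, case3):
        auto = {frozenset(s.names) for s in triangulate(case3.phases)}
        curated = {frozenset(t) for t in case3.explicit_triplets}
        assert auto == curated

    def test_case1_double_salt_separates_the_salt_domains(self, case1):
        subs = triangulate(case1.phases, case1.explicit_triplets)
        for name in ("4", "5", "6"):
            assert any(name in s.names for s in subs)
        assert not any({"4", "6"} <= set(s.names) for s in subs)

    def test_unknown_phase_in_explicit_triplet(self, case1):
        with pytest.raises(ValueError, match="unknown"):
            triangulate(case1.phases, [["1", "2", "nope"]])

    def test_collinear_phases_rejected(self):
        phases = [
            make_phase("A", coords=(1, 0, 0)),
            make_phase("B", coords=(0.5, 0.5, 0)),
            make_phase("C", coords=(0, 1, 0)),
        ]
        with pytest.raises(ValueError):
            triangulate(phases)

    def test_triplet_with_interior_phase_rejected(self):
        # the whole simplex as one triangle swallows the interior double salt
        study = generate_synthetic_system(0, with_double_salt=True)
        with pytest.raises(ValueError, match="inside"):
            triangulate(study.phases, [["E1", "E2", "G"]])


class TestTernaryEutectic:
    def test_three_identical_phases_meet_at_equal_fractions(self):
        sub = SubTernary(tuple(corner_phases()))
        comp, t_eu, y = ternary_eutectic(sub)
        assert np.allclose(y, 1 / 3, atol=1e-9)
        assert np.allclose(comp.fractions, 1 / 3, atol=1e-9)
        assert t_eu < 400.0

    @pytest.mark.parametrize("seed", range(8))
    def test_below_every_pairwise_edge_eutectic(self, seed):
        rng = np.random.default_rng(seed)
        phases = corner_phases()
        phases = [
            CrystallinePhase(
                p.name, p.role, p.coords,
                rng.uniform(330, 470), rng.uniform(1.5e4, 7e4),
            )
            for p in phases
        ]
        sub = SubTernary(tuple(phases))
        _, t_star, _ = ternary_eutectic(sub)
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            pair = solve_simple_eutectic(phases[i], phases[j])
            assert t_star <= pair.T_eu + 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_grid_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        phases = [
            CrystallinePhase(
                n, Role.OTHER_SALT, c, rng.uniform(330, 470), rng.uniform(1.5e4, 7e4)
            )
            for n, c in [("A", (1, 0, 0)), ("B", (0, 1, 0)), ("C", (0, 0, 1))]
        ]
        _, t_star, _ = ternary_eutectic(SubTernary(tuple(phases)))
        assert t_star == pytest.approx(scan_ternary_eutectic(phases), abs=0.01)

    def test_pregabalin_salt_agent_triplet(self, case3):
        diagram = case3.diagram()
        key = ("4''", "5''", "6''")
        comp, t_star, _ = diagram.eutectics[key]
        sub = next(s for s in diagram.subternaries if s.names == key)
        assert t_star == pytest.approx(
            scan_ternary_eutectic(sub.phases), abs=0.01
        )


class TestLiquidusAt:
    def test_phase_coordinates_return_its_melting_point(self, case3):
        d = case3.diagram(compute_eutectics=False)
        for name in ("1''", "2''", "4''", "5''", "6''"):
            p = case3.phase(name)
            t, owner = d.liquidus_at(p.coords)
            assert owner == name
            assert t == pytest.approx(p.t_fus, abs=1e-6)

    def test_pregabalin_test_point_dominated_by_high_melting_salt(self, case3):
        d = case3.diagram(compute_eutectics=False)
        _, owner = d.liquidus_at((0.25, 0.25, 0.5))
        assert owner == "4''"

    def test_case1_test_point_dominated_by_double_salt(self, case1):
        d = case1.diagram(compute_eutectics=False)
        _, owner = d.liquidus_at((0.25, 0.25, 0.5))
        assert owner == "5"

    def test_outside_convex_hull_is_an_error(self, case1):
        # the agent corner is not covered in case 1 (no crystalline agent)
        d = case1.diagram(compute_eutectics=False)
        with pytest.raises(ValueError, match="outside"):
            d.liquidus_at((0.0, 0.0, 1.0))

    def test_edge_restriction_reproduces_binary_envelope(self, case3):
        """Along the salt-salt edge the surface equals the pseudo-binary
        two-branch envelope."""
        from saltscreen import solve_pair_diagram

        d = case3.diagram(compute_eutectics=False)
        bd = solve_pair_diagram(case3.phase("4''"), case3.phase("5''"))
        for x in [0.05, 0.086, 0.2, 0.5, 0.8, 0.95]:
            # section coordinate x of salt 4'' -> simplex composition
            c = tuple(
                x * np.asarray(case3.phase("4''").coords)
                + (1 - x) * np.asarray(case3.phase("5''").coords)
            )
            t_surface, _ = d.liquidus_at(c)
            t_binary, _ = bd.liquidus(x)
            assert t_surface == pytest.approx(t_binary, abs=1e-6)


class TestDomainMap:
    def test_identical_corner_system_has_equal_domains(self):
        d = assemble(corner_phases())
        areas = d.domain_map(60).areas()
        assert sum(areas.values()) == pytest.approx(1.0, abs=1e-12)
        for frac in areas.values():
            assert frac == pytest.approx(1 / 3, abs=0.05)

    def test_case1_nearly_mirror_symmetric(self, case1):
        areas = case1.diagram(compute_eutectics=False).domain_map(80).areas()
        assert areas["1"] == pytest.approx(areas["3"], abs=0.05)
        assert areas["4"] == pytest.approx(areas["6"], abs=0.05)

    def test_pregabalin_domains_very_asymmetric(self, case3):
        areas = case3.diagram(compute_eutectics=False).domain_map(80).areas()
        assert areas["4''"] > areas["5''"]

    def test_enantiomer_relabeling_mirrors_map_exactly(self, case1):
        d = case1.diagram(compute_eutectics=False)
        mirrored_phases = [
            CrystallinePhase(
                p.name, p.role, (p.coords[1], p.coords[0], p.coords[2]),
                p.t_fus, p.dh_fus,
            )
            for p in case1.phases
        ]
        d_mir = assemble(mirrored_phases, explicit_triplets=case1.explicit_triplets)
        n = 40
        orig = d.domain_map(n).as_dict()
        mir = d_mir.domain_map(n).as_dict()
        for (i, j, k), label in orig.items():
            assert mir[(j, i, k)] == label

    def test_grid_density_validation(self, case1):
        with pytest.raises(ValueError):
            case1.diagram(compute_eutectics=False).domain_map(1)


class TestAssembledDiagram:
    def test_every_ternary_eutectic_below_its_edge_eutectics(self, case3):
        d = case3.diagram()
        assert d.eutectics  # at least one sub-ternary fully parameterized
        for names, (comp, t_star, _) in d.eutectics.items():
            sub = next(s for s in d.subternaries if s.names == names)
            for i, j in [(0, 1), (1, 2), (0, 2)]:
                pair = solve_simple_eutectic(sub.phases[i], sub.phases[j])
                assert t_star <= pair.T_eu + 1e-9

    def test_synthetic_system_feeds_straight_into_assembly(self):
        study = generate_synthetic_system(3, with_double_salt=True)
        d = study.diagram()
        assert d.covers((0.25, 0.25, 0.5))
        t, owner = d.liquidus_at((0.25, 0.25, 0.5))
        assert owner == "D"
        assert t == pytest.approx(study.phase("D").t_fus)

    def test_json_export_contains_domains(self, case3):
        payload = case3.diagram().to_json(grid_density=40)
        assert set(payload["domain_areas"]) == {p.name for p in case3.phases}
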