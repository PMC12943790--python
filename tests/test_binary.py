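"""Binary diagram solvers against brute-force temperature-scan oracles."""

import numpy as np
import pytest

from saltscreen import (
    CompoundMetastableError,
    solve_compound_binary,
    solve_pair_diagram,
    solve_racemic_binary,
    solve_simple_eutectic,
)
from saltscreen.datasets import generate_synthetic_system
from tests.conftest import (
    make_phase,
    scan_side_eutectic,
    scan_simple_eutectic,
)


class TestSimpleEutectic:
    def test_pregabalin_salt_pair_eutectic_composition(self, case3):
        """The 150/100 °C diastereomeric salt pair melts together at
        x = 0.086 of the higher-melting salt."""
        eu = solve_simple_eutectic(case3.phase("4''"), case3.phase("5''"))
        assert eu.x_A == pytest.approx(0.086, abs=0.005)
        assert eu.T_eu < min(case3.phase("4''").t_fus, case3.phase("5''").t_fus)

    def test_identical_data_gives_symmetric_midpoint(self):
        a = make_phase("a", t_fus=400.0, dh_fus=25000)
        b = make_phase("b", coords=(0.0, 0.5, 0.5), t_fus=400.0, dh_fus=25000)
        eu = solve_simple_eutectic(a, b)
        assert eu.x_A == 0.5
        assert eu.degenerate

    def test_same_phase_twice_is_an_error(self, case3):
        with pytest.raises(ValueError, match="identical"):
            solve_simple_eutectic(case3.phase("4''"), case3.phase("4''"))

    def test_argument_swap_mirrors_composition_and_preserves_temperature(self):
        a = make_phase("a", t_fus=434.1, dh_fus=31585)
        b = make_phase("b", coords=(0.0, 0.5, 0.5), t_fus=430.1, dh_fus=26736)
        eu_ab = solve_simple_eutectic(a, b)
        eu_ba = solve_simple_eutectic(b, a)
        assert eu_ab.T_eu == eu_ba.T_eu
        assert eu_ab.x_A + eu_ba.x_A == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_grid_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = make_phase("a", t_fus=rng.uniform(330, 470), dh_fus=rng.uniform(1.5e4, 7e4))
        b = make_phase("b", coords=(0.0, 0.5, 0.5),
                       t_fus=rng.uniform(330, 470), dh_fus=rng.uniform(1.5e4, 7e4))
        eu = solve_simple_eutectic(a, b)
        t_scan, x_scan = scan_simple_eutectic(a, b)
        assert eu.T_eu == pytest.approx(t_scan, abs=0.01)
        assert eu.x_A == pytest.approx(x_scan, abs=1e-3)

    def test_missing_thermo_data_rejected(self):
        a = make_phase("a")
        b = make_phase("b", coords=(0.0, 0.5, 0.5), t_fus=None, dh_fus=None)
        with pytest.raises(ValueError, match="melting data"):
            solve_simple_eutectic(a, b)


class TestRacemicBinary:
    def _enantiomer_pair(self, t_fus, dh_fus):
        e1 = make_phase("E1", coords=(1, 0, 0), t_fus=t_fus, dh_fus=dh_fus)
        e2 = make_phase("E2", coords=(0, 1, 0), t_fus=t_fus, dh_fus=dh_fus)
        return e1, e2

    def test_2ClMA_diagram_is_mirror_symmetric(self, case2):
        bd = solve_racemic_binary(
            case2.phase("1'"), case2.phase("2'"), case2.phase("3'")
        )
        e_left, e_right = sorted(e.x_A for e in bd.eutectics)
        assert e_left + e_right == pytest.approx(1.0, abs=1e-9)
        t1, t2 = (e.T_eu for e in bd.eutectics)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_2ClMA_eutectics_match_grid_scan(self, case2):
        bd = solve_racemic_binary(
            case2.phase("1'"), case2.phase("2'"), case2.phase("3'")
        )
        t_scan, x_scan = scan_side_eutectic(case2.phase("1'"), case2.phase("2'"))
        right = max(bd.eutectics, key=lambda e: e.x_A)
        assert right.T_eu == pytest.approx(t_scan, abs=0.01)
        assert right.x_A == pytest.approx(x_scan, abs=1e-3)

    def test_4ClMA_both_eutectics_below_compound_melting_point(self, case1):
        bd = solve_racemic_binary(
            case1.phase("1"), case1.phase("2"), case1.phase("3")
        )
        assert len(bd.eutectics) == 2
        for e in bd.eutectics:
            assert e.T_eu < 395.4

    def test_eutectics_approach_pure_ends_as_compound_enthalpy_grows(self):
        """With the compound melting at the enantiomers' own temperature, a
        growing compound enthalpy flattens its branch toward T_RS across the
        whole section, pushing the side eutectics monotonically toward the
        pure ends x -> 0 and x -> 1."""
        e1, e2 = self._enantiomer_pair(400.0, 25000)
        prev = None
        for dh in [4e4, 8e4, 1.6e5, 3.2e5]:
            c = make_phase("C", coords=(0.5, 0.5, 0), t_fus=400.0, dh_fus=dh)
            bd = solve_racemic_binary(e1, c, e2)
            x_left, x_right = sorted(e.x_A for e in bd.eutectics)
            t_scan, x_scan = scan_side_eutectic(e1, c)
            assert x_right == pytest.approx(x_scan, abs=1e-3)
            if prev is not None:
                assert x_right > prev[1] and x_left < prev[0]
            prev = (x_left, x_right)
        assert prev[1] > 0.85

    def test_low_melting_low_enthalpy_compound_is_metastable(self):
        e1, e2 = self._enantiomer_pair(420.0, 40000)
        c = make_phase("C", coords=(0.5, 0.5, 0), t_fus=300.0, dh_fus=8000)
        with pytest.raises(CompoundMetastableError):
            solve_racemic_binary(e1, c, e2)

    def test_compound_must_sit_midway(self):
        e1, e2 = self._enantiomer_pair(400.0, 25000)
        c = make_phase("C", coords=(0.7, 0.3, 0), t_fus=380.0, dh_fus=45000)
        with pytest.raises(ValueError, match="midway"):
            solve_racemic_binary(e1, c, e2)


class TestCompoundBinary:
    def test_case2_salt_section_maximum_at_double_salt_melting_point(self, case2):
        bd = solve_compound_binary(
            case2.phase("4'"), case2.phase("5'"), case2.phase("6'")
        )
        t_mid, owner = bd.liquidus(0.5)
        assert owner == "5'"
        assert t_mid == pytest.approx(424.6, abs=1e-6)
        assert len(bd.eutectics) == 2

    def test_case2_salt_section_eutectics_match_grid_scan(self, case2):
        bd = solve_compound_binary(
            case2.phase("4'"), case2.phase("5'"), case2.phase("6'")
        )
        t_a, x_a = scan_side_eutectic(case2.phase("4'"), case2.phase("5'"))
        t_b, x_b = scan_side_eutectic(case2.phase("6'"), case2.phase("5'"))
        right = max(bd.eutectics, key=lambda e: e.x_A)
        left = min(bd.eutectics, key=lambda e: e.x_A)
        assert right.T_eu == pytest.approx(t_a, abs=0.01)
        assert right.x_A == pytest.approx(x_a, abs=1e-3)
        assert left.T_eu == pytest.approx(t_b, abs=0.01)
        assert left.x_A == pytest.approx(1 - x_b, abs=1e-3)

    def test_symmetric_flanking_salts_give_mirror_eutectics(self):
        s1 = make_phase("S1", coords=(0.5, 0, 0.5), t_fus=410, dh_fus=20000)
        s2 = make_phase("S2", coords=(0, 0.5, 0.5), t_fus=410, dh_fus=20000)
        d = make_phase("D", coords=(0.25, 0.25, 0.5), t_fus=425, dh_fus=55000)
        bd = solve_compound_binary(s1, d, s2)
        x_left, x_right = sorted(e.x_A for e in bd.eutectics)
        assert x_left + x_right == pytest.approx(1.0, abs=1e-9)

    def test_pair_eutectic_lies_between_the_double_salt_eutectics(self, case2):
        """Removing the double salt from the 4'/6' section leaves a single
        eutectic inside the interval the double salt's branch occupied."""
        bd = solve_compound_binary(
            case2.phase("4'"), case2.phase("5'"), case2.phase("6'")
        )
        x_left, x_right = sorted(e.x_A for e in bd.eutectics)
        eu = solve_simple_eutectic(case2.phase("4'"), case2.phase("6'"))
        assert x_left < eu.x_A < x_right


class TestDiagramEnvelope:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 6])
    def test_envelope_continuous_at_eutectics(self, seed):
        # seeds drawn from the generator's stable-racemic-compound regime
        study = generate_synthetic_system(seed, with_racemic_compound=True)
        bd = solve_racemic_binary(
            study.phase("E1"), study.phase("RC"), study.phase("E2")
        )
        for eu in bd.eutectics:
            below, _ = bd.liquidus(eu.x_A - 1e-7)
            above, _ = bd.liquidus(eu.x_A + 1e-7)
            assert below == pytest.approx(above, abs=0.01)

    def test_branches_cover_the_whole_section(self, case2):
        bd = solve_compound_binary(
            case2.phase("4'"), case2.phase("5'"), case2.phase("6'")
        )
        samples = bd.sample(101)
        assert all(np.isfinite(samples["T_K"]))
        lo = min(br.x_lo for br in bd.branches)
        hi = max(br.x_hi for br in bd.branches)
        assert lo == 0.0 and hi == 1.0

    def test_pair_diagram_export_round_trip(self, case3):
        bd = solve_pair_diagram(case3.phase("4''"), case3.phase("5''"))
        payload = bd.to_json(n=51)
        assert len(payload["samples"]["x"]) == 51
        assert payload["eutectics"][0]["x_A"] == pytest.approx(0.086, abs=0.005)
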