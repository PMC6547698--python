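"""Safety margins, exposure sign conventions, risk rule, regression."""

import numpy as np
import pandas as pd
import pytest

from vegrisk.risk import (
    adaptive_capacity,
    build_assemblages,
    cell_risk_table,
    exposure,
    proportional_drying_fraction,
    risk,
    risk_capacity_regression,
    safety_margins,
)


def _niches(limits, lowers=None, breadths=None):
    n = len(limits)
    return pd.DataFrame({
        "species": [f"s{i}" for i in range(n)],
        "upper_mat_limit": limits,
        "lower_map_limit": lowers if lowers is not None else [100.0] * n,
        "mat_breadth": breadths if breadths is not None else [5.0] * n,
        "map_breadth": [400.0] * n,
    })


class TestSafetyMargins:
    def test_single_species_at_cell_climate_zero_margin(self):
        s_mat, _, n = safety_margins(np.array(["s0"]), _niches([26.5]), 26.5, 800.0)
        assert s_mat == 0.0 and n == 1

    def test_hand_median_three_species(self):
        s_mat, _, _ = safety_margins(
            np.array(["s0", "s1", "s2"]), _niches([28.0, 30.0, 31.0]), 26.5, 800.0
        )
        assert s_mat == pytest.approx(3.5)

    def test_even_count_median_averages_central_pair(self):
        s_mat, _, _ = safety_margins(
            np.array(["s0", "s1", "s2", "s3"]),
            _niches([28.0, 29.0, 31.0, 33.0]), 25.0, 800.0,
        )
        assert s_mat == pytest.approx(30.0 - 25.0)

    def test_map_margin_sign(self):
        _, s_map, _ = safety_margins(
            np.array(["s0"]), _niches([30.0], lowers=[300.0]), 25.0, 750.0
        )
        assert s_map == pytest.approx(450.0)

    def test_translation_equivariance(self):
        sp = np.array(["s0", "s1", "s2"])
        base = _niches([28.0, 30.0, 31.0])
        shifted = base.copy()
        shifted["upper_mat_limit"] = shifted["upper_mat_limit"] + 2.5
        s0, _, _ = safety_margins(sp, base, 26.5, 800.0)
        s1, _, _ = safety_margins(sp, shifted, 26.5, 800.0)
        assert s1 - s0 == pytest.approx(2.5)

    def test_species_order_insensitive(self):
        tab = _niches([28.0, 30.0, 31.0])
        a, _, _ = safety_margins(np.array(["s0", "s1", "s2"]), tab, 26.0, 800.0)
        b, _, _ = safety_margins(np.array(["s2", "s0", "s1"]), tab, 26.0, 800.0)
        assert a == b

    def test_no_niche_rows_errors(self):
        with pytest.raises(ValueError):
            safety_margins(np.array(["zz"]), _niches([30.0]), 25.0, 800.0)


class TestExposureAndRisk:
    def test_wetting_clamps_drying_exposure_to_zero(self):
        assert exposure(2.0, 120.0) == (2.0, 0.0)

    def test_drying_sign_convention(self):
        assert exposure(2.0, -300.0) == (2.0, 300.0)

    def test_risk_rule(self):
        r, flag = risk(2.0, 3.0)
        assert r == pytest.approx(1.0) and flag

    def test_boundary_not_at_risk(self):
        r, flag = risk(2.0, 2.0)
        assert r == 0.0 and not flag

    def test_at_risk_iff_e_greater_s(self):
        rng = np.random.default_rng(8)
        for s, e in rng.normal(size=(100, 2)):
            _, flag = risk(s, e)
            assert flag == (e > s)


class TestAdaptiveCapacity:
    def test_median_breadth(self):
        ac_mat, _ = adaptive_capacity(
            np.array(["s0", "s1", "s2"]),
            _niches([30.0] * 3, breadths=[2.0, 4.0, 6.0]),
        )
        assert ac_mat == 4.0

    def test_single_species_own_breadth(self):
        ac_mat, ac_map = adaptive_capacity(
            np.array(["s0"]), _niches([30.0], breadths=[3.3])
        )
        assert ac_mat == 3.3 and ac_map == 400.0


class TestProportionalDrying:
    def _cells(self, s_map, mp):
        return pd.DataFrame({"s_map": s_map, "map": mp})

    def test_zero_fraction_zero_share(self):
        cells = self._cells([50.0, 200.0], [1000.0, 700.0])
        assert proportional_drying_fraction(cells, 0.0) == 0.0

    def test_hand_case(self):
        cells = self._cells([50.0], [1000.0])
        assert proportional_drying_fraction(cells, 0.1) == 1.0

    def test_mixed_cells(self):
        cells = self._cells([50.0, 500.0], [1000.0, 1000.0])
        assert proportional_drying_fraction(cells, 0.1) == 0.5
        assert proportional_drying_fraction(cells, 0.5) == 0.5
        assert proportional_drying_fraction(cells, 0.6) == 1.0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            proportional_drying_fraction(self._cells([1.0], [2.0]), 1.5)


class TestRegression:
    def test_exact_parabola_r2_one(self):
        x = np.linspace(2, 9, 40)
        y = 1.0 - 0.8 * x + 0.05 * x**2
        cells = pd.DataFrame({"risk_mat": y, "ac_mat": x})
        res = risk_capacity_regression(cells)
        assert res.r_squared == pytest.approx(1.0)
        assert (res.df_model, res.df_resid) == (2, len(x) - 3)

    def test_coefficient_recovery_within_ci(self):
        # seeded replicates: the 95% CIs should cover the truth ~95% of the time
        rng = np.random.default_rng(12)
        true = np.array([2.0, -0.7, 0.04])
        n, reps = 120, 200
        covered = np.zeros(3)
        for _ in range(reps):
            x = rng.uniform(2, 10, n)
            y = true[0] + true[1] * x + true[2] * x**2 + rng.normal(0, 0.5, n)
            res = risk_capacity_regression(
                pd.DataFrame({"risk_mat": y, "ac_mat": x})
            )
            half = 1.96 * res.bse
            covered += (np.abs(res.params - true) <= half)
        assert (covered / reps >= 0.90).all()  # binomial slack below nominal

    def test_too_few_cells_errors(self):
        cells = pd.DataFrame({"risk_mat": [1.0] * 5, "ac_mat": [2.0] * 5})
        with pytest.raises(ValueError):
            risk_capacity_regression(cells)


class TestCellRiskTable:
    def test_assemblage_and_risk_wiring(self, small_scenario):
        from vegrisk.grids import aggregate_to_coarse, median_anomaly
        from vegrisk.niche import estimate_limits
        from vegrisk.qc import clean_occurrences
        from vegrisk.synthetic import sample_matched_values

        scen = small_scenario
        clean, _ = clean_occurrences(scen.occurrences, scen.accepted_names,
                                     scen.exotic_names, scen.config.extent)
        grid = scen.coarse_grid
        asm = build_assemblages(clean, grid)
        assert (asm["n_records"] >= 1).all()
        niches = estimate_limits(sample_matched_values(scen, 60, seed=2))
        cm = aggregate_to_coarse(scen.current["MAT"], grid).set_index("cell_id")["value"]
        cp = aggregate_to_coarse(scen.current["MAP"], grid).set_index("cell_id")["value"]
        am = aggregate_to_coarse(
            median_anomaly(scen.current["MAT"], [f["MAT"] for f in scen.futures]),
            grid).set_index("cell_id")["value"]
        ap = aggregate_to_coarse(
            median_anomaly(scen.current["MAP"], [f["MAP"] for f in scen.futures]),
            grid).set_index("cell_id")["value"]
        cells = cell_risk_table(asm, niches, cm, cp, am, ap)
        assert len(cells) > 0
        # at-risk flag is exactly the strict E > S rule, both variables
        assert (cells["at_risk_mat"] == (cells["e_mat"] > cells["s_mat"])).all()
        assert (cells["at_risk_map"] == (cells["e_dry"] > cells["s_map"])).all()
        assert (cells["risk_mat"] == cells["e_mat"] - cells["s_mat"]).all()
        assert (cells["e_dry"] >= 0).all()
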