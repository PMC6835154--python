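import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geoapportion.massbalance import (
    CellYield,
    Uncertain,
    build_contribution_table,
    compartment_production,
    contribution_table_frame,
    contribution_to_flesh,
    contribution_to_water,
    per_cell_yield,
)


@pytest.fixture
def culture_yield() -> CellYield:
    return per_cell_yield(73e-9, 67e-9, 1e9)


class TestPerCellYield:
    def test_culture_fixture(self, culture_yield):
        assert culture_yield.free_g_per_cell == pytest.approx(73e-18, rel=1e-12)
        assert culture_yield.bound_g_per_cell == pytest.approx(67e-18, rel=1e-12)
        assert culture_yield.total_g_per_cell == pytest.approx(140e-18, rel=1e-12)

    def test_zero_supernatant(self):
        y = per_cell_yield(0.0, 67e-9, 1e9)
        assert y.free_g_per_cell == 0.0

    def test_doubling_cells_halves_yields(self):
        y1 = per_cell_yield(73e-9, 67e-9, 1e9)
        y2 = per_cell_yield(73e-9, 67e-9, 2e9)
        assert y2.free_g_per_cell == pytest.approx(y1.free_g_per_cell / 2)
        assert y2.bound_g_per_cell == pytest.approx(y1.bound_g_per_cell / 2)

    def test_zero_cells_rejected(self):
        with pytest.raises(ZeroDivisionError):
            per_cell_yield(73e-9, 67e-9, 0.0)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            per_cell_yield(-1e-9, 0.0, 1e9)


class TestCompartmentProduction:
    def test_zero_density(self, culture_yield):
        assert compartment_production(0.0, "water", culture_yield).value == 0.0

    def test_water_unit_conversion_oracle(self, culture_yield):
        # d per mL * 1000 mL/L * 140e-18 g/cell * 1e9 ng/g; at d = 8643 -> ~1.21 ng/L
        d = 8643.0
        expected = d * 1000 * 140e-18 * 1e9
        got = compartment_production(d, "water", culture_yield)
        assert got.value == pytest.approx(expected, rel=1e-9)
        assert got.value == pytest.approx(1.21, abs=0.005)

    def test_mucous_area_inversion_oracle(self, culture_yield):
        # area chosen so that 4.32e5 per cm^2 yields 186 ng per intestine
        d = 4.32e5
        area = 186e-9 / (d * 140e-18)
        got = compartment_production(d, "mucous", culture_yield, mucous_area_cm2=area)
        assert got.value == pytest.approx(186.0, rel=1e-9)

    def test_digesta_pg_per_g(self, culture_yield):
        got = compartment_production(1000.0, "digesta", culture_yield)
        assert got.value == pytest.approx(1000.0 * 140e-18 * 1e12, rel=1e-9)

    def test_fin_ng_per_cm2(self, culture_yield):
        got = compartment_production(1e5, "fin", culture_yield)
        assert got.value == pytest.approx(1e5 * 140e-18 * 1e9, rel=1e-9)

    def test_copies_per_cell_scales_down(self, culture_yield):
        one = compartment_production(100.0, "water", culture_yield)
        two = compartment_production(100.0, "water", culture_yield, copies_per_cell=2.0)
        assert two.value == pytest.approx(one.value / 2)

    def test_mucous_without_area_rejected(self, culture_yield):
        with pytest.raises(ValueError):
            compartment_production(10.0, "mucous", culture_yield)

    def test_unknown_compartment_rejected(self, culture_yield):
        with pytest.raises(ValueError):
            compartment_production(10.0, "gills", culture_yield)

    @given(
        d=st.floats(0.001, 1e8),
        k=st.floats(0.01, 100),
    )
    def test_linearity_in_density(self, d, k):
        y = CellYield(73e-18, 67e-18)
        base = compartment_production(d, "water", y).value
        assert compartment_production(d * k, "water", y).value == pytest.approx(base * k, rel=1e-9)

    @given(k=st.floats(0.01, 100))
    def test_linearity_in_yield(self, k):
        base = compartment_production(100.0, "fin", CellYield(73e-18, 67e-18)).value
        scaled = compartment_production(100.0, "fin", CellYield(73e-18 * k, 67e-18 * k)).value
        assert scaled == pytest.approx(base * k, rel=1e-9)

    @given(k=st.floats(0.01, 100))
    def test_linearity_in_area(self, k):
        y = CellYield(73e-18, 67e-18)
        base = compartment_production(100.0, "mucous", y, mucous_area_cm2=10.0).value
        scaled = compartment_production(100.0, "mucous", y, mucous_area_cm2=10.0 * k).value
        assert scaled == pytest.approx(base * k, rel=1e-9)


class TestContributions:
    @pytest.mark.parametrize(
        "prod, flesh, expected",
        [(94.0, 351.0, 26.8), (114.0, 408.0, 27.9)],
    )
    def test_flesh_contribution_worked_rows(self, prod, flesh, expected):
        assert round(contribution_to_flesh(prod, flesh, 1.0), 1) == expected

    def test_zero_production(self):
        assert contribution_to_flesh(0.0, 351.0) == 0.0

    def test_nonpositive_flesh_undefined(self):
        assert math.isnan(contribution_to_flesh(94.0, 0.0))

    @given(
        p=st.floats(0.001, 1e4),
        c=st.floats(0.1, 1e4),
        m=st.floats(0.1, 10),
        k=st.floats(0.01, 100),
    )
    def test_flesh_scale_invariance(self, p, c, m, k):
        a = contribution_to_flesh(p, c, m)
        b = contribution_to_flesh(p, c * k, m / k)
        assert b == pytest.approx(a, rel=1e-9)

    def test_water_contribution_worked_row(self):
        assert contribution_to_water(1.21, 2.7) == pytest.approx(44.8, abs=0.05)

    def test_water_zero_calc(self):
        assert contribution_to_water(0.0, 2.7) == 0.0
        assert contribution_to_water(0.0, 0.0) == 0.0

    def test_water_equal_is_hundred(self):
        assert contribution_to_water(2.5, 2.5) == pytest.approx(100.0)

    def test_water_zero_measurement_undefined(self):
        assert math.isnan(contribution_to_water(1.0, 0.0))


class TestUncertain:
    def test_pythagorean_sum(self):
        y = Uncertain(10.0, 3.0) + Uncertain(20.0, 4.0)
        assert y.value == 30.0
        assert y.se == pytest.approx(5.0)

    def test_product_relative_errors(self):
        a = Uncertain(10.0, 1.0)  # 10% relative
        b = Uncertain(5.0, 0.5)  # 10% relative
        y = a * b
        assert y.value == 50.0
        assert y.se / y.value == pytest.approx(math.sqrt(0.02), rel=1e-9)  # ~14.14%

    def test_quotient_relative_errors(self):
        y = Uncertain(10.0, 1.0) / Uncertain(5.0, 0.5)
        assert y.value == 2.0
        assert y.se / y.value == pytest.approx(math.sqrt(0.02), rel=1e-9)

    def test_scalar_operations(self):
        y = 2.0 * Uncertain(10.0, 1.0)
        assert y.value == 20.0 and y.se == pytest.approx(2.0)

    def test_zero_with_se_in_denominator_flagged(self):
        with pytest.raises(ZeroDivisionError):
            Uncertain(10.0, 1.0) / Uncertain(0.0, 0.5)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            Uncertain(1.0, -0.1)

    def test_product_chain_against_monte_carlo(self, rng):
        # delta method vs 1e5-draw simulation for a product/quotient chain
        n = 100_000
        a = Uncertain(10.0, 1.0)
        b = Uncertain(4.0, 0.4)
        c = Uncertain(8.0, 0.8)
        y = a * b / c
        draws = (
            rng.normal(a.value, a.se, n)
            * rng.normal(b.value, b.se, n)
            / rng.normal(c.value, c.se, n)
        )
        assert y.se == pytest.approx(np.std(draws, ddof=1), rel=0.10)

    def test_delta_converges_to_mc_as_se_shrinks(self, rng):
        n = 100_000
        for rel in (0.10, 0.02):
            a = Uncertain(10.0, 10.0 * rel)
            b = Uncertain(4.0, 4.0 * rel)
            y = a * b
            draws = rng.normal(a.value, a.se, n) * rng.normal(b.value, b.se, n)
            mc = np.std(draws, ddof=1)
            assert abs(y.se - mc) / mc < max(3 * rel, 0.02)


class TestBuildContributionTable:
    def setup_method(self):
        self.cy = CellYield(73e-18, 67e-18)

    def test_all_zero_densities(self):
        dens = {"1": {c: Uncertain(0.0) for c in ("water", "mucous", "digesta", "fin")}}
        meas = {"1": {"flesh": Uncertain(300.0, 10.0), "water": Uncertain(2.0, 0.1)}}
        rows = build_contribution_table(dens, meas, self.cy, mucous_area_cm2=100.0)
        assert rows[0].mucous_production.value == 0.0
        assert rows[0].contribution_pct == 0.0

    def test_farm6_style_row(self):
        # density tuned so mucous production is exactly 94 ng per intestine
        area = 3000.0
        d = 94e-9 / (area * 140e-18)
        dens = {"6": {"mucous": Uncertain(d), "water": Uncertain(0.0),
                      "digesta": Uncertain(0.0), "fin": Uncertain(0.0)}}
        meas = {"6": {"flesh": Uncertain(351.0, 27.1), "water": Uncertain(0.0)}}
        rows = build_contribution_table(dens, meas, self.cy, mucous_area_cm2=area)
        frame = contribution_table_frame(rows)
        assert frame.loc[0, "mucous_ng_per_intestine"] == pytest.approx(94.0, rel=1e-9)
        assert frame.loc[0, "contribution_pct"] == 26.8

    def test_missing_compartment_flagged_not_dropped(self):
        dens = {"1": {"water": Uncertain(10.0)}}
        meas = {"1": {"water": Uncertain(2.0)}}
        rows = build_contribution_table(dens, meas, self.cy, mucous_area_cm2=10.0)
        assert len(rows) == 1
        assert "missing_density:mucous" in rows[0].gaps
        assert "missing_measurement:flesh" in rows[0].gaps
        assert math.isnan(rows[0].contribution_pct)

    def test_se_propagates_to_production(self):
        dens = {"1": {"mucous": Uncertain(1000.0, 100.0)}}
        rows = build_contribution_table(dens, {}, self.cy, mucous_area_cm2=50.0)
        prod = rows[0].mucous_production
        assert prod.se / prod.value == pytest.approx(0.1, rel=1e-9)
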