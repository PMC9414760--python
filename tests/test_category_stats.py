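import numpy as np
import pytest
from scipy import stats

from ons_exchanges.category_stats import (
    InsufficientDataError,
    VolumeExclusionRule,
    compare_to_isocaloric,
    exchange_correlations,
    mann_whitney,
    normality_diagnostic,
    summarize_category,
    summary_variables,
)
from ons_exchanges.model import ServingUnit

from conftest import make_product


def liquid(product_id, carbohydrate=20.0, protein=8.0, fat=5.0, fiber=0.0,
           volume=200.0, density=1.1):
    """Liquid product at a chosen energy density (isocaloric by default)."""
    return make_product(
        product_id=product_id,
        amount=volume,
        energy_kcal=density * volume,
        carbohydrate_g=carbohydrate,
        protein_g=protein,
        fat_g=fat,
        fiber_g=fiber,
    )


def brute_force_u(x, y):
    """Rank-free U statistic of x: count of (x_i > y_j) pairs, ties as 1/2."""
    return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y)


class TestSummarizeCategory:
    def test_odd_count_median_of_starch_exchanges(self):
        # carbohydrate 15 -> 1, 22 -> 1.5, 30 -> 2 starch exchanges
        products = [
            liquid("A", carbohydrate=15),
            liquid("B", carbohydrate=22),
            liquid("C", carbohydrate=30),
        ]
        summary = summarize_category(products, "total")
        assert summary.n == 3
        assert summary.table.loc["starch_exchanges", "median"] == 1.5
        assert summary.table.loc["starch_exchanges", "q25"] == 1.25  # linear interp

    def test_high_volume_products_excluded(self):
        products = [liquid("A"), liquid("B"), liquid("BIG", volume=1000)]
        summary = summarize_category(products, "total")
        assert summary.n == 2
        assert summary.n_total == 3

    def test_powders_pass_the_volume_filter(self):
        powder = make_product(
            product_id="POW", amount=60, unit=ServingUnit.GRAM,
            energy_kcal=240, carbohydrate_g=30, protein_g=10, fat_g=8,
        )
        assert summarize_category([powder, liquid("A")], "total").n == 2

    def test_single_product_collapses_quartiles(self):
        summary = summarize_category([liquid("A", carbohydrate=15)], "total")
        row = summary.table.loc["carbohydrate_g"]
        assert row["median"] == row["q25"] == row["q75"] == 15

    def test_category_selection_uses_labels(self):
        products = [liquid("ISO", density=1.1), liquid("HE", density=1.5)]
        assert summarize_category(products, "isocaloric").n == 1
        assert summarize_category(products, "high_energy").n == 1

    def test_empty_group_flagged(self):
        summary = summarize_category([liquid("HE", density=1.5)], "isocaloric")
        assert summary.n == 0 and not summary.defined
        assert summary.table.isna().all().all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            summarize_category([liquid("A")], "mega_energy")

    def test_custom_cutoff(self):
        products = [liquid("A", volume=250), liquid("B", volume=300)]
        summary = summarize_category(
            products, "total", exclusion=VolumeExclusionRule(cutoff_ml=260)
        )
        assert summary.n == 1


class TestCompareToIsocaloric:
    def test_identical_groups_not_significant(self):
        iso = [liquid(f"I{i}", carbohydrate=c, density=1.1) for i, c in enumerate([10, 20, 30])]
        high = [liquid(f"H{i}", carbohydrate=c, density=1.5) for i, c in enumerate([10, 20, 30])]
        result = compare_to_isocaloric(iso + high, "high_energy", "carbohydrate_g")
        assert result.pvalue > 0.05

    def test_fully_separated_groups_reach_minimal_u(self):
        iso = [liquid(f"I{i}", carbohydrate=1, density=1.1) for i in range(3)]
        high = [liquid(f"H{i}", carbohydrate=100, density=1.5) for i in range(3)]
        result = compare_to_isocaloric(iso + high, "high_energy", "carbohydrate_g")
        assert result.statistic == 0  # isocaloric group below every comparator
        assert result.n_isocaloric == result.n_other == 3

    def test_empty_group_errors(self):
        iso = [liquid(f"I{i}", density=1.1) for i in range(3)]
        with pytest.raises(InsufficientDataError):
            compare_to_isocaloric(iso, "high_energy", "carbohydrate_g")

    def test_unknown_variable_rejected(self):
        iso = [liquid("I", density=1.1), liquid("I2", density=1.1)]
        high = [liquid("H", density=1.5), liquid("H2", density=1.5)]
        with pytest.raises(ValueError, match="unknown variable"):
            compare_to_isocaloric(iso + high, "high_energy", "sugar_g")

    def test_u_statistic_matches_brute_force_pair_count(self):
        """Dual route: scipy's U equals direct enumeration of concordant pairs."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.integers(0, 12, size=9).astype(float)
            y = rng.integers(0, 12, size=7).astype(float)
            assert mann_whitney(x, y).statistic == pytest.approx(brute_force_u(x, y))

    def test_exact_method_used_for_small_tie_free_samples(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        # exact two-sided p for complete separation with n=m=3 is 2/20
        assert mann_whitney(x, y).pvalue == pytest.approx(0.1)


class TestExchangeCorrelations:
    def test_matched_pair_perfectly_monotone(self):
        products = [
            liquid(f"P{i}", carbohydrate=c, protein=4 + i, fat=2 + i)
            for i, c in enumerate([10, 20, 30, 40, 50])
        ]
        result = exchange_correlations(products)
        assert result.rho.loc["starch_exchanges", "carbohydrate_g"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        products = [
            liquid(f"P{i}", carbohydrate=c, protein=p)
            for i, (c, p) in enumerate([(10, 30), (20, 15), (30, 5)])
        ]
        result = exchange_correlations(products)
        # protein grams strictly decrease as carbohydrate (hence starch) increases
        assert result.rho.loc["starch_exchanges", "protein_g"] == pytest.approx(-1.0)

    def test_constant_variable_undefined(self):
        products = [liquid(f"P{i}", carbohydrate=c, fiber=0) for i, c in enumerate([10, 20, 30])]
        result = exchange_correlations(products)
        assert np.isnan(result.rho.loc["starch_exchanges", "fiber_g"])

    def test_independent_columns_near_zero(self):
        """Null check: with independent carbohydrate and fat, the cross
        correlation fat grams x starch exchanges stays within the
        asymptotic 1/sqrt(n-1) scale."""
        rng = np.random.default_rng(123)
        products = [
            liquid(
                f"P{i}",
                carbohydrate=round(rng.uniform(5, 60), 1),
                fat=round(rng.uniform(0, 20), 1),
            )
            for i in range(1000)
        ]
        result = exchange_correlations(products)
        assert abs(result.rho.loc["starch_exchanges", "fat_g"]) < 0.1

    def test_too_few_products_rejected(self):
        with pytest.raises(InsufficientDataError):
            exchange_correlations([liquid("A"), liquid("B")])

    def test_row_and_column_order_fixed(self):
        products = [liquid(f"P{i}", carbohydrate=10 * (i + 1)) for i in range(4)]
        result = exchange_correlations(products)
        assert list(result.rho.index) == [
            "starch_exchanges", "lean_meat_exchanges", "fat_exchanges",
        ]
        assert list(result.rho.columns) == [
            "carbohydrate_g", "protein_g", "fat_g", "fiber_g", "energy_kcal",
        ]


class TestSummaryVariables:
    def test_exchanges_match_engine(self):
        table = summary_variables([liquid("A", carbohydrate=36.8, protein=11.8, fat=11.6)])
        assert table.loc[0, "starch_exchanges"] == 2.5
        assert table.loc[0, "lean_meat_exchanges"] == 1
        assert table.loc[0, "fat_exchanges"] == 2


class TestNormalityDiagnostic:
    def test_matches_scipy_kstest_on_fitted_normal(self):
        rng = np.random.default_rng(5)
        values = rng.normal(10, 2, size=50)
        stat, p = normality_diagnostic(values)
        expected = stats.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
        assert stat == pytest.approx(expected.statistic)
        assert 0 <= p <= 1

    def test_needs_three_observations(self):
        with pytest.raises(InsufficientDataError):
            normality_diagnostic([1.0, 2.0])
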