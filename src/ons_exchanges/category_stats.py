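"""Summary statistics and nonparametric comparisons over a product database.

Label data are skewed, so the toolkit reports medians with interquartile
ranges, compares categories with the Mann–Whitney rank-sum test, and
measures the association between macronutrient grams and computed exchanges
with tie-corrected Spearman correlations.  Liquid products serving more
than 500 mL are excluded from all statistics to keep portions comparable
(typical ONS servings are 130–300 mL); powders have no volume and pass the
volume filter.

Quartiles use linear interpolation between order statistics (numpy's
default), and no multiple-testing correction is applied: each p-value is
read against the 0.05 level on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CategoryLabel, Product, assign_categories
from .exchange_engine import DEFAULT_RULES, ExchangeRuleTables, compute_exchanges

__all__ = [
    "VolumeExclusionRule",
    "CategorySummary",
    "CorrelationResult",
    "apply_exclusion",
    "summary_variables",
    "summarize_category",
    "compare_to_isocaloric",
    "exchange_correlations",
    "normality_diagnostic",
]

SUMMARY_VARIABLES = (
    "carbohydrate_g",
    "starch_exchanges",
    "protein_g",
    "lean_meat_exchanges",
    "fat_g",
    "fat_exchanges",
)

CORRELATION_ROWS = ("starch_exchanges", "lean_meat_exchanges", "fat_exchanges")
CORRELATION_COLUMNS = (
    "carbohydrate_g",
    "protein_g",
    "fat_g",
    "fiber_g",
    "energy_kcal",
)

#: matched macronutrient for each exchange type
MATCHED_PAIRS = {
    "starch_exchanges": "carbohydrate_g",
    "lean_meat_exchanges": "protein_g",
    "fat_exchanges": "fat_g",
}


@dataclass(frozen=True)
class VolumeExclusionRule:
    """Exclude liquid products above a serving-volume cutoff (default 500 mL)."""

    cutoff_ml: float = 500.0

    def keeps(self, product: Product) -> bool:
        if not product.serving.is_liquid:
            return True
        return product.serving.amount <= self.cutoff_ml


DEFAULT_EXCLUSION = VolumeExclusionRule()


class InsufficientDataError(ValueError):
    """A statistical routine received too few observations."""


@dataclass(frozen=True)
class CategorySummary:
    """Median / quartile summary of one supplement category.

    ``table`` has one row per variable with columns ``median``, ``q25``,
    ``q75``; all-NaN when the category is empty after exclusion.  ``n`` is
    the post-exclusion count, ``n_total`` the pre-exclusion count.
    """

    label: str
    n: int
    n_total: int
    table: pd.DataFrame

    @property
    def defined(self) -> bool:
        return self.n > 0


def apply_exclusion(
    products: Sequence[Product],
    exclusion: VolumeExclusionRule = DEFAULT_EXCLUSION,
) -> List[Product]:
    return [p for p in products if exclusion.keeps(p)]


def summary_variables(
    products: Sequence[Product],
    rules: ExchangeRuleTables = DEFAULT_RULES,
) -> pd.DataFrame:
    """Per-product grams, kcal and per-serving exchanges, one row per product."""
    rows = []
    for product in products:
        exchanges = compute_exchanges(product.profile, 1, rules)
        p = product.profile
        rows.append(
            {
                "product_id": product.product_id,
                "carbohydrate_g": p.carbohydrate_g,
                "protein_g": p.protein_g,
                "fat_g": p.fat_g,
                "fiber_g": p.fiber_g,
                "energy_kcal": p.energy_kcal,
                "starch_exchanges": exchanges.starch,
                "lean_meat_exchanges": exchanges.lean_meat,
                "fat_exchanges": exchanges.fat,
            }
        )
    columns = ["product_id", *CORRELATION_COLUMNS, *CORRELATION_ROWS]
    return pd.DataFrame(rows, columns=columns)


def _carries_label(product: Product, label: str) -> bool:
    if label == "total":
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # powder warnings are not of interest here
        return CategoryLabel(label) in assign_categories(product)


def summarize_category(
    products: Sequence[Product],
    label: str,
    exclusion: VolumeExclusionRule = DEFAULT_EXCLUSION,
    rules: ExchangeRuleTables = DEFAULT_RULES,
) -> CategorySummary:
    """Median (IQR) of grams and exchanges for one category (or ``"total"``).

    The volume exclusion is applied after selecting the category, so
    ``n_total`` counts every product carrying the label and ``n`` those
    that also pass the exclusion.
    """
    if label != "total":
        CategoryLabel(label)  # raises ValueError for unknown labels
    selected = [p for p in products if _carries_label(p, label)]
    kept = apply_exclusion(selected, exclusion)
    if not kept:
        table = pd.DataFrame(
            np.nan, index=list(SUMMARY_VARIABLES), columns=["median", "q25", "q75"]
        )
        return CategorySummary(label=label, n=0, n_total=len(selected), table=table)
    values = summary_variables(kept, rules)
    table = pd.DataFrame(
        {
            "median": values[list(SUMMARY_VARIABLES)].median(),
            "q25": values[list(SUMMARY_VARIABLES)].quantile(0.25),
            "q75": values[list(SUMMARY_VARIABLES)].quantile(0.75),
        }
    )
    return CategorySummary(label=label, n=len(kept), n_total=len(selected), table=table)


class RankSumResult(NamedTuple):
    statistic: float  # Mann–Whitney U of the isocaloric group
    pvalue: float
    n_isocaloric: int
    n_other: int


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> "stats._stats_py.MannwhitneyuResult":
    """Two-sided Mann–Whitney U, exact for small tie-free samples.

    Exact enumeration is used when both samples have at most 20
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) else "asymptotic"
    return stats.mannwhitneyu(x, y, alternative="two-sided", method=method)


def compare_to_isocaloric(
    products: Sequence[Product],
    label: str,
    variable: str,
    exclusion: VolumeExclusionRule = DEFAULT_EXCLUSION,
    rules: ExchangeRuleTables = DEFAULT_RULES,
) -> RankSumResult:
    """Mann–Whitney comparison of ``variable`` between isocaloric products
    and the products carrying ``label``.

    The U statistic reported is that of the isocaloric group.  Raises
    :class:`InsufficientDataError` when either group has fewer than two
    products after the volume exclusion.
    """
    if variable not in SUMMARY_VARIABLES and variable not in CORRELATION_COLUMNS:
        raise ValueError(f"unknown variable {variable!r}")
    iso = apply_exclusion(
        [p for p in products if _carries_label(p, CategoryLabel.ISOCALORIC.value)],
        exclusion,
    )
    other = apply_exclusion(
        [p for p in products if _carries_label(p, label)], exclusion
    )
    if len(iso) < 2 or len(other) < 2:
        raise InsufficientDataError(
            f"need at least 2 products per group, got isocaloric n={len(iso)}, "
            f"{label} n={len(other)}"
        )
    x = summary_variables(iso, rules)[variable].to_numpy()
    y = summary_variables(other, rules)[variable].to_numpy()
    result = mann_whitney(x, y)
    return RankSumResult(float(result.statistic), float(result.pvalue), len(iso), len(other))


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho and p per (exchange type, macronutrient) pair.

    Rows are the exchange types, columns the macronutrient variables.
    A constant variable yields NaN entries (correlation undefined).
    """

    rho: pd.DataFrame
    pvalue: pd.DataFrame

    def matched_pair_is_row_maximum(self, row: str) -> bool:
        """Whether the matched macronutrient has the largest rho in ``row``."""
        series = self.rho.loc[row]
        return series.idxmax() == MATCHED_PAIRS[row]


def exchange_correlations(
    products: Sequence[Product],
    exclusion: VolumeExclusionRule = DEFAULT_EXCLUSION,
    rules: ExchangeRuleTables = DEFAULT_RULES,
) -> CorrelationResult:
    """Spearman correlation matrix between grams/kcal and computed exchanges."""
    kept = apply_exclusion(products, exclusion)
    if len(kept) < 3:
        raise InsufficientDataError(
            f"need at least 3 products after exclusion, got {len(kept)}"
        )
    values = summary_variables(kept, rules)
    rho = pd.DataFrame(
        index=list(CORRELATION_ROWS), columns=list(CORRELATION_COLUMNS), dtype=float
    )
    pvalue = rho.copy()
    for row in CORRELATION_ROWS:
        for col in CORRELATION_COLUMNS:
            x = values[col].to_numpy()
            y = values[row].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho.loc[row, col] = np.nan
                pvalue.loc[row, col] = np.nan
                continue
            r, p = stats.spearmanr(x, y)
            rho.loc[row, col] = r
            pvalue.loc[row, col] = p
    return CorrelationResult(rho=rho, pvalue=pvalue)


def normality_diagnostic(values: Sequence[float]) -> "tuple[float, float]":
    """Kolmogorov–Smirnov statistic and p against a fitted normal.

    Reported as a diagnostic only: the toolkit's statistics are
    nonparametric regardless of the outcome.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) < 3:
        raise InsufficientDataError("need at least 3 observations")
    sd = arr.std(ddof=1)
    if sd == 0:
        return float("nan"), float("nan")
    stat, p = stats.kstest(arr, "norm", args=(arr.mean(), sd))
    return float(stat), float(p)
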