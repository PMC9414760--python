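"""Banded conversion of per-serving macronutrient grams to diabetic exchanges.

The published gram ranges only cover small amounts (e.g. 11–20 g of
carbohydrate for one starch exchange).  Real supplements exceed them, so the
engine uses the minimal periodic extension of the printed bands:

* starch  — whole-exchange bands of width 10 g centred on multiples of the
  15 g starch reference, half-exchange bands of width 5 g between them:
  [0, 5.5) → 0, [5.5, 10.5) → 0.5, and for k ≥ 1 the bands
  [15k − 4.5, 15k + 5.5) → k and [15k + 5.5, 15k + 10.5) → k + 0.5.
* lean meat — 0 below 4 g, 1 up to (but excluding) 14 g, then floor(g / 7).
  Protein exchanges are always whole units.
* fat — [0, 2) → 0, [2, 4) → 0.5, and for k ≥ 1 the bands
  [5k − 1, 5k + 2] → k (closed: the printed "2–4" and "4–7" ranges meet at
  4 g and the whole-exchange band wins) and (5k + 2, 5k + 4) → k + 0.5.

When a serving declares more than 5 g of fiber, only half of the fiber
grams count toward carbohydrate before the starch lookup.

All band parameters live in :class:`ExchangeRuleTables` and can be loaded
from a ``key = value`` text file, so revised exchange lists can be adopted
without code changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace
from typing import TextIO, Union

from .model import MacronutrientProfile
from ._config import read_key_values

__all__ = [
    "ExchangeSet",
    "ExchangeRuleTables",
    "DEFAULT_RULES",
    "net_carbohydrate",
    "starch_exchanges",
    "lean_meat_exchanges",
    "fat_exchanges",
    "compute_exchanges",
]

_HALF_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class ExchangeSet:
    """Starch / lean-meat / fat exchange counts.

    Starch and fat come in half-units, lean meat in whole units; the
    granularity is validated via :meth:`checked` (used whenever the number
    of servings is integral — fractional servings scale linearly and may
    break the grid).
    """

    starch: float
    lean_meat: float
    fat: float

    def __post_init__(self) -> None:
        if min(self.starch, self.lean_meat, self.fat) < 0:
            raise ValueError("exchange counts must be non-negative")

    @classmethod
    def checked(cls, starch: float, lean_meat: float, fat: float) -> "ExchangeSet":
        for name, value, step in (
            ("starch", starch, 0.5),
            ("lean_meat", lean_meat, 1.0),
            ("fat", fat, 0.5),
        ):
            if abs(value / step - round(value / step)) > _HALF_UNIT_TOL:
                raise ValueError(
                    f"{name} exchanges must be a multiple of {step}, got {value}"
                )
        return cls(starch, lean_meat, fat)

    def scaled(self, factor: float) -> "ExchangeSet":
        return ExchangeSet(
            self.starch * factor, self.lean_meat * factor, self.fat * factor
        )


@dataclass(frozen=True)
class ExchangeRuleTables:
    """Band boundaries and reference gram weights of the exchange rules.

    ``*_zero_upper_g`` is the exclusive upper bound of the zero-exchange
    band; ``starch_half_upper_g`` / ``fat_half_upper_g`` close the first
    half-exchange band; ``protein_one_upper_g`` closes the single
    lean-meat-exchange band.  ``*_reference_g`` is the gram weight of one
    exchange, which is also the period of the extension.
    """

    starch_reference_g: float = 15.0
    starch_zero_upper_g: float = 5.5
    starch_half_upper_g: float = 10.5
    protein_reference_g: float = 7.0
    protein_zero_upper_g: float = 4.0
    protein_one_upper_g: float = 14.0
    fat_reference_g: float = 5.0
    fat_zero_upper_g: float = 2.0
    fat_half_upper_g: float = 4.0
    fiber_threshold_g: float = 5.0
    fiber_counted_fraction: float = 0.5

    @classmethod
    def from_file(cls, source: Union[str, TextIO]) -> "ExchangeRuleTables":
        """Load overrides from a ``key = value`` file; unset keys keep defaults."""
        values = read_key_values(source)
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown rule-table keys: {sorted(unknown)}")
        return replace(cls(), **{k: float(v) for k, v in values.items()})


DEFAULT_RULES = ExchangeRuleTables()


def _require_non_negative(value: float, what: str) -> None:
    if value < 0:
        raise ValueError(f"{what} must be non-negative, got {value}")


def net_carbohydrate(
    carbohydrate_g: float,
    fiber_g: float,
    rules: ExchangeRuleTables = DEFAULT_RULES,
) -> float:
    """Carbohydrate grams counted toward starch exchanges.

    Above the fiber threshold (5 g per serving) only half of the fiber
    grams count, i.e. half of the fiber is subtracted from the total.
    The result is floored at zero for pathological labels declaring more
    fiber than carbohydrate (with a warning).
    """
    _require_non_negative(carbohydrate_g, "carbohydrate_g")
    _require_non_negative(fiber_g, "fiber_g")
    if fiber_g > carbohydrate_g:
        warnings.warn(
            f"fiber ({fiber_g} g) exceeds total carbohydrate ({carbohydrate_g} g)",
            stacklevel=2,
        )
    if fiber_g > rules.fiber_threshold_g:
        return max(0.0, carbohydrate_g - rules.fiber_counted_fraction * fiber_g)
    return carbohydrate_g


def starch_exchanges(
    net_cho_g: float, rules: ExchangeRuleTables = DEFAULT_RULES
) -> float:
    _require_non_negative(net_cho_g, "net carbohydrate")
    zero, half, period = (
        rules.starch_zero_upper_g,
        rules.starch_half_upper_g,
        rules.starch_reference_g,
    )
    if net_cho_g < zero:
        return 0.0
    if net_cho_g < half:
        return 0.5
    # whole-exchange band of width period - (half - zero), then a half band
    u = net_cho_g - half
    k = math.floor(u / period) + 1
    r = u - (k - 1) * period
    whole_width = period - (half - zero)
    return float(k) if r < whole_width else k + 0.5


def lean_meat_exchanges(
    protein_g: float, rules: ExchangeRuleTables = DEFAULT_RULES
) -> float:
    _require_non_negative(protein_g, "protein")
    if protein_g < rules.protein_zero_upper_g:
        return 0.0
    if protein_g < rules.protein_one_upper_g:
        return 1.0
    return float(math.floor(protein_g / rules.protein_reference_g))


def fat_exchanges(fat_g: float, rules: ExchangeRuleTables = DEFAULT_RULES) -> float:
    _require_non_negative(fat_g, "fat")
    zero, half, period = (
        rules.fat_zero_upper_g,
        rules.fat_half_upper_g,
        rules.fat_reference_g,
    )
    if fat_g < zero:
        return 0.0
    if fat_g < half:
        return 0.5
    u = fat_g - half
    k = math.floor(u / period) + 1
    r = u - (k - 1) * period
    # whole band is closed at its upper boundary (4 g belongs to 1 exchange)
    whole_width = period - (half - zero)
    return float(k) if r <= whole_width else k + 0.5


def compute_exchanges(
    profile: MacronutrientProfile,
    servings: float = 1.0,
    rules: ExchangeRuleTables = DEFAULT_RULES,
) -> ExchangeSet:
    """Exchange set for ``servings`` servings of a product.

    Band lookups apply per serving (the ranges are per-serving rules), then
    scale linearly.  For an integral number of servings the result is
    validated against the half-unit grid.
    """
    if servings <= 0:
        raise ValueError(f"servings must be positive, got {servings}")
    per_serving = ExchangeSet.checked(
        starch_exchanges(
            net_carbohydrate(profile.carbohydrate_g, profile.fiber_g, rules), rules
        ),
        lean_meat_exchanges(profile.protein_g, rules),
        fat_exchanges(profile.fat_g, rules),
    )
    total = per_serving.scaled(servings)
    if float(servings).is_integer():
        return ExchangeSet.checked(total.starch, total.lean_meat, total.fat)
    return total
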