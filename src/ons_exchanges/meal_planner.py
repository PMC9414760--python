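"""Exchange-based diet-plan arithmetic with ONS incorporation.

A diet plan is a count of exchanges per food group.  Each group contributes
fixed grams of carbohydrate, protein and fat (and kcal) per exchange; plan
totals are the count-weighted sums.  An attached supplement contributes its
label macronutrients directly (the label is the ground truth, the exchange
set is its discrete approximation).

Incorporating a supplement into an existing plan subtracts the supplement's
exchange set from the matching food groups (starch → starch, lean meat →
lean meat, fat → fat), clamping at zero with a warning if the plan has too
few exchanges in a group.

The default per-exchange composition covers the six groups whose values the
package can state with confidence; other exchange-list groups (non-fat or
whole milk, very-lean/medium-fat/high-fat meat) must be supplied by the
user via a config file rather than invented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, NamedTuple, Optional, TextIO, Union

from .model import MacronutrientProfile
from .exchange_engine import ExchangeSet
from ._config import read_key_values

__all__ = [
    "GroupComposition",
    "ExchangeComposition",
    "default_composition",
    "composition_from_file",
    "SupplementDose",
    "MealPlan",
    "NutritionTargets",
    "PlanTotals",
    "TargetReport",
    "plan_totals",
    "incorporate_supplement",
    "check_targets",
]


@dataclass(frozen=True)
class GroupComposition:
    """Grams and kcal contributed by one exchange of a food group."""

    carbohydrate_g: float
    protein_g: float
    fat_g: float
    energy_kcal: float

    def __post_init__(self) -> None:
        if min(self.carbohydrate_g, self.protein_g, self.fat_g, self.energy_kcal) < 0:
            raise ValueError("composition entries must be non-negative")


#: food group name -> per-exchange composition
ExchangeComposition = Mapping[str, GroupComposition]

_DEFAULT_COMPOSITION: Dict[str, GroupComposition] = {
    "milk_medium_fat": GroupComposition(12.0, 8.0, 5.0, 120.0),
    "fruit": GroupComposition(15.0, 0.0, 0.0, 60.0),
    "vegetables": GroupComposition(5.0, 2.0, 0.0, 25.0),
    "starch": GroupComposition(15.0, 3.0, 0.3, 80.0),
    "lean_meat": GroupComposition(0.0, 7.0, 3.0, 55.0),
    "fat": GroupComposition(0.0, 0.0, 5.0, 45.0),
}

_FIELDS = ("carbohydrate_g", "protein_g", "fat_g", "energy_kcal")


def default_composition() -> Dict[str, GroupComposition]:
    """A fresh copy of the default six-group composition table."""
    return dict(_DEFAULT_COMPOSITION)


def composition_from_file(source: Union[str, TextIO]) -> Dict[str, GroupComposition]:
    """Load a composition table from ``group.field = value`` lines.

    Starts from the default table; listed groups are replaced wholesale, so
    every field of a redefined or new group must be given.
    """
    values = read_key_values(source)
    per_group: Dict[str, Dict[str, float]] = {}
    for key, raw in values.items():
        group, _, fieldname = key.partition(".")
        if fieldname not in _FIELDS:
            raise ValueError(
                f"expected '<group>.<field>' with field in {_FIELDS}, got {key!r}"
            )
        per_group.setdefault(group.strip(), {})[fieldname] = float(raw)
    table = default_composition()
    for group, entries in per_group.items():
        missing = set(_FIELDS) - set(entries)
        if missing:
            raise ValueError(f"group {group!r} missing fields: {sorted(missing)}")
        table[group] = GroupComposition(**entries)
    return table


@dataclass(frozen=True)
class SupplementDose:
    """A supplement attached to a plan: label profile × number of servings."""

    profile: MacronutrientProfile
    servings: float = 1.0

    def __post_init__(self) -> None:
        if self.servings <= 0:
            raise ValueError("servings must be positive")


@dataclass(frozen=True)
class MealPlan:
    """Exchange counts per food group, with an optional attached supplement."""

    exchanges: Mapping[str, float] = field(default_factory=dict)
    supplement: Optional[SupplementDose] = None

    def __post_init__(self) -> None:
        for group, count in self.exchanges.items():
            if count < 0:
                raise ValueError(f"negative exchange count for group {group!r}")

    def with_supplement(self, dose: SupplementDose) -> "MealPlan":
        return replace(self, supplement=dose)


class PlanTotals(NamedTuple):
    carbohydrate_g: float
    protein_g: float
    fat_g: float
    energy_kcal: float


@dataclass(frozen=True)
class NutritionTargets:
    """Weight-based energy and protein targets.

    Defaults follow common recommendations for older adults: 30 kcal/kg and
    at least 1 g protein per kg body mass per day.  The protein target is a
    floor; the energy target is a band around mass × kcal/kg.
    """

    body_mass_kg: float
    energy_kcal_per_kg: float = 30.0
    protein_g_per_kg: float = 1.0

    def __post_init__(self) -> None:
        if min(self.body_mass_kg, self.energy_kcal_per_kg, self.protein_g_per_kg) <= 0:
            raise ValueError("targets must be positive")

    @property
    def energy_kcal(self) -> float:
        return self.body_mass_kg * self.energy_kcal_per_kg

    @property
    def protein_g(self) -> float:
        return self.body_mass_kg * self.protein_g_per_kg


class TargetReport(NamedTuple):
    energy_met: bool
    protein_met: bool
    energy_target_kcal: float
    protein_target_g: float


def plan_totals(
    plan: MealPlan,
    composition: Optional[ExchangeComposition] = None,
) -> PlanTotals:
    """Macronutrient and energy totals of a plan.

    Food groups contribute count × per-exchange composition; an attached
    supplement contributes servings × its label profile.
    """
    table = _DEFAULT_COMPOSITION if composition is None else composition
    carbohydrate = protein = fat = energy = 0.0
    for group, count in plan.exchanges.items():
        try:
            comp = table[group]
        except KeyError:
            raise ValueError(
                f"food group {group!r} not in the composition table "
                f"(known: {sorted(table)})"
            ) from None
        carbohydrate += count * comp.carbohydrate_g
        protein += count * comp.protein_g
        fat += count * comp.fat_g
        energy += count * comp.energy_kcal
    if plan.supplement is not None:
        dose = plan.supplement
        carbohydrate += dose.servings * dose.profile.carbohydrate_g
        protein += dose.servings * dose.profile.protein_g
        fat += dose.servings * dose.profile.fat_g
        energy += dose.servings * dose.profile.energy_kcal
    return PlanTotals(carbohydrate, protein, fat, energy)


_GROUP_FOR_EXCHANGE = {"starch": "starch", "lean_meat": "lean_meat", "fat": "fat"}


def incorporate_supplement(plan: MealPlan, ons_exchanges: ExchangeSet) -> MealPlan:
    """Subtract a supplement's exchanges from the matching food groups.

    The supplement replaces food: its starch/lean-meat/fat exchanges are
    removed from the plan's corresponding groups, leaving the plan's
    exchange structure (and approximate totals) unchanged once the
    supplement itself is added back.  Counts clamp at zero with a warning
    when the plan has fewer exchanges than the supplement provides.
    """
    counts = dict(plan.exchanges)
    for attr, group in _GROUP_FOR_EXCHANGE.items():
        reduction = getattr(ons_exchanges, attr)
        if reduction == 0:
            continue
        available = counts.get(group, 0.0)
        if reduction > available:
            warnings.warn(
                f"supplement provides {reduction} {group} exchanges but the "
                f"plan only has {available}; clamping at 0",
                stacklevel=2,
            )
            counts[group] = 0.0
        else:
            counts[group] = available - reduction
    return replace(plan, exchanges=counts)


def check_targets(
    totals: PlanTotals,
    targets: NutritionTargets,
    energy_tolerance: float = 0.05,
) -> TargetReport:
    """Check plan totals against weight-based targets.

    Energy is met within ±``energy_tolerance`` (default 5 %) of the target;
    protein is met at or above the floor (inclusive).
    """
    energy_target = targets.energy_kcal
    protein_target = targets.protein_g
    energy_met = abs(totals.energy_kcal - energy_target) <= energy_tolerance * energy_target
    protein_met = totals.protein_g >= protein_target
    return TargetReport(energy_met, protein_met, energy_target, protein_target)
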