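"""Core domain types and supplement categorization.

Oral nutritional supplements (ONSs) are conventionally grouped by energy
density (kcal per mL of product) and by the fraction of energy supplied by
protein.  This module defines the per-serving product record and implements
the standard cutoffs:

* low energy        < 1.0 kcal/mL
* normal energy     1.0–1.2 kcal/mL (both bounds inclusive) — "isocaloric"
* high energy       > 1.2 kcal/mL
* high protein      > 20 % of energy from protein (4 kcal/g Atwater factor)

Energy density is only defined for liquid servings; powders keep their
protein-based labels but carry no energy category.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Iterator

from pydantic import BaseModel, NonNegativeFloat, PositiveFloat, model_validator

# Atwater general factors (kcal per gram)
ATWATER_CARBOHYDRATE = 4.0
ATWATER_PROTEIN = 4.0
ATWATER_FAT = 9.0

LOW_ENERGY_UPPER_KCAL_PER_ML = 1.0
NORMAL_ENERGY_UPPER_KCAL_PER_ML = 1.2
HIGH_PROTEIN_THRESHOLD_PCT = 20.0


class ServingUnit(str, enum.Enum):
    """Unit in which one commercial serving is declared."""

    MILLILITER = "mL"
    GRAM = "g"


class DensityUndefinedError(ValueError):
    """Energy density requested for a non-liquid (gram-based) serving."""


class FractionUndefinedError(ValueError):
    """Protein-energy fraction requested for a zero-energy profile."""


class MacronutrientProfile(BaseModel, frozen=True):
    """Energy and macronutrient content of one serving, straight off the label.

    ``fiber_g`` defaults to 0 when the label does not declare fiber; the
    exchange engine's fiber rule only triggers above 5 g, so an absent value
    is equivalent to zero for every downstream computation.
    """

    energy_kcal: NonNegativeFloat
    carbohydrate_g: NonNegativeFloat
    protein_g: NonNegativeFloat
    fat_g: NonNegativeFloat
    fiber_g: NonNegativeFloat = 0.0

    def atwater_energy_kcal(self) -> float:
        """Energy reconstructed from the macronutrient grams (4/4/9 factors)."""
        return (
            ATWATER_CARBOHYDRATE * self.carbohydrate_g
            + ATWATER_PROTEIN * self.protein_g
            + ATWATER_FAT * self.fat_g
        )


class ServingDescriptor(BaseModel, frozen=True):
    amount: PositiveFloat
    unit: ServingUnit

    @property
    def is_liquid(self) -> bool:
        return self.unit is ServingUnit.MILLILITER


class Product(BaseModel, frozen=True):
    """One database entry: identity, serving descriptor and label profile."""

    product_id: str
    company: str = ""
    name: str = ""
    serving: ServingDescriptor
    profile: MacronutrientProfile

    @model_validator(mode="after")
    def _soft_mass_check(self) -> "Product":
        # Macronutrient mass cannot exceed the serving mass for gram-based
        # servings.  Label data is noisy, so this is a warning, not an error.
        if self.serving.unit is ServingUnit.GRAM:
            macro_mass = (
                self.profile.carbohydrate_g
                + self.profile.protein_g
                + self.profile.fat_g
            )
            if macro_mass > self.serving.amount:
                warnings.warn(
                    f"product {self.product_id!r}: macronutrient mass "
                    f"{macro_mass:.1f} g exceeds serving mass "
                    f"{self.serving.amount:.1f} g",
                    stacklevel=2,
                )
        return self


class EnergyCategory(str, enum.Enum):
    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"


class CategoryLabel(str, enum.Enum):
    """Overlapping supplement-category labels; a product may carry several."""

    ISOCALORIC = "isocaloric"
    HIGH_ENERGY = "high_energy"
    HIGH_PROTEIN = "high_protein"
    HIGH_ENERGY_HIGH_PROTEIN = "high_energy_high_protein"
    HIGH_ENERGY_NORMAL_PROTEIN = "high_energy_normal_protein"


@dataclass(frozen=True)
class CategoryLabelSet:
    """A validated set of category labels.

    Invariants: the composite labels imply both their parents, and a product
    cannot be isocaloric and high-energy at once.
    """

    labels: FrozenSet[CategoryLabel]

    def __post_init__(self) -> None:
        s = self.labels
        if CategoryLabel.HIGH_ENERGY_HIGH_PROTEIN in s and not (
            CategoryLabel.HIGH_ENERGY in s and CategoryLabel.HIGH_PROTEIN in s
        ):
            raise ValueError(
                "high_energy_high_protein requires high_energy and high_protein"
            )
        if CategoryLabel.HIGH_ENERGY_NORMAL_PROTEIN in s and (
            CategoryLabel.HIGH_ENERGY not in s or CategoryLabel.HIGH_PROTEIN in s
        ):
            raise ValueError(
                "high_energy_normal_protein requires high_energy and not high_protein"
            )
        if CategoryLabel.ISOCALORIC in s and CategoryLabel.HIGH_ENERGY in s:
            raise ValueError("isocaloric and high_energy are mutually exclusive")

    @classmethod
    def of(cls, labels: Iterable[CategoryLabel]) -> "CategoryLabelSet":
        return cls(frozenset(labels))

    def __contains__(self, label: CategoryLabel) -> bool:
        return label in self.labels

    def __iter__(self) -> Iterator[CategoryLabel]:
        return iter(sorted(self.labels, key=lambda l: l.value))

    def __len__(self) -> int:
        return len(self.labels)


def energy_density(product: Product) -> float:
    """kcal per mL for a liquid product.

    Raises :class:`DensityUndefinedError` for gram-based (powder) servings:
    the category cutoffs are defined per milliliter of ready-to-drink
    product, and are not transferable to powder mass.
    """
    if not product.serving.is_liquid:
        raise DensityUndefinedError(
            f"product {product.product_id!r}: energy density undefined "
            "for non-liquid serving"
        )
    return product.profile.energy_kcal / product.serving.amount


def classify_energy(density: float) -> EnergyCategory:
    """Map an energy density (kcal/mL) to its category.

    1.0 and 1.2 kcal/mL both belong to ``normal``; the neighbouring
    categories are bounded by strict inequalities.
    """
    if density < 0:
        raise ValueError(f"energy density must be non-negative, got {density}")
    if density < LOW_ENERGY_UPPER_KCAL_PER_ML:
        return EnergyCategory.LOW
    if density <= NORMAL_ENERGY_UPPER_KCAL_PER_ML:
        return EnergyCategory.NORMAL
    return EnergyCategory.HIGH


def protein_energy_fraction(profile: MacronutrientProfile) -> float:
    """Percent of label energy supplied by protein, at 4 kcal/g."""
    if profile.energy_kcal == 0:
        raise FractionUndefinedError(
            "protein-energy fraction undefined for zero-energy profile"
        )
    return 100.0 * ATWATER_PROTEIN * profile.protein_g / profile.energy_kcal


def assign_categories(product: Product) -> CategoryLabelSet:
    """Assign every category label the product qualifies for.

    Liquid products get energy labels (isocaloric / high_energy) from their
    density and protein labels from their protein-energy fraction, plus the
    composite high-energy × protein labels.  Powders only ever receive
    ``high_protein`` (with a warning that energy categories were skipped).
    Low-energy liquids carry no energy label: the five categories cover only
    normal- and high-energy products.
    """
    labels: set[CategoryLabel] = set()

    high_protein = False
    if product.profile.energy_kcal > 0:
        high_protein = (
            protein_energy_fraction(product.profile) > HIGH_PROTEIN_THRESHOLD_PCT
        )
    if high_protein:
        labels.add(CategoryLabel.HIGH_PROTEIN)

    if not product.serving.is_liquid:
        warnings.warn(
            f"product {product.product_id!r}: non-liquid serving, "
            "energy-based categories not assigned",
            stacklevel=2,
        )
        return CategoryLabelSet.of(labels)

    category = classify_energy(energy_density(product))
    if category is EnergyCategory.NORMAL:
        labels.add(CategoryLabel.ISOCALORIC)
    elif category is EnergyCategory.HIGH:
        labels.add(CategoryLabel.HIGH_ENERGY)
        if high_protein:
            labels.add(CategoryLabel.HIGH_ENERGY_HIGH_PROTEIN)
        else:
            labels.add(CategoryLabel.HIGH_ENERGY_NORMAL_PROTEIN)
    return CategoryLabelSet.of(labels)
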