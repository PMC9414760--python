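"""Synthetic ONS databases for testing and demonstration.

Real supplement databases are proprietary label data, so the toolkit ships
a generator that emulates their structure and value ranges instead: liquid
servings mostly between 125 and 330 mL with occasional >500 mL outliers,
energy densities spanning the low/normal/high bands, protein-energy
fractions on both sides of the 20 % high-protein cutoff, and a powder
archetype with gram-based servings.  Products are drawn from archetype
mixtures; generation keeps a margin from every category cutoff so that the
archetype is recoverable by classification even after the declared energy
is jittered around its Atwater reconstruction (the jitter exercises the
energy-consistency check in the reader).

Synthetic names follow the pattern ``SynthSupp-###`` — no real brand data
is fabricated.  The one real product included,
:func:`fortimel_fixture`, carries only its publicly printed per-serving
macronutrient grams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .model import MacronutrientProfile, Product, ServingDescriptor, ServingUnit

__all__ = ["ARCHETYPES", "GeneratorSpec", "generate_products", "fortimel_fixture"]

ARCHETYPES = (
    "isocaloric",
    "high_energy",
    "high_energy_high_protein",
    "high_protein",
    "powder",
)

_DEFAULT_WEIGHTS: Dict[str, float] = {
    "isocaloric": 0.30,
    "high_energy": 0.25,
    "high_energy_high_protein": 0.25,
    "high_protein": 0.12,
    "powder": 0.08,
}

Range = Tuple[float, float]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic database draw.

    Density ranges sit inside the category bands with a margin wider than
    ``energy_jitter`` so that the archetype survives the declared-energy
    jitter.  The ``high_protein`` archetype is generated at low energy
    density so its label set does not overlap the energy archetypes.
    """

    n_products: int = 400
    seed: int = 0
    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    volume_range_ml: Range = (125.0, 330.0)
    outlier_volume_range_ml: Range = (501.0, 1000.0)
    outlier_rate: float = 0.04
    density_low: Range = (0.70, 0.95)  # kcal/mL
    density_normal: Range = (1.05, 1.14)
    density_high: Range = (1.30, 2.30)
    protein_fraction_normal: Range = (0.08, 0.18)  # fraction of energy
    protein_fraction_high: Range = (0.23, 0.38)
    fiber_range_g: Range = (1.0, 8.0)
    fiber_rate: float = 0.35
    energy_jitter: float = 0.04  # relative jitter of declared vs Atwater energy
    powder_serving_g: Range = (50.0, 90.0)
    powder_energy_kcal_per_g: Range = (3.6, 4.4)


def _validate_weights(weights: Mapping[str, float]) -> np.ndarray:
    unknown = set(weights) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    w = np.array([float(weights.get(a, 0.0)) for a in ARCHETYPES])
    if np.any(w < 0):
        raise ValueError("archetype weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"archetype weights must sum to 1, got {w.sum():g}")
    return w


def _macronutrient_split(
    rng: np.random.Generator, protein_fraction_range: Range
) -> Tuple[float, float, float]:
    """Energy fractions (carbohydrate, protein, fat); fat is the remainder."""
    p = rng.uniform(*protein_fraction_range)
    c = rng.uniform(0.40, min(0.62, 0.92 - p))
    return c, p, 1.0 - c - p


def generate_products(spec: GeneratorSpec) -> List[Product]:
    """Draw a deterministic synthetic product list from ``spec``.

    The same spec (including seed) always yields the same products.
    """
    weights = _validate_weights(spec.weights)
    rng = np.random.default_rng(spec.seed)
    products: List[Product] = []
    for i in range(spec.n_products):
        archetype = str(rng.choice(ARCHETYPES, p=weights))
        protein_range = (
            spec.protein_fraction_high
            if archetype in ("high_energy_high_protein", "high_protein")
            else spec.protein_fraction_normal
        )
        c_frac, p_frac, f_frac = _macronutrient_split(rng, protein_range)

        if archetype == "powder":
            serving = ServingDescriptor(
                amount=round(rng.uniform(*spec.powder_serving_g), 1),
                unit=ServingUnit.GRAM,
            )
            atwater = serving.amount * rng.uniform(*spec.powder_energy_kcal_per_g)
        else:
            if rng.uniform() < spec.outlier_rate:
                volume = rng.uniform(*spec.outlier_volume_range_ml)
            else:
                volume = rng.uniform(*spec.volume_range_ml)
            serving = ServingDescriptor(amount=round(volume, 0), unit=ServingUnit.MILLILITER)
            density_range = {
                "isocaloric": spec.density_normal,
                "high_energy": spec.density_high,
                "high_energy_high_protein": spec.density_high,
                "high_protein": spec.density_low,
            }[archetype]
            atwater = serving.amount * rng.uniform(*density_range)

        carbohydrate = round(atwater * c_frac / 4.0, 1)
        protein = round(atwater * p_frac / 4.0, 1)
        fat = round(atwater * f_frac / 9.0, 1)
        fiber = 0.0
        if rng.uniform() < spec.fiber_rate:
            fiber = round(min(rng.uniform(*spec.fiber_range_g), carbohydrate), 1)
        # declared energy drifts around the Atwater reconstruction, as on labels
        declared = round(atwater * (1.0 + rng.uniform(-spec.energy_jitter, spec.energy_jitter)))

        products.append(
            Product(
                product_id=f"SYN-{i + 1:04d}",
                company="SynthCo",
                name=f"SynthSupp-{i + 1:03d}",
                serving=serving,
                profile=MacronutrientProfile(
                    energy_kcal=float(declared),
                    carbohydrate_g=carbohydrate,
                    protein_g=protein,
                    fat_g=fat,
                    fiber_g=fiber,
                ),
            )
        )
    return products


def fortimel_fixture() -> Product:
    """The one real worked-example product: Fortimel Energy Vanilla, 200 mL.

    The label prints 36.8 g carbohydrate, 11.8 g protein and 11.6 g fat per
    200 mL serving; the energy value here is Atwater-reconstructed from
    those grams (4·36.8 + 4·11.8 + 9·11.6 = 298.8 kcal) rather than taken
    from a label, and the product id flags that.
    """
    return Product(
        product_id="FORTIMEL-ENERGY-200ML-ATWATER",
        company="Nutricia",
        name="Fortimel Energy Vanilla",
        serving=ServingDescriptor(amount=200.0, unit=ServingUnit.MILLILITER),
        profile=MacronutrientProfile(
            energy_kcal=298.8,
            carbohydrate_g=36.8,
            protein_g=11.8,
            fat_g=11.6,
            fiber_g=0.0,
        ),
    )
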