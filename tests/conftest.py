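import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ons_exchanges.model import (
    MacronutrientProfile,
    Product,
    ServingDescriptor,
    ServingUnit,
)
from ons_exchanges.synthetic import GeneratorSpec, fortimel_fixture, generate_products


def make_product(
    product_id="P1",
    amount=200.0,
    unit=ServingUnit.MILLILITER,
    energy_kcal=None,
    carbohydrate_g=25.0,
    protein_g=10.0,
    fat_g=7.0,
    fiber_g=0.0,
) -> Product:
    """Liquid test product; energy Atwater-consistent unless given."""
    if energy_kcal is None:
        energy_kcal = 4 * carbohydrate_g + 4 * protein_g + 9 * fat_g
    return Product(
        product_id=product_id,
        company="TestCo",
        name=f"Test {product_id}",
        serving=ServingDescriptor(amount=amount, unit=unit),
        profile=MacronutrientProfile(
            energy_kcal=energy_kcal,
            carbohydrate_g=carbohydrate_g,
            protein_g=protein_g,
            fat_g=fat_g,
            fiber_g=fiber_g,
        ),
    )


@pytest.fixture
def fortimel() -> Product:
    return fortimel_fixture()


@pytest.fixture(scope="session")
def synthetic_db_400():
    """Seed-fixed 400-product synthetic database (default generator spec)."""
    return generate_products(GeneratorSpec(n_products=400, seed=20260930 % (2**31)))
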