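"""Read, validate and write ONS product databases as delimited text.

The canonical serialization is a delimited-text table with the header

    company,name,serving_amount,serving_unit,energy_kcal,carbohydrate_g,
    protein_g,fat_g[,fiber_g][,product_id]

``serving_unit`` is ``mL`` for liquids and ``g`` for powders.  Header names
are matched case-insensitively after whitespace trimming; ``fiber_g`` and
``product_id`` are optional (absent fiber is read as 0, absent ids are
generated).  European-style decimal commas are normalized to decimal
points.  Validation is total: every input row either becomes a
:class:`~ons_exchanges.model.Product` or is recorded in the
:class:`ValidationReport` — no row can crash the reader.

A row whose declared energy disagrees with the Atwater reconstruction
4·C + 4·P + 9·F by more than 15 % (configurable) draws a warning, not an
error: fiber and polyol energy make the reconstruction inexact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, TextIO, Tuple, Union

import pandas as pd
from pydantic import ValidationError

from .model import (
    CategoryLabelSet,
    MacronutrientProfile,
    Product,
    ServingDescriptor,
    ServingUnit,
    assign_categories,
    energy_density,
)
from .exchange_engine import (
    DEFAULT_RULES,
    ExchangeRuleTables,
    ExchangeSet,
    compute_exchanges,
)

REQUIRED_COLUMNS = (
    "company",
    "name",
    "serving_amount",
    "serving_unit",
    "energy_kcal",
    "carbohydrate_g",
    "protein_g",
    "fat_g",
)
OPTIONAL_COLUMNS = ("fiber_g", "product_id")

#: relative Atwater-reconstruction mismatch above which a warning is issued
DEFAULT_ENERGY_TOLERANCE = 0.15

_UNIT_ALIASES = {
    "ml": ServingUnit.MILLILITER,
    "milliliter": ServingUnit.MILLILITER,
    "millilitre": ServingUnit.MILLILITER,
    "g": ServingUnit.GRAM,
    "gram": ServingUnit.GRAM,
    "grams": ServingUnit.GRAM,
}


@dataclass
class ValidationReport:
    """Row-level errors and warnings from a table read.

    Each entry is ``(row, field, message)`` with ``row`` the 1-based data
    row number (header excluded).  A row with any error is excluded from
    the returned product list; warnings do not exclude.
    """

    errors: List[Tuple[int, str, str]] = field(default_factory=list)
    warnings: List[Tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


class SchemaError(ValueError):
    """A required column is missing from the table header."""


def _parse_number(raw: str) -> float:
    """Parse a label number, accepting a decimal comma."""
    text = raw.strip()
    if "," in text and "." not in text:
        text = text.replace(",", ".")
    return float(text)


def _canonicalize_header(columns: Sequence[str]) -> dict:
    mapping = {}
    for col in columns:
        key = str(col).strip().lower()
        if key in REQUIRED_COLUMNS or key in OPTIONAL_COLUMNS:
            mapping[col] = key
    return mapping


def products_from_dataframe(
    df: pd.DataFrame,
    energy_tolerance: float = DEFAULT_ENERGY_TOLERANCE,
) -> Tuple[List[Product], ValidationReport]:
    """Validate a raw (string-typed) table into products plus a report."""
    report = ValidationReport()
    df = df.rename(columns=_canonicalize_header(df.columns))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    products: List[Product] = []
    seen_ids: set = set()
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        row_errors: List[Tuple[int, str, str]] = []

        def text(col: str, default: str = "") -> str:
            value = row.get(col)
            return default if value is None or pd.isna(value) else str(value).strip()

        numbers = {}
        for col in ("serving_amount", "energy_kcal", "carbohydrate_g",
                    "protein_g", "fat_g"):
            try:
                numbers[col] = _parse_number(text(col))
            except ValueError:
                row_errors.append((i, col, f"unparseable number {text(col)!r}"))
        fiber_text = text("fiber_g") if "fiber_g" in df.columns else ""
        if fiber_text:
            try:
                numbers["fiber_g"] = _parse_number(fiber_text)
            except ValueError:
                row_errors.append((i, "fiber_g", f"unparseable number {fiber_text!r}"))
        else:
            numbers["fiber_g"] = 0.0

        unit_text = text("serving_unit").lower()
        unit = _UNIT_ALIASES.get(unit_text)
        if unit is None:
            row_errors.append(
                (i, "serving_unit", f"unknown serving unit {text('serving_unit')!r}")
            )

        if row_errors:
            report.errors.extend(row_errors)
            continue

        if numbers["serving_amount"] <= 0:
            report.errors.append((i, "serving_amount", "non-positive serving"))
            continue

        product_id = text("product_id") if "product_id" in df.columns else ""
        if not product_id:
            product_id = f"P{i:04d}"
        if product_id in seen_ids:
            report.errors.append(
                (i, "product_id", f"duplicate product_id {product_id!r}")
            )
            continue

        try:
            product = Product(
                product_id=product_id,
                company=text("company"),
                name=text("name"),
                serving=ServingDescriptor(amount=numbers["serving_amount"], unit=unit),
                profile=MacronutrientProfile(
                    energy_kcal=numbers["energy_kcal"],
                    carbohydrate_g=numbers["carbohydrate_g"],
                    protein_g=numbers["protein_g"],
                    fat_g=numbers["fat_g"],
                    fiber_g=numbers["fiber_g"],
                ),
            )
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"]) or "row"
            report.errors.append((i, loc, first["msg"]))
            continue

        stated = product.profile.energy_kcal
        reconstructed = product.profile.atwater_energy_kcal()
        if stated > 0 and abs(stated - reconstructed) / stated > energy_tolerance:
            report.warnings.append(
                (
                    i,
                    "energy_kcal",
                    f"declared {stated:g} kcal differs from Atwater "
                    f"reconstruction {reconstructed:.1f} kcal by more than "
                    f"{energy_tolerance:.0%}",
                )
            )
        seen_ids.add(product_id)
        products.append(product)
    return products, report


def read_product_table(
    source: Union[str, TextIO],
    delimiter: str = ",",
    energy_tolerance: float = DEFAULT_ENERGY_TOLERANCE,
) -> Tuple[List[Product], ValidationReport]:
    """Read a delimited-text product table.

    ``source`` is a path or an open text stream with a header row.  Returns
    the well-formed products (input order preserved) and the validation
    report.  Raises :class:`SchemaError` when a required column is missing.
    """
    df = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    return products_from_dataframe(df, energy_tolerance=energy_tolerance)


def read_product_spreadsheet(
    path: str,
    sheet: Union[int, str] = 0,
    energy_tolerance: float = DEFAULT_ENERGY_TOLERANCE,
) -> Tuple[List[Product], ValidationReport]:
    """Read a product table from a spreadsheet (.xlsx) with the same schema.

    Intended for externally supplied product workbooks; the canonical
    persistence format remains delimited text.
    """
    df = pd.read_excel(path, sheet_name=sheet, dtype=str).fillna("")
    return products_from_dataframe(df, energy_tolerance=energy_tolerance)


def _product_row(product: Product) -> dict:
    p = product.profile
    return {
        "company": product.company,
        "name": product.name,
        "serving_amount": f"{product.serving.amount:.1f}",
        "serving_unit": product.serving.unit.value,
        "energy_kcal": f"{p.energy_kcal:.0f}",
        "carbohydrate_g": f"{p.carbohydrate_g:.1f}",
        "protein_g": f"{p.protein_g:.1f}",
        "fat_g": f"{p.fat_g:.1f}",
        "fiber_g": f"{p.fiber_g:.1f}",
        "product_id": product.product_id,
    }


def write_product_table(
    products: Iterable[Product],
    sink: Union[str, TextIO],
    delimiter: str = ",",
) -> None:
    """Write products in the canonical column order.

    Grams are written with one decimal place and energy as integer kcal;
    reading the output back reproduces the products to that precision.
    """
    columns = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    df = pd.DataFrame([_product_row(p) for p in products], columns=columns)
    df.to_csv(sink, sep=delimiter, index=False)


def write_product_spreadsheet(products: Iterable[Product], path: str) -> None:
    """Mirror of :func:`write_product_table` in .xlsx form (no formulas)."""
    columns = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    df = pd.DataFrame([_product_row(p) for p in products], columns=columns)
    df.to_excel(path, index=False)


def annotate_products(
    products: Sequence[Product],
    rules: ExchangeRuleTables = DEFAULT_RULES,
) -> pd.DataFrame:
    """Per-serving exchanges and category labels for every product.

    Returns one row per product in input order with the label data, the
    energy density and category (empty for powders), the exchange counts at
    one serving, and the assigned category labels joined by ``;``.
    """
    rows = []
    for product in products:
        exchanges: ExchangeSet = compute_exchanges(product.profile, 1, rules)
        labels: CategoryLabelSet = assign_categories(product)
        if product.serving.is_liquid:
            density: Optional[float] = energy_density(product)
        else:
            density = None
        rows.append(
            {
                **_product_row(product),
                "energy_density_kcal_per_ml": density,
                "starch_exchanges": exchanges.starch,
                "lean_meat_exchanges": exchanges.lean_meat,
                "fat_exchanges": exchanges.fat,
                "labels": ";".join(l.value for l in labels),
            }
        )
    columns = (
        list(REQUIRED_COLUMNS)
        + list(OPTIONAL_COLUMNS)
        + [
            "energy_density_kcal_per_ml",
            "starch_exchanges",
            "lean_meat_exchanges",
            "fat_exchanges",
            "labels",
        ]
    )
    return pd.DataFrame(rows, columns=columns)


def annotate_table(
    source: Union[str, TextIO],
    delimiter: str = ",",
    rules: ExchangeRuleTables = DEFAULT_RULES,
) -> Tuple[pd.DataFrame, ValidationReport]:
    """Read a table and annotate it in one step."""
    products, report = read_product_table(source, delimiter=delimiter)
    return annotate_products(products, rules), report


def format_report(report: ValidationReport) -> str:
    """Human-readable rendering of a validation report."""
    lines = []
    for row, col, msg in report.errors:
        lines.append(f"error: row {row}, {col}: {msg}")
    for row, col, msg in report.warnings:
        lines.append(f"warning: row {row}, {col}: {msg}")
    return "\n".join(lines)


def products_to_csv_text(products: Iterable[Product], delimiter: str = ",") -> str:
    buffer = io.StringIO()
    write_product_table(products, buffer, delimiter=delimiter)
    return buffer.getvalue()
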