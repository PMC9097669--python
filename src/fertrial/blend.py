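"""Fertilizer-blend nutrient accounting.

Converts a treatment's product application rates (kg product ha-1) into
elemental/oxide nutrient amounts (kg nutrient ha-1) and their total (TNA,
total nutrient applied).  Supports the urea top-up rule that raises total N
to a fixed target, the standard practice when comparing compound-blend rates
against a blanket N recommendation.

Two rounding regimes are provided:

``full``
    Every amount at double precision; TNA is the exact sum.  This is the
    default for downstream computation.
``display``
    Per-nutrient amounts rounded half-up to one decimal (boron to two)
    before TNA is summed, matching how composition tables are customarily
    printed; the arithmetic runs in :mod:`decimal` so that ties like 2.75
    round up rather than to even.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DomainError
from .trial_data import NUTRIENTS, FertilizerProduct, TreatmentSpec

UREA = "Urea"


@dataclass(frozen=True)
class NutrientComposition:
    """Per-nutrient amounts (kg ha-1) delivered by one treatment."""

    treatment: str
    amounts: Mapping[str, float]
    tna: float
    urea_applied: float


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed agronomy tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def elemental_contribution(product: FertilizerProduct, rate: float) -> dict:
    """Nutrient vector (kg ha-1) supplied by ``rate`` kg ha-1 of a product."""
    if rate < 0:
        raise DomainError(f"application rate must be >= 0, got {rate}")
    return {n: rate * product.grade.get(n, 0.0) for n in NUTRIENTS}


def urea_topup(blend_rate: float, blend_n_fraction: float, target_n: float,
               urea_n_fraction: float) -> float:
    """Urea rate (kg ha-1) needed to raise total N to ``target_n``.

    Returns 0 when the blend alone already supplies the target.
    """
    if urea_n_fraction <= 0:
        raise DomainError("urea N fraction must be > 0")
    return max(0.0, (target_n - blend_rate * blend_n_fraction) / urea_n_fraction)


def resolve_rates(spec: TreatmentSpec,
                  products: Mapping[str, FertilizerProduct]) -> dict:
    """Application rates with the urea top-up resolved to a concrete rate."""
    for name in spec.applications:
        if name not in products:
            raise ConfigurationError(
                f"treatment {spec.code}: unknown product {name!r}"
            )
    rates = dict(spec.applications)
    if spec.urea_rule == "topup_to_target_N":
        if UREA not in products:
            raise ConfigurationError(
                f"treatment {spec.code}: top-up rule requires a {UREA!r} product"
            )
        n_from_others = sum(
            rate * products[name].grade.get("N", 0.0)
            for name, rate in rates.items()
            if name != UREA
        )
        urea_frac = products[UREA].grade.get("N", 0.0)
        rates[UREA] = rates.get(UREA, 0.0) + urea_topup(
            0.0, 0.0, spec.target_n - n_from_others, urea_frac
        )
    return rates


def treatment_composition(spec: TreatmentSpec,
                          products: Mapping[str, FertilizerProduct],
                          rounding: str = "full") -> NutrientComposition:
    """Total nutrient amounts and TNA for one treatment.

    With ``rounding='display'`` each nutrient is rounded half-up to one
    decimal (B to two) before summing TNA, and the urea rate to one decimal.
    """
    if rounding not in ("full", "display"):
        raise DomainError(f"unknown rounding mode {rounding!r}")
    rates = resolve_rates(spec, products)
    if rounding == "full":
        amounts = {n: 0.0 for n in NUTRIENTS}
        for name, rate in rates.items():
            for n, amount in elemental_contribution(products[name], rate).items():
                amounts[n] += amount
        tna = sum(amounts.values())
        return NutrientComposition(spec.code, amounts, tna, rates.get(UREA, 0.0))

    # display mode: exact decimal products of rate x grade, then half-up
    totals = {n: Decimal(0) for n in NUTRIENTS}
    for name, rate in rates.items():
        if rate < 0:
            raise DomainError(f"application rate must be >= 0, got {rate}")
        d_rate = Decimal(repr(rate))
        for n, frac in products[name].grade.items():
            totals[n] += d_rate * Decimal(repr(frac))
    amounts = {}
    for n, value in totals.items():
        ndigits = 2 if n == "B" else 1
        amounts[n] = float(value.quantize(Decimal(1).scaleb(-ndigits),
                                          rounding=ROUND_HALF_UP))
    tna = float(
        sum(Decimal(repr(v)) for v in amounts.values()).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return NutrientComposition(
        spec.code, amounts, tna, round_half_up(rates.get(UREA, 0.0), 1)
    )


def composition_table(specs: Sequence[TreatmentSpec],
                      products: Mapping[str, FertilizerProduct],
                      rounding: str = "display") -> pd.DataFrame:
    """Treatment-composition table: one row per treatment with the resolved
    urea rate, the six nutrient amounts and TNA."""
    rows = []
    for spec in specs:
        comp = treatment_composition(spec, products, rounding=rounding)
        label = " + ".join(
            f"{rate:g} {name}" for name, rate in spec.applications.items()
        ) or "Control (no fertilizer)"
        rows.append({
            "code": spec.code,
            "treatment": label,
            "urea_applied": comp.urea_applied,
            **{n: comp.amounts[n] for n in NUTRIENTS},
            "TNA": comp.tna,
        })
    return pd.DataFrame(rows)
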