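"""CIMMYT-style partial-budget and marginal-rate-of-return analysis.

The procedure compares fertilizer treatments on the costs and benefits that
vary between them:

1. Experimental grain and straw yields are adjusted downward (default 10%)
   to reflect what farmers can expect relative to research plots.
2. Gross field benefits value the adjusted yields at farm-gate prices;
   variable costs are fertilizer plus seed.  Net benefit NB = benefits - costs.
3. A treatment is *dominated* when a cheaper (or equally costly) treatment
   yields at least the same net benefit; dominated treatments are excluded
   from marginal analysis.
4. The marginal rate of return between successive non-dominated treatments
   (ordered by total variable cost) is MRR = 100 * dNB / dTVC; the
   recommended treatment is the highest-MRR one clearing a floor
   (default 100%, i.e. one extra birr of return per birr invested).

Two MRR conventions are implemented: ``canonical`` (both marginal cost and
marginal net benefit taken between successive non-dominated rows, the
standard procedure) and ``paper_table``, which reproduces a common printed
layout where the marginal-cost column steps to the immediately preceding
row of the full cost-ordered table even when that row is dominated, while
marginal net benefit still steps to the previous non-dominated row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .blend import round_half_up
from .errors import ConfigurationError, DomainError

#: Default prices (Ethiopian birr): grain/straw per kg, products per kg,
#: seed per hectare.  The blend surcharge is an extra cost per kg of the
#: compound blend (distribution margin over the listed product price).
DEFAULT_PRODUCT_PRICES = {"DAP": 15.5, "NPSZnB": 15.5, "Urea": 12.0, "KCl": 0.0}


@dataclass(frozen=True)
class PriceSet:
    grain_price: float = 13.5
    straw_price: float = 3.5
    product_prices: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRODUCT_PRICES)
    )
    seed_cost: float = 1440.0
    blend_surcharge: float = 0.89
    surcharged_products: tuple = ("NPSZnB",)
    adjustment_fraction: float = 0.10
    mrr_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.grain_price < 0 or self.straw_price < 0 or self.seed_cost < 0:
            raise DomainError("prices must be >= 0")
        if any(p < 0 for p in self.product_prices.values()):
            raise DomainError("product prices must be >= 0")
        if not 0 <= self.adjustment_fraction < 1:
            raise DomainError("adjustment_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class Recommendation:
    label: object  # None when no treatment clears the threshold
    mrr: float
    net_benefit: float
    message: str


def adjust_yield(yield_kg: float, fraction: float) -> float:
    """Downward-adjusted yield: ``yield * (1 - fraction)``."""
    if yield_kg < 0:
        raise DomainError(f"yield must be >= 0, got {yield_kg}")
    if not 0 <= fraction < 1:
        raise DomainError(f"adjustment fraction must lie in [0, 1), got {fraction}")
    return yield_kg * (1.0 - fraction)


def fertilizer_cost(rates: Mapping[str, float], prices: PriceSet) -> float:
    """Fertilizer cost (birr ha-1) for resolved application rates.

    Rates are rounded half-up to 0.1 kg (the precision at which product is
    weighed out in the field); products carrying the blend surcharge cost
    ``price + surcharge`` per kg.  A positive rate without a listed price is
    a configuration error.
    """
    total = 0.0
    for name, rate in rates.items():
        if rate <= 0:
            continue
        if name not in prices.product_prices:
            raise ConfigurationError(f"no price configured for product {name!r}")
        unit = prices.product_prices[name]
        if name in prices.surcharged_products:
            unit += prices.blend_surcharge
        total += round_half_up(rate, 1) * unit
    return total


def benefit_rows(rows: pd.DataFrame, prices: PriceSet) -> pd.DataFrame:
    """Add gross benefits, TVC and NB to rows carrying agy/asy/fc/sc.

    Columns in (kg ha-1 / birr ha-1): ``agy, asy, fc, sc``; columns out:
    ``tvc, gfbg, gfbs, tgfb, nb``.
    """
    out = rows.copy()
    out["tvc"] = out["fc"] + out["sc"]
    out["gfbg"] = out["agy"] * prices.grain_price
    out["gfbs"] = out["asy"] * prices.straw_price
    out["tgfb"] = out["gfbg"] + out["gfbs"]
    out["nb"] = out["tgfb"] - out["tvc"]
    return out


def dominance(rows: pd.DataFrame) -> pd.DataFrame:
    """Flag dominated rows: some row with TVC <= theirs has NB >= theirs
    (strictly better on at least one side).

    Equal-TVC ties: the lower-NB row is dominated; rows equal on both are
    resolved by input order (the later row is flagged) with a warning.
    The result is sorted ascending by TVC, stable in input order.
    """
    if rows.empty:
        raise DomainError("dominance requires at least one row")
    out = rows.copy().reset_index(drop=True)
    tvc = out["tvc"].to_numpy(dtype=float)
    nb = out["nb"].to_numpy(dtype=float)
    n = len(out)
    dominated = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if tvc[j] < tvc[i] and nb[j] >= nb[i]:
                dominated[i] = True
            elif tvc[j] == tvc[i]:
                if nb[j] > nb[i]:
                    dominated[i] = True
                elif nb[j] == nb[i] and j < i:
                    dominated[i] = True
                    warnings.warn(
                        "rows with identical TVC and NB: later input row "
                        "flagged dominated", stacklevel=2,
                    )
    out["dominated"] = dominated
    return out.sort_values("tvc", kind="stable").reset_index(drop=True)


def marginal_rate_of_return(rows: pd.DataFrame,
                            mode: str = "canonical") -> pd.DataFrame:
    """Add marginal cost (mc), marginal net benefit (mnbc), MRR (%) and rank.

    Requires the ``dominated`` flag (see :func:`dominance`).  Rank orders
    MRR descending among rows where it is defined (1 = highest).
    """
    if mode not in ("canonical", "paper_table"):
        raise DomainError(f"unknown MRR mode {mode!r}")
    if "dominated" not in rows.columns:
        raise DomainError("run dominance() before marginal_rate_of_return()")
    out = rows.sort_values("tvc", kind="stable").reset_index(drop=True)
    n = len(out)
    mc = np.full(n, np.nan)
    mnbc = np.full(n, np.nan)
    mrr = np.full(n, np.nan)
    nd_indices = [i for i in range(n) if not out.loc[i, "dominated"]]

    if mode == "canonical":
        for prev, cur in zip(nd_indices, nd_indices[1:]):
            mc[cur] = out.loc[cur, "tvc"] - out.loc[prev, "tvc"]
            mnbc[cur] = out.loc[cur, "nb"] - out.loc[prev, "nb"]
    else:  # paper_table: MC steps to the immediate predecessor in TVC order
        for i in range(1, n):
            mc[i] = out.loc[i, "tvc"] - out.loc[i - 1, "tvc"]
        for prev, cur in zip(nd_indices, nd_indices[1:]):
            mnbc[cur] = out.loc[cur, "nb"] - out.loc[prev, "nb"]
        # dominated rows print no marginal analysis
        for i in range(n):
            if out.loc[i, "dominated"]:
                mnbc[i] = np.nan

    for i in range(n):
        if np.isnan(mc[i]) or np.isnan(mnbc[i]) or out.loc[i, "dominated"]:
            continue
        if mc[i] == 0:
            warnings.warn(
                f"zero marginal cost between consecutive rows at index {i}; "
                "MRR undefined", stacklevel=2,
            )
            continue
        mrr[i] = 100.0 * mnbc[i] / mc[i]

    out["mc"] = mc
    out["mnbc"] = mnbc
    out["mrr"] = mrr
    order = np.argsort(-mrr, kind="stable")
    rank = np.full(n, np.nan)
    next_rank = 1
    for i in order:
        if not np.isnan(mrr[i]):
            rank[i] = next_rank
            next_rank += 1
    out["rank"] = rank
    return out


def recommend(rows: pd.DataFrame, threshold: float = 100.0,
              label_column: str = "label") -> Recommendation:
    """Pick the highest-MRR non-dominated treatment clearing ``threshold``."""
    if "mrr" not in rows.columns:
        raise DomainError("run marginal_rate_of_return() before recommend()")
    candidates = rows[(~rows["dominated"]) & rows["mrr"].notna()
                      & (rows["mrr"] >= threshold)]
    if candidates.empty:
        return Recommendation(
            None, float("nan"), float("nan"),
            f"no treatment reaches the {threshold:g}% MRR floor",
        )
    best = candidates.loc[candidates["mrr"].idxmax()]
    label = best[label_column]
    return Recommendation(
        label, float(best["mrr"]), float(best["nb"]),
        f"treatment {label} recommended: MRR {best['mrr']:.1f}% "
        f"(>= {threshold:g}%), net benefit {best['nb']:.1f} birr ha-1",
    )


def econ_table(inputs: pd.DataFrame, prices: PriceSet,
               mrr_mode: str = "canonical") -> pd.DataFrame:
    """Full partial-budget table from per-treatment inputs.

    ``inputs`` columns: ``label`` (treatment identifier), ``agy, asy``
    (adjusted yields, kg ha-1), ``fc, sc`` (fertilizer and seed cost,
    birr ha-1).  Output adds benefits, NB, dominance, marginal analysis
    and rank, sorted ascending by TVC.
    """
    required = {"label", "agy", "asy", "fc", "sc"}
    missing = required - set(inputs.columns)
    if missing:
        raise DomainError(f"econ inputs missing columns {sorted(missing)}")
    rows = benefit_rows(inputs, prices)
    rows = dominance(rows)
    return marginal_rate_of_return(rows, mode=mrr_mode)


def econ_inputs_from_trial(means: pd.DataFrame, specs: Mapping[str, object],
                           products: Mapping[str, object],
                           prices: PriceSet) -> dict:
    """Build per-soil econ input frames from treatment-mean yields.

    ``means`` is tidy with columns ``soil, treatment, GY, SY`` (t ha-1).
    Returns ``{soil: inputs DataFrame}`` with yields adjusted downward and
    costs resolved from the treatment specs.
    """
    from .blend import resolve_rates  # local import avoids cycle at module load

    out = {}
    for soil, sub in means.groupby("soil", sort=False):
        rows = []
        for _, row in sub.iterrows():
            code = row["treatment"]
            if code not in specs:
                raise ConfigurationError(f"no treatment spec for {code!r}")
            rates = resolve_rates(specs[code], products)
            rows.append({
                "label": code,
                "agy": adjust_yield(1000.0 * float(row["GY"]),
                                    prices.adjustment_fraction),
                "asy": adjust_yield(1000.0 * float(row["SY"]),
                                    prices.adjustment_fraction),
                "fc": fertilizer_cost(rates, prices),
                "sc": prices.seed_cost,
            })
        out[soil] = pd.DataFrame(rows)
    return out
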