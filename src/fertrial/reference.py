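"""Bundled reference trial: a two-soil NPSZnB-rate bread-wheat experiment.

This module ships the published summary constants of the reference trial
the package was built around — product grades, treatment definitions, local
prices, treatment-mean yields with standard errors, printed total-nutrient-
applied values, and the printed partial-budget table — so that the full
pipeline can run and be checked without the raw plot data (which was never
deposited; only plot-level summaries were published).

The treatment layout: T1 unfertilized control, T2 blanket NP reference
(100 kg DAP + 50 kg KCl + 100 kg urea ha-1), T3-T8 the NPSZnB compound
blend at 50/75/100/125/150/175 kg ha-1 each with 50 kg KCl and urea topped
up to 64 kg N ha-1.

Note on the KCl grade: the printed composition table reports 25 kg K2O from
50 kg KCl, implying a 50% K2O grade rather than the 60% of standard muriate
of potash; the bundled product uses 0.50 to stay consistent with the rest of
the bundled constants (override in a treatments file if needed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .economics import PriceSet
from .trial_data import FertilizerProduct, TreatmentSpec

SOILS = ("Vertisol", "Cambisol")
TREATMENT_CODES = tuple(f"T{i}" for i in range(1, 9))

#: Blend rate labels as used in the partial-budget table, keyed by code.
ECON_LABELS = {"T1": "0", "T2": "NP", "T3": "50", "T4": "75",
               "T5": "100", "T6": "125", "T7": "150", "T8": "175"}


def products() -> dict:
    """Fertilizer products with grade fractions (kg nutrient / kg product)."""
    return {
        "NPSZnB": FertilizerProduct("NPSZnB", {
            "N": 0.178, "P2O5": 0.357, "S": 0.077, "Zn": 0.022, "B": 0.001,
        }),
        "Urea": FertilizerProduct("Urea", {"N": 0.46}),
        "DAP": FertilizerProduct("DAP", {"N": 0.18, "P2O5": 0.46}),
        "KCl": FertilizerProduct("KCl", {"K2O": 0.50}),
    }


def treatments() -> dict:
    """The eight treatment specifications, keyed by code."""
    specs = {
        "T1": TreatmentSpec("T1", {}),
        "T2": TreatmentSpec("T2", {"DAP": 100.0, "KCl": 50.0, "Urea": 100.0}),
    }
    for code, rate in zip(("T3", "T4", "T5", "T6", "T7", "T8"),
                          (50.0, 75.0, 100.0, 125.0, 150.0, 175.0)):
        specs[code] = TreatmentSpec(
            code, {"NPSZnB": rate, "KCl": 50.0},
            urea_rule="topup_to_target_N", target_n=64.0,
        )
    return specs


def prices() -> PriceSet:
    """Local farm-gate prices (Ethiopian birr, 2017-2018 seasons)."""
    return PriceSet()


#: Two-season pooled soil x treatment mean grain yield (t ha-1).
GRAIN_YIELD_MEANS = {
    ("Vertisol", "T1"): 1.58, ("Vertisol", "T2"): 2.13,
    ("Vertisol", "T3"): 1.77, ("Vertisol", "T4"): 2.07,
    ("Vertisol", "T5"): 2.63, ("Vertisol", "T6"): 3.23,
    ("Vertisol", "T7"): 3.27, ("Vertisol", "T8"): 4.33,
    ("Cambisol", "T1"): 2.49, ("Cambisol", "T2"): 4.21,
    ("Cambisol", "T3"): 2.96, ("Cambisol", "T4"): 3.76,
    ("Cambisol", "T5"): 4.12, ("Cambisol", "T6"): 4.78,
    ("Cambisol", "T7"): 4.86, ("Cambisol", "T8"): 5.36,
}

GRAIN_YIELD_SE = {
    ("Vertisol", "T1"): 0.10, ("Vertisol", "T2"): 0.12,
    ("Vertisol", "T3"): 0.09, ("Vertisol", "T4"): 0.09,
    ("Vertisol", "T5"): 0.15, ("Vertisol", "T6"): 0.07,
    ("Vertisol", "T7"): 0.06, ("Vertisol", "T8"): 0.15,
    ("Cambisol", "T1"): 0.04, ("Cambisol", "T2"): 0.04,
    ("Cambisol", "T3"): 0.02, ("Cambisol", "T4"): 0.07,
    ("Cambisol", "T5"): 0.08, ("Cambisol", "T6"): 0.08,
    ("Cambisol", "T7"): 0.02, ("Cambisol", "T8"): 0.02,
}

#: Biological yield (t ha-1) and harvest index (%) cell means.
BIOLOGICAL_YIELD_MEANS = {
    ("Vertisol", "T1"): 7.22, ("Vertisol", "T2"): 8.50,
    ("Vertisol", "T3"): 8.12, ("Vertisol", "T4"): 8.33,
    ("Vertisol", "T5"): 9.13, ("Vertisol", "T6"): 9.65,
    ("Vertisol", "T7"): 10.18, ("Vertisol", "T8"): 11.93,
    ("Cambisol", "T1"): 7.58, ("Cambisol", "T2"): 9.20,
    ("Cambisol", "T3"): 8.67, ("Cambisol", "T4"): 8.87,
    ("Cambisol", "T5"): 10.22, ("Cambisol", "T6"): 10.90,
    ("Cambisol", "T7"): 10.87, ("Cambisol", "T8"): 10.98,
}

HARVEST_INDEX_MEANS = {
    ("Vertisol", "T1"): 21.92, ("Vertisol", "T2"): 25.06,
    ("Vertisol", "T3"): 21.76, ("Vertisol", "T4"): 24.88,
    ("Vertisol", "T5"): 28.81, ("Vertisol", "T6"): 33.50,
    ("Vertisol", "T7"): 32.08, ("Vertisol", "T8"): 36.29,
    ("Cambisol", "T1"): 33.23, ("Cambisol", "T2"): 46.11,
    ("Cambisol", "T3"): 34.22, ("Cambisol", "T4"): 42.78,
    ("Cambisol", "T5"): 40.37, ("Cambisol", "T6"): 43.95,
    ("Cambisol", "T7"): 44.74, ("Cambisol", "T8"): 48.86,
}

#: Printed total nutrient applied (kg ha-1), rounded to one decimal.
TNA_PRINTED = {"T1": 0.0, "T2": 135.0, "T3": 112.0, "T4": 123.4,
               "T5": 134.7, "T6": 146.1, "T7": 157.7, "T8": 169.1}

#: Printed resolved urea rates (kg ha-1) per treatment.
UREA_PRINTED = {"T1": 0.0, "T2": 100.0, "T3": 119.8, "T4": 110.0,
                "T5": 100.4, "T6": 90.7, "T7": 81.1, "T8": 71.3}

# Printed partial-budget tables, one per soil, rows ascending by TVC.
# Columns: label, agy/asy (10%-adjusted yields, kg ha-1), fc/sc/tvc (birr),
# then printed derived columns kept for cross-checking.
_ECON_COLUMNS = ("label", "agy", "asy", "fc", "sc", "tvc", "mc", "gfbg",
                 "gfbs", "tgfb", "nb", "mnbc", "mrr", "rank", "dominated")
NA = float("nan")

_ECON_VERTISOL = [
    ("0",   1422, 3717, 0.0,    1440, 1440.0, NA,     19197.0, 13009.5, 32206.5, 30766.5, NA,      NA,     NA, False),
    ("50",  1917, 4023, 2257.1, 1440, 3697.1, 2257.1, 25879.5, 14080.5, 39960.0, 36262.9, 5496.4,  243.5,  6,  False),
    ("75",  1593, 4527, 2549.3, 1440, 3989.3, 292.2,  21505.5, 15844.5, 37350.0, 33360.8, NA,      NA,     NA, True),
    ("NP",  1863, 5337, 2750.0, 1440, 4190.0, 200.8,  25150.5, 18679.5, 43830.0, 39640.0, 6279.3,  3127.9, 3,  False),
    ("100", 2367, 5220, 2843.8, 1440, 4283.8, 93.8,   31954.5, 18270.0, 50224.5, 45940.7, 6300.7,  6717.2, 1,  False),
    ("125", 2907, 5778, 3137.2, 1440, 4577.2, 293.4,  39244.5, 20223.0, 59467.5, 54890.4, 8949.7,  3050.8, 4,  False),
    ("150", 2943, 6363, 3431.7, 1440, 4871.7, 294.6,  39730.5, 22270.5, 62001.0, 57129.3, 2239.0,  760.1,  5,  False),
    ("175", 3897, 6903, 3723.9, 1440, 5163.9, 292.2,  52609.5, 24160.5, 76770.0, 71606.2, 16715.8, 5721.7, 2,  False),
]

_ECON_CAMBISOL = [
    ("0",   2241, 4995, 0.0,    1440, 1440.0, NA,     30253.5, 17482.5, 47736.0, 46296.0, NA,      NA,     NA, False),
    ("50",  3789, 4788, 2257.1, 1440, 3697.1, 2257.1, 51151.5, 16758.0, 67909.5, 64212.4, 17916.4, 793.9,  4,  False),
    ("75",  2664, 5031, 2549.3, 1440, 3989.3, 292.2,  35964.0, 17608.5, 53572.5, 49583.3, NA,      NA,     NA, True),
    ("NP",  3384, 5220, 2750.0, 1440, 4190.0, 200.8,  45684.0, 18270.0, 63954.0, 59764.0, NA,      NA,     NA, True),
    ("100", 3708, 5481, 2843.8, 1440, 4283.8, 93.8,   50058.0, 19183.5, 69241.5, 64957.7, 745.3,   794.7,  3,  False),
    ("125", 4302, 5490, 3137.2, 1440, 4577.2, 293.4,  58077.0, 19215.0, 77292.0, 72714.9, 7757.2,  2644.3, 1,  False),
    ("150", 4374, 5292, 3431.7, 1440, 4871.7, 294.6,  59049.0, 18522.0, 77571.0, 72699.3, NA,      NA,     NA, True),
    ("175", 4824, 5625, 3723.9, 1440, 5163.9, 292.2,  65124.0, 19687.5, 84811.5, 79647.7, 6932.8,  2373.0, 2,  False),
]


def econ_printed(soil: str) -> pd.DataFrame:
    """The printed partial-budget table for one soil."""
    data = {"Vertisol": _ECON_VERTISOL, "Cambisol": _ECON_CAMBISOL}[soil]
    return pd.DataFrame(data, columns=_ECON_COLUMNS)


def econ_inputs(soil: str) -> pd.DataFrame:
    """Only the input columns of the printed partial-budget table."""
    return econ_printed(soil)[["label", "agy", "asy", "fc", "sc"]].copy()


def _tidy(cells: Mapping[tuple, float], name: str) -> pd.DataFrame:
    rows = [{"soil": s, "treatment": t, name: v}
            for (s, t), v in cells.items()]
    return pd.DataFrame(rows)


def grain_yield_frame() -> pd.DataFrame:
    """Tidy soil/treatment/GY frame of the reference grain-yield means."""
    return _tidy(GRAIN_YIELD_MEANS, "GY")


@dataclass(frozen=True)
class ReferenceTrial:
    products: dict
    treatments: dict
    prices: PriceSet
    grain_yield: pd.DataFrame
    tna: dict
    econ: dict  # soil -> printed partial-budget DataFrame


def load_reference_trial() -> ReferenceTrial:
    """Bundle of every reference constant the pipeline consumes."""
    return ReferenceTrial(
        products=products(),
        treatments=treatments(),
        prices=prices(),
        grain_yield=grain_yield_frame(),
        tna=dict(TNA_PRINTED),
        econ={soil: econ_printed(soil) for soil in SOILS},
    )
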