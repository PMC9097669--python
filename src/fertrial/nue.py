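"""Nutrient-use-efficiency indices.

Agronomic efficiency (AE) is the extra grain produced per kg of nutrient
applied relative to the blanket NP reference::

    AE (kg grain / kg nutrient) = 1000 * (GY - GY_NP) / TNA

Partial factor productivity (PFP) is total grain per kg of nutrient::

    PFP (kg grain / kg nutrient) = 1000 * GY / TNA

where grain yields (GY) are in t ha-1, total nutrient applied (TNA) in
kg ha-1, and the factor 1000 converts tonnes to kg.  Both indices are
undefined (not zero) for the unfertilized control (TNA = 0); AE is
additionally undefined for the NP reference itself.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError


def agronomic_efficiency(gy_treat: float, gy_reference: float, tna: float) -> float:
    """AE in kg grain per kg nutrient; yields in t ha-1, TNA in kg ha-1."""
    if tna <= 0:
        raise DomainError(f"AE requires TNA > 0, got {tna}")
    return 1000.0 * (gy_treat - gy_reference) / tna


def partial_factor_productivity(gy: float, tna: float) -> float:
    """PFP in kg grain per kg nutrient; yield in t ha-1, TNA in kg ha-1."""
    if tna <= 0:
        raise DomainError(f"PFP requires TNA > 0, got {tna}")
    return 1000.0 * gy / tna


def percent_gain(new: float, base: float, convention: str = "new_denominator") -> float:
    """Relative gain of ``new`` over ``base`` in percent.

    ``new_denominator`` divides the difference by the new value (the
    convention used when a gain is quoted as a share of the higher figure);
    ``base_denominator`` is the ordinary relative change.
    """
    if convention == "new_denominator":
        if new == 0:
            raise DomainError("new value must be nonzero")
        return 100.0 * (new - base) / new
    if convention == "base_denominator":
        if base == 0:
            raise DomainError("base value must be nonzero")
        return 100.0 * (new - base) / base
    raise DomainError(f"unknown convention {convention!r}")


def nue_table(grain_yields: pd.DataFrame, tna: Mapping[str, float],
              reference: str = "T2") -> pd.DataFrame:
    """AE and PFP per soil x treatment.

    Parameters
    ----------
    grain_yields:
        Tidy frame with columns ``soil, treatment, GY`` (treatment-mean
        grain yields in t ha-1).
    tna:
        Mapping treatment code -> total nutrient applied (kg ha-1).  The
        control is recognized by TNA = 0.
    reference:
        Treatment code of the NP reference; AE is computed against its
        grain yield within each soil.

    Returns a tidy frame ``soil, treatment, TNA, GY, AE, PFP`` with NaN in
    the undefined cells.
    """
    required = {"soil", "treatment", "GY"}
    if not required.issubset(grain_yields.columns):
        raise DomainError(f"grain_yields needs columns {sorted(required)}")
    if reference not in set(grain_yields["treatment"]):
        raise ConfigurationError(
            f"NP reference treatment {reference!r} absent from grain yields"
        )
    rows = []
    for soil, sub in grain_yields.groupby("soil", sort=False):
        gy_ref = float(sub.loc[sub["treatment"] == reference, "GY"].iloc[0])
        for _, row in sub.iterrows():
            code = row["treatment"]
            if code not in tna:
                raise ConfigurationError(f"no TNA for treatment {code!r}")
            t = float(tna[code])
            gy = float(row["GY"])
            ae = np.nan
            pfp = np.nan
            if t > 0:
                pfp = partial_factor_productivity(gy, t)
                if code != reference:
                    ae = agronomic_efficiency(gy, gy_ref, t)
            rows.append({"soil": soil, "treatment": code, "TNA": t,
                         "GY": gy, "AE": ae, "PFP": pfp})
    return pd.DataFrame(rows)
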