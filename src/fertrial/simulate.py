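"""Synthetic balanced-trial generator.

Generates plot-level data under exactly the additive model the factorial
ANOVA assumes::

    y = grand_mean + soil + treatment + soil:treatment
        + block + season + N(0, residual_sd)

Soil, treatment and interaction effects are fixed and sum to zero (enforced
by centering); block and season effects are Gaussian random effects drawn
once per level per generated dataset; the residual is drawn per plot.
Traits are non-negative, so values are clipped at zero with a warning when
clipping occurs.

The default grain-yield effect specification decomposes the bundled
reference trial's 16 soil x treatment cell means, with ``residual_sd``
0.17 t ha-1 so that the implied error mean square (~0.03) is on the order
of the reference analysis, and ``block_sd`` 0.10 t ha-1 as a modest
replicate-to-replicate field gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError
from .trial_data import KEY_COLUMNS, POOLED, TrialDesign


@dataclass
class EffectSpec:
    """Additive effect specification for one trait."""

    trait: str
    grand_mean: float
    soil_effects: dict = field(default_factory=dict)
    treatment_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)  # (soil, trt) -> offset
    block_sd: float = 0.0
    season_sd: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        for sd in (self.block_sd, self.season_sd, self.residual_sd):
            if sd < 0:
                raise DomainError(f"standard deviations must be >= 0, got {sd}")
        self.soil_effects = _centered(self.soil_effects)
        self.treatment_effects = _centered(self.treatment_effects)
        self.interaction_effects = _centered(self.interaction_effects)

    def cell_mean(self, soil: str, treatment: str) -> float:
        return (self.grand_mean
                + self.soil_effects.get(soil, 0.0)
                + self.treatment_effects.get(treatment, 0.0)
                + self.interaction_effects.get((soil, treatment), 0.0))


def _centered(effects: Mapping) -> dict:
    if not effects:
        return {}
    mean = sum(effects.values()) / len(effects)
    return {k: v - mean for k, v in effects.items()}


def effects_from_cell_means(cell_means: Mapping[tuple, float], trait: str = "GY",
                            block_sd: float = 0.0, season_sd: float = 0.0,
                            residual_sd: float = 0.0) -> EffectSpec:
    """Decompose soil x treatment cell means into additive effects.

    ``cell_means`` maps ``(soil, treatment)`` to the target mean; the
    decomposition is the exact balanced one (grand mean, centered marginal
    effects, interaction as the remainder), so :meth:`EffectSpec.cell_mean`
    reproduces every input cell exactly.
    """
    soils = list(dict.fromkeys(s for s, _ in cell_means))
    treatments = list(dict.fromkeys(t for _, t in cell_means))
    missing = [(s, t) for s in soils for t in treatments if (s, t) not in cell_means]
    if missing:
        raise DomainError(f"cell means missing for {missing}")
    grand = sum(cell_means.values()) / len(cell_means)
    soil_eff = {s: np.mean([cell_means[s, t] for t in treatments]) - grand
                for s in soils}
    trt_eff = {t: np.mean([cell_means[s, t] for s in soils]) - grand
               for t in treatments}
    inter = {(s, t): cell_means[s, t] - grand - soil_eff[s] - trt_eff[t]
             for s in soils for t in treatments}
    return EffectSpec(trait, grand, soil_eff, trt_eff, inter,
                      block_sd=block_sd, season_sd=season_sd,
                      residual_sd=residual_sd)


def default_grain_yield_effects(block_sd: float = 0.10,
                                residual_sd: float = 0.17) -> EffectSpec:
    """Grain-yield effects matching the bundled reference trial cell means."""
    from .reference import GRAIN_YIELD_MEANS

    return effects_from_cell_means(GRAIN_YIELD_MEANS, trait="GY",
                                   block_sd=block_sd, residual_sd=residual_sd)


def balanced_design(soils: Sequence[str] = ("Vertisol", "Cambisol"),
                    treatments: Sequence[str] = tuple(f"T{i}" for i in range(1, 9)),
                    n_blocks: int = 3,
                    seasons: Sequence = (POOLED,)) -> TrialDesign:
    """Convenience factory for a balanced design description."""
    if n_blocks < 1:
        raise DomainError("n_blocks must be >= 1")
    return TrialDesign(tuple(soils), tuple(treatments), n_blocks,
                       tuple(seasons), balanced=True)


def generate_trial(design: TrialDesign,
                   effects: EffectSpec | Sequence[EffectSpec],
                   seed: int | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate one balanced synthetic trial as a tidy frame.

    Identical ``(design, effects, seed)`` yields identical output.  Pass an
    existing ``rng`` instead of ``seed`` to chain replicate datasets.
    """
    if not design.balanced:
        raise IntegrityError("generate_trial requires a balanced design")
    if rng is None:
        rng = np.random.default_rng(seed)
    specs = [effects] if isinstance(effects, EffectSpec) else list(effects)
    if not specs:
        raise DomainError("at least one EffectSpec required")

    soils, trts = design.soils, design.treatments
    blocks = range(1, design.n_blocks + 1)
    seasons = design.seasons
    index = [(s, t, b, season)
             for s in soils for t in trts for b in blocks for season in seasons]
    frame = pd.DataFrame(index, columns=list(KEY_COLUMNS))

    clipped = 0
    for spec in specs:
        block_draws = dict(zip(blocks, rng.normal(0.0, spec.block_sd or 0.0,
                                                  design.n_blocks)))
        season_draws = dict(zip(seasons, rng.normal(0.0, spec.season_sd or 0.0,
                                                    len(seasons))))
        noise = rng.normal(0.0, spec.residual_sd or 0.0, len(index))
        values = np.array([
            spec.cell_mean(s, t) + block_draws[b] + season_draws[season]
            for s, t, b, season in index
        ]) + noise
        clipped += int((values < 0).sum())
        frame[spec.trait] = np.clip(values, 0.0, None)
    if clipped:
        warnings.warn(f"clipped {clipped} negative values to 0", stacklevel=2)
    return frame
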