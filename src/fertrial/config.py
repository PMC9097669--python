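"""Run configuration and the treatments/prices file loader.

The treatments file is YAML or JSON with three optional blocks::

    products:
      NPSZnB: {N: 0.178, P2O5: 0.357, S: 0.077, Zn: 0.022, B: 0.001}
    treatments:
      - code: T3
        applications: {NPSZnB: 50, KCl: 50}
        urea_rule: topup_to_target_N
        target_N: 64
    prices:
      grain_price: 13.5
      product_prices: {DAP: 15.5, NPSZnB: 15.5, Urea: 12}

Any omitted block falls back to the bundled reference trial constants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import reference
from .economics import PriceSet
from .errors import ConfigurationError, DomainError
from .trial_data import FertilizerProduct, TreatmentSpec


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    trial_path: str
    treatments_path: str | None = None
    out_dir: str = "fertrial_out"
    alpha: float = 0.05
    mrr_mode: str = "canonical"
    mrr_threshold: float = 100.0
    block_structure: str = "crossed"
    seed: int | None = None
    reference_treatment: str = "T2"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mrr_mode not in ("canonical", "paper_table"):
            raise DomainError(f"unknown mrr_mode {self.mrr_mode!r}")


def load_treatments_file(path) -> tuple[dict, dict, PriceSet]:
    """Load ``(products, treatment specs, prices)`` from a YAML/JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"treatments file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")

    if "products" in data:
        products = {
            name: FertilizerProduct(name, {k: float(v) for k, v in grade.items()})
            for name, grade in data["products"].items()
        }
    else:
        products = reference.products()

    if "treatments" in data:
        specs = {}
        for entry in data["treatments"]:
            try:
                spec = TreatmentSpec(
                    entry["code"],
                    {k: float(v) for k, v in entry.get("applications", {}).items()},
                    entry.get("urea_rule", "fixed"),
                    float(entry.get("target_N", entry.get("target_n", 0.0))),
                )
            except KeyError as exc:
                raise ConfigurationError(
                    f"{path}: treatment entry missing field {exc}"
                ) from None
            specs[spec.code] = spec
    else:
        specs = reference.treatments()

    if "prices" in data:
        defaults = dataclasses.asdict(PriceSet())
        block = dict(data["prices"])
        unknown = set(block) - set(defaults)
        if unknown:
            raise ConfigurationError(f"{path}: unknown price fields {sorted(unknown)}")
        defaults.update(block)
        defaults["product_prices"] = dict(defaults["product_prices"])
        defaults["surcharged_products"] = tuple(defaults["surcharged_products"])
        price_set = PriceSet(**defaults)
    else:
        price_set = reference.prices()

    return products, specs, price_set
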