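"""Plot-level trial data model and tidy-CSV readers/writers.

A trial is a balanced factorial layout: soil type x fertilizer treatment x
block, optionally repeated over seasons.  The canonical in-memory container
is a tidy :class:`pandas.DataFrame` with one plot per row, key columns
``soil, treatment, block, season`` and one column per measured trait.
Dataclasses (:class:`PlotRecord`, :class:`TrialDesign`,
:class:`FertilizerProduct`, :class:`TreatmentSpec`) carry the validated
domain objects that the other modules consume.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, IntegrityError, ParseError, SchemaError

#: Nutrient labels a fertilizer product may supply (oxide basis for P and K).
NUTRIENTS = ("N", "P2O5", "K2O", "S", "Zn", "B")

#: Measured traits: total/productive tillers (m-2), kernels per spike,
#: thousand-kernel weight (g), biological/grain/straw yield (t ha-1),
#: harvest index (%), grain protein content (%), hectoliter weight (kg hl-1).
TRAITS = ("TT", "PT", "NKS", "TKW", "BY", "GY", "SY", "HI", "GPC", "HLW")

KEY_COLUMNS = ("soil", "treatment", "block", "season")

#: Season label used after averaging over seasons.
POOLED = "pooled"


@dataclass(frozen=True)
class FertilizerProduct:
    """A named fertilizer with nutrient grade fractions (kg nutrient per kg
    product)."""

    name: str
    grade: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.grade) - set(NUTRIENTS)
        if unknown:
            raise DomainError(
                f"product {self.name!r}: unknown nutrient labels {sorted(unknown)}"
            )
        total = 0.0
        for label, frac in self.grade.items():
            if not 0.0 <= frac <= 1.0:
                raise DomainError(
                    f"product {self.name!r}: grade fraction for {label} "
                    f"must lie in [0, 1], got {frac}"
                )
            total += frac
        if total > 1.0 + 1e-9:
            raise DomainError(
                f"product {self.name!r}: grade fractions sum to {total:.4f} > 1"
            )


@dataclass(frozen=True)
class TreatmentSpec:
    """A treatment's product application rates (kg ha-1) plus the urea rule.

    ``urea_rule='topup_to_target_N'`` means urea is added on top of the
    listed applications until total N reaches ``target_n`` kg ha-1.
    """

    code: str
    applications: Mapping[str, float] = field(default_factory=dict)
    urea_rule: str = "fixed"
    target_n: float = 0.0

    def __post_init__(self) -> None:
        if self.urea_rule not in ("fixed", "topup_to_target_N"):
            raise DomainError(f"unknown urea_rule {self.urea_rule!r}")
        for product, rate in self.applications.items():
            if rate < 0:
                raise DomainError(
                    f"treatment {self.code}: negative rate {rate} for {product}"
                )
        if self.urea_rule == "topup_to_target_N" and self.target_n <= 0:
            raise DomainError(
                f"treatment {self.code}: top-up rule requires target_n > 0"
            )


@dataclass
class PlotRecord:
    """One plot's trait measurements with its design labels."""

    soil: str
    treatment: str
    block: int
    season: object = POOLED
    traits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.block < 1:
            raise DomainError(f"block must be >= 1, got {self.block}")
        for trait, value in self.traits.items():
            if trait not in TRAITS:
                raise DomainError(f"unknown trait {trait!r}")
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            if value < 0:
                raise DomainError(f"{trait} must be >= 0, got {value}")
        hi = self.traits.get("HI")
        if hi is not None and not _isnan(hi) and hi > 100:
            raise DomainError(f"HI must lie in [0, 100], got {hi}")
        by, gy = self.traits.get("BY"), self.traits.get("GY")
        if by is not None and gy is not None and not _isnan(by) and not _isnan(gy):
            if by < gy - 1e-9:
                raise DomainError(f"BY ({by}) must be >= GY ({gy})")


@dataclass(frozen=True)
class TrialDesign:
    """Factor levels of a trial; ``balanced`` is true iff every
    soil x treatment x block x season cell holds exactly one plot."""

    soils: tuple
    treatments: tuple
    n_blocks: int
    seasons: tuple
    balanced: bool

    @property
    def n_cells(self) -> int:
        return len(self.soils) * len(self.treatments) * self.n_blocks * len(self.seasons)


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


def _parse_number(raw: str, column: str, row_number: int) -> float:
    text = raw.strip().replace(",", "")  # printed tables use 1,917-style values
    if text == "" or text.upper() in ("NA", "NAN"):
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"non-numeric value {raw!r} for column {column!r} at row {row_number}"
        ) from None


def read_trial_csv(path, trait_map: Mapping[str, str] | None = None):
    """Read a tidy trial CSV into ``(DataFrame, TrialDesign)``.

    Parameters
    ----------
    path:
        CSV with a header row; required columns ``soil, treatment, block``;
        optional ``season``; remaining columns must be trait labels or be
        renamed to one through ``trait_map`` (csv column -> trait label).
    trait_map:
        Optional mapping from a file column name to one of :data:`TRAITS`.

    Raises
    ------
    SchemaError
        Missing required column, or a column that is neither a key, a trait,
        nor mapped.
    ParseError
        Non-numeric or out-of-range value; the message cites the 1-based
        data row number.
    IntegrityError
        Duplicate soil x treatment x block x season cell.
    """
    trait_map = dict(trait_map or {})
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header row required") from None
        for required in ("soil", "treatment", "block"):
            if required not in header:
                raise SchemaError(f"{path}: missing required column {required!r}")
        trait_columns: dict[int, str] = {}
        for idx, column in enumerate(header):
            if column in KEY_COLUMNS:
                continue
            trait = trait_map.get(column, column)
            if trait not in TRAITS:
                raise SchemaError(
                    f"{path}: unknown column {column!r} "
                    f"(map it to one of {', '.join(TRAITS)} or drop it)"
                )
            trait_columns[idx] = trait

        i_soil = header.index("soil")
        i_trt = header.index("treatment")
        i_block = header.index("block")
        i_season = header.index("season") if "season" in header else None

        rows = []
        seen_cells = set()
        for row_number, row in enumerate(reader, start=1):
            if not any(cell.strip() for cell in row):
                continue
            soil = row[i_soil].strip()
            treatment = row[i_trt].strip()
            try:
                block = int(row[i_block].strip())
            except ValueError:
                raise ParseError(
                    f"non-integer block {row[i_block]!r} at row {row_number}"
                ) from None
            season: object = POOLED
            if i_season is not None:
                raw_season = row[i_season].strip()
                if raw_season and raw_season != POOLED:
                    try:
                        season = int(raw_season)
                    except ValueError:
                        raise ParseError(
                            f"season must be an integer year or {POOLED!r}, "
                            f"got {raw_season!r} at row {row_number}"
                        ) from None
            cell = (soil, treatment, block, season)
            if cell in seen_cells:
                raise IntegrityError(
                    f"duplicate plot for soil={soil}, treatment={treatment}, "
                    f"block={block}, season={season} at row {row_number}"
                )
            seen_cells.add(cell)
            traits = {
                trait: _parse_number(row[idx], header[idx], row_number)
                for idx, trait in trait_columns.items()
            }
            try:
                PlotRecord(soil, treatment, block, season, traits)
            except DomainError as exc:
                raise ParseError(f"{exc} at row {row_number}") from None
            rows.append({"soil": soil, "treatment": treatment, "block": block,
                         "season": season, **traits})

    columns = list(KEY_COLUMNS) + [trait_columns[i] for i in sorted(trait_columns)]
    frame = pd.DataFrame(rows, columns=columns)
    return frame, infer_design(frame)


def write_trial_csv(frame: pd.DataFrame, path) -> None:
    """Write a tidy trial frame back to CSV at full stored precision."""
    frame.to_csv(path, index=False)


def infer_design(frame: pd.DataFrame) -> TrialDesign:
    """Infer the factor levels and balance of a tidy trial frame."""
    soils = tuple(dict.fromkeys(frame["soil"]))
    treatments = tuple(dict.fromkeys(frame["treatment"]))
    blocks = sorted(set(frame["block"]))
    seasons = tuple(dict.fromkeys(frame["season"])) if "season" in frame else (POOLED,)
    n_blocks = len(blocks)
    expected = len(soils) * len(treatments) * n_blocks * len(seasons)
    cells = set(zip(frame["soil"], frame["treatment"], frame["block"],
                    frame.get("season", POOLED)))
    balanced = len(frame) == expected and len(cells) == len(frame)
    return TrialDesign(soils, treatments, n_blocks, seasons, balanced)


def pool_seasons(frame: pd.DataFrame) -> pd.DataFrame:
    """Average each soil x treatment x block cell over seasons.

    Every cell must carry the same set of seasons; traits are replaced by
    their unweighted mean and the season label becomes ``'pooled'``.
    """
    if "season" not in frame.columns:
        out = frame.copy()
        out.insert(3, "season", POOLED)
        return out
    season_sets = frame.groupby(["soil", "treatment", "block"])["season"].agg(
        lambda s: frozenset(s)
    )
    if season_sets.nunique() > 1:
        raise IntegrityError(
            "ragged seasons: not every soil x treatment x block cell carries "
            "the same set of seasons"
        )
    trait_cols = [c for c in frame.columns if c not in KEY_COLUMNS]
    pooled = (
        frame.groupby(["soil", "treatment", "block"], sort=False)[trait_cols]
        .mean()
        .reset_index()
    )
    pooled.insert(3, "season", POOLED)
    return pooled[list(KEY_COLUMNS) + trait_cols]


def records_to_frame(records: Iterable[PlotRecord]) -> pd.DataFrame:
    """Convert :class:`PlotRecord` objects to the tidy frame layout."""
    rows = [
        {"soil": r.soil, "treatment": r.treatment, "block": r.block,
         "season": r.season, **r.traits}
        for r in records
    ]
    traits = [t for t in TRAITS if any(t in r for r in rows)]
    return pd.DataFrame(rows, columns=list(KEY_COLUMNS) + traits)


def frame_to_records(frame: pd.DataFrame) -> list[PlotRecord]:
    trait_cols = [c for c in frame.columns if c not in KEY_COLUMNS]
    return [
        PlotRecord(
            row["soil"], row["treatment"], int(row["block"]),
            row.get("season", POOLED),
            {t: row[t] for t in trait_cols if not _isnan(row[t])},
        )
        for _, row in frame.iterrows()
    ]
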