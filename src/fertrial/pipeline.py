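"""End-to-end report assembly: compose, describe, test, rank, recommend.

Runs every stage of the trial analysis on one tidy trial CSV and writes the
standard report tables (composition, descriptives, ANOVA summary, mean
separation, nutrient-use efficiency, per-soil partial budgets) plus a
human-readable ``summary.md``.  All logging goes to stderr; files are the
only data output, so the pipeline is machine-consumable and a pure function
of (input files, configuration).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import anova as an
from . import blend, economics, nue, reference, trial_data
from .config import RunConfig, load_treatments_file
from .errors import FertrialError

log = logging.getLogger("fertrial")


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FertrialError as exc:
                raise type(exc)(f"stage {name!r}: {exc}") from exc
        return wrapped
    return decorator


@_stage("read")
def _read(config: RunConfig):
    frame, design = trial_data.read_trial_csv(config.trial_path)
    log.info("read %d plots (%d soils x %d treatments x %d blocks x %d seasons)",
             len(frame), len(design.soils), len(design.treatments),
             design.n_blocks, len(design.seasons))
    if len(design.seasons) > 1:
        frame = trial_data.pool_seasons(frame)
        log.info("pooled seasons: %d analysis units", len(frame))
    return frame


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the report tables and writes them under
    ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.treatments_path:
        products, specs, prices = load_treatments_file(config.treatments_path)
    else:
        products = reference.products()
        specs = reference.treatments()
        prices = reference.prices()

    frame = _read(config)
    traits = [c for c in frame.columns if c not in trial_data.KEY_COLUMNS]
    report: dict = {}

    # nutrient composition of each treatment
    spec_list = [specs[c] for c in sorted(specs)]
    composition = _stage("compose")(blend.composition_table)(spec_list, products)
    report["composition"] = composition
    composition.to_csv(out_dir / "table2.csv", index=False)
    log.info("composition: %d treatments, TNA %.2f-%.2f kg/ha",
             len(composition), composition["TNA"].min(), composition["TNA"].max())

    # descriptive statistics per soil
    descriptives = _stage("describe")(an.descriptive_stats)(frame, traits)
    report["descriptives"] = descriptives
    descriptives.to_csv(out_dir / "table4.csv", index=False)

    # ANOVA per trait: mean-square matrix with significance stars
    results = {}
    for trait in traits:
        results[trait] = _stage("anova")(an.fit_factorial_anova)(
            frame, trait, block_structure=config.block_structure
        )
    ms_rows = []
    for source in an.SOURCES:
        row = {"source": source,
               "df": int(results[traits[0]].table.loc[source, "df"])}
        for trait in traits:
            tab = results[trait].table
            ms = tab.loc[source, "mean_sq"]
            stars = an.significance_stars(tab.loc[source, "p"])
            row[trait] = f"{ms:.4g}{stars}"
        ms_rows.append(row)
    anova_summary = pd.DataFrame(ms_rows)
    report["anova"] = results
    report["anova_summary"] = anova_summary
    anova_summary.to_csv(out_dir / "table5.csv", index=False)

    # mean separation with LSD letters, per trait over all cells
    sep_frames = []
    for trait in traits:
        sep = _stage("separate")(an.interaction_separation)(
            frame, trait, alpha=config.alpha, anova=results[trait]
        )
        cells = an.cell_means(frame, trait)
        cells["trait"] = trait
        cells["letters"] = [
            sep.letters[f"{s}:{t}"]
            for s, t in zip(cells["soil"], cells["treatment"])
        ]
        cells["lsd"] = sep.lsd
        sep_frames.append(cells)
    separation = pd.concat(sep_frames, ignore_index=True)
    report["separation"] = separation
    separation.to_csv(out_dir / "table6-8.csv", index=False)

    # nutrient-use efficiency from grain-yield cell means and composition TNA
    nue_frame = None
    if "GY" in traits:
        gy_means = an.cell_means(frame, "GY").rename(columns={"mean": "GY"})
        tna = {
            spec.code: blend.treatment_composition(spec, products, "display").tna
            for spec in spec_list
        }
        nue_frame = _stage("nue")(nue.nue_table)(
            gy_means[["soil", "treatment", "GY"]], tna,
            reference=config.reference_treatment,
        )
        report["nue"] = nue_frame
        nue_frame.to_csv(out_dir / "table9.csv", index=False)

    # partial budget per soil (needs grain and straw yields)
    recommendations = {}
    if "GY" in traits and "SY" in traits:
        means = gy_means[["soil", "treatment", "GY"]].merge(
            an.cell_means(frame, "SY").rename(columns={"mean": "SY"})
            [["soil", "treatment", "SY"]],
            on=["soil", "treatment"],
        )
        inputs = _stage("econ")(economics.econ_inputs_from_trial)(
            means, specs, products, prices
        )
        report["econ"] = {}
        for soil, soil_inputs in inputs.items():
            table = _stage("econ")(economics.econ_table)(
                soil_inputs, prices, mrr_mode=config.mrr_mode
            )
            report["econ"][soil] = table
            table.to_csv(out_dir / f"table10_{soil}.csv", index=False)
            rec = economics.recommend(table, config.mrr_threshold)
            recommendations[soil] = rec
            log.info("%s: %s", soil, rec.message)
    report["recommendations"] = recommendations

    _write_summary(out_dir / "summary.md", frame, traits, results,
                   nue_frame, recommendations, config)
    log.info("report written to %s", out_dir)
    return report


def _write_summary(path, frame, traits, results, nue_frame,
                   recommendations, config) -> None:
    lines = ["# Trial analysis summary", ""]
    design = trial_data.infer_design(frame)
    lines.append(
        f"Analyzed {len(frame)} plots: {len(design.soils)} soils x "
        f"{len(design.treatments)} treatments x {design.n_blocks} blocks."
    )
    lines.append("")
    lines.append("## Interaction significance (soil x fertilizer)")
    for trait in traits:
        tab = results[trait].table
        p = tab.loc["soil:fertilizer", "p"]
        stars = an.significance_stars(p)
        lines.append(f"- {trait}: p = {p:.3g} {stars} "
                     f"(CV {results[trait].cv_percent:.1f}%, "
                     f"R2 {results[trait].r2_percent:.1f}%)")
    lines.append("")
    if nue_frame is not None and nue_frame["PFP"].notna().any():
        best = nue_frame.loc[nue_frame.groupby("soil")["PFP"].idxmax()]
        lines.append("## Nutrient-use efficiency maxima")
        for _, row in best.iterrows():
            lines.append(f"- {row['soil']}: PFP {row['PFP']:.2f} kg grain / kg "
                         f"nutrient at {row['treatment']}")
        lines.append("")
    lines.append("## Economic recommendation "
                 f"(MRR floor {config.mrr_threshold:g}%, {config.mrr_mode} mode)")
    for soil, rec in recommendations.items():
        lines.append(f"- {soil}: {rec.message}")
    lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
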