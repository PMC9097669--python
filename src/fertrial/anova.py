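"""Descriptive statistics, balanced two-way factorial ANOVA, LSD mean
separation with letter displays, and Pearson correlation matrices.

The ANOVA model is the classical balanced randomized-block factorial::

    y = mu + replication + soil + fertilizer + soil:fertilizer + error

fitted by the exact balanced-layout decomposition (sums of squares from
marginal-mean deviations), which for a balanced design coincides with the
least-squares fit.  Blocks are by default a single replication factor
crossed with both soils (2 df for 3 blocks); a nested variant
(blocks-within-soil, 4 df) is available through ``block_structure``.

Mean separation follows Fisher's protected LSD: two means differ at level
``alpha`` when their absolute difference exceeds
``t(1 - alpha/2, df_error) * sqrt(2 * MSE / n)``.  Letter displays are built
from maximal runs of statistically indistinguishable means so that two means
share a letter if and only if they are within one LSD of each other.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, IntegrityError
from .trial_data import KEY_COLUMNS, infer_design

SOURCES = ("replication", "soil", "fertilizer", "soil:fertilizer", "residual")


@dataclass
class AnovaResult:
    """ANOVA table plus the summary statistics printed alongside it."""

    trait: str
    table: pd.DataFrame  # index: SOURCES; columns: df, sum_sq, mean_sq, F, p
    grand_mean: float
    cv_percent: float
    r2_percent: float
    n_blocks: int

    @property
    def mse(self) -> float:
        return float(self.table.loc["residual", "mean_sq"])

    @property
    def df_residual(self) -> int:
        return int(self.table.loc["residual", "df"])


@dataclass
class MeanSeparation:
    """Cell means with standard errors, the LSD, and letter groups."""

    means: pd.Series
    se: pd.Series
    lsd: float
    letters: dict


def descriptive_stats(frame: pd.DataFrame, traits: Sequence[str] | None = None,
                      by: str = "soil") -> pd.DataFrame:
    """Min, median, mean, max and sample SD per group for each trait."""
    if traits is None:
        traits = [c for c in frame.columns if c not in KEY_COLUMNS]
    rows = []
    for group, sub in frame.groupby(by, sort=False):
        for trait in traits:
            values = sub[trait].dropna()
            if values.empty:
                raise DomainError(f"no {trait} observations for {by}={group}")
            rows.append({
                by: group, "trait": trait,
                "min": values.min(), "median": values.median(),
                "mean": values.mean(), "max": values.max(),
                "sd": values.std(ddof=1) if len(values) > 1 else 0.0,
            })
    return pd.DataFrame(rows)


def _level_ss(frame: pd.DataFrame, cols, trait: str, grand_mean: float) -> float:
    means = frame.groupby(list(cols), sort=False)[trait].mean()
    n_per = len(frame) / len(means)
    return float(n_per * ((means - grand_mean) ** 2).sum())


def fit_factorial_anova(frame: pd.DataFrame, trait: str,
                        block_structure: str = "crossed") -> AnovaResult:
    """Fit the replication + soil x fertilizer model on a balanced layout.

    Raises :class:`IntegrityError` on unbalanced data or on data still
    carrying more than one season (pool first).
    """
    if block_structure not in ("crossed", "nested"):
        raise DomainError(f"unknown block_structure {block_structure!r}")
    if trait not in frame.columns:
        raise DomainError(f"trait {trait!r} not present")
    if frame[trait].isna().any():
        raise IntegrityError(f"missing {trait} values; balanced data required")
    design = infer_design(frame)
    if len(design.seasons) > 1:
        raise IntegrityError("multiple seasons present; apply pool_seasons first")
    if not design.balanced:
        raise IntegrityError("unbalanced design: every soil x treatment x "
                             "block cell must hold exactly one plot")
    if design.n_blocks < 2:
        raise IntegrityError("at least 2 blocks required")

    y = frame[trait].to_numpy(dtype=float)
    n = len(y)
    s = len(design.soils)
    f = len(design.treatments)
    r = design.n_blocks
    grand_mean = float(y.mean())
    ss_total = float(((y - grand_mean) ** 2).sum())

    if block_structure == "crossed":
        ss_rep = _level_ss(frame, ("block",), trait, grand_mean)
        df_rep = r - 1
    else:  # blocks nested within soils
        soil_means = frame.groupby("soil", sort=False)[trait].mean()
        sb_means = frame.groupby(["soil", "block"], sort=False)[trait].mean()
        n_per = n / len(sb_means)
        ss_rep = float(n_per * sum(
            (sb_means[soil, b] - soil_means[soil]) ** 2
            for soil, b in sb_means.index
        ))
        df_rep = s * (r - 1)

    ss_soil = _level_ss(frame, ("soil",), trait, grand_mean)
    ss_fert = _level_ss(frame, ("treatment",), trait, grand_mean)
    ss_cells = _level_ss(frame, ("soil", "treatment"), trait, grand_mean)
    ss_int = ss_cells - ss_soil - ss_fert
    ss_model = ss_rep + ss_soil + ss_fert + ss_int
    ss_res = ss_total - ss_model
    tol = 1e-10 * max(ss_total, 1.0)
    if ss_int < 0:
        if ss_int < -tol:
            raise IntegrityError("negative interaction SS on balanced data")
        ss_int = 0.0
    if ss_res < 0:
        if ss_res < -tol:
            raise IntegrityError("negative residual SS on balanced data")
        ss_res = 0.0

    df_soil, df_fert = s - 1, f - 1
    df_int = df_soil * df_fert
    df_res = n - 1 - df_rep - df_soil - df_fert - df_int
    dfs = [df_rep, df_soil, df_fert, df_int, df_res]
    sss = [ss_rep, ss_soil, ss_fert, ss_int, ss_res]
    mss = [ss / df if df > 0 else math.nan for ss, df in zip(sss, dfs)]
    mse = mss[-1]

    f_vals, p_vals = [], []
    for source_ms, source_df in zip(mss[:-1], dfs[:-1]):
        if mse == 0 or math.isnan(mse) or df_res < 1:
            f_vals.append(math.nan)
            p_vals.append(math.nan)
        else:
            f_stat = source_ms / mse
            f_vals.append(f_stat)
            p_vals.append(float(stats.f.sf(f_stat, source_df, df_res)))
    f_vals.append(math.nan)
    p_vals.append(math.nan)

    table = pd.DataFrame(
        {"df": dfs, "sum_sq": sss, "mean_sq": mss, "F": f_vals, "p": p_vals},
        index=list(SOURCES),
    )
    cv = 100.0 * math.sqrt(mse) / grand_mean if grand_mean != 0 else math.nan
    r2 = 100.0 * (1.0 - ss_res / ss_total) if ss_total > 0 else math.nan
    return AnovaResult(trait, table, grand_mean, cv, r2, r)


def lsd_value(mse: float, df_error: int, n_per_mean: int,
              alpha: float = 0.05) -> float:
    """Fisher's least significant difference for equal-n means."""
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if mse < 0:
        raise DomainError(f"MSE must be >= 0, got {mse}")
    if df_error < 1 or n_per_mean < 1:
        raise DomainError("df_error and n_per_mean must be >= 1")
    t = stats.t.ppf(1 - alpha / 2, df_error)
    return float(t * math.sqrt(2.0 * mse / n_per_mean))


def _letter_sequence(k: int) -> str:
    letters = string.ascii_lowercase
    if k < len(letters):
        return letters[k]
    return letters[k // len(letters) - 1] + letters[k % len(letters)]


def letter_groups(means: Mapping[str, float] | pd.Series, lsd: float) -> dict:
    """Assign compact letter displays to means separated by an LSD.

    Means are sorted descending (ties keep input order); maximal runs whose
    spread does not exceed the LSD each receive one letter, so two means
    share a letter iff their absolute difference is within the LSD.
    """
    if lsd < 0:
        raise DomainError(f"LSD must be >= 0, got {lsd}")
    items = list(pd.Series(means).items())
    order = sorted(range(len(items)), key=lambda i: -items[i][1])
    values = [items[i][1] for i in order]
    windows = []
    last_end = -1
    for start in range(len(values)):
        end = start
        while end + 1 < len(values) and values[start] - values[end + 1] <= lsd:
            end += 1
        if end > last_end or start == 0:
            windows.append((start, end))
            last_end = end
    letters = {label: "" for label, _ in items}
    for k, (start, end) in enumerate(windows):
        letter = _letter_sequence(k)
        for pos in range(start, end + 1):
            letters[items[order[pos]][0]] += letter
    return letters


def cell_means(frame: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per soil x treatment mean, SE over blocks, and n."""
    grouped = frame.groupby(["soil", "treatment"], sort=False)[trait]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.reset_index()


def interaction_separation(frame: pd.DataFrame, trait: str,
                           alpha: float = 0.05,
                           anova: AnovaResult | None = None) -> MeanSeparation:
    """LSD letters over all soil x treatment cell means jointly."""
    if anova is None:
        anova = fit_factorial_anova(frame, trait)
    cells = cell_means(frame, trait)
    n_per = int(cells["n"].iloc[0])
    lsd = lsd_value(anova.mse, anova.df_residual, n_per, alpha)
    labels = [f"{s}:{t}" for s, t in zip(cells["soil"], cells["treatment"])]
    means = pd.Series(cells["mean"].to_numpy(), index=labels)
    se = pd.Series(cells["se"].to_numpy(), index=labels)
    return MeanSeparation(means, se, lsd, letter_groups(means, lsd))


def pearson_matrix(frame: pd.DataFrame, traits: Sequence[str] | None = None):
    """Pairwise Pearson correlations with p-values.

    Returns ``(r, p)`` DataFrames; a zero-variance trait yields NaN (not 0)
    against every other trait.
    """
    if traits is None:
        traits = [c for c in frame.columns if c not in KEY_COLUMNS]
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            pair = frame[[traits[i], traits[j]]].dropna()
            if len(pair) < 3:
                raise DomainError(
                    f"need >= 3 paired observations for {traits[i]}/{traits[j]}"
                )
            x = pair[traits[i]].to_numpy(dtype=float)
            yv = pair[traits[j]].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(yv) == 0:
                continue  # undefined correlation stays NaN
            res = stats.pearsonr(x, yv)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=traits, columns=traits),
            pd.DataFrame(p, index=traits, columns=traits))


@dataclass(frozen=True)
class ShapiroResult:
    statistic: float
    pvalue: float
    normal: bool


def shapiro_wilk_check(values, alpha: float = 0.05) -> ShapiroResult:
    """Shapiro-Wilk normality check; ``normal`` is true when p > alpha."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not 3 <= len(x) <= 5000:
        raise DomainError("Shapiro-Wilk requires a 1-d sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DomainError("Shapiro-Wilk is undefined for a constant sample")
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    w, pval = stats.shapiro(x)
    return ShapiroResult(float(w), float(pval), bool(pval > alpha))


def significance_stars(p: float) -> str:
    """Conventional significance marks used in printed ANOVA tables."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
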