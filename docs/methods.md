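# Methods

## Data model

A trial is stored tidy: one plot per row with key columns
`soil, treatment, block, season` and one column per trait
(`TT, PT, NKS, TKW, BY, GY, SY, HI, GPC, HLW`; tillers m⁻², kernels
spike⁻¹, g, t ha⁻¹, %, kg hl⁻¹). The reader accepts comma
thousands-separators inside quoted numeric fields, because published tables
print values like "1,917" and fixtures are transcribed from them. Harvest
index is carried as a measured trait rather than recomputed as 100·GY/BY:
the per-plot ratio averaged over replicates is not the ratio of averaged
yields, and published cell means are consistent with per-plot ratios.

Season pooling takes the unweighted mean of each soil × treatment × block
cell across seasons and is applied before ANOVA by default: with two
seasons pooled, a 2 × 8 × 3 layout yields 48 analysis units and a
30-df residual, which is the error stratum all reported tests use. Fitting
the 96 per-season plots directly is possible by skipping `pool_seasons`,
but treats season as unmodeled replication and is not the default.

## Blend composition

Nutrient amounts are `rate × grade` summed over products. The urea top-up
solves `urea = max(0, (target_N − N_from_other_products) / 0.46)`. Everything
downstream uses full double precision; a separate *display* mode reproduces
how composition tables are customarily printed — each nutrient rounded
half-up to one decimal (boron to two) **before** TNA is summed, computed in
decimal arithmetic so ties such as 2.75 → 2.8 and 0.125 → 0.13 round away
from zero rather than to even. The bundled KCl product uses a 50% K₂O grade
(not the 60% of standard muriate of potash) because the reference
composition table reports 25 kg K₂O from 50 kg KCl; it can be overridden in
a treatments file. The reference table's printed urea rates for the 75, 125
and 175 kg ha⁻¹ blends (110, 90.7, 71.3) sit up to 0.11 kg below the
top-up formula's value; the package reports the formula value and tests
compare at 0.15 kg tolerance rather than matching the prints silently.

## ANOVA, LSD and letters

The model is `y = μ + rep + soil + fert + soil:fert + ε` on a balanced
layout, computed by the exact marginal-means decomposition (identical to
least squares here, and fast enough for simulation studies). Replication is
by default a single block factor crossed with both soils — for 48 units
this gives df (2, 1, 7, 7, 30), matching the reference analysis — with a
`nested` option (blocks within soil: 4 and 28 df) for trials where blocks
were laid out independently per soil. Unbalanced data raise an error; no
Type II/III approximation is attempted. F-ratios use the residual mean
square; with a zero MSE the F and p are reported missing, not infinite.

LSD = t₁₋α/2,df·√(2·MSE/n) with n = 3 replicates per interaction cell on
pooled data. Published LSDs cannot be matched exactly from published mean
squares (those are rounded to two decimals); tests assert the printed LSD
falls inside the interval implied by that rounding. Letter displays are
built from maximal runs of the descending-sorted means whose spread is
within one LSD, each run getting one letter; this yields compact labels
("ab") and guarantees two means share a letter iff they differ by at most
the LSD. Ties keep input order. p-values are reported raw; no
multiple-testing correction is applied across traits.

Pearson correlations and the Shapiro–Wilk check wrap scipy; a
zero-variance trait yields a missing correlation rather than 0.

## Nutrient-use efficiency

The denominator of AE and PFP is TNA — the sum of all six nutrients, not N
alone (back-calculation from the reference values confirms this: a
2,200 kg grain gain divided by AE 13.01 gives 169.1 kg, the TNA of the top
rate). AE is undefined for the control and the NP reference; PFP for the
control. The helper `percent_gain` exposes both the ordinary relative
change and the new-value-denominator convention (difference divided by the
*larger, newer* value) used when gains are quoted against the improved
figure, e.g. the 38.4% PFP advantage and the 63.5% maximum grain-yield gain.

One reference cell is internally inconsistent: Cambisol treatment-4 AE is
printed −0.36 while its own inputs give 1000·(3.76 − 4.21)/123.4 = −3.65
(a ×100-for-×1000 slip); the package reports the recomputed value.

## Partial budget

Adjusted yield = 0.9 × experimental yield; grain 13.5 and straw
3.5 birr kg⁻¹; seed fixed at 1,440 birr ha⁻¹ for every row including the
control; KCl carries zero cost (the NP row's printed cost is exactly
DAP + urea). Blend rows cost `rate × (15.5 + 0.89) + urea × 12`: the 0.89
birr kg⁻¹ `blend_surcharge` is the consistent margin by which reference
fertilizer costs exceed the listed product price (settable to 0). Costing
uses rates rounded to 0.1 kg, the precision at which product is weighed out.

Dominance: sorted by total variable cost, a row is dominated when some row
with TVC ≤ its own has NB ≥ its own (strict on at least one side); equal
TVC and NB resolves against the later input row with a warning. The
`canonical` MRR takes both ΔTVC and ΔNB between successive non-dominated
rows. The `paper_table` mode reproduces a common printed layout in which
the marginal-cost column steps to the immediately preceding row of the full
cost-ordered table even when dominated, while marginal net benefit steps to
the previous non-dominated row; printed tables are not fully consistent
even with that rule (two rows of the reference table step their marginal
net benefit differently), so those cells are not used as anchors.
Recommendation = highest-MRR non-dominated row with MRR ≥ the floor
(default 100%); ranking is by MRR descending. Monetary values are kept at
full precision and rounded half-up to one decimal only for display.

From the *printed* adjusted yields and costs, gross-benefit cells reproduce
exactly but five net-benefit cells differ by exactly 0.1 birr because the
printed fertilizer costs are themselves rounded to one decimal; with the
package's full-precision costs, every printed NB cell is reproduced exactly
after display rounding.

## Synthetic trials

`generate_trial` draws `y = cell mean + block + season + N(0, σ_res)` on a
balanced design: soil/treatment/interaction effects are fixed and centered;
block and season effects are Gaussian random effects drawn once per level
per dataset; residuals per plot. Values are clipped at zero (traits are
non-negative) with a warning counting clipped draws. Identical
`(design, effects, seed)` reproduce byte-identical output.

Defaults emulate the reference trial's grain yield: cell means are the 16
published soil × treatment means, `residual_sd = 0.17` t ha⁻¹ (implied
error mean square ≈ 0.03, the order of the reference residual — approximate,
since the published value is rounded), `block_sd = 0.10` t ha⁻¹ as a modest
field gradient, `season_sd = 0`. The generator reproduces exactly the
additive, homoscedastic, Gaussian world the ANOVA assumes — no
weather/soil process detail, no variance heterogeneity between soils, no
spatial correlation within blocks — so passing recovery tests demonstrate
the estimators are correct under the model, not that real trials satisfy it.

## Simulation sizes and numerical choices

The type-I-error check runs 1,000 null replicates of the 48-plot design
(grand mean 10 so the non-negativity clip never engages) and expects the
5%-level interaction rejection rate in [0.03, 0.07]; cell-mean recovery
runs 200 replicates of the default grain-yield simulation and expects ≥95%
of estimated cell means within 3 true standard errors
(SE = √((σ_block² + σ_res²)/3)). Both complete in seconds. Sums of squares
are validated against a brute-force marginal-means oracle and statsmodels
at 10⁻⁸ relative tolerance; tiny negative residual SS from floating
cancellation (below 10⁻¹⁰ of SST) are clamped to zero.

## Known limitations

Balanced complete designs only: missing plots require a mixed-model
framework that is out of scope. Only Fisher's LSD is offered for mean
separation (no Tukey/Duncan). Economics covers a single price scenario per
run; sensitivity analysis means re-running with another `PriceSet`. The
blend surcharge is an empirical fitting constant of the reference cost
structure, not a market model.
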