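# fertrial

Analysis pipeline for balanced fertilizer-rate field trials: blend nutrient
accounting, two-way factorial ANOVA with LSD mean separation, nutrient-use
efficiency indices, and CIMMYT-style partial-budget economics. Written for
agronomists who run soil type × fertilizer-rate experiments (the motivating
case is a bread-wheat trial comparing an NPSZnB compound blend against the
blanket urea+DAP recommendation on Vertisol and Cambisol soils) and want a
tested, reproducible route from plot-level CSV data to a fertilizer
recommendation.

## What it computes

**Blend composition.** Each treatment's product rates (kg ha⁻¹) are converted
to elemental/oxide nutrient amounts via the product grades, with a urea
top-up rule that fixes total N at a target rate (here 64 kg N ha⁻¹), and
summed to TNA (total nutrient applied).

**ANOVA.** The balanced model
*y = μ + rep + soil + fert + soil:fert + ε* is fitted by the exact
balanced-layout decomposition; a 2 soil × 8 treatment × 3 block layout gives
the df partition (2, 1, 7, 7, 30). Mean separation uses Fisher's LSD,
*t*₁₋α/2,df√(2·MSE/n), with compact letter displays; CV = 100·√MSE/ȳ and
R² = 1 − SSE/SST are reported per trait.

**Nutrient-use efficiency.** Agronomic efficiency
AE = 1000·(GY − GY₍NP₎)/TNA and partial factor productivity
PFP = 1000·GY/TNA, in kg grain per kg nutrient (yields in t ha⁻¹).

**Partial budget.** Yields adjusted down 10%, valued at farm-gate prices;
net benefit NB = gross field benefits − variable costs; dominance analysis
removes treatments beaten by a cheaper alternative; the marginal rate of
return MRR = 100·ΔNB/ΔTVC between successive non-dominated treatments picks
the recommendation at a 100% MRR floor.

A synthetic-trial generator (`fertrial.simulate`) draws balanced trials from
exactly the additive model the ANOVA assumes, so every stage is testable
without the original raw plot data; `fertrial.reference` bundles the
published summary constants of the reference trial.

## Worked example

```python
from fertrial import reference as ref, economics, nue

trial = ref.load_reference_trial()
table = nue.nue_table(trial.grain_yield, trial.tna, reference="T2")
print(table[table.soil == "Vertisol"].round(2).to_string(index=False))

econ = economics.econ_table(ref.econ_inputs("Vertisol"), trial.prices)
print(economics.recommend(econ, 100.0).message)
```

prints

```
    soil treatment   TNA   GY    AE   PFP
Vertisol        T1   0.0 1.58   NaN   NaN
Vertisol        T2 135.0 2.13   NaN 15.78
Vertisol        T3 112.0 1.77 -3.21 15.80
Vertisol        T4 123.4 2.07 -0.49 16.77
Vertisol        T5 134.7 2.63  3.71 19.52
Vertisol        T6 146.1 3.23  7.53 22.11
Vertisol        T7 157.7 3.27  7.23 20.74
Vertisol        T8 169.1 4.33 13.01 25.61
treatment 100 recommended: MRR 6717.2% (>= 100%), net benefit 45940.7 birr ha-1
```

AE is undefined for the unfertilized control (TNA = 0) and for the NP
reference itself; the 175 kg ha⁻¹ blend (T8) reaches the maximum AE of
13.01 kg grain per kg nutrient, while the partial budget recommends the
100 kg ha⁻¹ rate — the cheapest step with the highest return per birr
invested (MRR 6717%).

The same stages are available from the shell:

```bash
fertrial simulate --seed 1 --out trial.csv     # synthetic balanced trial
fertrial run --trial trial.csv --out report/   # all tables + summary.md
```

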