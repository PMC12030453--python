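# lignotrial

Analysis toolkit for evaluating lignocellulose (bioenergy) traits in
germplasm trials grown under contrasting irrigation regimes — the setting
of guayule (*Parthenium argentatum*), its relative mariola (*P. incanum*)
and their hybrids, screened as rubber/bioenergy feedstock in arid-zone
field trials.

It is aimed at plant-breeding and quantitative-genetics users who run
**augmented block designs**: replicated check genotypes in every block,
unreplicated test entries, repeated across a well-watered (`IRRI`) and a
water-stressed (`DRY`) environment.

## What it computes

**Fiber chemistry.** From sequential detergent-fiber fractions (percent of
dry matter): hemicellulose = NDF − ADF, cellulose = ADF − ADL,
lignin = ADL. Component yields scale concentrations by plot dry biomass
(kg ha⁻¹), and theoretical ethanol yield follows the stoichiometric chain

```
ethanol [L/ha] = (cellulose + hemicellulose) [kg/ha] × 1.11 × 0.51 × efficiency / 0.79
```

(hydrolysis mass gain, Gay-Lussac fermentation yield, ethanol density; all
configurable).

**Variance components and BLUPs.** The all-random trial model

```
y = μ + E + B(E) + G + CE·is_check + GE + ε
```

is fitted by EM-REML (with a safeguarded SQUAREM accelerator), and
genotype predictions come from Henderson's mixed-model equations — overall
(μ + u_G) and per environment (μ + u_E + u_G + u_GE), the y_C/y_D inputs
of the stress indices. An ANOVA method-of-moments oracle for balanced
layouts is included for cross-checking.

**Heritability.** Entry-mean broad-sense
h² = σ²_G / (σ²_G + σ²_GxE/e), optionally with a residual term
σ²_ε/(e·r̄) in the denominator.

**Stress indices.** STI, YI, YSI, TOL, RSI, STE, GMP and HM per
genotype × trait, plus a consistency checker for their algebraic
identities (e.g. STI·YSI/YI² must equal (Y_D/Y_C)² for every genotype of
a set — which also lets published index tables be validated when the
underlying yields are not available).

**Summaries.** Group means ± SD, trait ranges with argmin/argmax
genotypes, stress-induced percent changes, and Pearson correlation
matrices with two-sided p-values.

**Synthetic trials.** A generator draws complete augmented-design trials
with known variance components (and emits NDF/ADF/ADL so the fiber
arithmetic recovers the simulated traits exactly), so the estimation
stages are testable by parameter recovery.

Reference tables for the 51-genotype USDA guayule/mariola collection
(variance components, genotype BLUPs, group×environment means, stress
indices) ship with the package: `load_fixture("table1")` … `"table4"`.

## Worked example

```python
>>> from lignotrial import load_fixture, group_summary, trait_range, entry_mean_h2
>>> table2 = load_fixture("table2")          # 51 genotypes x 7 traits
>>> gs = group_summary(table2, ["cellulose_pct", "ethanol_yield"]).set_index(["group", "trait"])
>>> round(gs.loc[("mariola", "cellulose_pct"), "mean"], 1)
31.9
>>> round(gs.loc[("_overall", "ethanol_yield"), "mean"])
5342
>>> rng = trait_range(table2, "ethanol_yield")
>>> rng.max_genotype, rng.max_value
('PI 599675', 10982.0)
```

Mariola entries average 31.9% cellulose — about 10 points above the
guayule group — while the collection-wide theoretical ethanol yield
averages 5342 L ha⁻¹, topped by the hybrid PI 599675 at 10,982 L ha⁻¹.

Heritability from the bundled cellulose variance components
(σ²_G = 15.52, σ²_GxE = 0.94, two environments):

```python
>>> t1 = load_fixture("table1").set_index("factor")
>>> h2 = entry_mean_h2({"genotype": t1.loc["genotype", "cellulose_pct"],
...                     "gxe": t1.loc["gxe", "cellulose_pct"]},
...                    e=2, variant="compact")
>>> round(h2.h2, 3)
0.971
```

i.e. nearly all the variance among genotype means is genetic — selection
on cellulose should be effective.

The full pipeline is also available from the shell:

```bash
lignotrial run --seed 7 --out results/demo      # simulate -> derive -> fit -> indices -> summarize
lignotrial summarize --out results/tables       # group summaries of the bundled genotype table
```

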