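# Methods

## Trial model

A plot observation from the two-environment augmented block design is
modelled as

    y = μ + E + B(E) + G + CE·is_check + GE + ε,

with irrigation environment E, block B nested in environment, genotype G,
a check-by-environment interaction CE active only on the replicated check
plots, and genotype-by-environment GE. Every design factor is random with
its own variance σ²; the grand mean μ is the only fixed effect. This
all-random treatment matches standard practice for augmented designs,
where the replicated checks carry the information that adjusts the
unreplicated test entries.

Identification in this design is uneven, and users should know where the
information comes from: σ²_ε is identified by the checks (replicated
across blocks within an environment), σ²_G by the cross-environment
covariance of the same entry, and σ²_GE only by the remainder — for test
entries each genotype×environment cell has a single plot, so GE and ε
separate solely through the check replication. σ²_GE estimates are
correspondingly noisy and right-skewed at the default trial size (see
"Known behaviour" below). σ²_E rests on just two environment levels and
is reported but essentially unestimable.

## EM-REML

Variance components are estimated by restricted maximum likelihood using
the classic EM fixed-point sweep on the REML projection matrix
P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹:

    σ²_i ← σ²_i + (σ²_i)² (‖Z_i′Py‖² − tr(Z_i′PZ_i)) / q_i,

with the analogous update for σ²_ε. EM was chosen for desk-scale
robustness: components stay non-negative by construction and the
restricted likelihood never decreases. Because plain EM converges
sublinearly when a component approaches the zero boundary, sweeps are
extrapolated by a safeguarded SQUAREM step (two EM sweeps, extrapolation
along their difference, then one EM sweep from the extrapolated point;
if the extrapolated likelihood is lower, the plain double sweep is kept).
The accelerator shares EM's fixed point and preserves the monotone
likelihood, and cuts typical sweep counts from tens of thousands to a few
hundred; `accelerate=False` recovers the plain iteration.

Numerical choices:

- **Convergence** when the largest component change in one plain sweep
  falls below `tol · max(1, var(y))` (default `tol = 1e-8`, at most 5000
  sweeps). The variance scaling makes one tolerance meaningful both for
  concentration traits (variance ≈ 10) and yield traits (variance ≈ 10⁶).
- **Boundary handling**: a component update below `1e-12 · max(1, var(y))`
  is pinned to exactly zero (the EM boundary estimate; reference variance
  tables show exact zeros of this kind). The residual is floored rather
  than pinned so V stays invertible in noiseless data.
- **Non-convergence** is flagged on the result object (iterations, final
  change), never silenced.
- Missing responses are dropped with a recorded count; the solver never
  assumes balance.

Estimates are validated three ways: against a method-of-moments ANOVA
oracle on balanced one-way and two-way layouts (where interior REML and
ANOVA estimates coincide), against an independent mixed-model
implementation (statsmodels MixedLM) on unbalanced one-way data, and by
parameter recovery over replicated simulated trials.

## BLUPs

Genotype predictions solve Henderson's mixed-model equations at the
estimated components, with zero-variance terms dropped (their predictions
are identically zero). The per-environment prediction for genotype g in
environment j is μ + u_E(j) + u_G(g) + u_GE(g,j); these environment-split
values are the y_C (well-watered) and y_D (stressed) inputs of the stress
indices. The check-by-environment term is a plot-level adjustment for
check entries and is excluded from genotype predictions. BLUPs shrink
toward the mean: the variance of predicted genotype values never exceeds
the variance of raw genotype means, which the tests assert on every
simulated dataset.

## Heritability

Entry-mean broad-sense heritability is offered in two variants:

- `compact`: h² = σ²_G / (σ²_G + σ²_GxE/e), the compact
  multi-environment form;
- `with_residual` (default): h² = σ²_G / (σ²_G + σ²_GxE/e + σ²_ε/(e·r̄)).

Both are provided because published heritability figures in this domain
are often inconsistent with the compact formula applied to the published
variance components, implying a residual term with an unstated effective
replication r̄. In an augmented design r̄ is not a design constant; the
CLI defaults to the harmonic mean of plots per genotype per environment.

## Stress indices

For a genotype with yields y_C (well-watered) and y_D (stressed), and
population means Y_C, Y_D over the genotype set supplied:

STI = y_C·y_D/Y_C², YI = y_D/Y_D, YSI = y_D/y_C, TOL = y_C − y_D,
RSI = (y_C/y_D)/(Y_C/Y_D), STE = 100·y_D/y_C, GMP = √(y_C·y_D),
HM = 2y_C·y_D/(y_C+y_D).

RSI is implemented exactly in this orientation although part of the
literature defines its reciprocal. Population means are computed over
whichever genotype subset is passed; y_D = 0 leaves RSI undefined (NaN
with a warning) rather than raising.

The family satisfies exact identities (STE = 100·YSI, GMP² = y_C·y_D,
HM·(y_C+y_D) = 2y_C·y_D, RSI·YSI = Y_D/Y_C, and STI·YSI/YI² = (Y_D/Y_C)²
constant across genotypes). `consistency_check` verifies whichever
identities the available columns allow. This is how the bundled published
index table is validated: its underlying per-environment yields are not
public, but the constancy of STI·YSI/YI² can be checked from the printed
two-decimal values — rows with YI < 0.3 are excluded from that scan
because the YI² denominator amplifies rounding error at small YI.

## Synthetic trials

The generator emulates the target study's conditions: 51 unreplicated
test entries, 6 checks in each of 4 blocks per environment, two
environments. All effects are i.i.d. Gaussian — the distributional
assumption under which REML is derived, and the choice that makes
closed-form recovery checks possible. Test entries are assigned to blocks
round-robin (the true field map is not modelled). Default variances for
the concentration traits follow the bundled cellulose variance components
(σ²_E = 1.75, σ²_G = 15.52, σ²_GxE = 0.94) with σ²_B(E) = 0.5,
σ²_CE = 0.25 and σ²_ε = 4 as plausible plot-level noise for a trait
measured in percent. Grand means (lignin 16.3, hemicellulose 15.5,
cellulose 22.5% DM) sit at the collection-wide averages of the bundled
genotype table. Dry biomass uses mean 25,000 kg ha⁻¹ with genotype SD
5,000 and plot SD 2,500, multiplied by 0.3 under DRY — chosen so the
per-group component yields land in the range of the bundled
group×environment table (well-watered cellulose yields near 10⁴ kg ha⁻¹,
roughly 70% reduction under stress).

NDF/ADF/ADL are emitted as ADL = lignin, ADF = lignin + cellulose,
NDF = ADF + hemicellulose, so the derivation stage recovers the simulated
traits exactly. If noise drives a concentration negative, that plot's
residuals are redrawn (at most 50 times, then clipped at zero), keeping
0 ≤ ADL ≤ ADF ≤ NDF. One integer seed feeds a `SeedSequence` whose
children give each factor its own stream, so output is reproducible and
factor draws are independent.

What the generator does **not** emulate: spatial field trend, perennial
multi-year growth, non-Gaussian or heteroscedastic errors, genotype-
specific stress response in the concentration traits (stress enters
through the environment effect and the biomass multiplier), and
measurement error in the fiber assay beyond the plot residual. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to real-data violations
of it.

## Problem sizes and known behaviour

Parameter recovery (in the test suite and the acceptance script) uses 200
simulated full-size trials (150 plots each) at σ²_G = 16, σ²_GxE = 1,
σ²_ε = 4, fitting to a scaled convergence tolerance of 1e-7; mean
estimates of genotype, GxE and residual variance land within two
Monte-Carlo standard errors of truth. Individual σ²_GxE estimates are
strongly right-skewed (median well below the mean) because the component
is weakly identified in this design, and its replicate-mean can sit a few
percent below the simulated value in some seed batches — a finite-sample
property of boundary-truncated REML, not an implementation defect; the
genotype and residual components show no such sensitivity.

Reporting convention for printed outputs: concentrations to 1 decimal,
yields and ethanol to integers, percent changes to the nearest integer
(one decimal where the source reports one), correlations to 3 decimals;
all computation is done and stored at full precision.

## Known limitations

- σ²_E with two environment levels is reported but carries almost no
  information; do not interpret it.
- The moments oracle intentionally refuses unbalanced data; it exists as
  an independent check, not as an estimator for real trials.
- Correlation p-values use n = number of genotype rows supplied. When a
  published matrix was computed at plot level, its p-values are not
  comparable to genotype-level recomputation.
- Theoretical ethanol is a stoichiometric upper bound; process efficiency
  below 1 must be supplied by the user to approximate realistic recovery.
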