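# Methods

## System and model

The package models an integrated production system: Spirulina cultivated
in geothermally powered photobioreactors, phycocyanin extracted by
ultrasound-assisted extraction, and the soluble amino-acid-rich waste
fraction applied to degraded Icelandic soils as a plant biostimulant. All
flows are normalised to the functional unit of 1 color unit (CU) of
phycocyanin delivered at factory gate.

Impact assessment is the standard linear LCA map: each inventory flow is
converted to SI base units (t→kg ×1000, g→kg ×0.001) and multiplied by a
per-unit characterization factor and a direction sign. Amounts are stored
non-negative; removals (CO₂ biofixation during cultivation, SOC
sequestration) carry `direction_sign = −1` so the shipped inventory
fixture keeps its published amounts verbatim while the climate total
correctly nets them out. Climate (GWP100) is always computed; water
(AWARE) and land-quality scores are computed only when a factor table for
those categories is supplied and are otherwise reported as "not
characterized", never as zero. Because per-flow background factors are
licensed database content, the default configuration characterizes the
system through *stage-level* climate intensities (cultivation 0.15,
extraction 4.83, sequestration −1602.48 kg CO₂-eq/CU); a full per-flow
factor table can be supplied to use the per-flow path instead.

### Parameters that matter

| parameter | default | unit | note |
|---|---|---|---|
| pigment per CU | 7.12 | g | canonical; the nominal 140 CU/kg implies 7.143 g (0.3 % gap, display metadata only) |
| pigment yield y_pc | 0.0322 | – | fraction of dry biomass |
| waste fraction f_w | 0.158 | – | fraction of dry biomass |
| SOC rate r_soc | 25.0 | kg SOC g⁻¹ yr⁻¹ | per gram biostimulant |
| C→CO₂ | 44/12 | – | exact molar ratio; the rounded reported rates 91.8/45.9 kg CO₂-eq g⁻¹ imply ≈3.672 — no calibration constant is introduced and the ≤0.15 % gap is tolerated in tests |
| reversal buffer | 0.5 | – | credited fraction after the reserve |
| uncertainty margin | 0.30 | – | case-study deduction, applied to the net negative balance only |
| application rate | 47.6 | g ha⁻¹ yr⁻¹ | implies 1.19 t SOC ha⁻¹ yr⁻¹, below the trial's 1.34 tC ha⁻¹ yr⁻¹ lower bound — crediting is conservative relative to observation |
| credited flow per CU | 1602.48 | kg CO₂-eq | inventory-table value; the mass-balance route w·r·b·44/12 gives 1601.26 (0.08 % apart). The inventory flow is the default baseline; set `stages.sequestration_credit_kg_per_cu: null` to derive the credit from the mass balance when changing y_pc, f_w or the crediting parameters |

Internally everything is kg CO₂-eq and grams at full precision; rounding
(2 decimals for kg, 1 for percentages) happens only in report output.

## Sensitivity and scenarios

OAT sensitivity perturbs one parameter by ±δ (default 20 %). The
sequestration rate scales the credit term exactly; the other parameters
(cultivation energy, cultivation yield, transport) act through named
per-CU GWP contributions. These contribution magnitudes are **not
published**; the defaults (5.15, 6.72, 0.75 kg CO₂-eq/CU) are back-solved
from the published response table and are flagged as reconstructions.
Energy and transport are modelled `linear` (contribution ∝ 1+δ);
cultivation yield is `inverse` (per-CU burden ∝ 1/(1+δ)), which
reproduces the published +20 % response and explains the asymmetry of its
printed ±rows; its −20 % response computes to +1.68 kg vs the printed
+1.90 — a documented divergence. Antisymmetry of ±δ responses holds for
linear-mode parameters only. Percentage changes use
(net−baseline)/|baseline|, so a deeper credit prints negative.

Scenarios: S1 scales the credit (×0.5); S2 removes 90 % of the
cultivation-energy contribution; S3 applies a configured net delta for
ground-based instead of drone application (default −1.60 kg/CU,
back-solved); S4 sets y_pc = 0.20 — since every per-CU flow scales with
the biomass needed per CU, the whole net balance scales by y_old/y_new
(−257.20 kg/CU, an 83.9 % loss of carbon-negative potential). The
reported reference values for S1 (−793.96) and S2 (−1603.89) cannot be
derived from any combination of the published constants; the pipeline
computes −796.26 and −1602.14 and logs a warning with the delta instead
of force-fitting.

## Case study

Product footprint: raw-material emissions × (1 + overhead) + packaging,
with overhead 0.30 as a conservative stand-in for missing production
data. The shipped ingredient emission factors are **synthetic,
illustrative values** (the real background-database factors are licensed
and unpublished), so computed bag footprints demonstrate the pipeline and
are not reproductions. Colorant substitution adds
dosage (0.28 CU/kg) × unit mass × net-per-CU; the removed colorant's own
share defaults to zero (its proxy mass, 0.1 g/bag, is negligible). The
corporate table scales a back-computed 26,374,480 t Scope 1+2+3 total
linearly across reduction goals; the per-bag (5.349 kg) and per-CU
(9551.6 kg) conversions are back-solved reconstructions, and only the
table's linear structure is asserted by tests.

## Field-trial statistics

The trial: treated (EXP) and control (CTRL) sites of 12.45 ha, 60 cm
cores, n = 9/6 at baseline and 9/9 a year later; cores are destructive,
so timepoints are independent samples. Analyses:

* **Kruskal–Wallis** (tie-corrected, χ² p-value) on EXP T1 vs T0 stocks —
  a rank test was chosen because n ≤ 9 per stratum makes normality
  unverifiable. All-identical data return H = 0, p = 1.
* **Annual increase**: difference-in-differences
  (ΔEXP − ΔCTRL, the default) or the plain EXP change; the one-sided
  lower confidence bound (default 90 %) is a seeded percentile bootstrap
  resampling cores within each stratum (default 10,000 resamples,
  bit-reproducible per seed). One-sided was chosen because only a lower
  bound is scientifically at stake for crediting.
* **Analytical CV**: sample sd/mean of replicate measurements of one
  homogenised sample.
* **Relative increase**: annual change / baseline stock.

## Synthetic data generator

Per-core stock = lognormal(site-time mean, between-core CV) ×
(1 + N(0, analytical CV)). Lognormal was chosen because SOC stocks are
positive and right-skewed; the multiplicative factor models instrument
noise. Defaults: baseline 30.5 tC/ha (back-solved from a 1.34 t gain
being a 4.4 % relative increase), between-core CV 12 % (an assumption —
the real sites' between-core variability is unpublished — and the single
most consequential generator choice), analytical CV 3.44 %, EXP effect
+1.6 tC/ha/yr, CTRL effect 0. All draws flow through
`numpy.random.default_rng` (PCG64); a fixed seed gives byte-identical
tables. A paired mode shares per-position multipliers across timepoints
for method testing; spatial autocorrelation, covariates and drift are not
modelled.

What passing tests show — and don't: the generator reproduces its own
parameters (CV and effect recovery), the rank test holds its nominal
type-I error (~5 % over 1000 null trials), and the bootstrap bound covers
the true effect at close to its nominal 90 % (percentile bootstraps at
n ≈ 9 undercover by a few points; the test band is 84–96 %). Under the
default 12 % between-core CV the per-core noise (sd ≈ 3.7 tC/ha) dwarfs a
1.6 t effect at n = 9, so a single simulated trial is usually
non-significant and its lower bound wide — the simulation is a
calibration-level emulation of the design, not a reproduction of the
reported trial outcome (raw cores are unpublished). Real field data add
spatial structure and sampling-protocol effects the generator does not
represent.

## Numerical choices and scale

Bootstrap quantiles use numpy's default linear interpolation. Monte-Carlo
problem sizes (1000 trials for error-rate checks, 500 bootstrap resamples
inside coverage loops, 2000–3000 seeds for recovery means) were chosen so
Monte-Carlo error is comfortably inside each test band while the whole
suite runs in well under a minute. Validation is strict everywhere:
unknown units, unmapped stages, missing characterization factors, missing
strata and unknown config keys are hard errors, never silent defaults.

## Known limitations

No dynamic SOC decay/permanence modelling over the 100-year horizon; no
spatial SOC mapping or interpolation; no Monte-Carlo uncertainty
propagation of the LCA itself (only OAT and scenarios); no co-product
allocation beyond the fixed mass-balance fractions; background emission
factors are user-supplied configuration, not reproduced data.
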