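# Methods

## Problem setting

A hydrocarbon reservoir flooded with CO₂ for enhanced oil recovery retains
part of the injected gas for decades. Three sinks can shrink the free CO₂
pool: dissolution into formation water (solubility trapping), carbonate
precipitation, and microbial conversion to CH₄ by hydrogenotrophic
methanogens (CO₂ + 4H₂ → CH₄ + 2H₂O). The package infers, per sample and per
field, how much CO₂ has been removed and how that removal partitions between
dissolution and methanogenesis, then cross-checks the inference with
isotope-exchange thermometry, helium source attribution, gas dryness, and an
environmental feasibility screen.

## Removal accounting with CO₂/³He

³He has no significant crustal source, is inert and is effectively insoluble
at reservoir conditions, so the CO₂/³He ratio of a trapped gas changes only
through CO₂ addition or removal. The most pristine sample — the highest
CO₂/³He in the field, overridable in the config — anchors the accounting:
every other sample's remaining fraction is f = (CO₂/³He) / (CO₂/³He)_ref.
Samples whose ratio exceeds the reference (apparent CO₂ *gain*) are excluded
from the removal fit and reported with the reason; the model's domain is
removal only. An alternative mode (`f_source: co2_molpct`) uses CO₂
concentrations relative to the reference instead, as an independent
consistency check. Because the reference has itself usually undergone some
removal, every removal and consumption estimate is a lower bound.

Helium provenance is established first: the measured ³He/⁴He (R/R_A) is
air-corrected with X = (⁴He/²⁰Ne)_sample / (⁴He/²⁰Ne)_air via
Rc/R_A = (R/R_A·X − 1)/(X − 1) (all ²⁰Ne taken as atmospheric; samples with
X ≤ 1 are rejected as air-dominated), then unmixed linearly between a crustal
(0.02 R_A) and a subcontinental-lithospheric-mantle (6.1 R_A) endmember.
Linear-in-Rc mixing (total-He weighting) is the default; the ³He-budget
weighting is exposed as `mantle_he3_fraction` for comparison. For natural
(never-injected) CO₂ fields the pre-removal CO₂/³He endmember is estimated by
ordinary least squares of CO₂/³He against CO₂ mole fraction, extrapolated to
mole fraction 1.0; the endpoint choice is a convention of this package since
only the extrapolation idea, not its abscissa, is standardised.

## Fractionation models

Let δ ≡ δ¹³C-CO₂ (‰ VPDB), δ_i the initial (reference) composition, f the
remaining fraction.

* **Dissolution — open-system Rayleigh.** The standalone curve is computed on
  the (1000 + δ) scale, (1000 + δ) = (1000 + δ_i)·f^(α_d−1), which matches an
  incremental-removal oracle (10⁶ equal mass steps, each removing an
  α-fractionated increment) to better than 0.01 ‰ for f ≥ 0.05. α_d = 1.0038
  ± 0.0012, the value appropriate to the field's near-neutral pH; carbonate
  precipitation uses the same form with α_p = 1.0086 ± 0.0012.
* **Methanogenesis — closed-system equilibrium.** Microbial cycling
  (methanogenesis plus anaerobic oxidation of methane, AOM) holds CH₄ and CO₂
  near isotopic exchange equilibrium, so the residual pool shifts linearly:
  δ = δ_i − (α_m − 1)(1 − f)·1000 with α_m = 0.9363 ± 0.003 (thermal
  equilibration at reservoir temperature). A pool-weighted mass balance
  (f·δ_res + (1−f)·δ_CH₄ = δ_i with δ_CH₄ one equilibrium offset below
  δ_res) holds to first order in (α−1), verified numerically to < 0.05 ‰.
* **Hybrid.** With dissolution share F_d of the removed CO₂, the apparent
  factor is α_A = F_d·α_d + (1−F_d)·α_m and

      δ = δ_i · f^(α_A−1) − (α_A − 1)(1 − f) · 1000.

  The hybrid is deliberately evaluated on the δ scale (δ multiplied directly
  by f^(α_A−1)) with α_A in **both** terms. On this scale the
  pure-methanogenesis limit (F_d = 0) is exact at δ_i = 0 and within
  |f^(α_m−1) − 1|·|δ_i| (hundredths of ‰) otherwise, and at F_d = 1 the curve
  approaches the standalone Rayleigh curve to within the scale-convention
  term 1000(α_d−1)(ln f + 1 − f) — at most ~5 ‰ at f ≈ 0.1 and < 1 ‰ for
  f ≥ 0.5. Evaluating the first term on the (1000 + δ) scale instead would
  inject a 1000·(f^(α_m−1) − 1) artefact (≈ +150 ‰ at f = 0.11, F_d = 0)
  that contradicts both limiting curves and the ‰-scale data the model is
  meant to describe; the δ-scale blended form is the only variant that
  recovers both endmember trajectories. A *sequential partitioned* variant
  (`hybrid_mode: sequential`; (1000+δ)-scale Rayleigh step over the dissolved
  share, then a closed-system step over the converted share of the original
  pool) is provided as a robustness check; it tracks the default within the
  same analytic bound.

**Inversion.** δ is strictly decreasing in F_d at fixed f < 1 (monotonicity
is asserted before inversion), so F_d is recovered by bisection on [0, 1]
(`scipy.optimize.brentq`, xtol 1e-12; round-trips to < 1e-6). Observations
outside the envelope bounded by the F_d = 1 and F_d = 0 curves are flagged
with their signed per-mil distance and excluded, never clamped. δ_i defaults
to the reference sample's measured δ¹³C-CO₂ (the accounting is defined
relative to that sample); the injectate composition can be supplied instead
via an explicit reference override.

The removed fraction then splits exactly: methanogenic consumption
(1−f)(1−F_d), dissolved share (1−f)F_d, summing to 1−f by construction.
Field-level reporting uses the mean F_d, the dissolution:methanogenesis ratio
D:M = F_d/(1−F_d), and the per-sample consumption ranges.
`CO2PartitionModel.fit(mc_draws=...)` additionally refits under Gaussian
draws of (α_d, α_m) within their 1σ uncertainties (draws violating
α_m < 1 < α_d are rejected) and reports 16/84-percentile intervals on the
mean F_d and M:D — calibration uncertainty, separate from measurement noise.

## Thermometry

All calibrations are polynomials in x = 1000/T[K], shipped as an editable
data file and identified in reports by checksum; each curve must be strictly
decreasing in T over its validity range (270–700 K, asserted at 1 K steps).

* **CO₂–CH₄ carbon exchange**: the Horita (2001) experimental calibration,
  1000 ln α = 0.16 + 11.754x² − 2.3655x³ + 0.2054x⁴. The separation is
  computed on the ln-ratio scale 1000·ln[(1000+δ_CO₂)/(1000+δ_CH₄)] — the
  scale thermodynamic calibrations are defined on — with the raw difference
  also exposed for comparability (they differ by < 2 ‰ here).
* **Clumped isotopologues** (Δ¹³CH₃D, Δ¹²CH₂D₂): the bundled defaults are
  *synthetic* two-term fits A·x² + B·x³, each anchored to two published
  (Δ, apparent-temperature) equilibrium pairs and decaying to the stochastic
  limit (0 ‰) at infinite temperature. They reproduce literature-scale
  equilibrium values (≈5.7 ‰ and ≈20 ‰ at 25 °C respectively) but are
  stand-ins, not a published theoretical curve; substitute a preferred
  calibration by editing `co2fate/data/calibrations.yaml`. Apparent
  temperatures from different published clumped calibrations can differ by
  several °C, so cross-study comparisons should pin the calibration file.

Apparent temperatures invert the observed value by bisection (round trip
< 0.01 K). Uncertainty is propagated by Monte Carlo: draws
δ ~ Normal(δ_obs, σ), inverted through a cached dense grid (60 000 nodes;
interpolation error ≪ the 0.01 K solver tolerance), reported as the 16th/84th
percentiles; draws outside the attainable range are rejected and counted,
with > 50 % rejection raising a "poorly constrained" error. Because the
curves flatten toward high T, the intervals are correctly asymmetric (longer
upper tail). Coverage of the 16/84 interval is ≈ 68 % by simulation. The
disequilibrium vector (observed minus equilibrium-at-reservoir-T, per
isotopologue) classifies samples: a Δ¹²CH₂D₂ deficit with near-equilibrium
Δ¹³CH₃D (tolerance 1 ‰, the measurement scale) is the signature of microbial
methane being driven back toward equilibrium by AOM, which equilibrates
Δ¹³CH₃D faster.

## Budgets and the environmental window

CH₄ production is 1:1 with consumed CO₂. Volumes are m³ (STP); moles use a
molar volume of 24.465 L/mol (25 °C, 1 atm — the gas-industry STP convention
that reproduces the study's printed rates, vs 22.414 at 0 °C), configurable.
The rate normalisation volume defaults to the total injected CO₂ volume.
Biogenic gas fractions follow from two-component dryness mixing,
b = (r_obs − r_t)/(1 − r_t) against a purely thermogenic endmember
r_t = 0.909; both the biogenic share of total gas and of CH₄ (b/r_obs) are
reported since the headline figure is ambiguous between them.

The methanogenesis screen applies hard physiological limits (T ≤ 80 °C,
4 ≤ pH ≤ 9, Cl⁻ ≤ 1500 mM, SO₄²⁻ ≤ 1 mM, Fe ≤ 1 mM — any breach names the
condition and rules the window unfavourable), reports optimal ranges
(40–50 °C; Cl⁻ 200–600 mM) as notes, and evaluates supporting indicators of
past methanogenesis (alkalinity > 10 meq/kg, Ca/Mg < 1.5,
δ¹³C-DIC > +20 ‰) only when the fields are present. The chloride limit is a
hard flag even though salinities near it are observed in producing
methanogenic fields; the flag is surfaced rather than suppressed.

## Synthetic data generator

`generate_field` produces the study conditions for an injected field: a
pristine reference (f = 1) plus n−1 samples with f ~ U(0.11, 0.61) (the
observed 39–89 % removal span), overprinted through the hybrid model at a
single true F_d (default 0.79); injectate δ¹³C ~ N(0.85, 0.92) ‰; reference
CO₂/³He 2×10⁹ (mantle range); reservoir temperatures U(29.2, 50.7) °C;
mantle He fractions U(0.25, 0.35); ⁴He/²⁰Ne U(3210, 20900); CH₄ δ¹³C set by
exact ln-ratio exchange equilibrium at each sample's reservoir temperature;
clumped values at equilibrium plus disequilibrium offsets (0, −6) ‰
reproducing the methanogenesis/AOM pattern; dryness from a drawn biogenic
fraction. Noise: δ¹³C 0.5 ‰ (normal), CO₂/³He 5 % relative (lognormal, unit
median — ratios stay positive), clumped 0.3 ‰. `generate_control_field`
emulates the never-injected neighbour (CO₂ 1.02 ± 0.69 mol%, mantle He
2–8 %, CO₂/³He scattered with no δ¹³C trend, clumped equilibrium at
thermogenic 140–180 °C). The seed is required; identical seeds give
bit-identical datasets, and ground truth is emitted as a separate record.

What the generator does *not* emulate: spatial correlation between wells,
time evolution, mixed thermogenic/microbial CH₄ endmember proportions in the
clumped values, correlated measurement errors, or a reference sample that has
itself been altered. Passing recovery tests therefore demonstrate the
estimator's correctness and noise tolerance under the stated forward model,
not robustness to structural mismatch in real fields.

## Numerical and reporting choices

Degenerate inputs raise typed errors (air-dominated helium, zero-variance
extrapolation, f = 1 with δ_obs ≠ δ_i, empty reports). Ties in reference
selection break lexicographically on sample id. Reports serialise floats via
`%.17g` / JSON repr so re-reading reproduces every value bit-for-bit; reruns
under the same config are byte-identical, with timestamps confined to the
manifest (identified by a content hash the report references). All Monte
Carlo is seeded from the config. Tests and the acceptance script use 20-well
fields, 200 fit replicates, 500 coverage repetitions and 2 000-draw Monte
Carlo — sizes at which every statistical check is stable to well inside its
asserted band.

## Known limitations

* The dissolution share and methanogenic consumption are lower bounds
  anchored to an assumed-pristine reference sample.
* α_d, α_p, α_m are field-level constants; per-sample pH/temperature
  dependence of the factors is not modelled.
* The clumped equilibrium curves are synthetic anchored fits (above);
  absolute clumped temperatures inherit that calibration choice.
* No carbonate mineral-mass modelling behind α_p, no kinetic (non-
  equilibrium) methanogenesis fractionation, no hydrogen-isotope
  thermometry, and no Ne/Ar/Xe deconvolution beyond the ⁴He/²⁰Ne air
  correction.
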