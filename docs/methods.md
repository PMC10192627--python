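# Methods

## The measurement being modelled

A soil slurry is spiked with a ring-labelled hydrophobic contaminant
(¹⁴C-phenanthrene, 450 Bq per flask on top of 50 mg kg⁻¹ unlabelled
compound) and incubated in a sealed respirometer for 120 days.  Evolved
¹⁴CO₂ is captured in an alkali trap and counted periodically by liquid
scintillation; the cumulative trapped activity, expressed as percent of
the applied label, is the mineralization curve.  Because the trap is
cumulative, a curve is physically constrained to start at 0% at t = 0, to
be non-decreasing, and to stay below 100%.  In practice curves plateau
far below 100% — part of the label is assimilated into biomass or bound
to soil organic matter and never appears as CO₂.

## Kinetic models

All three families are classical parent-decline models used in their
cumulative-formation parameterization `M(t) = m_max · (1 − C(t)/C(0))`,
with `m_max` the plateau amplitude in percent of applied:

* **SFO** (simple first order): `M(t) = m_max (1 − e^{−k₁ t})`.
* **FOMC** (first-order multi-compartment, Gustafson–Holden): a gamma
  continuum of first-order rates, `M(t) = m_max (1 − (1 + t/β)^{−α})`,
  with shape `α` (dimensionless) and location `β` (days).  Small `α`
  gives strongly biphasic, heavy-tailed behaviour; `α = kβ, β → ∞`
  recovers SFO.
* **HS** (Hockey-Stick): sequential first order with rate `k₁` until a
  breakpoint `tb` (days), then rate `k₂`; continuous at `tb` and equal to
  SFO when `k₁ = k₂`.

Rates are in d⁻¹ and may be zero (a sterile control that evolves no CO₂);
`tb`, `α`, `β` must be positive; `m_max ∈ (0, 100]`.

## DT endpoints

`DT_x` is the time for `x` percent of the substrate to dissipate.  Two
amplitude conventions exist and the package implements both, defaulting
to **applied**: the amplitude is fixed at 100% of applied and only the
rate parameters enter, which is the convention under which endpoint
tables quote half-lives from rate constants (`DT50 = ln 2 / k₁` for SFO
even when the observed plateau is 15%).  The **plateau** basis targets
`x` percent of the fitted `m_max`; for these single-pool saturating
curves the amplitude cancels and the two conventions coincide
numerically, so the option is interface-level, kept for explicitness.

Closed forms (`L = ln(100/(100−x))`): SFO `L/k₁`; FOMC
`β((100/(100−x))^{1/α} − 1)`; HS `L/k₁` if that precedes `tb`, otherwise
`tb + (L − k₁ tb)/k₂`.  Unreachable targets (zero rate; HS second phase
with `k₂ = 0`) return `+inf` with a warning rather than an error, so
batch tables can render a `>10^7` sentinel.  An independent numeric
solver (Brent root-finding on the curve, bracket 0–10⁷ days, 10⁻¹⁰
absolute tolerance) cross-checks every closed form; the two agree to
1 × 10⁻⁸ relative wherever the target is inside the bracket.

## Goodness of fit: the chi-square error percentage

The error statistic is the smallest relative measurement error at which
a chi-square test (5% level, `m − p` degrees of freedom for `m` fitted
observations and `p` free parameters) would fail to reject the fit:

    err% = (100 / Ō) · sqrt( Σ(Oᵢ − Cᵢ)² / χ²₀.₉₅(m − p) )

with `Ō` the mean observation.  The quantile comes from the exact
inverse CDF (`scipy.stats.chi2.ppf`), not an approximation.  Values
below 15% conventionally denote an acceptable fit; the package flags
(`poor_fit`) but never discards fits at or above 15%.  The statistic is
invariant under common rescaling of observed and predicted values.

## Fitting protocol

Observations are replicate means per sampling time (pooled-replicate
fitting is available as an option; with balanced replicates both carry
the same information).  The t = 0 reading is a real trap measurement and
is included in `m`.  Parameters are estimated by bounded least squares
(lmfit over scipy's trust-region reflective solver, function/step
tolerances 10⁻¹⁰, at most 1000 evaluations).  Bounds: rates
10⁻⁸–10 d⁻¹, `α` 10⁻³–50, `β` 10⁻³–10⁵ d, `tb` inside the sampling
window, `m_max ∈ (0, 100]` free by default with an option to fix at 100.

Starting values are data-driven: plateau from the curve maximum, `k₁`
from a log-linear regression of the early rise, `α₀ = 1`, `β₀` = median
sampling time, `tb₀` = schedule midpoint, `k₂₀ = k₁₀/10`.  Ten seeded
multi-starts jitter the rate-like parameters by ±50% (plus, for HS, one
single-phase start `k₂ = k₁` so the nested SFO solution is always
reachable); the best SSR is kept, making refits bit-reproducible given
the seed.  A fit counts as converged only if the optimizer met its
tolerance and no rate/shape parameter sits on a bound; an all-zero curve
therefore comes back `converged = False` with the rate at its lower
bound.

**Model selection** keeps the converged fit with the smallest error
percentage; fits within 0.1 percentage points of the minimum are
tie-broken toward fewer free parameters.

## Synthetic study generator

The generator draws triplicate curves from a known truth model on a
15-point schedule (0, 1, 3, 7, 10, 14, 17, 21, 28, 35, 42, 60, 80, 100,
120 d — dense early where the fast phase lives; real sampling days are
rarely reported, so the schedule is a design choice).  Counting error is
additive Gaussian with σ = 1.5% of applied by default — scintillation
error is approximately absolute, not proportional — applied either to
the cumulative values (default) or to the inter-sample increments.  Trap
physics is then restored: the cumulative mode takes a running maximum
and clips to [0, 100]; the increment mode floors increments at zero and
re-accumulates.  The t = 0 value is exactly zero.

Both restorations truncate the noise one-sidedly and therefore bias
plateaus upward: about +1.1% of applied for the running maximum and
+3.3% for increment flooring at σ = 1.5 on a slowly-rising tail (the
flatter the curve, the larger the bias; a sterile preset therefore uses
σ = 0, which is also physically right — no CO₂, no trap signal).  This
bias is the main way the synthetic curves differ from ideal data, and it
slightly inflates fitted second-phase rates.  What passing tests show is
that the estimation machinery recovers known kinetics through this noise
model; they cannot show anything about sorption kinetics, microbial lag,
or other structure real soils add and the generator does not emulate.

A packaged preset regenerates a full 5-soil × 5-treatment study from
published rate constants of a phenanthrene bioremediation experiment
(amplitude 100).  Regenerated extents follow from those kinetics; the
experiment's observed extents are data, not generator targets.

## Identifiability and the recovery experiment

On a 120-day window a biphasic curve with a slow second phase constrains
only the product `m_max · k₂` — the tail is a straight line of slope
`m_max k₂ e^{−k₁ tb}` and its curvature is unmeasurable — so HS rate
constants are not separately identifiable when the amplitude floats.
The recovery experiment therefore fits with the amplitude pinned at 100,
the same convention under which DT50 is quoted.  With 200 simulated
triplicate studies per family at σ = 1.5 (seeded, deterministic), SFO
and FOMC parameters and endpoints are recovered with median absolute
relative errors well under 5%, and model selection identifies the
biphasic truth essentially always.  HS is the hard case: the tail slope
(~0.035% d⁻¹ for the default truth `k₁ = 0.03, k₂ = 5 × 10⁻⁴,
tb = 12`) is estimable to at best ~15% median relative error given
replicate-mean noise of 1.5/√3 ≈ 0.87% — a free-intercept regression
information bound, not an optimizer deficiency — and the measured HS
DT50 and `k₂` medians sit at 14–19% accordingly.  `k₁` (~2%) and `tb`
(~4%) are tightly recovered.

Problem sizes used throughout the analysis scripts and tests — 200
simulations per family, triplicates, the 15-point schedule — are the
study conditions themselves, chosen to mirror the respirometry design.

## Assay arithmetic

Three exact calculations accompany the kinetics: CFU g⁻¹ from serial
1:10 dilution plating, `(colonies/plated volume)·10^d·(suspension
volume/soil mass)` with the normalization factor exposed because
counting conventions differ; percent of applied compound recovered in an
aqueous extract, `conc · volume / applied mass`, with a mass-balance
guard at 100%; and the cyclodextrin mass dosing a soil at a chosen molar
ratio to the contaminant (HPBCD molar mass defaults to 1380 g mol⁻¹, a
typical substitution grade, and is configurable since the grade is
seldom reported).  All three are exactly linear in their leading input,
which the property tests assert.

## Known limitations

* Single-pool models only: no metabolite chains, no parallel-pool DFOP,
  no temperature or moisture normalization of rates.
* The selection rule is the chi-square error criterion alone (no
  AIC/BIC), matching how such tables are usually produced.
* Family identity is not always recoverable from 120-day curves:
  heavy-tailed FOMC (α < 0.1) and HS mimic each other closely, and
  near-flat control curves carry almost no shape information.  Endpoint
  and curve recovery are the meaningful checks there.
* No uncertainty intervals on fitted parameters; the chi-square error
  percentage is the only fit-quality summary.
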