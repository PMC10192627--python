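# minkin — mineralization kinetics for soil respirometry

`minkin` analyses cumulative ¹⁴CO₂ mineralization curves from soil
respirometry — the standard assay for judging bioremediation treatments
of a contaminated soil (biostimulation with nutrients, bioaugmentation
with a degrader strain, bioavailability enhancers such as
hydroxypropyl-β-cyclodextrin).  It is written for environmental
microbiologists and fate modellers who need defensible kinetic endpoints
from replicated 120-day slurry experiments.

Three kinetic families are fitted to each curve, in their
cumulative-formation form `M(t) = m_max (1 − C(t)/C(0))`:

* **SFO** — simple first order, `M(t) = m_max (1 − e^{−k₁ t})`
* **FOMC** — Gustafson–Holden multi-compartment,
  `M(t) = m_max (1 − (1 + t/β)^{−α})`
* **HS** — Hockey-Stick biphasic first order: rate `k₁` to breakpoint
  `tb`, rate `k₂` after

From the fitted constants the package derives `DT50`/`DT90` (closed form,
cross-checked by root finding), the chi-square error percentage

    err% = (100/Ō) · sqrt( Σ(Oᵢ−Cᵢ)² / χ²₀.₉₅(m−p) )

(values < 15% denote an acceptable fit), and selects the best model per
soil × treatment.  A synthetic respirometry generator — triplicate
curves, additive counting noise, cumulative-trap physics — makes the
whole pipeline testable end to end, and small assay helpers cover CFU
plate counts, extractability percentages and cyclodextrin dosing.
See `docs/methods.md` for the full model and protocol description.

## Worked example

Simulate a 5-soil × 5-treatment study from the packaged preset (truth
kinetics taken from a published phenanthrene bioremediation experiment)
and fit it:

```sh
minkin simulate --preset paper --seed 1 --out curves.csv
minkin fit curves.csv --model auto --seed 1 --out fit_table.csv
```

or equivalently `python analysis/01_simulate_study.py` then
`python analysis/02_fit_kinetics.py`, which print:

```
paper: 25 curves -> results/curves_paper.csv (final extents 2.7-88.1% of applied)
fitted 25 curves; 24 pass the chi2 < 15% rule
selected families: {'SFO': 2, 'FOMC': 10, 'HS': 13}
```

The first lines of the resulting table:

```
soil,treatment,kinetic_model,k1_per_d,k2_per_d,tb_d,alpha,beta_d,dt50_d,extent_pct,chi2_error_pct
ALC,A,SFO,4.6e-03,-,-,-,-,150,14.3,10.8
ALC,C,FOMC,-,-,-,3.2e-01,8.4e+00,63.1,54.5,2.4
ALC,E,FOMC,-,-,-,1.0e+00,4.3e+01,40.5,75.1,1.8
```

Each row is one soil × treatment: the selected family, its rate/shape
constants (dashes where a parameter does not apply), the half-life in
days on the applied basis, the observed extent of mineralization at
120 d, and the chi-square error.  The ALC/E row illustrates recovery:
the generating kinetics were FOMC with α = 1, β = 40.15 d (DT50 =
40.15 d), and the refit reports DT50 = 40.5 d with a 1.8% error level.

In Python the same pipeline is three calls:

```python
from minkin import load_preset, generate_study, fit_all

curves = generate_study(load_preset("paper", seed=1))
outcomes = fit_all(curves, seed=1)
best = outcomes[0].selected
print(best.params.model_id, best.dt50.value, best.chi2_error_pct)
```

`minkin recover --model hs --n-sims 200 --seed 7` runs the
parameter-recovery simulation study (see `analysis/03_parameter_recovery.py`)
and `analysis/04_soil_assays.py` tabulates the assay arithmetic.

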