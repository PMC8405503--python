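# thyropop

Population pharmacokinetic modeling of free thyroxine (FT4) in newborns and
infants with congenital hypothyroidism (CH) under levothyroxine (LT4)
replacement therapy.

CH is a rare disease in which the thyroid gland produces too little
thyroxine; affected newborns are treated with oral LT4, dosed per kg and
titrated over the first two years of life.  Retrospective multi-center
datasets of such patients mix dozens of laboratory assays, each with its own
FT4 reference range, and the FT4 distribution itself changes under therapy —
right-skewed at diagnosis (many near-zero values), approximately normal once
treatment has pulled values into the healthy range.  `thyropop` provides the
full analysis pipeline for this situation, aimed at pharmacometricians and
pediatric-endocrinology researchers:

* **time-dependent reference-range normalization** that blends the scale
  formula (right-skewed data) into the location-scale (Chuang–Stein)
  formula (normal data) over treatment time,
* a **structural PK model** — one compartment, first-order oral absorption
  and elimination, a zero-order endogenous production rate for the residual
  gland function, and an allometric weight–volume relationship — with an
  exact analytic solver and an independent numeric cross-check,
* **nonlinear mixed-effects estimation** (SAEM) with log-normal
  inter-individual variability, proportional residual error,
  covariate/TSH-feedback machinery and likelihood-ratio testing,
* **diagnostics** (visual predictive check, goodness-of-fit tables) and a
  fully seeded **synthetic multi-center cohort generator** standing in for
  the clinical records, which are not publicly deposited.

## Model

Amounts in nmol, times in days:

```
dA_B/dt = In(t_j, dose_j, F) - ka * A_B          A_B(0) = 0
dA_C/dt = ka * A_B + kendo - kel * A_C           A_C(0) = kendo / kel

C_FT4 = 0.3 * A_C / V(W)        V(W) = fV * (W / WRef)^betaW
```

`In` is a once-daily bolus of `F * 1.29 * dose` (mcg/day converted to
nmol/day); `ka = 20 /day`, `kel = 0.1 /day` (7-day half-life) and `F = 0.6`
are fixed; `kendo` (nmol/day), `fV` (l) and `betaW` carry log-normal
inter-individual variability, and observations have proportional error
`y = C * (1 + sigma * eps)`.  The untreated patient sits at the equilibrium
`kendo/kel`, to which the system returns whenever dosing stops — the
disease cannot be cured, only substituted.

Normalization maps a measurement `x` with assay range `(r_low, r_up)` onto
the postnatal-age-dependent target range `(r_low_std, r_up_std)`:

```
scale:           x * r_up_std / r_up
location-scale:  (x - r_low) * (r_up_std - r_low_std) / (r_up - r_low) + r_low_std
blended:         (t/ts) * LS + (1 - t/ts) * S     for t <= ts,  LS beyond
```

with `ts = 150` days by default.

## Worked example

```python
import thyropop as tp

ds, truth = tp.generate_cohort(tp.CohortConfig(), seed=42)
normed, norm = tp.normalize_dataset(ds)
tab = tp.summarize_comparison(normed)
fit = tp.fit_population(normed, wref=truth.population.wref, seed=42)
```

printing (exact output of this snippet):

```
cohort: 61 subjects, 482 rows
normalized 461 FT4 values (16 skipped, 0 negative)
    window  median_raw  median_norm  p_value
       t=0        4.05         3.54     0.75
    0<t<50       19.78        20.81     0.79
100<=t<150       19.69        19.55     0.78
      last       16.20        15.12     0.24
kendo=3.55 fv=5.08 betaw=0.720 omega_kendo=1.11 sigma=0.221
-2LL=2671.4  converged=True
shrinkage: {'kendo': 3.3, 'fv': 15.3, 'betaw': 24.3}
```

The 61-subject cohort was generated *at* the published final-model values
(`kendo` 3.66 nmol/day, `fV` 4.96 l, `betaW` 0.753, `omega_kendo` 1.12,
proportional error 0.228), so the fit demonstrates parameter recovery: the
estimates land within a few percent of the generating truth.  Normalized
medians sit slightly below the raw medians (the generated assay upper
limits exceed the target on average, as in real multi-center pools) and no
window shows a significant raw-vs-normalized difference.  The 16 skipped
values mimic measurements whose reference range was never recorded.

The same pipeline is available from the shell:

```bash
thyropop generate --seed 42 --out cohort.csv --truth truth.json
thyropop normalize --in cohort.csv --out normalized.csv --ts 150
thyropop fit --in normalized.csv --out fit.json --seed 42
thyropop vpc --in normalized.csv --fit fit.json --out vpc.csv
thyropop report --outdir report/ --seed 42      # everything in one go
```

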