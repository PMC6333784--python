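# amylokin

Chemical-kinetics analysis of amyloid self-assembly and of the small
molecules that modulate it.

Amyloid fibrils of the 42-residue amyloid-beta peptide (Abeta42) form
through three coupled microscopic steps: primary nucleation of new
aggregates from monomers (rate constant *k*<sub>n</sub>, order
*n*<sub>c</sub>), elongation of fibril ends (*k*<sub>+</sub>), and
monomer-dependent secondary nucleation on fibril surfaces (*k*<sub>2</sub>,
order *n*<sub>2</sub>) — the dominant proliferation route for Abeta42.
Working with the first two moments of the length distribution, the fibril
number *P* and mass *M* concentrations,

> d*P*/d*t* = *k*<sub>n</sub>*m*<sup>*n*<sub>c</sub></sup> + *k*<sub>2</sub>*m*<sup>*n*<sub>2</sub></sup>*M*,&emsp;
> d*M*/d*t* = 2*k*<sub>+</sub>*m P*,&emsp;
> d*m*/d*t* = −2*k*<sub>+</sub>*m P*,

the normalized aggregate mass follows a closed-form master-equation
solution whose parameters depend on the rate constants through the
combinations *k*<sub>+</sub>*k*<sub>2</sub> and
*k*<sub>+</sub>*k*<sub>n</sub>.  Fitting that solution globally to
ThT-fluorescence trace families — unseeded and seeded, with and without a
modulator — attributes a modulator's effect to a specific microscopic step;
the accompanying length-scaling law (mean fibril length ∝
√(*k*<sub>+</sub>/*k*<sub>2</sub>)) and AFM/TEM morphometry statistics test
that attribution against independent structural data.

The package is aimed at biophysicists analysing plate-reader aggregation
assays and fibril-dimension tables.  It provides:

- `amylokin.kinetics` — closed-form and numerical (moment-ODE) forward
  models, half-time extraction, the length-scaling law.  The closed form is
  certified against the ODE oracle to <1% of the amplitude up to 25% seeds.
- `amylokin.fitting` — ThT trace normalization, basin-hopping global fits
  with per-condition perturbation factors, AIC hypothesis ranking,
  half-time dose–response tables.
- `amylokin.morphometry` — fibril dimension summaries with the
  *total error* = SEM + instrument-sensitivity convention, sensitivity-
  shifted Welch tests, length-ratio/scaling consistency checks.
- `amylokin.synthetic` — a deterministic generator of the full emulated
  campaign (traces + morphometry) with planted ground truth.
- `amylokin.io` / `amylokin.cli` — CSV dialects, YAML config, JSON
  reports, and the `amylokin` console command
  (`simulate` / `fit` / `halftime` / `compare` / `morph`).

## Worked example

Generate an unseeded dose series (2 uM peptide, modulator ratios 10:1, 5:1,
1:1, planted *k*<sub>2</sub> fold-changes 1.5/2.5/5, noise σ = 0.02,
three replicates) and ask which microscopic step explains it:

```python
from amylokin import (FitConfig, PerturbationHypothesis, fit_global,
                      generate_tht_traces, halftime_dose_response,
                      predicted_length_scale)
from amylokin.synthetic import dose_series_spec

data, truth = generate_tht_traces(dose_series_spec(0.0, "unseeded", 3.0, 20, 0.02, 3, 150))
res = fit_global(data, PerturbationHypothesis("secondary_product"),
                 FitConfig(n_basinhop=8, seed=0))
print({k: round(float(v), 3) for k, v in sorted(res.fitted_factors.items())})
print(halftime_dose_response(data).to_string(index=False))
print(predicted_length_scale(res.fitted_factors["unseeded/tro_1"]))
```

prints

```
{'unseeded/control': 1.0, 'unseeded/tro_0.1': 1.491, 'unseeded/tro_0.2': 2.476, 'unseeded/tro_1': 5.039}
       condition  modulator_ratio  n  t50_mean  t50_sem  n_excluded
unseeded/control              0.0  3  0.993901 0.015359           0
unseeded/tro_0.1              0.1  3  0.912929 0.013897           0
unseeded/tro_0.2              0.2  3  0.799628 0.011212           0
  unseeded/tro_1              1.0  3  0.646127 0.006236           0
0.4455001769495714
```

The fit recovers the planted fold-changes (5.04 vs the planted 5 at the
equimolar dose) on rate constants it never saw; the half-time falls
monotonically with dose; and the recovered five-fold secondary-nucleation
enhancement predicts fibrils shortened to ≈ 0.45 of the control mean
length — the number the morphometry module then compares against measured
length distributions (`scaling_consistency`).

The same pipeline from the shell:

```sh
amylokin simulate --out-dir fixture
amylokin fit fixture/traces_unseeded.csv --hypothesis secondary_product --out fit.json
amylokin compare fixture/traces_unseeded.csv   # secondary vs primary, AIC-ranked
amylokin morph fixture/morphometry.csv
```

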