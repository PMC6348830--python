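# biokin

Biokinetics-to-dosimetry analysis for ¹⁷⁷Lu radiopharmaceuticals: fit
multi-exponential time–activity curves for organs and blood of mice,
pigs and humans, integrate them analytically into time-integrated
activity coefficients (TIACs, a.k.a. residence times) with Gaussian
error propagation, and extrapolate animal TIACs to human by five
interspecies scaling methods.

It is written for preclinical/clinical dosimetrists who have sampled
uptake data (%IA per organ, %IA/mL for blood) and need defensible human
TIAC predictions from animal cohorts — the setting of first-in-human
dosimetry for compounds such as the SST2 antagonist ¹⁷⁷Lu-OPS201.

## Model

Uptake is modelled as f(t) = Σᵢ Aᵢ e^(−λᵢ t) (one or two terms, washout
or uptake shape), where every effective rate λᵢ = λ_bio,i + λ_phys is
bounded below by the ¹⁷⁷Lu decay constant λ_phys = ln 2 / 159.5 h.
Weighted least squares (σ = 10% of the value by default) with AICc model
selection gives the fit; the TIAC follows in closed form,

    TIAC = Σᵢ (Aᵢ / 100) / λᵢ      [h, or h/mL for blood],

with a delta-method standard error from the fit covariance. Animal
TIACs are mapped to human by: (1) identity, (2) relative organ-mass
scaling, (3) biological time stretched by (m_WB,h/m_WB,a)^¼ applied to
the fitted rates, (4) time scaling then mass scaling, and (5) allometric
scaling by (m_WB,h/m_WB,a)^(b−1) with b(liver)=0.92, b(kidneys)=0.85.
See `docs/methods.md` for assumptions and edge cases.

## Worked example

The numbered scripts under `analysis/` run the whole chain on synthetic
cohorts with known ground truth (`python analysis/01_simulate.py`, then
02 … 06); the same stages are available as a CLI (`biokin simulate|fit|
tiac|scale|compare|run`) and as plain library calls:

```python
from biokin import (NoiseModel, fit_candidates, generate_curve,
                    integrate_tiac, select_model)
from biokin.synthkin import scenario_by_name

curve = generate_curve(scenario_by_name("pig_kidneys"), NoiseModel(cv=0.10, seed=11))
best = select_model(fit_candidates(curve, seed=11))
est = integrate_tiac(best)
print(best.form, round(est.value, 2), "+/-", round(est.se, 2), "h")
```

which prints `bi 7.56 +/- 0.35 h`: AICc picked the biexponential and the
estimate brackets the generating truth (TIAC 7.61 h) well within one
standard error.

Running `analysis/06_published_tables.py`, which applies the closed-form
methods to the published cohort TIACs and body masses, prints:

```
same-biodistribution comparison factors vs the human cohort:
  mouse  kidneys  under-estimated by a factor of 4
  mouse  liver    under-estimated by a factor of 7
  pig    kidneys  over-estimated by a factor of 1.3
  pig    liver    under-estimated by a factor of 1.3
```

i.e. taking mouse TIACs at face value underestimates human kidney and
liver TIACs four- and seven-fold, while pig values are within ~30%
either way — pigs mimic human biokinetics far better than mice. The same
script reports the allometric (Method 5) extrapolation of the mouse
liver TIAC, 0.75 h × (61/0.026)^(0.92−1) = 0.40 h.

## Layout

- `src/biokin/` — library: `curves` (types + I/O), `synthkin`
  (ground-truth simulation), `expofit` (fitting + AICc), `tiac`
  (integration + error propagation), `xscale` (the five methods),
  `pipeline` (one-shot runs), `reference` (published cohort values),
  `cli`.
- `analysis/` — numbered narrative drivers writing to `results/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — model, assumptions, numerical choices, limitations.
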