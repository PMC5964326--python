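# xylreg

Model-guided analysis of **GAL-type regulon feedback designs** in budding
yeast, built around the question: when a sugar sensor (Gal3p or an
engineered xylose-responsive variant) de-represses the master activator
Gal4p by sequestering the repressor Gal80p, what does wiring the sensor
behind one promoter (single positive feedback) versus two promoters
(dual positive feedback) buy you?

The package provides:

* a deterministic ODE model of the Gal4p/Gal80p/sensor network with
  `single_feedback`, `dual_feedback` and `constitutive_sensor`
  architectures and a non-degrading GFP reporter;
* dose–response simulation and the **sensitivity factor** (the inducer
  concentration at which fluorescence reaches half its maximum — an EC50
  analogue), fold-change, and a pre-incubation **hysteresis** protocol;
* a five-decade sweep of the lumped sensor–Gal80p binding constant
  (kf83) comparing the sensitivity of the two feedback designs, with
  classification into weak / intermediate / strong binding regimes;
* **Hill-curve fitting** (`F0 + Fmax·sⁿ/(Kⁿ+sⁿ)`) of fluorescence
  dose–response data to estimate promoter cooperativity;
* event-level **cytometry statistics**: ON/OFF mixture decomposition in
  log10 space, ON-fraction dose profiles, and the coefficient of
  variation (CV) as a noise measure;
* a **synthetic-data generator** for plate-reader and cytometry
  experiments with known ground truth, so every analysis step is testable
  end to end.

## The model

Six species (nM; GFP in relative fluorescence units), time in minutes:
free sensor `G3`, free repressor `G80`, free activator `G4`, the
sensor–repressor complex `C83`, the repressor–activator complex `C84`,
and the reporter `GFP`. Promoters follow Hill kinetics
`α + β·G4ⁿ/(Kⁿ+G4ⁿ)`; inducer at concentration `s` (% w/v) gates the
lumped sensor–repressor association as `kf83·s/(Ks+s)`; every species
except GFP dilutes at rate `γ`. The dual architecture adds a second,
strong/low-basal sensor production term driven by the GAL1 promoter.
Because GFP does not decay, "fluorescence" is always GFP accumulated at a
readout time (default 18 h).

## Worked example

```python
import numpy as np
from xylreg import default_params, dose_response, sensitivity_factor, fold_change
from xylreg.synth import standard_series

params = default_params()
grid = np.sort(standard_series("fig4c_xyl"))   # 0 ... 4 % xylose

for arch in ("single_feedback", "dual_feedback"):
    curve = dose_response(params, arch, grid)  # GFP at 18 h per dose
    sf = sensitivity_factor(curve)
    print(f"{arch:16s}  SF = {sf.value:.3f} %  fold(4%) = {fold_change(curve, 4.0):.1f}")
```

prints

```
single_feedback   SF = 0.257 %  fold(4%) = 13.8
dual_feedback     SF = 0.143 %  fold(4%) = 14.1
```

i.e. both designs induce ~14-fold at saturating xylose, but the dual
feedback design reaches half-maximal fluorescence at roughly half the
inducer concentration — it is the more sensitive switch.

The same analyses are scriptable from the shell:

```bash
xylreg sweep --outdir out          # sensitivity factor vs kf83, both designs
xylreg hysteresis --outdir out     # 24 h pre-incubation protocol
xylreg all --outdir out            # full pipeline incl. synthetic data
```

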