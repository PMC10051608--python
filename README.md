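# gisivivc

Multi-compartment gastrointestinal dissolution simulation and Level A
in vitro–in vivo correlation (IVIVC) for poorly soluble acidic drugs.

## The problem

Immediate-release formulations of BCS Class IIa drugs (low solubility, high
permeability, acidic — ibuprofen is the worked example throughout) dissolve
poorly in the stomach but freely at intestinal pH. Single-vessel quality
control dissolution tests run at a high, fixed pH and therefore cannot
distinguish a conventional tablet from rapid-dissolving salt or
pre-dissolved formulations, even though the latter are absorbed markedly
faster in vivo. A three-compartment Gastrointestinal Simulator (GIS) —
stomach, duodenum and jejunum connected by transfer pumps — captures the
mechanism behind the difference: rapid-release products supersaturate in
the acidic stomach (C/S_eq ≈ 1.8–2.5), partially precipitate, and the
continuously emptied suspension redissolves at duodenal pH, producing a
higher dissolution rate where absorption actually happens.

This package provides, for formulation scientists and biopharmaceutic
modellers:

* a **Henderson–Hasselbalch solubility model** for a monoprotic weak acid,
  `S(pH) = S0·(1 + 10^(pH−pKa))`, with log-space least-squares fitting of
  (S0, pKa) and packaged equilibrium-solubility tables for ibuprofen in
  buffers and biorelevant media;
* a **mass-balance ODE twin of the GIS apparatus** (volumes, secretion and
  transfer flows, z-factor dissolution, supersaturation caps and
  first-order precipitation);
* **dissolution metrics**: the f2 similarity factor
  `f2 = 50·log10(100/√(1 + mean((R_t−T_t)²)))` and Weibull release
  modelling `F(t) = F_inf·(1 − exp(−(t/td)^B))` parameterized by shape B
  and the true mean dissolution time MDT (`td = MDT/Γ(1+1/B)`);
* the **Level A IVIVC chain**: a biexponential unit impulse response
  `c_δ(t) = A1·e^(−α1 t) + A2·e^(−α2 t)`, exact convolution against
  piecewise-linear absorption profiles, non-negative least-squares
  deconvolution to the fraction absorbed Fa(t), Levy-plot time scaling
  `t_vivo = a·t_vitro + b`, and convolution-based prediction of plasma
  Cmax/tmax/AUC;
* a **synthetic-data generator** with known ground truth standing in for
  the physical apparatus and for digitized clinical curves, used by the
  recovery studies in the test suite.

Fit-shaped components follow the scikit-learn estimator API
(`HendersonHasselbalchEstimator`, `WeibullReleaseModel`,
`TwoCompartmentOralModel`, `AbsorptionDeconvolver`, `LevyTimeScaling`) and
compose with sklearn tooling; thin module-level functions (`fit_hh`,
`fit_weibull`, `fit_disposition`, `deconvolve`, `levy_fit`) wrap them.

## Worked example

Run the full synthetic study (solubility fit → GIS simulation → f2 and
Weibull metrics → deconvolution → Levy regression → plasma prediction):

```sh
gisivivc pipeline --seed 1 --out demo/
```

prints

```
IBU: Cmax 31.36 ug/mL, ratio 1.00, tmax 153 min
IBU-Lys: Cmax 37.53 ug/mL, ratio 1.20, tmax 104 min
IBU-Na: Cmax 35.38 ug/mL, ratio 1.13, tmax 113 min
IBU-lq: Cmax 36.97 ug/mL, ratio 1.18, tmax 116 min
```

Every rapid-dissolving formulation (sodium salt IBU-Na, lysine salt
IBU-Lys, pre-dissolved soft-gel IBU-lq) is predicted to reach a higher peak
plasma concentration (Cmax ratio > 1 versus the conventional tablet IBU)
at an earlier tmax — the direction observed clinically. `demo/report.md`
additionally shows the fitted pKa (4.585 from the packaged buffer table),
the biorelevant-media solubility fold changes (3.4 / 7.4 / 44.6 between
gastric pH 1.6 and pH 4.5 / 5.0 / 6.5), per-formulation f2 values against
the reference tablet and Weibull (B, MDT) fits of the simulated
duodenum+jejunum curves, flagged when the asymptote is an extrapolation
beyond the 45-min run.

Library use mirrors the CLI:

```python
import numpy as np
from gisivivc import gis, ivivc, synthetic

smap = synthetic.solubility_map()
res = gis.simulate(gis.GISConfig(), gis.default_scenarios()["IBU-Na"], smap)
print(res.concentration[0].max())          # gastric peak, mg/L (~130)

fa, _ = ivivc.deconvolve(plasma, synthetic.fixture("uir"))  # Fa(t) from plasma
```

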