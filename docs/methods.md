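# Methods

This note documents the models implemented in `gisivivc`, their
assumptions, the tunable parameters that matter, and the numerical and
design choices made where the underlying physical method left the
mathematics open.

## pH-dependent solubility

A monoprotic weak acid obeys the Henderson–Hasselbalch relationship

    S(pH) = S0 · (1 + 10^(pH − pKa)),

with S0 the intrinsic (unionized) solubility in µg/mL. Fitting is done by
unweighted least squares on log10 S: the data span four orders of
magnitude, so a linear-scale fit would be dominated entirely by the most
soluble point. Measurements above pH 7.5 are excluded from fitting by
default — at high pH the solid phase in equilibrium is the sodium salt and
the measured solubility sits on a plateau outside the model. The packaged
ibuprofen measurements give pKa ≈ 4.59 and S0 ≈ 82 µg/mL; the literature
intrinsic solubility (log S0 = −3.62, i.e. ~49 µg/mL) was measured at
25 °C versus 37 °C here, and both values are carried without a temperature
correction (temperature is metadata only; no van 't Hoff model).

The model intentionally over-predicts the measured blank-FaSSIF value at
pH 6.5 (≈8000 vs 2513 µg/mL): buffer capacity and ionic-strength effects
in real media are not modelled, and no agreement is forced. Solubilization
by bile components is represented only through the measured biorelevant
values, not by a micelle-partitioning model.

## GIS simulator

The apparatus is three stirred vessels. Pump rates are constant, so the
volumes are linear in time:

    V_s(t) = 300 + (1 − 5.5) t      (stomach, mL)
    V_d(t) = 50  + (5.5 + 1 − 6.5) t = 50   (duodenum)
    V_j(t) = 6.5 t                  (jejunum, terminal vessel, no outflow)

The 45-min duration is the longest the initial gastric volume supports; a
configuration whose volumes would go negative is rejected with the
depletion time. The hardware description defines no rate law, so the
governing equations are this package's model, chosen as the simplest
mass-balance system reproducing the observed phenomenology:

* dissolution of solid X at concentration C (mg/L):
  `z · X · max(S_eff − C, 0)`, with z the dissolution rate coefficient in
  1/(min·(mg/L)) (a z-factor; linear in X — the 2/3-power surface
  correction is deliberately omitted as unidentifiable from vessel data);
* precipitation: first order in the supersaturation excess,
  `k_prec · max(C − S_eq, 0) · V`;
* liquid transfer carries dissolved drug at the vessel concentration;
  suspended solid is pumped with the same fractional rate Q/V as the
  liquid (suspension assumption);
* per-compartment pH is fixed (1.6 / 6.5 / 6.5; media are buffered) and
  S_eq is looked up from a pH → solubility map, by default the blank
  biorelevant values (56.3 mg/L gastric, 2513 mg/L intestinal).

Formulation types differ only in how the dose enters the stomach.
Free acid: solid with S_eff = S_eq (never supersaturates). Salt: solid
with kinetic solubility S_eff = r·S_eq, where r is the maximum
supersaturation ratio; the precipitate it sheds is ordinary free acid.
Pre-dissolved: the dose enters in solution, capped at r·S_eq (the excess
nucleates immediately), after a lag time for shell disintegration.
Internally each compartment tracks dissolved drug, free-acid solid and
undissolved salt separately; reported "solid" is their sum. Precipitate
does not redissolve in the stomach (C ≥ S_eq there whenever precipitate
exists) but dissolves normally after transfer to the intestinal
compartments.

Scenario defaults are a calibration of this simulator, chosen once to
reproduce the qualitative gastric record of the four studied products:
z = 2×10⁻⁴ for the conventional tablet (slow approach to S_eq, peak below
saturation), z = 6×10⁻³, r = 2.5/2.3 and k_prec = 0.4 min⁻¹ for the
sodium/lysine salts (peak ≈ 2.2–2.3×S_eq relaxing to ≈56 mg/L by 45 min),
and r = 1.8 with a 5-min lag for the soft-gel. With these defaults the
simulated supersaturation peaks occur within the first minutes of release;
the calibration favours peak magnitude and end-of-run relaxation over peak
timing.

Numerics: volumes are evaluated analytically inside the right-hand side;
the 9-state drug ODE is integrated with LSODA at rtol = atol = 1e−10 and
max step 1 min, reported on the 5-min sampling grid. Every term in the
right-hand side appears with opposite signs in exactly two states (or is
internal to a compartment), so total drug is conserved identically; the
solver keeps the error near machine precision (≪ the 1e−6·dose guard the
tests assert). The 0.5-mL manual sampling losses of the physical apparatus
(≤ ~3% of gastric volume over a run) are ignored. Dose-proportionality is
exact only in the limit C ≪ S_eq because the dissolution term is bilinear
in the state; the tests check a 2% band at small doses.

Cumulative dissolution in a compartment subset sums the currently
dissolved amounts; because the jejunum is terminal, the duodenum+jejunum
sum automatically includes everything already transferred onward — this is
the quantity correlated with in vivo absorption.

## Dissolution metrics

f2 is computed as `50·log10(100/√(1 + mean((R−T)²)))` on an identical time
grid with ≥ 3 points. By regulatory convention only points up to and
including the first reference point above 85% dissolved are used (the rule
is configurable); coefficient-of-variation limits do not apply since only
mean profiles exist here. f2 = 100 exactly iff the profiles coincide on
the grid.

The Weibull model is `F(t) = F_inf·(1 − exp(−(t/td)^B))`. Published
dissolution fits often report "MDT" without stating the parameterization;
here td = MDT/Γ(1 + 1/B), which makes the MDT parameter the true mean
dissolution time — the first moment of the release-rate density — and the
test suite pins this by quadrature (∫(1 − F/F_inf)dt = MDT to < 0.1%).
The alternative reading (MDT = td, the 63.2% time) is available via
`mdt_is_t63=True`. Fitting is nonlinear least squares in log-parameter
space; the asymptote can be fixed (the pipeline fixes F_inf = 100% of
dose) or estimated under a hard cap of 110%. A fit is flagged
`extrapolated` when the fitted curve is below 99% of F_inf at the last
observed point — always the case for 45-min runs with MDT ≈ 44–72 min, so
the asymptotic phase of such fits carries extra uncertainty. Profiles that
sit at their asymptote from the first time point leave B unidentifiable
and are rejected.

## IVIVC chain

The unit impulse response is biexponential,
`c_δ(t) = A1·e^(−α1 t) + A2·e^(−α2 t)`, the disposition response to an
instantaneous input of the reference dose (400 mg = 2 × 200 mg here; times
in minutes, rates in 1/min throughout). It is obtained from oral data by
fitting the two-compartment first-order-absorption model in macro-constant
form, `C(t) = A1 e^(−α1 t) + A2 e^(−α2 t) − (A1+A2) e^(−ka t)`. The
absorption constant ka is reported but never enters the UIR. The fit uses
variable projection (amplitudes solved linearly for each candidate rate
triple) over a data-driven multistart grid, followed by a bounded joint
polish in log space; a flip-flop warning is raised when ka < max(α). The
packaged reference constants (A1 = 50.32, A2 = 0.007514, α1 = 0.004773,
α2 = 0.004006) are used verbatim, including the internally odd magnitude
of A2.

Convolution `C(t) = (dose/ref)·∫ c_δ(t−τ) dFa(τ)` is evaluated exactly for
piecewise-linear Fa: against a linear segment each exponential integrates
in closed form, giving the one-step recursion
`y(t+h) = e^(−αh) y(t) + A·m·(1−e^(−αh))/α`, which on a uniform grid is a
first-order IIR filter (O(n), no quadrature error; verified against the
analytic triexponential for first-order absorption to < 1e−8). A nonzero
Fa at t = 0 is treated as a bolus.

Deconvolution inverts that operator: the increments of Fa on the plasma
grid (refined to ≤ 5 min where sampling is coarser) are found by
non-negative least squares against basis responses (one bolus column, one
linear-ramp column per interval), making Fa non-negative and
non-decreasing by construction. When observation and unknown grids
coincide the roundtrip deconvolve∘convolve is exact to machine precision;
on refined (underdetermined) grids Fa is pinned only through the
residuals, which the report exposes. An ill-conditioning warning is raised
above condition number 1e10; no explicit regularization is applied because
the monotonicity constraint is itself a strong regularizer.

The Levy plot regresses t_vivo on t_vitro at matched fraction levels
(default 0.1…0.9): in vivo times by linear interpolation of the
deconvolved Fa, in vitro times by closed-form Weibull inversion. The
regression direction is a convention; prediction applies the inverse map
t_vitro = (t − intercept)/slope, clipped at zero. Predicted absorption is
the fraction dissolved at the mapped time, clipped to [0, 1] and made
non-decreasing, then convolved with the UIR on a 1-min grid over 0–720 min
from which Cmax (maximum), tmax (first attained) and AUC(0–last,
trapezoidal) are read. %PE = 100·(observed − predicted)/observed.

## Synthetic data and what the tests show

The study that motivates this package deposited no raw data, so all
pipeline inputs are generated with known ground truth: GIS curves from the
simulator above, and plasma curves by convolving the packaged UIR with the
absorption implied by the packaged Weibull parameter sets through a chosen
truth Levy scaling (slope 1.1, intercept 5 min — the published analysis
plots but does not print its regression, and any positive slope serves the
recovery studies). Noise is multiplicative lognormal with mean 1,
parameterized by CV (default 5%), since concentrations are strictly
positive; the default plasma grid is 0–720 min every 15 min. Fixed seeds
make all outputs byte-identical.

The recovery study (50 replicates at 5% noise: deconvolve the noisy
reference plasma, refit the Levy scaling, predict all four formulations)
recovers Cmax ratios within 10% of the noise-free truth and always
reproduces the qualitative clinical pattern — Cmax ratio > 1 and earlier
tmax for every rapid formulation. That validates the chain's internal
consistency, not its fidelity to any particular clinical dataset: the
synthetic generator shares the pipeline's model family (no model
misspecification), uses mean profiles only (no inter-subject variability),
and its noise model is an assumption. The published point predictions for
the external formulations depend on digitized in vivo curves and an
unprinted regression and are therefore treated as context, not as
recomputation targets.

## Known limitations

* No hydrodynamics, particle-size distributions, or distinct precipitate
  redissolution kinetics in the simulator; no absorption sink (the
  physical apparatus has none).
* The solubility model covers the Henderson–Hasselbalch branch of a
  monoprotic acid only; no common-ion effects or salt-plateau modelling.
* The disposition fit's second exponential is nearly collinear with the
  first for the packaged constants (α1 ≈ α2, A2 ≈ 1.5×10⁻⁴·A1); under
  noise its parameters are weakly identified, and only median accuracy of
  the dominant constant is guaranteed by the tests.
* Fed-state conditions and per-subject statistics are out of scope.
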