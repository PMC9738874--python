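# Methods

This note records the models, numerical choices and design decisions behind
`renalpet`, and what the synthetic validation does and does not demonstrate.

## Kinetic model

FDG kinetics are modelled with the standard irreversible two-tissue
compartment model: plasma → free tissue tracer (K₁, mL·cm⁻³·min⁻¹), free →
plasma efflux (k₂, min⁻¹), free → trapped phosphorylation (k₃, min⁻¹),
k₄ = 0.  Dephosphorylation is negligible over a 40-min scan, and
irreversibility is what makes the Patlak transform linear, so the model
order is fixed rather than estimated.  The measured concentration includes a
fractional blood volume V_b ∈ [0, 1):

    C_T(t) = (1 − V_b)·(C_f + C_t) + V_b·C_p(t).

Blood and plasma concentrations are treated as identical (no
whole-blood/plasma or metabolite correction); for FDG in rat over 40 min
this mainly rescales K₁ and is documented rather than corrected.  The net
influx macro-parameter is K_i = K₁k₃/(k₂+k₃), defined as 0 when k₂+k₃ = 0.

### Forward evaluation

Time is stored in seconds everywhere; rate constants are per minute at every
interface and converted internally.  The plasma curve is represented as
piecewise-linear on a time grid.  On each grid interval the two convolution
states z = ∫C_p and y = ∫e^{−β(t−s)}C_p ds (β = k₂+k₃ in s⁻¹) have closed
forms, as do their interval integrals, using the stabilised kernels
φ₁ = (1−e⁻ˣ)/x, φ₂ = (e⁻ˣ−1+x)/x², φ₃ = (x²/2−x+1−e⁻ˣ)/x³ (series below
x = 0.03 to avoid cancellation).  Tissue curves and — importantly — exact
frame-interval averages follow without quadrature error for the
piecewise-linear input.  Because the protocol mixes 1 s and 30 s frames,
predictions are always frame averages, never midpoint samples; midpoint
sampling biases long late frames where the curves are convex.  The
degenerate case k₂ = k₃ = 0 reduces to pure delivery C_f = K₁∫C_p and is
handled explicitly, not as an error.

Validation: the forward model agrees with a stiff ODE solution (LSODA,
rtol 10⁻¹⁰) to better than 0.1% of the curve peak, and frame averages agree
with adaptive-quadrature integrals of the explicit kernel expressions to
10⁻⁹ relative.

### Fitting

`fit_2tcm` minimises weighted least squares with
w_k = Δt_k / max(C_k, floor), floor = 1% of the curve peak — the
leading-order behaviour of reconstructed count statistics (long frames are
more precise; hot frames are noisier in absolute terms) with a floor that
keeps empty early frames from dominating.  The optimiser is SciPy's bounded
trust-region-reflective least squares with default bounds
K₁ ∈ [10⁻⁶, 5], k₂ ∈ [0, 10], k₃ ∈ [0, 5], V_b ∈ [0, 0.9] and two
deterministic restarts (parameters ×0.5 / ×2) if the first start fails —
the k₂/k₃ trade-off gives shallow minima.  The fit interval is the full
0–40 min by default; the early nonlinear phase dominates the weight budget
through the 300 one-second frames, so no truncation is applied (a `t_max`
option exists).  Non-convergence returns diagnostics, not an exception.
Input curves sampled on frames are interpolated piecewise-linearly through
frame mid-times with constant end extrapolation.

## Patlak coordinates and the early markers

The transform plots y = C_T/C_p against x = ∫₀ᵗC_p/C_p at frame mid-times;
the cumulative integral is trapezoidal with a constant lead-in before the
first mid-time (exact for a constant input, negligible for a bolus).
Points are emitted only where C_p exceeds 1% of its peak so near-zero
denominators never enter a regression.  On noiseless irreversible curves the
20–40 min slope reproduces K_i to better than 1%; with a blood-volume term
the asymptotic slope is attenuated to (1−V_b)·K_i, which is why the
equivalence checks draw random (K₁,k₂,k₃) with V_b = 0.

The renal markers deliberately regress *early* segments of these
coordinates, where the equilibrium assumption behind Patlak linearity does
not hold.  They are empirical slopes, not net-influx constants:

- cortex/medulla: [t₀, t₀+9 s], t₀ = first frame of the aorta curve above
  2% of its peak (a pure ">0" rule is unusable on noisy 1 s frames).  In
  the model this slope is ≈ (1−V_b)·K₁ — an early-delivery (vascular)
  analog.
- pelvis: [t₀+60 s, t₀+120 s], the ramp-up of urinary excretion.  The
  window is anchored to the aorta t₀ (a config switch allows per-region
  anchoring; the anchor curve is genuinely ambiguous).
- liver: [t₀, t₀+55 s] — the liver rises linearly for about a minute; the
  window ends 5 s before the nominal peak to stay inside the linear rise.
  The end point is a package choice; nothing pins it exactly.

Slopes are reported per minute.  An automatic alternative
(`detect_linear_segment`) finds the longest contiguous run of points whose
OLS fit keeps R² ≥ 0.95 (min 5 points, exhaustive scan, ties to the earlier
start), but the prescribed windows are the default pipeline path.  Note the
5-point minimum is fragile against pure noise — the null R² distribution at
n = 5 has a fat upper tail, and ~10% of 30-point noise series contain a
qualifying 5-point run; runs of 8+ points are robust.

## Blood-curve QC

Tracer trapped at the tail-vein injection site leaks into circulation for
the whole scan: the aorta curve keeps ascending instead of showing bolus
transit, and every downstream number is invalid.  The screen computes a
flatness index = (OLS slope over the terminal third of the scan)/(OLS slope
from tracer arrival to the curve peak) and fails a curve when the index
exceeds 0.10 or the global maximum falls in the terminal third.  Both the
ceiling and the terminal-third rule are package choices — the underlying
exclusion rule is qualitative ("persistently ascending, no flattening").
On the generator's clean curves the false-positive rate is 0/100; all
injected depot artifacts are flagged.

## Static SUV

TP1/TP2/TP3 = [0,300], [900,1200], [2100,2400] s are the single source of
truth shared by all modules.  SUV = C/(1000·dose/weight) with tissue density
1 g/mL and total body weight (no lean-mass variant); concentrations are
assumed decay-corrected upstream.  Window means weight frames pro-rata by
overlap duration — the framed-data equivalent of reconstructing a static
frame.  The blood reference is the aorta VOI mean over the same window; the
renal output proxy is the pelvis/cortex window-mean ratio.

## Synthetic cohort

The generator emulates the *statistical structure* of a cardiorenal study —
groups L1 (control), L2 (heart failure), L3 (cardiorenal), L4 (renocardiac),
age controls L2Aco/L34Aco, sizes 8/8/8/10+2+2 — not any real cohort's
effect sizes.  Components:

- **Input function**: tri-exponential bolus (Feng-type) with an 8 s
  appearance delay, peak ≈ 120 kBq/mL at ~25 s, tail < 10% of peak at
  40 min.  Per-subject log-normal jitter (10%) on amplitudes and ±1 s on
  delay.
- **Organs**: literature-plausible healthy-rat baselines (per minute):
  cortex K₁=0.8, k₂=1.4, k₃=0.06, V_b=0.10; medulla 0.9/1.2/0.02/0.50;
  liver 0.5/0.9/0.01/0.25; myocardium (fasted) 0.6/1.2/0.02/0.30; muscle
  0.10/0.8/0.02/0.04.  The medullary vascular-window amplitude exceeds the
  cortical one via both a larger V_b and larger delivery K₁ — a pure-V_b
  encoding would leave the medullary early slope ≈ (1−V_b)K₁ too small to
  carry any group signal; low medullary k₃ keeps medullary K_i below
  cortical.  Calibrated once so the healthy cortex/medulla peak-amplitude
  ratio sits mid-band in (0.4, 0.6).
- **Pelvis**: an accumulation compartment dC/dt = rate·C_free(t−delay) fed
  by the delayed cortical free-compartment outflow (rate 0.45 min⁻¹, delay
  55 s) — the simplest model in which the pelvic rise starts ≈ 60 s after
  tracer arrival and is irreversible.  The early pelvic spillover bump seen
  in real data is *not* modelled; the 60–120 s window avoids it by design.
- **Disease encoding** (multiplicative factors): renal K₁ falls to
  0.78/0.60/0.45 of baseline in L2/L3/L4; pelvic extraction rate to
  0.80/0.60/0.35; myocardial k₃ rises ×3.8 in L3 and ×2.3 in L4
  (calibrated once to give ≈2× and ≈1.5× blood-normalised TP3 uptake);
  L4 adds muscle k₃ ×3 and liver k₃ ×2.5 (systemic uremic remodelling).
  These encode directions and approximate fold-changes only.
- **Between-subject variability**: independent log-normal multipliers,
  CV 15% on rates, 10% on V_b (clipped below 0.85).  Weight ~ N(300, 18) g,
  dose ~ N(9.56, 0.7) MBq/100 g, glycemia ~ N(120, 15) mg/dL (L3: 155).
- **Noise**: additive Gaussian, σ_k = scale·√(max(C_k, floor)/Δt_k),
  floor 1% of peak, clipped at zero.  Default scale 0.05 ≈ 1–2% relative
  noise on hot 1 s frames — the regime of heavily regularised MAP
  reconstructions, consistent with per-subject early linear segments being
  identifiable at R² ≥ 0.95.  Framed reconstructed PET is approximately
  Gaussian; Poisson sampling is not modelled.
- **Tail-depot artifact**: blood = (1−leak)·C_p + leak·peak(C_p)·(1−e^{−t/τ}),
  τ = 10⁴ s ≫ scan, i.e. first-order release of the trapped fraction toward
  the bolus peak concentration scale; organs are re-simulated from the
  modified input.  Default leak 0.9 reflects near-complete trapping.
- **Morphometry**: kidney axes at fixed aspect 1.55:1:1.03 scaled to
  group-typical volumes (1590 mm³ control at 14 wk, 1480 mm³ L2, 2101 mm³
  L2 age control, plausible values for the older groups), ±4% axis jitter;
  body-weight series from the 5-anchor logistic reference with blunted gain
  in L2/L3 and an early plateau in L4.

Everything is a pure function of (configuration, seed): per-subject and
per-curve seeds are spawned from the master seed.

What passing tests show: the pipeline separates groups whose kinetics differ
in the encoded directions, at the encoded noise, and recovers known ground
truth.  What they do not show: performance on real reconstructions with
spillover, partial-volume effects, motion, attenuation residuals or
non-Gaussian noise — none of which the generator emulates.

## Morphometry

Ellipsoid volume uses full axis lengths, V = (π/6)·L·W·D (equivalent to
(4/3)π·abc on semi-axes).  Growth rate is the OLS slope of ln(weight) on
postnatal day.  The reference growth trajectory is a 4-parameter logistic
w(t) = a + (b−a)/(1+e^{−c(t−t₀)}) fitted to five anchors; a 4-parameter
form is the most that five points identify.  Bounds force a ≤ min(anchor),
b ≥ max(anchor), c ≥ 0, so the curve is monotone for monotone anchors and
the asymptotes bracket the data; the asymptotes themselves are
extrapolations and may be unphysical.  Cumulative regimen dose is the plain
product dose × administrations/week × weeks.

## Pipeline

Order: QC → static SUV → Patlak markers → compartmental fits → morphometry →
group summaries.  QC-failing subjects are excluded from every PET analysis
and listed with reasons, so summary n plus exclusions always equals cohort
size.  Statistics are descriptive only (n, mean, median, min, max, ratio to
age-control mean): with 8–10 animals per group and dozens of endpoints,
hypothesis tests would be decoration, so none are produced.  Age-control
ratios divide by the arithmetic mean of the matched control group (L2 vs
L2Aco; L3 and L4 vs L34Aco).  Runs are deterministic given inputs and
configuration, and the configuration is echoed to YAML beside the tables.

## Known limitations

- No spillover/partial-volume correction; the pelvic 60 s spillover
  artifact is handled only by window placement.
- Blood = plasma; no metabolite or whole-blood correction.
- The early cortical/medullary slope is an empirical vascular analog; its
  mapping to (1−V_b)K₁ holds only within this model family.
- The liver window end (t₀+55 s) and the QC numeric thresholds are package
  choices on top of qualitative descriptions.
- Reported problem sizes in tests and the acceptance script (e.g. 20
  replicates per organ, 100 QC subjects) are the package's validation
  choices, sized to characterise medians and rates without excess.
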