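# Methods

This note documents the models, numerical choices and known limitations of
`pharmglass`, in the order the analysis chain runs.

## Eutectic thermodynamics (`phase`)

The liquidus of each component obeys the Schröder–Van Laar equation for an
ideal solution, ln x = −(ΔH0/R)(1/T − 1/T0) with R = 8.314 J mol⁻¹ K⁻¹.
No activity coefficients are applied: the package deliberately uses the
bare ideal-solution form, so predicted eutectics for strongly non-ideal
pairs will deviate from experiment. Note that for x ∈ (0, 1] the closed
form 1/T = 1/T0 − R ln x/ΔH0 always yields a positive inverse
temperature, so the liquidus is defined on the whole composition range
(it merely plunges unphysically low at extreme dilution); a defensive
domain guard remains in the code.

*Binary eutectics* are found by Brent bracketing of the branch
intersection on [1e-6, 1−1e-6]; the residual temperature mismatch at the
root is below 1e-6 K. *Ternary eutectics* solve the two equal-temperature
conditions as a Levenberg–Marquardt least-squares problem in (x₁, x₂),
seeded by a vectorized barycentric grid scan (step 0.005) of the liquidus
surface; convergence requires residuals below 1e-6 K and an interior
solution, otherwise a `NoEutecticError` carries the grid diagnostics. The
liquidus surface at any composition is the maximum of the three branch
temperatures, with the governing component recorded.

*Expected endotherm count*: a DSC scan of an off-eutectic mixture shows
the eutectic melt plus one dissolution endotherm per component whose
branch temperature at that composition exceeds the eutectic temperature
by more than a resolvability tolerance (default 1 K, configurable).
Because the mole fractions and the eutectic fractions both sum to one, at
most two of three branches can lie above the eutectic temperature, giving
counts in {1, 2, 3} for ternary and {1, 2} for binary systems.

*Experimental assembly*: a composition is labelled the experimental
eutectic when its solidus and liquidus coincide within 2 K (instrument
resolution scale, configurable); absent such a record the interpolated
liquidus minimum is used.

The registry ships molar masses of EZB/SVT/FEN as published (409.4,
418.6, 360.83 g/mol) but *placeholder literature values* for their
melting points and fusion enthalpies, because the constants behind the
published phase diagrams were not tabulated. They are user-replaceable
and are never used in validation, which runs on synthetic constants.
A related caveat: one published worked example ("35 wt% EZB ⇒
x_EZB = 0.645" for the EZB/SVT pair) is inconsistent with the stated
molar masses — 0.645 is the simvastatin fraction at that composition —
and is therefore not used as a reference value; the two self-consistent
worked examples (x_EZB = 0.089, x_SVT = 0.177) are.

## DSC feature extraction (`dsc`)

Heat flow is canonicalized endo-up. Endotherms are located with a
prominence-filtered local-extremum search (default threshold: 5× a robust
noise scale estimated from the median absolute deviation of the second
difference) after Savitzky–Golay smoothing over a 1 K window (order 2,
configurable, 0 disables). Peak feet come from the 97%-of-prominence
width positions, clipped at inter-peak minima so adjacent events never
swallow each other's baseline.

The onset uses the tangent construction: intersection of the pre-peak
baseline tangent (linear fit over ≈2 K before the foot) with a line
fitted to the leading edge between 25% and 75% of peak height — the
chord variant of the steepest-slope tangent, chosen because a single
steepest-point estimate is noise-biased. Enthalpy is the trapezoidal
area above a linear baseline spanning the peak feet (the baseline model
is an assumption; the instrument's true curvature is not modelled),
converted to J/g when the sample mass and heating rate allow.

The glass transition is the midpoint of the heat-capacity step: linear
baselines are fitted on configurable pre/post windows (defaults: first
and last 25% of the scan — override them when melting events share the
trace) and Tg is the interpolated crossing of the half-step level.
Solidus = onset of the first endotherm; liquidus = peak maximum of the
last; a single event returns equal values flagged eutectic-like.

## Havriliak–Negami fitting (`dielectric`)

The model is ε*(ω) = ε∞ + Δε/(1 + (iωτ_HN)^a)^b − iσ_dc/(ε0ω) with
0 < a ≤ 1 and 0 < ab ≤ 1 (the product is the fitted quantity, which
enforces the joint constraint with simple bounds). By default only the
loss ε″ enters the objective, as residuals in log10 — uniform weight per
decade, equivalent to relative weighting for small deviations — because
spectra span many decades; ε′ co-fitting is optional (`fit_real=True`)
and is required to identify ε∞, which the loss does not constrain.

Conductivity is reparameterized as its loss contribution at the lowest
measured frequency (an O(1) quantity) rather than σ_dc itself (~1e-11
S/m); without this the optimizer stalls on the badly scaled coordinate.
The loss-only objective has shallow local minima along the correlated
a–Δε–τ valley (a tends to escape to the Debye bound), so the fit is
multi-started from four shape guesses, each with Δε and τ_HN seeded
consistently with the observed peak position and height, and the lowest
residual wins. On noiseless synthetic spectra this recovers all
parameters to machine precision; under 1% multiplicative loss noise the
median loss-peak-time error is below 0.02 decades (tested over 50
draws). A peak at either frequency boundary triggers a warning flag.

τ_α is the loss-peak time, τ_HN·[sin(πa/(2+2b))]^(−1/a)·
[sin(πab/(2+2b))]^(1/a), verified against a dense numeric argmax to
0.1%. Only a single relaxation process is modelled; secondary (β/γ)
relaxations and electrode polarization are out of scope.

## Relaxation dynamics (`relaxation`)

The VFT convention is τ = τ∞ exp(B/(T−T0)) (natural log, B in K,
τ∞ reported as log10 seconds); this convention reproduces the derived
columns of the published dynamics table and is therefore fixed. Fits run
on log10 τ with bounds B > 0, 0 ≤ T0 < min(T), seeded from the Stickel
linearization, which is exact for VFT data. Derived quantities are
closed-form inversions: Tg = T0 + B/ln(τ_ref/τ∞) with τ_ref = 100 s,
the same formula for any isochrone (default 0.63 μs, a parameter, not a
constant), and m_p = B·Tg/(ln10·(Tg−T0)²); evaluating the VFT at the
returned temperature reproduces τ_ref to machine precision.

The Stickel transform uses central differences on the raw points (no
smoothing by default — smoothing would bias the crossover location;
Savitzky–Golay pre-smoothing is available upstream). Points with
non-negative derivative are dropped with a warning. Crossover detection
fits all admissible two-segment splits (≥3 points per side) and accepts
the best one only if (i) the residual-variance F-ratio against the
single-line fit exceeds 4 (configurable; no published criterion exists)
and (ii) the two slopes differ by more than 2% relative. The slope
criterion exists because finite-difference derivatives of *exact* VFT
data leave a smooth curvature residual that a two-segment fit always
reduces — the F-ratio alone would report a spurious break — while a
genuine VFT1/VFT2 crossover changes the Stickel slope by (B1/B2)^(1/2),
tens of percent. Exactly collinear transforms short-circuit to "no
crossover". The crossover temperature is the intersection of the two
fitted lines.

Two rows of the published parameter registry carry a `consistent=False`
flag and are excluded from validation: the neat-EZB row, whose printed
derived columns (Tg 333 K, m_p 93) are not reproduced by inverting its
own printed VFT parameters (inversion gives ≈336.6 K and ≈131 — likely a
fit-range or typographical issue), and the 10/40/50 row, which prints a
Vogel temperature (277.7 K) above its own Tg (271 K), impossible for a
VFT law (plausibly 227.7 K). The neat-FEN isochronal column prints
298 K where inversion of its VFT parameters gives 296 K — presumably
read off the graphical intersection — so FEN contributes only its
fragility to validation.

## Crystallization kinetics (`crystallization`)

ε′_N(t) = (ε′(0) − ε′(t))/(ε′(0) − ε′(∞)); plateau levels default to the
means of the first/last 5% of points unless supplied. Normalization is
affine-invariant by construction (property-tested). Onset/half-life/
endset are linear-interpolated threshold crossings at 0.05/0.5/0.95 —
the outer thresholds are this package's choice (the reported onset and
endset times are not given an operational definition) and are
configurable. A threshold never reached yields a partial summary with a
warning, not an error. The Avrami fit (1 − exp(−(kt)^n), seeded by the
double-log linearization) is a shape diagnostic only.

## Synthetic data (`synthesize`)

All generators are deterministic given a `GeneratorConfig` seed and
return a ground-truth dictionary (written as a JSON sidecar by the I/O
layer) that round-trip tests consume. Noise defaults: 1% additive on DSC
heat flow, 0.5% multiplicative on dielectric loss, 0.5% additive on
permittivity decays.

*DSC*: baseline drift + sigmoid Tg step + one melting endotherm per
expected event, at the solidus/liquidus temperatures of the chosen
component set, with areas proportional to melting mass fractions. The
mixture Tg follows a Gordon–Taylor rule with unit interaction parameter
— a documented stand-in, not a fitted law. Peaks have a linear leading
edge and exponential tail so the tangent-construction onset is exact by
construction; all events shift by a rate-lag coefficient × heating rate
(default 0.05 K per K/min) to emulate thermal lag.

*Dielectric series*: for each temperature, τ_HN is set so the loss-peak
time equals the VFT-prescribed τ_α (one or two regimes; the two-regime
constructor `second_regime_parameters` enforces continuity of both τ_α
and the Stickel operator at the crossover, which is what makes the
crossover the intersection of the two Stickel lines). The dc
conductivity, when enabled, is σ_dc = ε0·Δε·c/τ_α — it follows the same
super-Arrhenius activation as the structural relaxation
(Debye–Stokes–Einstein-type coupling) with configurable amplitude c.
The default frequency window is 0.1 Hz – 10 MHz at 10 points/decade;
regimes whose loss peak leaves that window need a wider synthetic band
(the two-regime tests use one).

*Crystallization*: ε′(t) = ε∞ + (ε0−ε∞)·exp(−ln2·(t/t½)^n), sampled
every 600 s (the reported instrument cadence). Named presets carry the
reported half-lives of the neat drugs (79, 114, 330 min) and of the
therapeutic ternary composition (10.5 h) at their isochronal storage
temperatures.

What the generators do **not** emulate: thermal-lag deconvolution,
electrode polarization, secondary relaxations, multi-step nucleation,
instrument drift. Passing round-trip tests therefore demonstrates the
correctness of the analysis chain, not its robustness to every artefact
of real instruments.

## Pipeline and problem sizes

`run_pipeline` executes synth → dsc → eutectic → hn → vft → kinetics,
records per-stage status and timings, skips stages whose prerequisites
failed, and writes a summary row in the published table's schema
(temperatures rounded to integer kelvin, fragility to integer, full
precision in the serialized values). Default problem sizes — 9
temperatures per relaxation map, 81-point spectra, 0.005 barycentric
grid resolution, 50-draw noise studies — were chosen so each stage's
statistical error is comfortably below the tolerances quoted above while
a full run completes in seconds.
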