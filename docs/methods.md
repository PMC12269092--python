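# Methods

This note documents the models behind `lakephotochem`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real monitoring data.

## Trend testing and browning classification

The seasonal Mann–Kendall test (Hirsch–Slack form) compares observations
only within the same calendar month: for each season the statistic
S_g = Σ_{i<j} sign(x_j − x_i) and its tie-corrected variance
[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 are summed over seasons, a ±1
continuity correction is applied, and a two-sided normal p-value is taken.
The Sen slope is the median of all within-season pairwise slopes, computed
per month and multiplied by 12 (avoiding calendar-day irregularities);
pairs at identical times are skipped. Missing months are simply absent
from their season's pair set — no imputation. Records shorter than 24
months for a parameter are flagged missing rather than tested.

Two properties of this test matter in practice:

* **Size under serial correlation.** The variance formula assumes serial
  independence. The false-positive rate at α=0.05 is nominal on white
  noise (~3% empirically) but inflates quickly with month-to-month AR(1)
  correlation — roughly 12% at φ=0.3 and 20%+ at φ=0.5 in our Monte-Carlo
  runs — because the seasonal statistics are treated as independent while
  adjacent months are not. The synthetic chemistry generator therefore
  defaults to mild persistence (φ=0.15, empirical size ≈5.5%), keeping a
  valid null for the trend stage; a documentation test records the
  inflation at φ=0.5 without asserting a tight value. Users applying the
  test to strongly autocorrelated data should expect this inflation; the
  pre-whitened or covariance-corrected variants are out of scope here.
* **Monotone-transform invariance.** S and p depend only on ranks within
  seasons; the Sen slope does not. Both are covered by property tests.

For classification, slopes with p ≥ 0.05 are replaced by zero, the
(DOC, color, SUVA₂₅₄) triples are z-scored per dimension, and k-means with
k=3, k-means++ initialization, 100 restarts and a fixed seed partitions the
lakes (input rows are sorted by lake id first, so the assignment is
invariant to input order). Raw labels are mapped deterministically: cluster
A (mild) has the lowest mean standardized DOC+color slope; of the remaining
two, C (intense) has the more negative standardized SUVA₂₅₄ slope and B
(moderate) is the other. Identical slope triples across all lakes trigger a
degenerate-clustering warning and a uniform A assignment.

## Wavelet coherence

Each series is linearly interpolated across gaps (refused above 10%
missing by default; the fraction is recorded), shifted strictly positive
if needed, Box-Cox transformed at the maximum-likelihood λ, linearly
detrended, and z-scored. The continuous wavelet transform uses the complex
Morlet wavelet with ω₀ = 6 (PyWavelets `cmor` with bandwidth 2 and centre
frequency 6/2π) on a logarithmic period grid of 24 voices per octave
spanning each band edge to edge. The cone of influence follows the
standard e-folding form, √2 × (Torrence–Compo scale), excluded at both
record edges. PyWavelets estimates the wavelet centre frequency
numerically, which shifts the nominal scale↔period map by about 2%;
this is immaterial for octave-wide band aggregates and cancels entirely in
phases.

Band coherence is the modulus of the average unit cross-wavelet phasor
w_x·conj(w_y)/(|w_x||w_y|) over retained time points, site pairs, and
in-band scales; the mean phase is its argument. Averaging unit-modulus
numbers bounds the magnitude in [0,1] by construction. **Sign convention:
positive phase means x leads y** — a series delayed by a quarter cycle
against a 12-month oscillation yields phase +π/2; this convention is
pinned by a test because the lagged-positive/lagged-negative class labels
depend on it. Phase classes: positive in-phase [−π/4, π/4], lagged
negative (π/4, 3π/4), lagged positive (−3π/4, −π/4), negative antiphase
beyond ±3π/4, with boundaries assigned to the in-phase/antiphase side.

Significance uses Fourier phase-randomized surrogates of the y series
(autocorrelation preserved), sharing one random rotation across sites per
surrogate so the cross-site alignment of the surrogate ensemble is
preserved, with p = (1 + #{m_surr ≥ m_obs})/(n_surrogates + 1) and at
least 99 surrogates. Monte-Carlo checks place the empirical rejection rate
on independent noise within [0.02, 0.09] at α=0.05.

Because the aggregate is a phasor mean, its expectation for partially
coherent Gaussian signals is slightly below the underlying correlation
(the classic π/4-type bias at low coherence); the generator's coupling
magnitude is therefore exact at 0 and 1 and approximate in between.

## Probe kinetics, actinometry, and quantum yields

FFA loss is pseudo-first-order: k_obs is the negated OLS slope of ln C vs
t (≥4 points, positive concentrations), giving the in-vial steady state
[¹O₂]ss,exp = k_obs/k_rxn,FFA and the apparent quantum yield
Φ = [¹O₂]ss,exp·k_dΔ/R_a, where R_a is the trapezoidal 290–550 nm sum of
irradiance × fraction absorbed per unit volume. Yields outside (0,1) raise
a warning but are returned. The PNA/pyridine actinometer fixes the photon
flux scale via Φ_PNA = 0.29·[pyridine] + 0.00029 and
scale = k_obs,PNA/(Φ_PNA · specific absorption rate of PNA under the
reference spectrum). Defaults (configurable in `PhotoConstants`):
k_rxn,FFA = 1.00×10⁸ M⁻¹ s⁻¹ at 25 °C, k_dΔ = 2.76×10⁵ s⁻¹ (¹O₂ lifetime
≈3.6 µs in water), and the PNA coefficients above — conventional
literature values, to be overridden when better numbers are at hand. The
PNA molar absorptivity is a synthetic single-Gaussian band model (316 nm
peak, 1.0×10⁴ M⁻¹ cm⁻¹); generator and analyser share it, so actinometry
round-trips exactly.

## The steady-state light-field model

Implemented term for term on a 1-nm grid with trapezoidal integration and
inclusive 290/550 nm endpoints. Irradiance is corrected for surface
reflection (default 0.066) and underwater pathlength enhancement (default
1.2); CF = 0.60 is the regional non-clear-sky factor; f_backscatter = 0.02
and f_abs,CDOM = 1.0 by default. All are configuration keys, documented as
assumptions rather than measured values. The euphotic depth
z_eu = 4.6/(0.15·DOC^1.08)·100 cm and attenuation
K_d,λ = exp(−0.01347·λ + 5.36·DOC^0.157) are empirical DOC relationships
for humic temperate lakes.

**K_d units.** The K_d formula's output is read as m⁻¹ and converted to
cm⁻¹ internally (toggleable via `kd_units`). Read as cm⁻¹ it would imply
millimetre-scale light penetration at ordinary DOC — irreconcilable with
the ~7 m euphotic depths the companion DOC model produces — so the m⁻¹
reading is the only physically consistent one.

The near-surface variant replaces the depth-average factor
(1−e^(−K_d·z))/z by K_d; their ratio tends to 1 as attenuation vanishes
and to 0 as z → ∞, and the euphotic-zone value never exceeds the
near-surface value. Epilimnion concentrations are computed only when a
mixed-layer depth is supplied and are excluded from default reports,
since that depth is not modeled from DOC here. The depth-averaged
concentration rises strictly with DOC across 1–15 mg C/L: growing
volumetric absorption outweighs the shrinking euphotic depth.

Half-lives use ln 2/(k_rxn·[¹O₂]) with a 30.44-day month. Screening
classes by log₁₀(t₁/₂/τ): below 0 faster than flushing, 0–1 comparable,
above 1 slower, boundaries belonging to the slower class.

## The synthetic-data generator

`synthio` emulates the statistical structure the analysis assumes, not any
real lake district:

* **Chemistry**: DOC = baseline + trend·t + 0.5·sin(2πt/12) + AR(1) noise
  (sd 0.15 mg C/L, φ=0.15 — see the size discussion above), floored at
  0.05; color = DOC/0.095 (Pt–Co per mg C/L) plus noise, truncatable to
  emulate a discontinued color record; SUVA₂₅₄ with its own trend; 5%
  missing completely at random. Months are integer-indexed; no leap
  handling at monthly resolution.
* **Regional forcing**: an optional shared AR(1) (φ=0.85) interannual DOC
  anomaly. Without it, lakes share only the annual cycle and per-lake DOC
  carries nothing coherent with a common driver — the synchrony stage
  would have no signal to find. The pipeline default (sd 0.4 mg C/L)
  makes the lake set regionally synchronous, which is the premise of the
  driver-coherence analysis.
* **Drivers**: band-limited Fourier components of the (mean) DOC record,
  phase-delayed by the requested coherence phase, mixed with a
  random-phase surrogate of the same component (spectrum-matched noise, so
  the in-band signal-to-noise ratio is uniform across scales), then mapped
  to plausible physical units.
* **Kinetics**: exact inversion of the quantum-yield arithmetic with
  multiplicative lognormal noise; the default design samples 9 points over
  4 h, reaching beyond one half-life at typical rates so the slope is well
  determined.
* **Solar spectrum**: Z(λ) = z_scale·(λ/550)²·exp(−10·e^(−(λ−290)/13)) —
  a power-law tilt for the rising photon flux plus preferential
  short-wavelength scattering losses, cut off by an exponential ozone
  (Hartley–Huggins) edge; z_scale = 5×10⁻¹⁰ mol-photons cm⁻² s⁻¹ nm⁻¹ at
  550 nm puts the resulting steady-state concentrations in the
  10⁻¹⁵–10⁻¹⁴ M range typical of humic temperate lakes.
* **Compounds**: log-uniform rate constants spanning 6.3×10³–3.7×10⁹
  M⁻¹ s⁻¹ with the extremes pinned.

What passing tests show: the pipeline recovers planted trends, coherence
phases, quantum yields and cluster structure under the stated noise, and
its statistics hold their nominal size under their own assumptions. What
they do not show: performance under real-data pathologies — heteroscedastic
noise, regime shifts, non-sinusoidal seasonality, strongly autocorrelated
residuals, instrument changes — none of which the generator emulates.

## Group comparisons

Kruskal–Wallis first; pairwise two-sided Mann–Whitney U only when the
omnibus test is significant at 0.05, exact p-values when both groups have
≤8 samples and the tie-corrected normal approximation otherwise, starred
as * (<0.05), ** (<0.01), *** (<0.001), **** (<0.0001). No
multiple-testing correction is applied to the pairwise p-values — this
mirrors the tiered-caption protocol the pipeline reproduces and is not a
statistical recommendation. Groups with fewer than 3 samples are excluded
with a warning. Spearman correlations use average ranks for ties.

## Problem sizes

The bundled analysis runs 37 lakes × 360 months with 199 surrogates per
band test; the test suite uses 6–37 lakes, 96–360 months, 99–999
surrogates, and 50–200 Monte-Carlo seeds per size/recovery check. These
sizes give the Monte-Carlo assertions comfortable binomial margins while
keeping a full run in minutes on one core.

## Known limitations

* Ties in the exact Mann–Whitney path are rare in continuous simulated
  data but would make the "exact" p conservative; SciPy's implementation
  is used as-is.
* The wavelet stage refuses series with >10% missing rather than modeling
  gaps; heavily gapped records need upstream treatment.
* Coherence magnitudes between 0 and 1 are recovered with the phasor-mean
  bias noted above; only the endpoints are exact.
* The K_d and euphotic-depth relationships are empirical fits from humic
  temperate lakes; outside roughly DOC 1–15 mg C/L they extrapolate.
* Quantum yields are solar-integrated, bulk aqueous-phase quantities; no
  wavelength resolution, no microheterogeneity, no temperature dependence
  of k_dΔ.
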