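# lakephotochem

Long-term browning of softwater lakes — rising dissolved organic carbon
(DOC) and water color — reshapes their light climate, and with it the
photochemistry that dissolved organic matter (DOM) drives. This package
implements, as a tested analysis pipeline, the computational chain that
links browning trends to the photochemical production of singlet oxygen
(¹O₂) and its consequences for contaminant fate:

1. **Trend classification** — seasonal Mann–Kendall tests and Sen's slopes
   on monthly DOC, color and SUVA₂₅₄ records, with insignificant slopes
   zero-replaced and k-means (k=3) classification into mild/moderate/intense
   browning clusters.
2. **Synchrony** — Morlet wavelet coherence between per-lake DOC and
   regional drivers (acid deposition, precipitation, soil wetness, solar
   irradiance) over short (3–6), intermediate (12–24) and long (36–72
   month) bands, with phase classes and Fourier-surrogate significance.
3. **Quantum yields** — apparent ¹O₂ quantum yields Φ from furfuryl-alcohol
   (FFA) probe photolysis, with p-nitroanisole/pyridine actinometry and
   normalization against a parallel Suwannee River NOM reference.
4. **Steady state** — the depth-averaged euphotic-zone concentration

   ```
   [¹O₂]ss = (Φ / k_dΔ) · CF · Σ_λ  Z_λ / z_eu · (1 − e^(−K_d,λ · z_eu))
                                     · (1 − f_backscatter) · f_abs,CDOM
   ```

   over 290–550 nm, with the euphotic depth z_eu = 4.6/(0.15·DOC^1.08)·100 cm
   and attenuation K_d,λ = exp(−0.01347·λ + 5.36·DOC^0.157) both empirical
   functions of DOC, plus a near-surface variant (the depth-average factor
   replaced by K_d,λ).
5. **Screening** — contaminant half-lives t₁/₂ = ln 2/(k_rxn·[¹O₂])
   benchmarked against hydraulic residence time τ via log₁₀(t₁/₂/τ),
   classed as faster than flushing (<0), comparable (0–1) or slower (>1).

A first-class synthetic-data module (`synthio`) generates every input the
pipeline consumes — chemistry records with planted trends, drivers with
controllable band-limited coherence, probe kinetics inverted from the
quantum-yield arithmetic, CDOM spectra, a clear-sky-like solar spectrum and
a contaminant rate table — so every stage's hidden truth is recoverable and
testable without external data.

Intended users: aquatic photochemists and biogeochemists who want a
reproducible, tested implementation of this analysis chain to adapt to
their own monitoring and photolysis data.

## Worked example

```python
import numpy as np
from lakephotochem import photochem, synthio
from lakephotochem.photochem import LakeOpticalModel

constants = synthio.PhotoConstants()

# quantum yield from a (simulated) FFA photolysis experiment
ra = 1.25e-5  # rate of light absorption by the sample, M/s
trace = synthio.gen_kinetics(phi_true=0.022, ra=ra, species="FFA",
                             noise_cv=0.02, seed=7)
k_obs = photochem.fit_first_order(trace).k_obs
qy = photochem.apparent_quantum_yield(k_obs, ra, constants, phi_srnom=0.0214)
print(f"Phi = {qy.phi_app:.4f}, Phi/Phi_SRNOM = {qy.phi_ratio_srnom:.2f}")

# field steady state for a DOC 4 mg C/L lake under a daily-average spectrum
field = synthio.gen_solar_spectrum()
lake = LakeOpticalModel.from_doc(4.0, field.wavelengths)
ss = photochem.steady_state_1o2(qy, field, lake, constants)
print(f"z_eu = {lake.z_euphotic_cm:.0f} cm")
print(f"[1O2]ss euphotic = {ss.c_euphotic:.2e} M, "
      f"near-surface = {ss.c_near_surface:.2e} M "
      f"({100 * ss.c_euphotic / ss.c_near_surface:.1f}%)")

# how long would a median-reactivity contaminant last?
print(f"t_half = {photochem.half_life(1.8e6, ss.c_euphotic):.0f} months")
```

prints

```
Phi = 0.0219, Phi/Phi_SRNOM = 1.02
z_eu = 686 cm
[1O2]ss euphotic = 5.48e-15 M, near-surface = 9.08e-14 M (6.0%)
t_half = 27 months
```

i.e. the probe experiment returns the planted quantum yield of 2.2% to
within its noise, a 4 mg C/L lake has a ~7 m euphotic zone whose
depth-averaged ¹O₂ is ~6% of the near-surface value (light attenuation
does the rest), and a compound with the median literature rate constant of
1.8×10⁶ M⁻¹ s⁻¹ reacts away with a half-life of a couple of years.

## Analysis scripts

The numbered drivers under `analysis/` run the full study on synthetic
data and write tidy tables under `results/`:

```
python analysis/01_simulate.py       # generate all inputs
python analysis/02_trends.py         # Sen slopes + browning clusters
python analysis/03_synchrony.py      # wavelet coherence vs color & drivers
python analysis/04_quantum_yield.py  # probe kinetics -> Phi, comparisons
python analysis/05_steady_state.py   # light-field model -> [1O2]ss
python analysis/06_screening.py      # half-life vs flushing, by cluster
```

Each accepts `--seed` (default 1) and `--outdir`. `pipeline.run_pipeline`
executes the same stages end to end from a single `RunConfig` and writes a
manifest whose hash is stable across identical runs.

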