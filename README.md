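# imsquant

Quantification-performance analysis for volatile organic compounds (VOCs)
measured by thermal-desorption gas chromatography with a drift-tube ion
mobility spectrometer (TD-GC-IMS), compared against a mass spectrometer
(TD-GC-MS) on the same separation.

It is written for analytical chemists who need to validate GC-IMS
quantification — calibration strategy, limits of detection and
quantification (LOD/LOQ), linear range, long-term precision — and for
method developers who want a fully synthetic, seeded testbed for those
procedures.

## The problem and the model

A drift-tube IMS ionizes analytes by proton transfer from a reservoir of
reactant ions (the reactant ion peak, RIP). The response is intrinsically
non-linear: analyte monomers `MH+` form first, then proton-bound dimers
`M2H+` as concentration rises, while the reactant reservoir is depleted.
`imsquant` models this as a two-step mass-action equilibrium. For an
amount *c* (ng loaded per desorption tube),

```
q        = 1 + αc + αβc²
M(c)     = αc  · R₀ / q        monomer intensity
D(c)     = αβc²· R₀ / q        dimer intensity
R_free   = R₀ − M − D = R₀/q   surviving RIP
```

so charge is conserved exactly, the monomer peaks at `c* = 1/√(αβ)`, and
the summed analyte signal saturates at the reservoir intensity `R₀`.

On top of this the package implements:

- **Window-maximum extraction** — peak height `H` is the in-window maximum
  above a local (border-median) baseline; blank noise `γ` is the same
  statistic on a blank, the one-sided (half peak-to-peak) reading under
  which `S/N = 2H/γ`.
- **Calibration in three modes** — monomer height, monomer+dimer sum
  (mandatory when blanks already show dimer signal at the analyte
  position), and the CIP linearization `CIP = AIP/(RIP − AIP)`, which is
  exactly `αc` when dimerization is negligible and extends the usable
  linear range by roughly a decade.
- **Detection limits** — the blank-statistics method
  `x_D = x̄_b + k·s_b`, `x_Q = x̄_b + 10·s_b` with the
  degrees-of-freedom-aware factor `k = t₁₋α,ν + t₁₋β,ν` (`k = 3.592` for
  12 blanks at α = β = 0.05), and the S/N method
  `x_D = 1.5γ`, `x_Q = 5γ`; both converted to ng/tube through a low-range
  calibration fit.
- **Quality control** — repeatability / intermediate-precision RSDs and
  Shewhart-style property control charts (warning limits at ±2·SD,
  control limits at ±3·SD).
- **A synthetic data generator** for 2D IMS chromatograms (retention time ×
  RIP-relative drift time) and linear GC-MS TIC traces, including blank
  contamination (nonanal from adsorbent degradation, 2-butanone as a
  solvent impurity), so the entire pipeline runs without instrument data.

## Worked example

```python
import imsquant as iq

result = iq.run_pipeline(iq.default_config(seed=1))

nonanal = result.ims["nonanal"]
k = iq.detection_factor_k(nonanal.blank_stats.n)          # 3.592
print(nonanal.mode.value)                                 # monomer_plus_dimer
print(nonanal.blank_stats.mean, nonanal.blank_stats.sd)   # 0.358, 0.089 a.u.
print(iq.lod_presented(nonanal.blank_stats, k))           # 0.677 a.u.
print(iq.loq_presented(nonanal.blank_stats))              # 1.247 a.u.
print(nonanal.limits["presented"].cD)                     # 0.045 ng/tube
print(result.comparison.round(3))
```

The pipeline routes nonanal to monomer+dimer calibration automatically
because its blanks carry both species (tube contamination), computes the
blank statistics (0.358 ± 0.089 a.u. over 12 blanks), places the
detection limit at `0.358 + 3.592 × 0.089 = 0.677` a.u., and inverts it
through the low-range calibration to 0.045 ng/tube. The comparison table
shows the two detector regimes: the IMS calibration is linear over about
1.4 decades before monomer–dimer conversion and reservoir depletion bend
it, while the MS trace stays linear over the full 3.3-decade span, and
MS detection limits sit one to two orders of magnitude higher (less
sensitive) in amount terms:

```
  compound  cD_ims_ng_per_tube  cD_ms_ng_per_tube  lod_ratio_ms_over_ims  log10_ratio  ims_decades  ms_decades
2-hexanone               0.006              1.034                182.897        2.262        1.412       3.301
   nonanal               0.045              1.244                 27.927        1.446        1.412       3.301
```

On the same run, the CIP-linearized 2-hexanone calibration fits a line
with slope 1.01 (the configured α = 1.0) at R² = 0.9995 over 0.01–8
ng/tube, while the raw monomer response manages R² = 0.11 over the full
span — the linearization in action.

A command-line interface mirrors the stages
(`imsquant simulate | extract | calibrate | lod | qc | compare | run`):

```sh
imsquant run --seed 1 --out report/
```

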