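# Methods

## Response model

The IMS channel is modelled as a single-analyte, two-step equilibrium
under radioactive atmospheric-pressure chemical ionization: reactant ions
(intensity `R₀`) protonate analyte molecules to monomers with association
strength `α` (per ng/tube), and monomers bind a second neutral to form
proton-bound dimers with strength `β`. Solving the mass balance gives

```
q = 1 + αc + αβc²,   M = αcR₀/q,   D = αβc²R₀/q,   R_free = R₀/q.
```

`R_free` is computed as `R₀ − M − D` so the charge balance holds at
machine precision. The model reproduces the qualitative behaviours the
analysis depends on — a split monomer/dimer signal, a unique interior
monomer maximum at `c* = 1/√(αβ)`, RIP depletion, and saturation of the
summed signal at `R₀` — with the fewest parameters that can do so.
Trimers, higher oligomers, humidity and temperature effects on drift time
are deliberately out of scope.

Assumptions worth keeping in mind: ionization is single-analyte (no
charge competition between co-eluting compounds; the generator places
compounds at separated retention times), and the equilibrium is
instantaneous relative to the chromatographic timescale.

## Synthetic chromatograms

Peaks are separable Gaussians in retention time (s) and RIP-relative
drift time (dimensionless, RIP at 1.0; dimers drift slower than
monomers). The RIP is a ridge at drift 1.0 whose amplitude is locally
depleted across each compound's retention profile, so each retention
slice conserves charge — matching how GC pre-separation delivers analytes
to the ionization region sequentially. Additive baseline plus Gaussian
noise comes last; intensities are clipped to `[0, ceiling]`.

Defaults, chosen once as a realistic desk-scale instrument and not
revisited:

| parameter | default | rationale |
|---|---|---|
| grid | retention 0–2400 s @ 2 s, drift 0.9–2.2 @ 0.005 | covers the compound set; ~0.3 M cells renders in milliseconds |
| `R₀` | 6 a.u. | puts a 10 ng/tube ketone's monomer+dimer sum near 5 a.u. |
| ceiling | 15 a.u. | detector saturation well above `R₀` |
| baseline / noise sd | 0.10 / 0.015 a.u. | window-maximum blank amplitude γ ≈ 0.05 a.u. |
| `α` | 1.0 /ng | linear-range knee near 0.3–0.5 ng/tube |
| `β` | 0.01 /ng (low-dimerizing ketone) | the linearization demo regime |
| contaminant `β` | 30 /ng (nonanal, 2-butanone) | blanks show clear monomer **and** dimer peaks |
| nonanal blank level | 0.030 ± 0.005 ng/tube | targets a summed blank height of ≈0.35 ± 0.08 a.u. |
| MS gain / noise | 1 a.u. per ng / 0.3 a.u. | MS LODs land ~1–2 orders of magnitude above IMS |

Blank contamination amounts are drawn from a normal truncated at zero
(negative loadings are unphysical). The MS channel is strictly linear in
amount below a very high ceiling — its role is to contrast a wide-linear
detector with the saturating IMS, not to model mass spectrometry.

What the generator does **not** emulate: retention/drift drift over
months, co-elution and charge competition, oligomer chemistry,
non-Gaussian peak tailing, and vendor file formats. Passing tests
therefore demonstrate that the estimators implement their definitions and
behave correctly on data obeying the stated ion chemistry — not that any
particular real instrument will reproduce specific numbers.

## Extraction conventions

Peak height is the in-window maximum minus a local baseline. The baseline
is the median of the window's border cells (for 1D traces: the median of
the first and last 5% of in-window points); it is robust to the peak
itself provided the window brackets the peak. Argmax ties break to the
smallest retention, then the smallest drift time, making extraction
deterministic. Blank noise γ re-uses the same statistic on a blank, which
means γ deliberately includes contaminant signal when present — the
reason the S/N and blank-statistics methods can disagree on contaminated
compounds. γ is baseline-subtracted before use; heights are never
negative because the maximum dominates the border median.

The RIP used for linearization is read in the same spectrum on a single
retention slice at the analyte apex (a one-row window over drift
0.94–1.06; wide enough that the window median used as the baseline falls
on the off-ridge floor, not the RIP flank). Because `R₀ − AIP = R_free`,
dividing the AIP by this measured, depleted RIP is algebraically
identical to the textbook `AIP/(RIP_blank − AIP)` — the identity is unit
tested — and is what real data provides directly.

## Calibration and linear range

All fits are unweighted ordinary least squares. The linear working range
is found by greedy expansion from the three lowest levels of the
replicate-mean curve, keeping the widest prefix whose fit retains
R² ≥ 0.99 (the default threshold; loose enough that a CIP calibration at
R² ≈ 0.997 passes comfortably, strict enough that the saturating raw
response fails a decade and a half in). The CIP fit is restricted to
amounts below 8 ng/tube and to spectra with at least 5% of the reservoir
surviving, since the normalization diverges as the RIP is consumed.
Calibration series contain only the spiked analyte; tube contamination
enters through the blank statistics, as in practice.

Inversion of an intensity limit to ng/tube uses the fit restricted to the
detected linear range. A limit below the fit intercept yields a negative
amount and is clipped to zero with a flag — this can happen for very
clean compounds whose blank statistics sit below the calibration's
lowest level; the flag, not silence, reports it.

## Detection limits

`k = t₁₋α,ν + t₁₋β,ν` (ν = n−1 blanks) controls the false-positive and
false-negative rates separately; at α = β = 0.05 and n = 12 it is 3.592,
decreasing towards 2·z₀.₉₅ = 3.29 as n grows. The decision threshold that
controls α alone sits at `x̄ + (k/2)·s`; the Monte-Carlo test checks that
fresh blanks exceed it at a rate consistent with α. The LOQ multiplier 10
is the conventional 10% relative-precision requirement. The S/N limits
`1.5γ` and `5γ` follow from `S/N = 2H/γ` at thresholds 3 and 10. No
ordering between the two methods is asserted on synthetic data — they
agree in magnitude, not rank, and the pipeline reports both.

## Quality control

Sample statistics use the n−1 denominator throughout. Control-chart
exceedance is strict and two-sided at ±2·SD (warning) and ±3·SD
(control); no run rules are applied. RSDs are reported per compound ×
quantity × design (repeatability vs intermediate precision).

## Pipeline routing

A compound is calibrated on the monomer+dimer sum when its blanks show
dimer signal: the mean blank dimer-window height must exceed twice the
mean height of a signal-free reference band (drift 2.05–2.15) at the same
retention. Otherwise monomer-only calibration is used. The factor 2
separates a genuine dimer peak from the noise-maximum statistic, which is
common to both windows.

## Problem sizes and determinism

The default campaign is 12 blanks, 18 IMS levels (0.01–100 ng/tube) and
13 MS levels (0.5–1000 ng/tube) in triplicate, and 16 QC replicates at
10 ng/tube — a full run takes a few seconds. All stochastic stages
consume generators seeded from a single integer; identical configurations
and seeds give byte-identical report bundles.

## Known limitations

- The window-maximum statistic carries a positive noise bias (the
  expected maximum of in-window noise, ≈3σ for the default window sizes);
  it inflates blank means and calibration intercepts slightly, exactly as
  it does in instrument software using the same convention.
- Linear-range width depends on the level grid: the greedy scan can only
  stop at a measured level, so the reported decades are quantized.
- The MS noise model is white; real TIC baselines drift and carry
  chemical noise, so synthetic MS detection limits are optimistic in
  structure if not in magnitude.
- LOD/LOQ values in ng/tube from the synthetic campaign characterize the
  generator's configured regimes; they are not predictions for any
  physical instrument.
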