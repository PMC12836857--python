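# Methods

This note records the model behind `slicelogp`, the parameter choices that
matter, what the synthetic data do and do not emulate, and the numerical
conventions of the processing chain.

## 1. Slice-selection geometry

A linear z-gradient *G* (G/cm) makes the Larmor frequency a function of axial
position. A frequency-selective pulse of bandwidth *BW* (Hz) then excites a
slab of thickness

Δz = BW / (γ̄ G),  d = Ω / (γ̄ G)

where Ω is the pulse's frequency offset, d the slab centre relative to the
gradient isocentre (placed at the octanol/water interface, which coincides
with the coil centre), and γ̄ = γ/2π. Positive offsets select the upper
(octanol) phase.

Constants and defaults:

* γ̄(¹⁹F) = 0.94094 × 42.577 = 40.0624 MHz/T, from the ¹⁹F/¹H frequency ratio
  Ξ and the proton value. Any γ̄ in 40.05–40.08 reproduces the same planning
  numbers at 2 significant figures; the constant is a field on `NucleusSpec`
  and fully configurable.
* Maximum gradient g_max = 55.0 G/cm (so 16% → 8.8 G/cm), configurable.
* Shaped-pulse time–bandwidth products: G4 (90°) 7.82, RSnob (180°) 2.332 —
  the standard shape-library values; duration = factor / bandwidth.
* Active coil half-length 9.0 mm by default (≈18 mm active region of a 5 mm
  probe). A plan is valid only when each slice clears the interface
  (|d| − Δz/2 > 0) and stays inside the coil (|d| + Δz/2 ≤ half-length).
  Invalid plans are returned with messages, never raised, so a planner UI can
  show *why* (e.g. 60 ppm offsets at 14.1 T land at 9.6 mm and fail; raising
  the gradient from 16% to 24% restores 6.4 mm).

## 2. Synthetic partitioned samples

`PartitionSample` fixes per-phase concentrations from the declared true
log *P* and exact mass balance: with P = 10^logP,
c_aq = n_total/(v_aq + P v_oct) and c_oct = P c_aq (mol/L for mmol and µL
inputs). The pseudo-2D generator then emulates the sequence
d1–90°–τ–(sel180°/grad)–τ–acquire:

* row amplitude ∝ c_phase × slice volume × n_F × (1 − e^(−d1/T1_phase)) ×
  e^(−2τ/T2_phase) × ns;
* the slice profile is an ideal rectangle, so both slices share one volume
  (thickness × tube cross-section) and geometry cancels in the ratio — the
  same assumption the physical measurement relies on;
* lines are Lorentzian (exponential damping at the phase-specific FWHM), at
  the phase-specific chemical shift, with optional scalar-coupling
  multiplets;
* noise is additive complex white Gaussian in the time domain; after
  co-addition of ns transients the signal scales with ns and the noise with
  √ns;
* a single integer seed expands into independent substreams (one per FID)
  via numpy `SeedSequence` spawn keys — identical seeds give bit-identical
  datasets.

The scout scan is the same signal model without slice selection: both phases
contribute ∝ c_phase × phase volume, over a 490 ppm window centred at
−50 ppm with 2048 complex points.

**Fixture compounds.** The five built-in analytes carry the literature
log *P* values (trifluoroethanol 0.41, hexafluoroisopropanol 1.66,
trifluorotoluene 3.01, 4-fluorophenol 1.77, 1-fluoroethanol −0.68) and
loadings in the 0.013–0.097 mmol / 540 µL range typical of short-acquisition
preparations. Every NMR parameter — shifts, linewidths, T1/T2 — is a
synthetic placeholder chosen to be plausible: shift separations of 2.2–4 ppm
between phases, linewidths 3.0–3.8 Hz (typical of unlocked two-phase
samples), T1 2.4–3.5 s, T2 0.5–0.8 s. Defaults use d1 = 30 s ≥ 5×T1 and
τ = 2 ms, so the relaxation weights agree between phases to ≲0.002 log units.

**Not modelled:** RF pulse physics and slice-profile imperfections,
J-evolution during the echo, chemical exchange between phases, octanol/water
mutual solubility, lock drift and lineshape distortion, receiver/digitizer
effects. Passing tests therefore demonstrate the correctness of the
geometry→simulation→processing chain and its statistical behaviour under
white noise — not robustness to the instrumental artefacts above.

## 3. Processing chain

1. **Fourier.** First FID point halved (flat baseline for a half-sampled
   decay; this scales all integrals by ½, which cancels in every ratio),
   zero-fill ×2, FFT scaled by the dwell time (continuous-FT convention: a
   unit-amplitude damped exponential → unit-integral Lorentzian), descending
   ppm axis about the carrier.
2. **Phasing.** Zero-order only (single-line ¹⁹F spectra; first-order is out
   of scope). The phase is `angle(Σ|s|²s)` over the whole spectrum: for any
   mixture of lines sharing one phase the dispersive component is odd around
   each line and cancels in this moment. This recovers a 37° rotation to
   ~0.01° and, crucially, never keys on a dispersive shoulder the way
   peak-region heuristics can. The *same* rotation is applied to both rows
   (estimated on their sum), so phasing errors cancel in the ratio. Pure
   noise yields a low-confidence warning, never a failure.
3. **Carrier search.** The scout's global magnitude maximum sets o1p. The
   noise level is the Rayleigh-median estimate σ = median(|s|)/√(ln 4); when
   the maximum is below 10σ and fewer than 16 transients were used, the scout
   is reacquired at 16 transients (the automation's weak-sample rule). For
   strong samples the median is dominated by truncation tails of the signal
   itself; this only overestimates σ, making the rule conservative.
4. **Windows.** 1 ppm wide (configurable), auto-centred on the two largest
   maxima of the summed spectrum separated by at least one window width;
   explicit window configuration always wins. Window edges are snapped to
   the grid by bin arithmetic so equal-width windows always cover the same
   number of points. If the two rows' maxima are closer than one window
   width the summed spectrum is declared unresolved: summed-mode
   quantification refuses (directing the user to separate mode or a manual
   displacement), while separate mode centres each window on its own row's
   line.
5. **Integration and SNR.** Uniform-weight (running-sum) integration of the
   real part over the window. SNR is the vendor-style amplitude/(2×RMS) with
   the RMS taken from a signal-free region (auto: a ~1.5 ppm strip at the
   spectrum edge farther from the windows) after linear detrending.
   Measured values above 10⁶ are baseline-limited, not noise-limited, and
   are reported as the 10¹² sentinel; uncertainties are then omitted.
6. **Mode choice and error.** Summed-spectrum integration when its smaller
   peak keeps SNR ≥ 10 (boundary inclusive), separate otherwise; both modes
   are always computed and reported. log P = log₁₀(I_oct/I_aq);
   σ_logP = √(SNR_oct⁻² + SNR_aq⁻²)/ln 10, taking each integral's relative
   error as 1/SNR.

## 4. Numerical and statistical behaviour

* **Exactness.** With equal per-phase relaxation factors and congruent line
  sampling (phase-shift separation an integer number of grid bins — e.g.
  2.5 ppm at td 16384 / 10 ppm / zero-fill ×2), separate-mode processing
  recovers the true log *P* to machine precision; the test suite asserts
  1e-6 across log *P* ∈ [−2, 3].
* **Summed-mode cross-talk.** Each 1 ppm window also collects the other
  line's Lorentzian tail (∝ FWHM/separation²). At a 10³ concentration ratio
  this biases the summed-mode value by a few × 0.01 log units — the physical
  reason separate integration is preferred for very asymmetric partitioning,
  and why the exactness test uses separate mode. Over the standard ensemble
  (all five compounds, summed minor-peak SNR 12–35, 200 runs) summed and
  separate values agree to 0.02 log units on average.
* **Error-model calibration.** The 1/SNR convention is deliberately simple:
  it ignores how much baseline noise a mostly-empty 1 ppm window
  accumulates, which grows relative to 1/SNR as lines get narrower. At the
  fixture linewidths (3–3.8 Hz) the empirical scatter of recovered log *P*
  is 1.2–1.6× the reported σ; below ~2.5 Hz the convention undercounts by
  more than 2×. Users quantifying very narrow lines should widen their
  error bars or narrow the window.
* **Saturation bias.** With d1 below 5×T1 the recovered value is biased by
  exactly log₁₀[(1−e^(−d1/T1_oct))/(1−e^(−d1/T1_aq))]; the pipeline
  reproduces this closed form to 1e-9 (noiseless) and warns whenever T1
  metadata indicates d1 < 5×T1.
* **Problem sizes.** Default acquisitions are 8192 complex points over
  10 ppm, scout scans 2048 points over 490 ppm; campaign statistics use 25
  seeds per compound (recovery means) and 200 runs (mode agreement) — sizes
  at which each full scout+measure+process cycle takes ~5 ms, keeping whole
  campaigns interactive.

## 5. Known limitations

* Single analyte, one line per phase: no multi-component deconvolution, no
  peak fitting, no reference-compound workflow (the method's point is that
  it is reference-free).
* Zero-order phasing only; magnitude-mode processing exists as a flagged
  fallback but is not used for quantification.
* The Bruker-style dialect covers raw data (`ser`/`acqus`) with the metadata
  the pipeline needs; processed-data files (`1r`, `procs`) and vendor
  automation parameter files are not emulated. Row order is not
  representable in that dialect and is assumed (with a warning) on read.
* ¹H/³¹P variants of the experiment are out of scope; the nucleus registry
  carries ¹H only for field conversions.
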