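# slicelogp

Octanol/water partition coefficients (log *P*) by **slice-selective ¹⁹F NMR**,
as a desk-scale toolkit: plan the spatial-encoding geometry, simulate
partitioned two-phase samples as pseudo-2D ¹⁹F datasets, and process them to a
log *P* value with an SNR-propagated uncertainty.

## Who this is for

log *P* — the base-10 logarithm of a solute's *n*-octanol/water concentration
ratio — is a core physicochemical descriptor in drug discovery, and measuring
it classically (shake-flask plus per-phase assays) is tedious and
contamination-prone. A slice-selective NMR experiment sidesteps the sampling
problem: with the octanol/water interface at the centre of the rf coil, a
frequency-selective pulse applied under a z-gradient excites a thin slab in
*each* phase of a single partitioned sample, and

```
log P = log10( I_oct / I_aq )
```

for the identically scaled ¹⁹F integrals of the two slice spectra — no
reference compound, no phase sampling. This package implements the desk-side
half of that workflow for method development, teaching, and validation:
everything after (and including the planning of) the pulse-sequence geometry,
with a physics-based synthetic data generator standing in for the
spectrometer.

## The model in brief

* **Geometry.** Under a gradient *G*, a selective pulse of bandwidth *BW*
  excites a slab of thickness Δz = *BW* / (γ̄·*G*), positioned at
  d = Ω / (γ̄·*G*) for a pulse offset Ω (γ̄ = γ/2π of ¹⁹F, 40.06 MHz/T).
  Shaped-pulse durations follow from their time–bandwidth products
  (G4 90°: 7.82; RSnob 180°: 2.332).
* **Signal.** The sequence d1–90°–τ–(sel180°/grad)–τ–acquire weights each
  phase's amplitude by c·V_slice·n_F·(1−e^(−d1/T1))·e^(−2τ/T2)·ns; lines are
  Lorentzian; noise is complex white Gaussian scaled √ns.
* **Processing.** A wide scout scan centres the carrier (rescanning at 16
  transients when too weak); the two rows are Fourier processed with a shared
  zero-order phase; 1-ppm windows on the two largest peaks are integrated in
  the summed spectrum, or in the separate spectra when the summed-spectrum
  minor peak drops below SNR 10:1; the uncertainty is
  σ_logP = √(SNR_oct⁻² + SNR_aq⁻²) / ln 10.

## Worked example

Plan the published 9.4 T setup (6 kHz pulses, 16% gradient, ±60 ppm offsets):

```text
$ slicelogp plan --proton-freq 400.13 --gradient-percent 16 --omega-ppm 60
1H frequency / MHz          400.13
19F frequency / MHz         376.50
gradient / G cm-1           8.8 (16%)
pulse bandwidth / Hz        6000
90deg G4 duration / us      1303.33
180deg Rsnob duration / us  388.67
slice thickness / mm        1.70
offset / kHz                +/-22.59
slice position / mm         +/-6.41
valid                       yes
```

The slices are 1.7 mm thick and sit 6.4 mm either side of the interface —
inside the ~9 mm active coil half-length, so the plan is valid. (At 600 MHz
the same offsets land at 9.6 mm and the plan is rejected until the gradient is
raised to 24%.)

Simulate a partitioned 4-fluorophenol sample (true log *P* 1.77) and quantify
it:

```text
$ slicelogp simulate --analyte 4-fluorophenol --seed 11 --noise 7e-3 --out demo/fp
demo/fp.slogp.json
$ slicelogp process demo/fp.slogp.json
log P = 1.782 +/- 0.014  [summed integration, SNR 1964.7 (oct) / 31.2 (aq)]
```

The aqueous-phase peak (the minor one at log *P* > 0) has SNR 31, so the
summed spectrum is integrated; the recovered 1.782 ± 0.014 brackets the true
value. `slicelogp report` tabulates a set of such result records against
literature values, and `--format bruker` writes/reads a Bruker-style
`ser`/`acqus` directory instead of the portable fixture format.

## Layout

| module | role |
| --- | --- |
| `slicelogp.geometry` | slice thickness/position, pulse durations, plan validation |
| `slicelogp.synth` | partitioned-sample model and pseudo-2D FID generator |
| `slicelogp.nmr_io` | Bruker-style directory + portable fixture + result records |
| `slicelogp.processing` | FT, phasing, scout carrier search, integration, SNR, log *P* |
| `slicelogp.automation` | end-to-end scout → simulate → quantify workflows |
| `slicelogp.cli` | `slicelogp plan / simulate / process / report` |

See `docs/methods.md` for assumptions, parameter choices and limitations.
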