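# rodnoise

Analysis of rod-photoreceptor physiology for a WT vs. GARP2-knockout
mouse study, with a synthetic-recording generator so every stage is
testable as a parameter-recovery problem without any raw data download.

GARP2 is a soluble splice variant of the *Cngb1* gene expressed only in
rod photoreceptors and proposed to stabilise the basal (dark) activity
of the phosphodiesterase PDE6. Because basal PDE6 activity sets the
dark turnover rate of cGMP, deleting GARP2 is predicted to change the
*continuous dark noise* of rods — the low-frequency fluctuation of the
dark current — while leaving flash sensitivity and kinetics largely
intact. Testing that prediction requires a small battery of standard
photoreceptor analyses, all implemented here:

* **Hill sensitivity.** Intensity–response relations of flash families
  are fitted with the Hill equation
  `R/R_max = I^n / (I^n + I_0.5^n)`, giving the half-maximal flash
  strength `I_0.5` (R*/rod, or cd·s/m² for ERG) and Hill coefficient `n`.
* **Phototransduction amplification.** The leading edges of a rod flash
  family are fitted jointly ("ensemble fit") with the Lamb–Pugh
  activation model `R(t) = R_max·(1 − exp(−½·Φ·A·(t − t_d)²))`, where
  `Φ` is photoisomerizations per flash, giving one amplification
  constant `A` (s⁻²) per cell.
* **Recovery kinetics.** A single exponential `a·e^(−t/τ)` is fitted to
  the final portion of the average dim-flash response — from the time
  recovery falls to 35% of peak — giving the recovery time constant
  `τ_rec` (ms).
* **Dark-noise band power.** Welch power spectra of a dark epoch and a
  light-saturated epoch (instrumental noise only, all CNG channels
  closed) are subtracted and the difference integrated over 0.6–10 Hz,
  isolating the cellular continuous noise in pA².
* **ROS morphometry.** Rod outer segment length histograms (2 µm bins,
  normalised frequency) are fitted with one- or two-component Gaussians;
  component areas use `area = height·FWHM·√(π/(4 ln 2))`.
* **Group statistics.** Two-way (genotype × age) type-II ANOVA with
  Bonferroni-corrected contrasts, Kruskal–Wallis for noise power,
  unpaired t tests computable from printed summaries, a Z-score outlier
  filter, and mean ± SD (n) table rendering.

The `simulate` module generates flash families, dark recordings, ERG
series and ROS length samples whose ground truth is known (presets carry
the published WT/KO response properties), so each analysis is validated
end-to-end by recovering the generating parameters.

## Worked example

```python
import rodnoise as rn

preset = rn.get_preset("WT", "PM3")
family = rn.generate_flash_family(preset, seed=1)

print(rn.HillModel.from_family(family).fit().summary())
print(rn.LambPughModel(family).fit().summary())
dim = rn.average_dim_flash_response(family)
print(rn.RecoveryModel(dim).fit().summary())
recording = rn.generate_dark_recording(preset, seed=1)
print(rn.analyze_noise(recording).summary())
```

prints

```
Hill intensity-response fit
  I_0.5        19.99
  n            1.241
  R_max        23.97
  ||residual|| 0.595
Lamb-Pugh ensemble (leading-edge) fit
  A (s^-2)     3.715
  t_delay (ms) 2.97
  R_max (pA)   23.67
  flashes      8
  ||residual|| 0.976 (fraction of R_max)
Recovery tail fit (final 35% of peak)
  tau_rec (ms)  352.8
  start index   6141
  amp at start  0.6219 pA
  ||residual||  15.1
Dark-noise spectral subtraction
  band (Hz)                 0.6-10.0
  total band power (pA^2)   0.1883
  instrumental (pA^2)       0.001967
  cellular (pA^2)           0.1864
  segments averaged         23
```

The WT preset generates with `I_0.5 = 20.8` R*/rod, `n = 1.3`,
`R_max = 23.4` pA, `A = 3.8` s⁻², `τ_rec = 251` ms and a cellular band
power of `0.17` pA², so the fitted values above are one noisy cell's
estimates of those truths. Sensitivity and amplification are tightly
determined by a single family; the recovery constant of one noisy cell
scatters widely (352.8 ms here) and only its average across cells
approaches the generating 251 ms — mirroring the large cell-to-cell
spread of recovery constants in real recordings. The dark-noise
pipeline recovers 0.186 pA² for this cell against the generating
0.17 pA², with the instrumental contribution (~0.002 pA²) subtracted
out.

A command-line interface mirrors the library:

```sh
rodnoise simulate flash --preset WT --age PM3 --seed 1 --out fam/
rodnoise analyze flash --in fam/ --out flash.tsv
rodnoise demo --seed 1 --out demo_run/   # full simulate→analyze→report
```

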