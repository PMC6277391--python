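# limnodigest

Quantitative analyses of wood digestion by marine woodborers (*Limnoria*,
"gribble") — the rare animals that live on lignocellulose without gut
microbes. The package implements, as a tested and reusable pipeline, the four
measurement chains with which that digestive strategy is quantified, each
driven by a synthetic-data generator that emulates the experimental design so
every stage is verifiable by parameter recovery:

1. **Biomass mass balance and fractionation.** Per-batch mass loss during gut
   passage, `100·(ingested − feces)/ingested`; acetyl-bromide-soluble lignin
   (ABSL, extinction coefficient 18.21 L g⁻¹ cm⁻¹); the three-fraction split
   into ABSL lignin, TFA-soluble hemicellulose and H₂SO₄-soluble cellulose;
   HPAEC monosaccharide quantification against linear calibration standards;
   and fecal fractions rescaled to `100 − loss` (e.g. 78% at 22% loss) before
   computing per-fraction digestion deltas.
2. **emPAI label-free proteomics.** In-silico tryptic digestion (cleave after
   K/R, not before P, ≤2 missed cleavages), observable peptides counted in the
   instrument's neutral-mass window, `emPAI = 10^(observed/observable) − 1`,
   molar percentages per compartment × replicate, the identification filters
   (expect ≤ 0.05; ≥2 distinct peptides), cross-organ replicate normalization,
   GH-family shares and fluid-versus-tissue contrasts.
3. **CPMG relaxometry.** Regularized non-negative least squares as a numerical
   inverse Laplace transform of multiexponential echo decays,
   `s(t) = Σ f(T2)·exp(−t/T2)`; deconvolution of the T2 distribution into
   Gaussian components on the log₁₀(T2) axis with relative areas
   `A = √(2π)·a·c` and first-order error propagation; BIC component-count
   selection scored against the measured decay; the fast-diffusion pore map
   `1/T2 = ρ·(S/V) = 2ρ/r`; and the ssNMR normalize-to-region / difference
   spectrum utilities.
4. **Thermal shift.** Five-parameter-sigmoid melt-curve fits,
   `y(T) = L + (U−L)/(1+e^{−k(T−m)})^d`, with the melting temperature Tm
   reported as the half-transition midpoint, and condition-to-condition Tm
   shifts with quadrature errors.

## Layout

```
src/limnodigest/     library: synth, composition, proteomics, relaxometry,
                     spectra, thermal, io, config, demo, cli
analysis/            numbered drivers: 01 simulate, 02 mass balance,
                     03 relaxometry, 04 proteome, 05 thermal shift
scripts/acceptance.py  recomputes the headline quantities (below)
tests/               pytest suite incl. parameter-recovery checks
```

## Worked example

`limno demo` (or `python -m limnodigest.cli demo`) generates every synthetic
dataset, runs all four stages, and self-checks recovery against the preset
truths; the numbered drivers do the same step by step. Running

```sh
python analysis/01_simulate_datasets.py --seed 1
python analysis/02_mass_balance.py
```

prints

```
willow: mass loss 22.5 +/- 4.1 % of ingested
         lignin:   -1.5 +/- 6.0 % reduction
  hemicellulose:    2.2 +/- 6.7 % reduction
      cellulose:   50.7 +/- 3.6 % reduction
pine: mass loss 22.5 +/- 4.1 % of ingested
         lignin:    2.5 +/- 4.8 % reduction
  hemicellulose:   19.5 +/- 4.7 % reduction
      cellulose:   39.5 +/- 3.4 % reduction
```

— i.e. the willow scenario loses ~22% of ingested mass, essentially all from
the cellulosic fraction (half of it digested), while pine additionally loses
~20% of its hemicellulose; the generator's true values (22%, 50%, 40%, 20%)
are recovered within sampling error. The later drivers report the
pore-population shift toward smaller pores after hemocyanin treatment
(`03_relaxometry.py`), the GH7+GH9 majority among gut-fluid glycosyl
hydrolases and the hemocyanin fluid-over-tissue enrichment
(`04_proteome_quant.py`), and the Tm ladder 70 °C (native/buffer) → 65 °C
(seawater) → 53 °C (copper chelator) (`05_thermal_shift.py`).

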