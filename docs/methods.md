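# Methods

This note documents the models implemented in `limnodigest`, the parameter
choices behind the synthetic-data presets, the numerical decisions that were
genuinely open, and what the passing tests do and do not establish about real
data.

## Synthetic-data generators

All generators are pure functions of `(inputs, seed)` — there is no global
RNG state, and every workflow derives per-stage substreams from one master
seed (`config.stage_seed`). The presets encode the experimental conditions
the analyses are built around; they are fixed study conditions, not tuning
knobs.

### Feeding experiments and composition

A `DigestionScenario` holds a wood composition (lignin / TFA-soluble
hemicellulose / H₂SO₄-soluble cellulose fractions summing to 1) and a
per-fraction consumption vector; the overall mass-loss fraction is their
weighted sum, enforced as an identity at construction so an inconsistent mass
budget is an error, never silently clipped.

* **Willow** (hardwood): composition 0.26 / 0.30 / 0.44 with cellulose
  consumption 0.50 and no lignin or hemicellulose consumption, giving exactly
  22% overall loss concentrated in the cellulosic fraction — half the
  cellulose digested. The composition is typical of willow sapwood rounded to
  values that make the 22% identity exact.
* **Scots pine** (softwood): composition 0.32 / 0.26 / 0.42 with consumption
  0 / 0.20 / 0.40 — the cellulosic fraction reduced by 40% and the
  hemicellulosic by 20%, again 22% overall.

Per-batch masses are a 150 mg stick of which ~20% is ingested over the
feeding period; fecal mass has expectation `ingested × (1 − loss)`. All
masses carry multiplicative log-normal noise with unit mean at the scenario
CV (default 0.05 — masses are positive, and a few percent is a realistic
gravimetric replicate spread). Composition samples are 3.5 mg milled
aliquots. Sugar makeups (nine monosaccharides) reflect hardwood
glucuronoxylan-type versus softwood galactoglucomannan-type hemicellulose;
sugars are consumed uniformly within their fraction — a simplification: the
generator does not emulate sugar-selective digestion within a fraction, so
per-sugar deltas test plumbing, not selectivity.

The mass-loss group summary defaults to the mean of per-batch ratios (with
SD), matching per-sample mean ± SD reporting; a pooled-ratio alternative is
provided. Fecal normalization defaults to the measured pooled loss
(equivalently the 22% constant for the presets); both options exist.

### CPMG decays

The forward model evaluates a log-Gaussian mixture on the inversion grid,
converts it to unit-sum point masses (so the noiseless extrapolate S(0) = 1;
the echo grid itself starts at t = TE, the first echo), and sums
`f_j·exp(−t/T2_j)` over 50,000 echoes at TE = 70 µs. SNR is defined as max
signal amplitude over noise SD — the definition is a package convention,
documented so the 199 (control) and 367 (treated) presets are reproducible.
The default test-sized acquisition keeps the first 4,096 echoes; the full
50,000 sit behind a `full_length` flag. Pore-population truths place three
components a decade apart (≈1, 10, 100 ms; widths 0.16–0.20 decades),
mirroring the three interstitial length scales of lignocellulose; the
"treated" preset moves weight into the two lower-T2 populations.

### Proteome evidence

Peptide evidence follows a two-layer model chosen to make the emPAI pipeline
exactly recoverable:

1. **Detectability.** For protein *i* with molar abundance *M_i*, the
   fraction of its observable tryptic peptides that get identified is
   `q_i = min(log10(1 + κ·M_i), 0.95)` with κ = 20 — the response law under
   which `emPAI = 10^q − 1 ≈ κ·M_i`, i.e. proportional to molar amount.
   Randomized rounding of `q_i × observable_i` (rather than a Bernoulli draw
   per peptide) keeps the detected count within one peptide of its
   expectation, so emPAI molar percentages converge to the preset truth as
   sampling depth grows; a naive multinomial-only model would saturate every
   protein's peptide count at high depth and compress emPAI toward equality.
2. **Sampling.** The per-replicate PSM rows (depth 10,000 by default) are
   multinomial over detected peptides with protein weight abundance ×
   detected-peptide count; peptides drawn zero times drop out, so low
   abundance and low depth both limit observed counts, and single-peptide
   proteins occur naturally to exercise the minimum-two-peptides filter.

Expect scores are a mixture with 10% of matches beyond the 0.05 cutoff (the
pre-filter failure rate is a package choice). The default digestome panel
has 20 proteins: three hemocyanins enriched in gut fluid over tissue, nine
GHs with GH7+GH9 at ~65% of GH molar abundance in gut fluid, a trace
ferritin (0.5 mol% in fluid), and structural/other proteins dominating
tissue. Sequences are generated deterministically from the seed with ~11%
K/R so tryptic peptides fall in the observable window.

### Melt curves

The five-parameter logistic evaluated on a 25–95 °C grid (0.5 °C steps) plus
Gaussian noise, default SD 2% of the fluorescence range. Midpoint presets:
native and buffer 70 °C, seawater 65 °C (−5 °C versus buffer), chelator
53 °C (below 55 °C). Defaults use asymmetry d = 1 and slope 0.5 /°C (a
~10 °C transition).

## Relaxometry numerics

* **Grid**: 128 log-spaced T2 points over [10⁻⁵, 10] s (configurable).
  Decays are subsampled log-uniformly to ≤2,048 echoes before inversion —
  multiexponential information lives on a log time scale, so this preserves
  the invertible content of the full acquisition at desk-scale cost.
* **Regularization**: Tikhonov on the amplitudes, solved as NNLS on the
  augmented system `[K; √λ·I]`. With `regularization="auto"` λ is set by the
  discrepancy principle: residual matched to `1.05·σ·√n`, the 5% margin
  because non-negativity alone already pins the unregularized residual near
  the noise floor. If the target is unreachable, it is re-set 5% above the
  achievable residual floor rather than letting λ collapse to zero (which
  would return a spiky, unphysical solution). σ comes from decay metadata
  when known, otherwise from a robust first-difference estimator over the
  later half of the echo train — unlike a tail-variance estimate, it is not
  biased by incomplete decay on short acquisitions.
* **Deconvolution**: Gaussians are fitted in x = log₁₀(T2) (the reported
  pore scales are decade-based), initialized at prominence-ranked local
  maxima (ties to lower T2), bounded least squares, components sorted by
  center; parameter SDs come from the fit covariance.
* **Component-count selection**: residuals of the distribution-domain fit
  are regularization bias, not noise, so a BIC computed there always prefers
  more components. Instead each candidate mixture is refined directly
  against the measured decay through the forward kernel and scored with a
  Gaussian-likelihood BIC in the decay domain, where the residual bottoms
  out at the measurement noise once k reaches the true count. The returned
  parameters remain the distribution-domain fit; the refinement is only the
  selection device.
* **Population comparison** matches components by ascending center and
  differences relative areas with quadrature errors. The surface relaxivity
  ρ is user-supplied with no default — only its order of magnitude is
  constrained by the known length scales, so pore sizes are reported only
  when the caller provides ρ.
* **Degenerate inputs**: an all-zero decay inverts to a zero distribution
  with a `degenerate` flag; deconvolving it is an error.

## Thermal-shift numerics

The 5PL is evaluated in log-space (`exp(−d·log1p(e^u))`) to avoid overflow at
steep slopes. Fits run from three deterministic starts — asymptotes from
smoothed extrema, midpoint from the smoothed half-range crossing or the
steepest-gradient temperature, slope from a range/width heuristic with sign
detection (decreasing curves fit with k < 0), d = 1 — and the best RMSE
wins. Tm is solved as the half-transition crossing, which has the closed
form `m − ln(2^{1/d} − 1)/k` and coincides with m when d = 1; its SD is
propagated numerically from the (m, k, d) covariance. Constant fluorescence
is rejected; a Tm outside the data range is flagged extrapolated. Truncation
of the post-peak quench region is available behind the fitting interface by
slicing the curve; the full grid is the default.

## emPAI details

Observable peptides are fully tryptic (0 missed cleavages, per the index's
definition) with monoisotopic mass inside [747.99, 7494.96] Da — the neutral
window implied by m/z 375–1500 at charges 2–5, `m/z·z − z·1.00728`;
configurable, since the acquisition software's internal definition is not
recoverable. Peptide masses include fixed carbamidomethyl-C (+57.02146 Da).
"Peptide matches" count distinct peptide sequences, not PSMs. Shared
peptides count toward every matching protein. Replicate normalization
rescales each replicate so its cross-organ total equals the across-replicate
mean; molar percentages are invariant to any per-replicate loading factor.

## What the tests show — and don't

Every stage is validated by recovering generator parameters at the preset
conditions (fixed seeds; multi-seed averages where single runs are noisy)
plus analytic identities of the printed formulas. The generators emulate the
statistical structure of the measurements — multiplicative mass noise,
multiexponential decays with white noise, peptide sampling with an
emPAI-consistent response, sigmoid melts — not their physics or chemistry.
Passing tests therefore demonstrate that the analysis chain is correct and
well-conditioned at realistic noise levels; they do not validate hydrolysis
chemistry, chromatographic peak integration, spectral acquisition, or any
biological claim about real samples. Problem sizes are chosen for desk-scale
runs: 4,096-echo decays (the full 50,000 behind a flag), proteome depth 10⁴
(10⁵ in the convergence check), 10 feeding batches, and 20-seed repetitions
for stochastic recovery checks.

## Known limitations

* The ILT is ill-posed; recovered distributions depend on λ, and relative
  areas carry a few percent of regularization bias at SNR ≈ 200 (the
  recovery tests budget ±0.05).
* BIC selection assumes white Gaussian noise in the decay; strongly
  correlated noise would require a generalized criterion.
* The emPAI response law is an idealization; real ionization efficiency
  varies per peptide, so real-data molar percentages are semi-quantitative
  in a way the generator does not reproduce.
* Fractionation arithmetic treats the three-fraction split as exhaustive;
  extractives and ash are outside the mass budget.
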