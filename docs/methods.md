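# Methods

## Quantification model

The pipeline's core assumption is the QconCAT calibration identity: a
construct of concatenated proteotypic peptides carries every peptide at
exactly the construct's molar amount, so a spike of `m` ng of a
construct of molecular weight `MW` adds `m / MW · 10⁶` fmol of every
heavy peptide to the digest. One quantification value is one
(peptide, spike level, replicate) triple,

    fmol/µg = (A_light / A_heavy) · spike_fmol / sample_µg,

and the per-protein estimate is the median over the pooled values of all
the protein's Q-peptides. The median is robust to the occasional
interference-inflated ratio and to peptide-level biases (incomplete
release of a particular peptide shifts only that peptide's values). The
ratio cancels the peptide-specific response factor because the heavy and
light species are chemically identical apart from ¹⁵N content; this
cancellation is the reason equimolar construct peptides can show XIC
areas spanning two orders of magnitude (up to ~370-fold) without
affecting the result, and it is asserted directly by the noiseless
round-trip test.

### ¹⁵N labeling

Heavy peptides are modeled by a deterministic centroid shift:
`light + n_N · 0.9970349 Da · efficiency`, with the ¹⁵N–¹⁴N mass
difference fixed at 0.9970349 Da and a default labeling efficiency of
0.9939. At that efficiency the probability that a peptide with N ≥ 8
nitrogens is entirely light is (1−0.9939)^N < 10⁻¹⁷, so no isotopologue
bookkeeping is needed at the area level; the binomial distribution is
exposed as `isotopologue_distribution` for diagnostics only. An optional
correction divides the heavy area by `1 − (1−eff)^N`; at default
efficiency it is numerically a no-op and it is off by default.

### Ratio filter

Observed n per peptide varies in real data (8–24 of a possible 24),
without a published censoring rule. The pipeline censors observations
whose light/heavy ratio falls outside a configurable window, default
[0.05, 20], chosen so both channels stay within a plausible quantifiable
dynamic range while high-abundance targets (ratio ≈ 100 at the lowest
spike) retain their mid-to-high spike observations. Censoring is logged,
never an error, and on noiseless data it provably leaves the estimate
unchanged as long as one value survives. We make no claim that this
window reproduces the published per-peptide n values.

## Synthetic-data generator

`simulate_ground_truth` draws a proteome of 12 proteins with log-uniform
abundances over 10–1300 fmol/µg (the ~128-fold span of the CBC panel,
≈0.3–36 amol/cell at 27.6 pg protein per cell), 2–3 peptides per
protein, and log-normal response factors with σ = 1.7 (wide enough that
a ~30-peptide construct's max/min spread can reach the observed
~370-fold). `simulate_xic_table` then emits one area pair per (peptide,
spike, replicate):

    light = abundance · sample_µg · RF · ε₁      heavy = spike_fmol · RF · ε₂

with independent multiplicative log-normal noise of unit median and
CV 0.2 by default, and observations dropped independently with
probability 1 − detection (default detection 0.85, mimicking the 8–24
n range). Unit-median noise makes the median estimator unbiased by
construction. The spike design follows the study: replicates 1–3 receive
12.5/25/50/100 ng, replicates 4–6 25/50/100/200 ng, into 20 µg of total
protein.

What the generator does *not* emulate: chromatographic interference,
charge states, saturation of the detector, retention-time drift,
correlated noise between spike levels of one replicate, or digestion
variability. Passing recovery tests therefore demonstrate the
correctness of the estimator arithmetic and its robustness to
multiplicative noise and missingness — not robustness to every failure
mode of real LC-MS data.

## Cellular context

Conversions use a cell model with three constants: 27.6 pg protein per
cell (strain-specific; the value for the UVM4 strain — cell-wall
deficient strains can differ by ~1.3-fold), 270 fL cell volume
(1 µm³ = 1 fL), and a chloroplast fraction of 0.5. Applying exactly 0.5
reproduces the published chloroplast molarities from the published
per-cell amounts within rounding, which supports that choice. Mass
fractions require mature-chain molecular weights (transit peptide
removed); real mature sequences are not packaged, so a synthetic FASTA
ships whose chains are generated to match the molecular weights implied
by the published per-cell amounts and mass fractions (back-computed as
`pct · 27.6 pg / amol`). The file and its loader are explicitly labeled
synthetic; users with real mature sequences can override per protein.

## Comparative statistics

Strain-vs-recipient comparisons operate on replicate-level abundances
(per-replicate medians). For each protein, every transformant is
compared to the recipient with a two-sided pooled-variance t-test and
Holm step-down adjustment within the protein, flagged at α = 0.01; log2
fold changes use group means (mean vs median is configurable — the
choice is not determined by the source material). Degenerate
zero-variance identical groups yield p = 1.

Dunnett's many-to-one procedure is implemented by Monte-Carlo
simulation of the null maximum |T|: group means at their actual
per-group precisions, pooled variance as χ²(N−k−1)/df, 50,000 draws by
default (standard error of an adjusted p near 0.05 is ~0.001; the
acceptance calibration uses 10⁶ draws). This reproduces the many-to-one
correlation structure for equal or unequal group sizes without critical-
value tables, at the cost of Monte-Carlo noise; `scipy.stats.dunnett`
serves as an independent oracle in the tests.

Cross-method folds are raw ratios (`a/b`, numerator chosen by the
comparison's convention) rounded only at reporting time, so
`fold(a,b)·fold(b,a) = 1` holds exactly.

## Occupancy analysis

Binding-site concentration defaults to one site per catalytic subunit,
so it equals the subunit's chloroplast concentration; for oligomeric
enzymes this convention leaves site molarity unchanged (n-mer of n
subunits: n× sites per complex, 1/n× complexes). It reproduces the
published fold arithmetic and is configurable via
`binding_sites_per_subunit`. Substrate-per-binding-site folds are
classified with left-closed thresholds: fold < 1 "below-sites",
1 ≤ fold < 4.5 "near-sites", ≥ 4.5 "excess". The packaged reaction map
lists substrates per CBC enzyme and adds product-side records for the
readily reversible steps (TPI, FBA/SBA, TRK, RPI, RPE). Metabolite
concentrations are inputs; the packaged table is synthetic — three
entries (GAP 32.6, E4P 40.0, Ru5P 56.3 µM) are back-computed as the
midpoints of the intervals consistent with all published folds
simultaneously, the rest are plausible placeholders for structural
tests.

## Numerical choices and degenerate inputs

- Residue masses (monoisotopic and average), nitrogen counts and
  chromophore flags ship as a CSV; peptide masses add one water. The
  trypsin rule is cleave-after-K/R-not-before-P, with missed cleavages
  formed by merging adjacent fragments.
- Sequences outside the 20 canonical residues are rejected with the
  offending character and position; empty sequences, non-positive
  molecular weights, non-increasing spike series and out-of-range
  probabilities all raise before any computation.
- XIC integration is the trapezoidal rule over the requested window
  (two-sample minimum); the Gaussian elution simulator is sampled over
  ±6σ so the trapezoid recovers the nominal area to <0.1% at ≥10 samples
  per σ.
- The synthetic mature-chain generator fills a sequence greedily, closes
  with the best residue pair and refines by single-residue swaps with
  random restarts, landing within ~0.02 Da of the target average mass.
- All simulation randomness flows through `numpy.random.default_rng`
  seeded from the config; CSV outputs carry a version/config-hash/seed
  header and regenerate byte-identically.

## Problem sizes

The default simulated experiment is the study-sized design (12 proteins,
~30 peptides, 4 spike levels, 6 replicates ≈ 700 observations). The
stochastic recovery check runs 20 such seeds; the Dunnett calibration
uses 10⁶ null draws for the critical value and 10⁴ simulated families.
These sizes keep every result stable at the tolerances tested while the
entire suite runs in well under a minute.

## Known limitations

- The pipeline consumes XIC areas; peak detection, deconvolution and
  retention-time alignment are upstream concerns and out of scope.
- Ionization-propensity ranks/scores are accepted as input columns only.
- emPAI and iBAQ values are consumed from tables, never recomputed from
  spectra.
- The censoring window is a modeling choice; per-peptide n values from
  real data are not reproduced.
- Mature-chain molecular weights are only as good as the packaged
  synthetic stand-ins unless real sequences are supplied.
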