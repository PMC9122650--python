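# Methods

## The assays and their metrics

Three quantitative readouts of sensory-cilium integrity and function are
integrated per strain. Dye filling scores each worm by the number of
phasmid (tail) neuron cell bodies (0–4) that take up lipophilic dye through
environmentally exposed cilia; the assay average is the mean number of
filled neurons per worm, and the population is also reported as the
proportion vector over 0..4 (the stacked-bar representation). Roaming
counts the squares of a 5×5 mm grid a single worm enters on a food lawn in
20 h; each worm's count is divided by the wild-type (N2) mean of its own
biological replicate, so day-to-day activity differences cancel, and the
assay average is the mean normalized value. Chemotaxis is a population
assay: each plate of 50–300 worms is scored by the index *(b − c)/n*
(worms in the benzaldehyde zone minus worms in the ethanol zone over the
plate total), and plates — not worms — are the statistical unit.

For roaming the per-replicate normalizer is the wild-type **mean** (the
choice between mean and median is genuinely open; the mean is the simpler
estimator and matches the normal-theory summaries used downstream).

## The integrated score and classification

Each assay average is divided by the positive-control
(`mks-3(+); nphp-4(Δ)`) average and capped at 1.0; the three components are
summed with equal weighting into a score on [0, 3]. The control against
itself is exactly 3.0. Classification is *pathogenic* iff score < 2.5, with
the strict inequality making a score of exactly 2.5 benign. Two floors are
applied before normalization: a negative chemotaxis mean (a
worse-than-random strain) is clamped to 0, since a component below 0 would
let one assay subtract evidence from the others, and the [0, 1] per-assay
range implies a floor. The roaming component is two-stage: per-replicate
N2 normalization first, then division by the control strain's mean
normalized value.

## Statistical battery

A Shapiro–Wilk gate (per group, all-groups-pass criterion) routes data to
the parametric or nonparametric branch. The assays map to: dye fill →
Kruskal–Wallis + Schaich–Hammerle; roaming → Kruskal–Wallis + Dunn;
chemotaxis and GFP quantification → one-way ANOVA + Tukey HSD. Stars are
\*, \*\*, \*\*\* at p < 0.05, 0.01, 0.001.

Kruskal–Wallis uses global mid-ranks and the tie-correction divisor
1 − Σ(t³ − t)/(N³ − N); identical-everywhere data make the divisor 0 and
raise a degenerate-input error. Dunn's z for pair (i, j) is the rank-mean
difference over √{[N(N+1)/12 − Σ(t³−t)/(12(N−1))](1/nᵢ + 1/nⱼ)} with
two-sided normal p-values; the default multiplicity adjustment is
Bonferroni (the conservative convention; Holm and others are available via
the `adjustment` argument). The Schaich–Hammerle procedure declares pair
(i, j) significant iff |R̄ᵢ − R̄ⱼ| > √{χ²₁₋α,k₋₁ · [N(N+1)/12] ·
(1/nᵢ + 1/nⱼ)}. The classic critical difference uses the untied variance
term N(N+1)/12; because dye-fill data are heavily tied, a tie-corrected
variant (substituting the Dunn variance term) is available behind the
`tie_corrected` flag, off by default. Using the full k−1 df chi-squared
quantile makes the procedure conservative: its familywise error rate under
a k = 4 null simulation stays at or below α (verified in the test suite).

Dunn's normal-approximation p is validated against an exhaustive
permutation oracle on N ≤ 12 instances using the **mid-p** convention
(permutations tied with the observed statistic count half): the rank-mean
statistic is discrete, and mid-p is the standard way to compare its
permutation null against a continuous approximation.

## Synthetic data generator

The generator emulates the statistical structure of the assays, not worm
biology: dye filling is categorical over {0..4}; roaming is negative
binomial (mean m, dispersion k, variance m + m²/k — counts accumulated
over 20 h are overdispersed; k = ∞ gives the Poisson limit used in tests);
chemotaxis is a per-plate trinomial over {benzaldehyde zone, ethanol zone,
elsewhere} with plate population uniform on [50, 300], abstracting the
1.5 cm zone geometry into (p_benz, p_etoh) since trajectories are not
modeled. TZ::GFP images are a flat background plus Gaussian spots (one
transition-zone pair, σ = 3 px, 12 px apart) with known discrete integrals;
there is no PSF/optics model beyond that. Densitometry tables center the
control phospho:unphospho ratio on a basal value and the Wnt5a ratio on
basal × rescue_factor, with multiplicative lognormal noise of a stated CV.

A single master seed expands into per-strain, per-assay substreams (CRC32
tag hashing into a `SeedSequence`), so every generator is bit-reproducible
and panel edits do not cascade into other strains' draws.

### Panel calibration

No raw per-strain distributions are published, so the default panel's
numeric parameters are calibration constants chosen once to reproduce the
published **qualitative** per-strain pattern: robust dye fill
(mean ≈ 3.63/4) for wild-type, control, benign and VUS2/3/7 strains versus
severe defects (≈ 1.1–1.4) for the null, known-pathogenic and VUS1/4/5/6/8
strains; roaming at 90–95% of wild-type for normal strains versus 40% for
defective ones (dispersion 15); chemotaxis zone-probability differences of
0.65 (control), 0.62 (normal), 0.50 (intermediate, VUS3/8), 0.35 (null)
and 0.10 (severe). With these values the null strain's integrated score
lands near 1.4 and VUS3 (robust dye fill and roaming, intermediate
chemotaxis) stays above the 2.5 cutoff, as in the published ranking.
Passing tests on this panel show the pipeline recovers the classes it was
calibrated to separate under realistic sampling noise; they say nothing
about assay repeatability, scorer blinding, or biological replication in
real data.

## Imaging quantification

The TZ::GFP signal of one transition-zone pair is the integrated intensity
in a 40×40 px box around the pair; "increased by one pixel in each
direction" is read as one pixel per side, giving the 42×42 px box whose
42² − 40² = 164 ring pixels estimate the per-pixel background. Corrected
signal = sum₄₀ − 1600 × ring mean, which is exactly 0 on a flat image and
invariant to adding a constant. The ring-mean construction (rather than
the full 42×42 mean) is chosen precisely because it makes the flat-field
case exact. Boxes use 0-based half-open indexing with the nominal center
as the upper-left pixel of the central 2×2 block. Corrected values can be
negative (signal in the ring only); they are retained and flagged. The
localization detection threshold is not prescribed by the protocol; the
default recipe is 3× the SD of corrected totals from signal-free images,
and the threshold is a plain argument everywhere.

## ROR2 induction and GDT

Per replicate, induction% = 100 × (Wnt5a phospho:unphospho ratio)/(control
ratio), reported as replicate mean ± SEM. The β-actin loading
normalization cancels in the ratio; it is applied anyway so the individual
normalized bands remain meaningful for QC. The arithmetic is invariant to
rescaling all of a replicate's band intensities by a common factor.

The GDT score is 1·N(1) + 0.75·N(2) + 0.5·N(4) + 0.25·N(8), divided by
protein length and ×100, where N(x) counts residues with estimated
modelling error < x Å. Taken literally the counts are cumulative and a
perfect model scores 250; the conventional shell reading (each residue
weighted once by its finest satisfied threshold) has maximum 100. Both
modes are implemented; **cumulative is the default**, following the
formula as printed, and the ambiguity is surfaced rather than resolved.

## Numerical and design choices

* Sample sizes default to the protocol scale: 135 worms/strain (dye fill),
  30 (roaming, 3 replicates of 10), 20 chemotaxis plates — and the
  acceptance script runs at exactly these sizes.
* Ranking ties break alphabetically by strain label (deterministic
  reports).
* Probability vectors must sum to 1 within 1e-12; the score equals the
  component sum to the same tolerance.
* Reduced panels are allowed: without N2 the roaming normalizer falls back
  to the reference strain, and single-strain panels skip between-strain
  statistics.

## Known limitations

* The generator does not model worm locomotion, plate geometry, optics, or
  between-replicate biological variance components beyond what the chosen
  families imply; estimates of assay power transfer to real data only to
  the extent those families fit.
* The per-assay components behind the null strain's published summary score
  are not printed anywhere, so the calibration can only be checked
  qualitatively (null below threshold and below all benign strains), not
  against exact component values.
* The Schaich–Hammerle procedure emits significance decisions at a level,
  not p-values; reports carry a decision column instead.
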