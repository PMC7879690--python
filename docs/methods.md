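# Methods

## The statistical model

The screen operates on unreplicated tag-count libraries: one multiplexed
sequencing pool per tissue × time point, each summarized as integer read
counts per contig plus a library total of mapped reads. With no
replicates, dispersion cannot be estimated, so differential expression
between two libraries rests on the exact conditional test for count
pairs (the Audic–Claverie statistic): given `x` reads among `N1` in the
reference library, the count `y` among `N2` in the other library follows,
under equal relative abundance,

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

algebraically the negative-binomial mass NB(size = x+1,
p = N1/(N1+N2)). This arises by placing a flat prior on the unknown
Poisson rate and integrating it out, and it conditions on the library
totals, so no depth normalization is applied before testing.

Numerically, the mass is computed in log-gamma space with a single final
exponentiation, and the tails through the regularized incomplete beta
form of the negative-binomial CDF (`P(Y ≤ k) = I_p(x+1, k+1)`). This
avoids overflow at large counts and is accurate to ~10⁻¹³ relative
against exact integer arithmetic; the direct-summation route is retained
in the test suite as an independent oracle, never as the implementation.
The two-sided p-value is `min(1, 2·min(P_le, P_ge))`; the audit trail
for each call records the direction (`sign(y/N2 − x/N1)`) separately.
With `x = y = 0` the p-value is 1 and the direction `none`: no evidence
by construction.

Multiple testing uses the Bonferroni correction, `min(1, p·m)`. The
family `m` is the number of contigs tested within one pairwise library
comparison; each time-point comparison is adjusted separately. `m` may be
set larger (e.g. contigs × comparisons) for sensitivity analysis, never
smaller than the number of tests.

## The four-stage screen

* **Stage 1 (ethylene response).** Each treated time point of the
  ripe-fruit AZ series (default 3, 6, 9, 12 h) is tested against the 0 h
  control; a contig is a DEG when adjusted p ≤ α (default 0.01) at
  ≥ `min_timepoints` (default 1) time points. A missing design cell is an
  error, never an imputed zero — silent zero-filling would corrupt the
  screen.
* **Stage 2 (spatial specificity).** At each shared time point (0, 3, 6,
  9 h — the comparator series stop at 9 h; the 12 h ripe-AZ library
  serves stage 1 only), a DEG is compared against the immature-fruit AZ
  and the ripe-fruit pedicel. It survives when significant versus
  **both** at the same time point and, by default, in the same
  direction: a gene higher than one comparator but lower than the other
  is not tissue-specific. The Bonferroni family here is the number of
  DEGs tested.
* **Stage 3 (natural profiles).** The field series of the AZ (30, 120,
  160 days after pollination) is expressed in RPKM,
  `count · 10⁹ / (length_bp · total)`. Ethylene-arm profiles, which come
  without transcript lengths, use counts per million instead; the
  conditional test needs neither.
* **Stage 4 (concordance).** The ethylene direction of each candidate
  comes from rule-based classification of its 5-point ripe-AZ profile:
  A (non-decreasing, ends above start) → up; D (non-increasing, ends
  below start) → down; B/C (strict 3 h or 6 h peak) and unclassifiable
  shapes → transient. The natural direction is `up` when
  `RPKM(160) + ε ≥ f·(max(RPKM(30), RPKM(120)) + ε)`, `down` under the
  mirrored condition, else `flat`, with fold threshold `f = 2` and
  pseudo-floor `ε = 0.1` RPKM to keep zero counts from producing 0/0 or
  infinite ratios. Sustained candidates enter the final up/down sets when
  ethylene and natural directions agree; transient candidates only when
  the natural direction is non-flat and matches the sign of their net
  0 h → last-time-point change. The qualitative requirement that
  profiles be "comparable" across the two contexts has no canonical
  quantitative form; the fold rule is this package's explicit,
  parameterized operationalization. Candidates absent from the natural
  table are logged as
  unresolvable and excluded rather than guessed.

The funnel is nested by construction (final ⊆ stage 2 ⊆ stage 1) and the
whole run is deterministic: identical inputs and configuration produce
byte-identical TSV reports (sets are written sorted, floats with fixed
formatting).

## Profile clustering

DEG time-course profiles are grouped by agglomerative clustering with
distance 1 − Pearson correlation and average linkage, the conventional
defaults of classic gene-expression clustering tools. Correlation
distance makes the partition invariant to per-gene affine rescaling, so
the (unknown) choice between raw, log or median-centered profiles cannot
change the result — asserted as a property test rather than guessed.
Zero-variance profiles, for which correlation is undefined, are set
aside in a reject class before clustering and logged. Tied 3 h/6 h peaks
classify as `other` and are logged, not silently broken. Sub-cluster
structure below the four main classes is out of scope.

## qPCR validation arm

Primer efficiency is the least-squares slope of mean Cq versus
log₁₀(relative template amount) over a serial dilution (default 5- to
3125-fold): `E = 10^(−1/slope)`, reported as the amplification factor
per cycle (2.0 = perfect doubling), matching the 1.8–2.0 retention gate,
which is inclusive at both boundaries. A non-negative slope flags an
invalid series. Estimation is invariant to a constant Cq offset (the
intercept is free), so absolute template amounts are not needed.

The opposite-profile check formalizes the non-shedding-genotype
prediction: after peak-normalizing both profiles to 1 (ripe stage last),
an up-regulated gene matches when the non-shedding ripe value is below
`t` times the shedding ripe value (default `t = 0.5`), a down-regulated
gene when it is above the shedding value divided by `t`. The source
study's match call was qualitative; `t` is this package's explicit
stand-in and is configurable. Reference-gene normalization and ΔΔCq
statistics are out of scope — profiles arrive as relative-expression
vectors.

## The synthetic study design

The generator reproduces the design the screen assumes: ethylene series
for AZ150 (0–12 h), AZ30 and P150 (0–9 h), and a natural AZ field series
(30/120/160 DAP) with transcript lengths drawn uniformly on
500–3000 bp. Counts are Poisson(total × proportion) — the sampling model
of the conditional test itself; with unreplicated libraries no
overdispersion is estimable, but a negative-binomial mode (gamma–Poisson
with configurable dispersion) is available for robustness experiments.

Per-gene base abundances π are log-normal across genes with natural-log
parameters μ = ln 10⁻⁵, σ = 1.5 (median 10 expected reads in a 10⁶-read
library, spanning rare to abundant tags). Effects multiply π in the
target cells only:

* `az_specific_up`: ramps linearly from 1× at 0 h to the full fold
  (default 8) at 9 h — the time by which cell separation is complete —
  and plateaus; concordantly high (fold × π) at 160 DAP.
* `az_specific_down`: π parameterizes the low state; the ripe-AZ series
  starts at fold × π and decays to π, and the pre-abscission field
  stages sit at fold × π with 160 DAP at π. (A gene repressed during
  abscission is high in the non-abscising AZ.)
* `az_transient`: triangular peak at 3 h or 6 h (alternating), back to
  baseline within 3 h; flat in the field.
* `shared_responsive`: the up-ramp applied identically in all three
  ethylene series (and high at 160 DAP) — stage 2's target.
* `natural_discordant`: the ripe-AZ up-ramp with a flat field series —
  stage 4's target.
* `null`: flat everywhere.

A per-library background contig absorbs the read mass not assigned to
the planted genes, so expected column sums equal the configured totals
(Poisson concentration within 4√N) without compositionally distorting
the planted genes' proportions. It is labelled `background` in the truth
table and excluded from recovery metrics. Generated tables carry
column-sum totals, the default of the data model. A seed is mandatory;
identical configurations and seeds are byte-identical on disk.

What the generator does **not** emulate: assembly artifacts, mapping
ambiguity, tag-sampling biases, overdispersion beyond the optional NB
mode, and correlated effects across genes. Passing recovery tests
therefore demonstrate the screen's logic and calibration under its own
sampling model, not performance on real libraries.

## Detection floor and the known sensitivity limit

At α = 0.01 with a ~300-contig Bonferroni family, an 8-fold effect is
detectable by the exact test only when the baseline expected count is
roughly 4 reads or more (π ≳ 4·10⁻⁶ of a 10⁶-read library; the same
bound applies to the high state of down-regulated genes). Under the
default log-normal abundance law about a quarter of genes sit below this
floor, which caps recovery sensitivity for planted AZ-specific genes
near 0.75–0.80 at the default depth — measured 0.75 over 20 seeded
replicates (stage 1 alone: 0.80). This is a property of the study
conditions, not an implementation artifact: the same planted effects are
recovered essentially completely at 10⁷-read depth or tighter abundance
spread (see the deep-totals screen test). Exclusion performance does not
share the floor: shared-responsive genes are removed at stage 2 at
~100%, and natural-discordant genes are kept out of the final sets at
~99%.

## Numerical and interface choices

* Problem sizes in the verification suite — a 61 × 61 × 9 exact-test
  grid, 10⁴ null genes, 20 replicate screens of the 300-gene default
  design, 1000 qPCR replicates — were chosen so each check completes in
  seconds while keeping Monte-Carlo error well below the asserted
  margins.
* The noisy qPCR recovery bound (|E − E*| within 0.05 at Cq noise
  SD 0.2) is asserted on the mean absolute error over 1000 replicates;
  individual replicates have SD ≈ 0.02, so a small fraction necessarily
  exceeds 0.05 by chance.
* Library totals default to column sums; an explicit totals file
  overrides them (totals may include reads mapped to contigs filtered
  out upstream) and must be at least the column sums.
* Count tables, sample sheets, lengths, dilution series and all reports
  are plain UTF-8 TSV.
* Multiple-testing procedures other than Bonferroni are deliberately
  absent. Bonferroni controls the family-wise error rate — stricter than
  false-discovery-rate control — which suits a screen whose output is a
  short list of candidates carried into experimental validation.
  Replicate-aware count models are likewise out of scope for
  unreplicated libraries.
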