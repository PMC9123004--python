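# Methods

This note records the models implemented in `panelprof`, the defaults and
their rationale, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## MSI tract calling (`msi_tract`)

Each mononucleotide tract is defined by a 0-based half-open interval, its
repeat base, a reference length in 13–30 bp, and two flanking seed
anchors of ≥8 bp. Read measurement is seed-based local realignment: both
seeds are located in the read by exact string match and the repeat
segment between them is measured; the indel offset is segment length
minus reference length. Eligibility requires, in order: locatable seeds;
the tract >8 bases inside both read ends; |offset| ≤ 12 bp; no
single-base change inside the realigned repeat segment (checked on the
segment only, not the whole read); MAPQ exactly 60 (the aligner's
maximum; configurable); and ≤20 soft-clipped bases. The first failed
criterion is recorded as the rejection reason.

The error-corrected length histogram counts *distinct fragments*, where
fragment identity is (alignment start, alignment end, indel offset) —
coordinate-based because the input carries no molecular barcodes.
Re-adding a duplicate fragment therefore never changes the histogram.

Peak finding: offset L is an allele iff its count strictly exceeds the
counts at L±1 and L±2 (absent offsets count 0 — the ±1 neighbours must be
covered for the ±2 rule to be meaningful), is >5 distinct fragments
(strict, i.e. ≥6), and is ≥8% of the absolute coverage, defined as the
total distinct eligible fragments at the tract (the only self-contained
denominator). A tie between adjacent counts disqualifies both — the
conservative direction, favouring stability. Only contractions of ≥2 bp
mark instability; insertions never do. A tract with at least one
supported allele is evaluable regardless of whether the reference-length
allele itself was detected. Sample rule: MSI-H iff >10 of the 68 panel
tracts are unstable.

Tract panel selection (a training-time helper) drops tracts with
<20-fragment coverage in more than half the cohort, tracts with more than
one supported allele in any microsatellite-stable sample (germline
polymorphism risk), and tracts whose unstable-call rate differs by <0.30
between classes. The shipped caller is mononucleotide-only, matching the
final panel; di-/trinucleotide discovery exists in `core_io` for panel
design.

## Context signature (`msi_signature`)

Substitutions are folded onto the pyrimidine strand (six classes C>A …
T>G; purine-reference events are reverse-complemented together with their
11-bp window). Per class, triplet probabilities are estimated at the nine
overlapping triplet start offsets (0–8) of the window in an MMR-deficient
and an MMR-proficient catalog, with additive smoothing (default
pseudocount 0.5 per triplet per position, keeping every entry finite) and
class-conditional normalization. The matrix entry is the natural-log
ratio; natural log is the log-odds convention, and any other base would
rescale scores and the fitted boundary jointly. An event's score sums the
nine entries along its window; a sample's signature total is the plain
(unnormalized) sum over substitutions — a per-mutation mean is exposed as
a diagnostic only, since mutation load itself is informative. Windows
containing non-ACGT bases are skipped with a warning.

The proficient training catalog should exclude POLE/POLD1 hypermutators
so the matrices capture context, not load; the generators provide a
POLE-like signature to verify that such samples score negative.

The ensemble boundary is a maximum-margin linear separator (linear-kernel
SVM, C = 10⁶ so separable data is separated exactly; features
standardized internally, weights returned on the raw scale). With one
point per class this reduces to the perpendicular bisector. Samples
within 10% of the training margin (configurable — no principled value
exists) can be relabelled by their deleterious MMR-gene mutation flag
(an input annotation; the package does not curate pathogenicity) before
one refit. Non-separable data yields a soft-margin fit and a warning
naming the violators. A combined score of exactly 0 is called MSS,
favouring specificity.

## TMB (`tmb`)

Eligibility: coding consequence (synonymous, nonsynonymous, splice,
insertion, deletion all count by default — configurable), caller quality
≥ 0.5, observations > 3 (strict), MAF > 0.05 (strict), COSMIC count < 25
(the hotspot definition), every population-database frequency < 1%
(databases are named in the annotation; no printed cutoff exists, 1% is
the conventional common-variant line), and MAF outside the private
germline band [0.40, 0.60] ∪ [0.90, 1.00] (a VAF heuristic; band
configurable). pTMB = n/1.3 Mb. eTMB applies the shipped log-log
regression; pTMB = 0 maps to eTMB = 0 by definition since the power law
is undefined at zero and a mutation-free panel must report zero burden.
`fit_etmb_model` is OLS of log10(exome TMB) on log10(pTMB) and recovers
the shipped coefficients exactly from noise-free points.

Reporting thresholds are tiered: high-evidence variants need ≥4
observations and MAF > 0.4%; all others ≥6 observations and MAF > 5.0%
(the endpoints of the stated 0.4–5.0% range; intermediate tiers are left
configurable). Deleterious BRCA1/BRCA2 variants bypass the germline
exclusion but not the count/MAF thresholds.

Limit of blank: CLSI EP17-A non-parametric 95th percentile — ascending
sort, rank 0.5 + 0.95·n, linear interpolation between bracketing order
statistics, clamped to the observed extremes.

## Panel-size simulation (`panel_sim`)

Panels are assembled by sampling exons without replacement until the
cumulative size first reaches the target; the last exon may overshoot,
and rates use the realized size so the overshoot does not bias the
mutation rate. Mutations with MAF ≥ 10%, nonsynonymous, are counted by
sorted-interval membership (verified against a brute-force scan). The
reference TMB is exome alteration count / 33.4 Mb (configurable).
Correlations are computed per replicate panel and summarized per size by
the median with a 5th–95th band. Population reweighting offers a weighted
mean of per-type correlations and a weighted-resampling pooled mode; the
shipped weights (lung 0.643 … uterine 0.051) sum to exactly 1.000.
Constant-TMB cohorts return NaN correlations rather than a silent 0.

## Structural variants (`sv_calls`)

Purity is estimated as min(1, 2 × median somatic MAF) — the
diploid-heterozygous relation, the simplest defensible estimator; it is
documented and swappable, and requires ≥5 usable variants, else purity is
undetermined. Amplification: per-ROI ratio r against the control-panel
mean; copy number CN = (2r − 2(1−p))/p; fold change CN/2; a gene is
amplified when fold > threshold (default 2.0; per-gene thresholds are
configuration inputs, as no printed values exist) in >25% of evaluated
ROIs. Low-coverage ROIs are masked entirely. ROIs whose deviation from
the control mean is insignificant (two-sided z-test at α = 0.01 against
the control dispersion; no test is prescribed) remain in the denominator
but can never count toward amplification — this keeps a perfectly flat
profile a clean "not amplified" rather than a no-call. With undetermined
purity, a gene passing at a hypothetical 20% purity is reported
indeterminate.

Translocations: pairs >2 kb apart, inter-chromosomal, or improper
(orientation-only anomalies under 2 kb included) with MAPQ ≥ 30 are
clustered greedily within a 500 bp breakpoint window (both defaults
configurable; no printed values exist). A cluster is reported when both
breakpoints are in annotated genes, the partners share coding strand
(productive fusion), the pair is absent from the control database, and
support is ≥5 distinct fragments.

## Agreement statistics (`agreement`)

PPA/NPA from 2×2 counts, undefined metrics reported as None, never 0.
Wilson intervals use the continuity-corrected closed form, clamped to
[0, 1] with k = 0 / k = n pinning the corresponding bound. Average
pairwise agreement enumerates all unordered replicate pairs per sample
and averages both directions of each pair, pooling to APA = 2a/(2a+d)
and ANA = 2c/(2c+d). Variance components use method-of-moments on the
nested design (site ⊃ operator ⊃ day ⊃ replicate; an instrument factor
can be inserted) — closed-form and dependency-light, adequate at these
design sizes; negative moment estimates truncate to 0, single-level
factors are inestimable (NaN), and each CV is 100·σ/mean. Reports round
to one decimal; machine outputs keep full precision.

## Synthetic data (`synth`)

`simulate_tract_reads` plants a contraction in a fraction
purity × unstable-fraction of fragments, applies symmetric ±1 bp
geometric-style stutter (real PCR stutter is deletion-biased; the bias is
configurable — the symmetric default is the simplest model that exercises
the peak finder's error correction), and varies flank lengths so fragment
identities differ. It does not model base-level sequencing error, FFPE
deamination, or mapping artifacts, so passing tests demonstrate the
length-distribution logic, not robustness to those error modes.

`simulate_mutation_catalog` draws window bases i.i.d. from a
per-signature base distribution and the class from a per-signature mix,
making every triplet probability (and hence every trained PWM entry)
analytically known. Real mutational signatures have position-dependent
context structure that this independence assumption flattens.

`simulate_tumor_cohort` draws cancer types from the shipped metastatic
weights, per-type log-normal TMB (median 4 mutations/Mb, 0.6 dex spread,
lung/melanoma medians doubled — a realistic pan-cancer spread with
hypermutators up to ~100 mutations/Mb), Poisson mutation counts, uniform
exonic positions, and uniform MAFs on [0.1, 0.9]. The dilution and
panel-size studies in `scripts/acceptance.py` use these defaults at
4,000 tumors and at 68 tracts × 500 fragments × 10 replicates × 5 purity
levels respectively — problem sizes chosen to exercise the full pipelines
at single-CPU scale while keeping sampling noise well inside the margins
being tested.

`simulate_coverage_profiles` draws control ROIs log-normal around 1 and
scales amplified-gene ROIs by the purity mixture (p·CN + 2(1−p))/2, so
the caller's CN inversion can be checked exactly.

## Known limitations

- The realignment is exact-match on seeds; mismatches within a seed drop
  the read rather than tolerating them.
- The boundary refit performs a single relabeling pass, not an iterative
  self-training loop.
- Variance components assume a (near-)balanced nested design; strongly
  unbalanced designs would need REML.
- The PWM assumes class-conditional matrices with no shared background;
  scores across classes are therefore comparable only through the
  training data.
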