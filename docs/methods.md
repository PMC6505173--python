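# Methods

This note documents the statistical model, the parameter choices, the
synthetic-data generator, and the numerical and design decisions behind
`doqc`, in enough detail to reproduce or audit any of its outputs.

## Data model and recoding

Genotypes are biallelic SNP calls in {AA, AB, BB, missing}, held as int8
codes. Raw nucleotide data are recoded so that allele **A is the allele
most frequent among the eight founder strains**, with ties broken
alphabetically by nucleotide — a deterministic stand-in for an arbitrary
assignment, chosen so that identical inputs always produce identical
outputs. Markers with more than two alleles across founders and samples
are excluded and reported; founder-monomorphic markers are flagged
non-informative and dropped from all founder-based diagnostics.
Heterozygous founder calls (impossible in fully inbred strains, but
present in real data as genotyping artifacts) are treated as missing and
counted. The major-allele count is taken among non-missing founders only.

Each informative marker gets a founder **MAF class** — the minor-allele
count among the eight founders (1/8 … 4/8) — computed only where all
eight founder calls are present; markers with any missing founder call
are "incomplete" and excluded from frequency diagnostics and from the
3-state collapse (their SNP-genotype posteriors are flagged partial).

## Map function

The Carter–Falconer map function `d(r) = 25·[atanh(2r) + atan(2r)]`
(strong positive interference) converts between genetic distance and
recombination fraction. The closed form runs distance-ward; the
recombination-ward direction is bracketed root finding (Brent) on
[0, 0.5), tolerance 1e-12 in r — robustness was preferred over speed
because the inversion runs once per marker interval at setup. Distances
beyond the representable range saturate toward r = 0.5. Zero-length
intervals (co-located markers) are floored at r = 1e-8 so transition
matrices stay irreducible. Note the direction of the interference
effect: at a given distance the Carter–Falconer fraction is *larger*
than Haldane's (100·r ≤ d_CF(r) ≤ d_Haldane(r)); the test suite asserts
this ordering.

## Diplotype hidden Markov model

**State space.** 36 unordered founder pairs, ordered lower-triangle
row-wise (AA, AB, BB, AC, BC, CC, …, HH). All serialization uses state
labels, never bare indices. The initial/stationary distribution is
uniform over *ordered* pairs: 1/64 per homozygote, 2/64 per heterozygote.

**Transitions.** Each haplotype is an exchangeable-founder exponential
mosaic: exchange points at density `a = n_gen_eff · 8/7` per Morgan,
founder redrawn uniformly (self allowed) at each exchange, so visible
switches occur at `n_gen_eff` per Morgan. The two haplotypes are
independent (random outbred mating, autosomes only); ordered-pair
products are collapsed to the 36 unordered states. This single-parameter
kernel is a deliberate approximation to full multiparent-pedigree
transition probabilities: it is self-contained, exactly matched by the
simulator, and asymptotically equivalent on dense maps. Marker distances
pass through the configured map function (d → r, floored, → effective d)
before entering the kernel.

**`n_gen_eff` calibration.** Defaults are anchored at 7.6 for
outbreeding generation 8 and 9.0 for generation 11 (linear in
generation between and beyond, floored at 0.5). These anchors were set
by a closed form, not by fitting: with total simulated map length L cM,
the expected visible diploid switch count is `2·L·n_gen_eff/100`, and on
the generator's default genome (1990 cM) the anchors give ≈302 and ≈358
switches — bracketing the average crossover counts reported for DO
cohorts at those generations. The parameter is exposed in
`HmmParams`/`SimConfig`; note that because it is calibrated to *counts
on the default synthetic genome*, applying the same defaults to a map of
different total length changes the genome-wide expectation
proportionally.

**Emissions.** For state (j,k) the true SNP genotype is the founder
allele sum; the observed call matches it with probability 1 − ε and is
each of the two wrong genotypes with probability ε/2 (symmetric 3-state
confusion — the simplest model consistent with a single error rate).
Default ε = 0.002. Missing observations are uninformative (emission 1),
as are states involving a founder whose call is missing at the marker.

**Inference.** Scaled forward–backward with per-marker normalization
constants (no underflow at 10⁴+ markers; the log-likelihood is retained).
Posterior rows sum to 1 within 1e-9 by construction; the implementation
is tested to 1e-10 against brute-force enumeration over all 36ⁿ paths on
toy chromosomes. Transition matrices are cached per unique (interval,
density) pair. An all-missing chromosome returns the stationary
distribution, not an error.

**Calls and summaries.** The max-marginal state is called where its
posterior *strictly* exceeds 0.5, otherwise missing. Crossovers are the
minimal switch count between consecutive non-missing calls per
chromosome (0 / 1 / 2 for identical / one-shared / disjoint founder
pairs), summed over autosomes; gaps of missing calls contribute the
flanking-call distance, which deliberately undercounts double
recombinants hidden in gaps — consistent with a *minimum* count. The
counter is tested against an exhaustive phased dynamic program.

**Error LOD.** Collapsing the 36-state posterior through the founder
alleles gives (p_AA, p_AB, p_BB); with q_y the posterior probability of
the observed genotype,

    LOD = log10[(1 − q_y)/q_y] + log10[(1 − ε)/ε],

clipped to ±12 at degenerate posteriors (a documented ceiling, applied
symmetrically on both sides). Posteriors *include* the focal observation; the
leave-one-out variant was considered and rejected because it flags every
site whose flanking-only support falls below ~0.83, which is far too
aggressive near recombination boundaries. Sites with LOD > 2 count as
likely errors in all error-rate summaries.

## Sample diagnostics

- **Missingness**: fraction of informative markers missing per sample;
  ≥ 20% triggers omission, ≥ 2% an annotation (annotated samples are
  retained).
- **Sex check**: per-marker intensity is the mean of the two channels;
  samples are placed by mean X-marker vs mean Y-marker intensity.
  Thresholds default to midpoints between the nominal-sex group medians
  (single-sex or unlabeled cohorts require user thresholds, else
  everything is "ambiguous"). Classification: high-X/low-Y → XX,
  low-X/high-Y → XY, low/low → XO, high/high → XXY. A mismatch is
  XX/XO inferred for a nominal male or XY/XXY for a nominal female.
  X markers that do not separate the nominal sexes (Welch z < 4 by
  default) are dropped first, mirroring the practice of excluding
  non-dosage-responsive X probes.
- **Duplicates**: proportion of matching calls over markers non-missing
  in both samples, computed for all pairs via one-hot matrix products;
  pairs sharing < 1000 markers are reported unscored. Pairs above 0.90
  are flagged as duplicates — real cohorts show duplicates above 99%
  against a background below ~76%, so the threshold sits in that gap
  with margin. High-missingness samples are excluded before duplicate
  flagging; the second member of each flagged pair is the recommended
  omission (callers may prefer to drop both when labels cannot be
  resolved). Sibling-level sharing is reported, never thresholded.
- **Intensity profiles**: pooled two-channel intensities per sample
  after log10(x+1); the 1st/99th percentiles (linear interpolation
  between order statistics, numpy type-7) plus a binned density table.
- **Genotype frequencies by MAF class**: observed (f_AA, f_AB, f_BB)
  among non-missing calls per class, against the equal-founder-dosage
  expectation ((1−m)², 2m(1−m), m²) at m = class/8. Ternary-plot
  coordinates (x = f_hom_major + f_het/2, y = f_het·√3/2) are exported
  for plotting by the caller.
- **Error rates**: fraction of scored sites with LOD > 2 per sample.

## Marker diagnostics

Computed only on samples surviving sample-level omission (samples first,
then markers — fixed order). Per-marker missingness, error rate among
scored sites (markers with none are NA), and genotype frequencies with
two *advisory* outlier flags drawn from anomalies seen in real DO data:
founder-MAF-1/8 markers whose population MAF exceeds 0.40 (the signature
of strong allele-frequency distortion such as meiotic drive), and
founder-MAF-4/8 markers with heterozygosity below 0.25. Both bounds are
config-exposed and advisory only; they apply to autosomes, because
hemizygous male X calls depress heterozygosity by design. Only the
error-rate rule (> 5%) drives marker omission.

**Cleaning impact.** Omitted markers are masked to missing (not dropped),
so the re-run posterior remains defined at every original marker and the
before/after comparison covers the full sample × marker grid. The change
measure is the sum of absolute posterior differences per site, in
[0, 2]; the summary counts sites above 1 and above 1.5.

**Allele-intensity export.** For any marker, a per-sample table of
(x, y, observed call, predicted call) supports the two-channel scatter
diagnostic; no re-calling or cluster fitting is performed — that
diagnosis is visual by design.

## Synthetic-data generator

The generator emulates: an 8-founder mosaic genome per sample with
generation-dependent switch density (identical kernel to the HMM, so
round-trips are exact model matches); founder alleles with a realistic
MAF-class spectrum (default: binomial(8, ½) conditioned on polymorphism,
i.e. class weights 16:56:112:70); biallelic genotypes from founder
alleles; independent per-call missingness then genotyping errors
(uniform flip to another genotype); engineered bad samples, duplicate
pairs (same mosaic, independent corruption), sex mislabels, XO and XXY
samples; and clustered two-channel intensities with X/Y dosage effects
(X dose 1 for XX/XXY, 0.5 for XY/XO; Y at carrier level or background).
All randomness flows from one seed through per-stage substreams;
identical configurations are bit-identical, including written files.

Default study conditions: 60 samples (20 at generation 8, 40 at
generation 11, mirroring the ~1:2 split of the motivating cohort),
10 autosomes × 200 markers at 1 cM plus 100 X and 30 Y markers,
ε = 0.002, 1% missingness, two high-missingness samples (25% and 55%
missing with elevated error rates), one duplicate pair, one sex
mislabel, one XO, one XXY.

**What it does not emulate** — and hence what passing tests cannot
show about real arrays: crossover interference within the mosaic (the
kernel is Markov; Carter–Falconer enters only at inference),
pedigree-exact DO breeding structure, linkage disequilibrium between
founder alleles at nearby markers, batch effects, intensity-cluster
pathologies (null alleles / extra clusters are only approximated by the
cluster-swap constructions used in tests), and meiotic drive (a biased
transmission option is deliberately absent; the frequency-outlier flags
are validated only for false-positive behaviour on drive-free data).

## Known information limits at desk scale

At the default 1 cM marker spacing with realistic DO switch densities,
the diplotype mosaic changes state roughly every 6 markers while a
random founder pair is distinguished by only ~½ of markers. Switch
boundaries are therefore ambiguous over about one marker, and ~15% of
haplotype segments span ≤ 2 markers. Consequences, measured on the
default cohort with the model matched exactly to the generator (so the
posteriors are Bayes-optimal and perfectly calibrated):

- called-site diplotype accuracy plateaus near 87% (interior accuracy
  is ~98%; nearly all wrong calls are one-founder near-misses adjacent
  to true switches);
- minimal-crossover counts undercount true mosaic switch counts by
  ~30% (short segments go uncalled and merge their flanks);
- error-LOD sensitivity at the LOD > 2 cut is ~40%, because the
  flanking-marker prior against the erroneous genotype is only ~10²
  at this spacing (the false-positive rate stays near 0.1%).

These are properties of the study conditions, not of the
implementation: on arrays with tens of markers per cM — typical of real
mouse genotyping platforms — the same method's implied error fraction
drops to a few per mille and the error LOD regains its sensitivity. The
dense-map regression tests (0.125–0.2 cM spacing) verify exactly that:
≥ 95% state recovery and full sensitivity with a sub-10⁻³ false-positive
rate.

## Pipeline and determinism

Stages run in a fixed order (sample missingness → sex check →
duplicates → intensity profiles → sample genotype frequencies → HMM →
crossovers → error LODs → sample error rates → marker QC → flags →
optional cleaning-impact rerun), each stage's tables written before the
next begins. Sample omission (high missingness + recommended duplicate
drops) is applied between the sample-level and marker-level stages.
Missing intensity data skips the intensity-dependent stages with a
warning and leaves everything else untouched. The pipeline is a pure
function of its inputs: reruns are byte-identical, every threshold
decision is logged with the triggering value, and the summary JSON uses
sorted keys.
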