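# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `tumorpool`. Nothing here states an empirical
result; all numbers quoted as defaults are inputs, and every measured
quantity is produced by the test suite or `scripts/acceptance.py`.

## Detection model

### Hard filters

A candidate somatic site is evaluated per tumor sample against three
thresholds collected in `FilterConfig`:

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 50 reads | minimum per-sample depth for the site to be evaluable |
| `min_alt` | 5 reads | mutant reads required in ≥ 1 tumor sample for the site to be kept |
| `min_corrected_vaf` | 0.05 | minimum purity-corrected VAF per sample |
| `clonal_vaf_threshold` | 0.10 | clonal vs sub-clonal boundary |
| `genotype_alpha` | 0.01 | Poisson rescue significance |
| `loh_alpha` | 0.05 | Fisher LOH significance |

The purity correction divides the observed allele fraction by the
specimen's tumor-cell fraction and clamps at 1 — the standard cellularity
rescaling. VAF exactly at the clonal threshold is assigned to the clonal
class so the two labels are exhaustive.

### Poisson joint genotyping

Once any sample of a patient calls a site, all samples are re-tested:
with background rate *e* and depth *d*, the observed mutant count *k* is
referred to the upper tail of Poisson(*e·d*), computed through the
regularized incomplete gamma identity P(X ≥ k) = P(k, λ), which is exact
for k = 0 and stable for λ well beyond 10³. Acceptance requires
p ≤ `genotype_alpha` **and** k ≥ 1.

The background is estimated per sample from non-candidate flanking
positions: within ±`window` (default 100 bp) of the site when flank
evidence exists there, else the pooled per-sample rate Σ nonref / Σ depth,
else a configured `fallback_rate` (default 10⁻³). Two guards matter:

* a **rate floor** (`min_error_rate`, default 10⁻⁴) prevents a pristine
  flank from making any single read significant (λ = 0 would give p = 0);
* no multiple-testing correction is applied by default — the genotyper's
  role is rescuing known candidates across samples of one patient, not
  genome-wide discovery. A Bonferroni option exists for the latter use.

Because the test is discrete, its realized type-I rate sits *below* α
(at e = 0.01, d = 100 acceptance needs k ≥ 5, a null rate near 0.004);
calibration checks therefore bound the rate from above rather than
asserting a two-sided band. A second consequence of discreteness is that
the effective read threshold steps up with depth wherever λ crosses the α
boundary, so detection-vs-coverage curves that include the rescue path can
dip by a point or two between neighbouring coverage folds even though they
rise over any wider span; the fixed-threshold hard-filter rule is monotone
in expectation.

### Sweep detection rule

In the pooling experiments a site counts as detected when
`depth ≥ min_depth` **and** (`alt ≥ min_alt` **or** the Poisson test
accepts). Depth gates everything — a 10× mixture detects nothing under the
default 50× requirement, whatever the evidence. The corrected-VAF filter
is not applied in sweeps because a read mixture has no single purity; it
is applied (with the per-sample purities) in the per-patient
classification stage, where presence is the more permissive
"per-sample filter pass OR genotyper rescue".

## LOH detection

Germline heterozygous sites are informative when they fall inside a
segment with minor copy number 0 (B-allele loss). Coordinates follow the
two conventions of the formats involved: segments are 0-based half-open
(BED-like), site positions 1-based (VCF-like); position *p* is inside
[start, end) iff start ≤ p−1 < end. Informative sites are tested with a
two-sided Fisher exact test (minimum-likelihood convention, the one scipy
and R implement, including the standard 1+10⁻⁷ relative tie tolerance) on
the normal-vs-tumor (ref, alt) table. A call requires p ≤ `loh_alpha` and
an actual shift; the direction records which allele was lost. Raw
p-values are reported by default (Benjamini–Hochberg optional), matching
how per-gene LOH findings are conventionally quoted. In real-data mode a
heterozygosity gate (normal B-allele fraction in [0.3, 0.7]) replaces the
germline caller's genotype, which this package does not compute.

## Read-pool resampling

All pooling operates on per-site (depth, alt) counts rather than reads.
Keeping a fraction *f* of a site's reads without replacement is exactly
depth′ ~ Binomial(d, f), alt′ | depth′ ~ Hypergeometric(d, k, depth′);
for site-level detection statistics this is distributionally equivalent
to subsampling the BAM, with no alignment dependencies. The iterative
variant extracts successive 10% tranches of the whole pool (multivariate
hypergeometric across sites, hypergeometric within a site) until the
target fraction is reached; the union of tranches is distributed as a
single without-replacement draw, and this equivalence is property-tested
(two-sample KS against one-shot thinning).

Coverage above the available reads uses a with-replacement bootstrap:
depth′ ~ Poisson(fold·d), alt′ ~ Binomial(depth′, k/d). This preserves
the per-site expected VAF but cannot create evidence the input lacks — a
site that shows zero mutant reads at base coverage stays empty at any
fold, which slightly caps attainable sub-clonal detection compared with
physically re-sequencing. It also recycles the input's error reads
rather than drawing fresh ones.

Mixtures default to `total_scale = 1`: mixing two pools at composition
*p* yields expected depth (1−p)·dₐ + p·d_b per site, i.e. one specimen's
coverage, which is how a re-sequenced pooled library behaves. Coverage
sweeps define onefold as the pooled input's own coverage.

Replicate *r* of any sweep uses seed `base_seed + r`, so a replicate is
reproducible in isolation.

## Synthetic data generator

One simulated patient consists of a matched normal plus `n_regions`
(default 3) tumor regions. The mutation catalogue has `n_trunk` (90)
mutations in every region, `n_branch` (30) in a random proper subset of
≥ 2 regions, and `n_private` (30) in one region each. Founder VAFs are
uniform on `clonal_vaf_range` (0.2–0.5); a configurable fraction of
private mutations instead draws from `subclonal_vaf_range`. Depth is
Poisson around `coverage_mean` (100×, exome-like); mutant reads are
Binomial with success purity·VAF + `error_rate` (10⁻³), so absent sites
and the normal accumulate error reads, and flanking non-variant positions
are emitted for background estimation. Purity defaults to 0.7 per
region. All randomness derives from one seed through fixed sub-streams
(truth, counts, flanks, LOH), making every output byte-reproducible and
each stage independently re-runnable.

The **hypermutator preset** floods region 1 with 500 private mutations at
VAF 0.10–0.15 on top of the usual trunk/branch load — sized so that the
flooded biopsy holds a small trunk share while pooling three regions
dilutes the privates toward a third of their VAF, reversing the
relationship between sample size and detected mutation count.

The **paired-pool generator** emulates a primary/metastasis pair for the
mixing experiments: shared clonal mutations at a common VAF in both pools,
private clonal mutations per pool, optionally shared fixed-VAF sub-clonal
sites, at ~70× per pool (the coverage of a standard sequencing run).

LOH data places half the germline heterozygous sites inside
B-allele-loss segments, where the expected tumor B-allele fraction is
(1−ρ)/((1−ρ)·2 + ρ·C) for purity ρ and tumor copy number C (default 1) —
the residual signal of contaminating normal cells; a copy-neutral segment
and uncovered balanced sites exercise the informativeness gate. A `null`
mode keeps loss-annotated sites balanced to measure the false-positive
rate on informative sites.

### What the generator does not model

Real exome data adds GC-dependent and capture-dependent depth
overdispersion, strand bias, mapping artifacts, multi-allelic and indel
sites, subclonal copy-number changes under somatic mutations, and
error rates that vary by sequence context. Passing tests on this
generator therefore demonstrate the statistical machinery under its
stated noise model, not robustness to those artifacts; the real-data
entry points (VCF/segment/purity readers) exist precisely so the same
machinery can be pointed at caller output.

## Design choices made where the design was open

* **Presence** of a mutation in a sample = per-sample hard-filter pass OR
  genotyper rescue, mirroring a primary caller union'd with joint
  genotyping; sweeps additionally gate on depth (see above).
* **Proportion-identified denominators**: whether a sample's identified
  fraction is taken over the union of all samples' calls or the largest
  single catalogue is not uniquely determined; both are exposed
  (`presence_proportions(denominator=...)`), union is the default.
* **Estimator surface**: the genotyper and LOH caller follow the
  scikit-learn fit/predict idiom (`fit` consumes flank counts or
  segments; fitted state carries a trailing underscore) so they compose
  with sklearn tooling; the simulators and sweeps are plain functions.
* **Problem sizes** in the test suite and acceptance script (10 seeds for
  recovery checks, 10 replicates per grid point, 10⁴ null genotyping
  tests, 10³ LOH sites per arm) were chosen as the smallest designs whose
  Monte-Carlo error is comfortably below the margins being asserted.

## Known limitations

* Count-level resampling cannot express read-level correlations
  (duplicates, overlapping mates, UMI families).
* The bootstrap upscaling caps sub-clonal detection at high folds at the
  fraction of sites with ≥ 1 observed mutant read in the input.
* Background noise is a single per-sample (or per-window) rate; no
  trinucleotide-context or strand decomposition.
* The LOH model assumes segments are correct and clonal; subclonal copy
  events attenuate the expected shift and are not simulated.
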