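# Methods

## The analysis

The package reconstructs, as reusable components, an analysis that groups
English GP practices by how their appointment systems behave. The unit of
observation is a practice-month count table: appointments cross-tabulated
by healthcare-professional type (GP vs other staff), consultation mode
(face-to-face, telephone, video, home visit), wait-time band (same day,
1 day, 2–7, 8–14, 15–21, 22–28, >28 days) and national appointment
category. A separate registry carries list size, sociodemographics and
workforce full-time equivalents (FTEs) per 10 000 patients.

### Quality filtering

Administrative appointment extracts vary in quality, so practices pass a
staged screen before analysis:

1. **Size/rate** — list size below 1000, or an appointment rate above a
   threshold (default 1500 per 1000 registered patients per *month*, an
   outlier screen; see "Open design points" below), excludes the
   practice. A zero list size excludes it outright (the rate is
   undefined), as does absence from the registry.
2. **Unmapped categories** — more than 10% of appointments (by count) in
   categories not on the standard national list.
3. **Annotation coverage** — fewer than 50% of appointments carrying a
   care-model label. The boundary is strict: coverage of exactly 0.5 is
   included. A practice with no appointments in the window passes stages
   2–3 vacuously (both shares are defined as 0) — the size/rate rule is
   the only one that can exclude it.

A practice is attributed to the first stage it fails, so the stage
counts partition the input and can be drawn as a flow diagram. The
filter is idempotent and monotone in its thresholds (tightening any
threshold never admits a practice), both covered by tests.

### The 12 measures

Per practice-month: five proportions over all appointments (GP share,
booked >1 week ahead, telephone, telephone-with-GP, same-day-wait with
GP); four proportions over *annotated* appointments (same-day label,
telephone same-day label, GP same-day label, routine label); the share
of routine-labelled appointments delivered within one day of booking;
a 0/1 flag for any clinical triage recording that month; and total
appointments per 1000 registered patients. A zero denominator yields 0
with a recorded flag rather than a gap, keeping vectors complete for
clustering; flagged practices are listed in the output.

Monthly vectors are averaged unweighted over the window months present
(the triage flag becomes a usage proportion), then each column is
min-max scaled to [0, 1] across practices. Constant columns map to 0.
The (min, max) pair per column is stored in a sidecar so a held-out
dataset can be scaled on the training ranges.

One printed source table lists "total GP appointments" as the
denominator for the first five measures, which would force the GP share
to 1 identically; the published cluster means (GP share ≈ 0.48/0.62)
show the intended denominator is all appointments, and that reading is
used for all five.

### Ensemble consensus clustering

`ConsensusClustering(data, k=2).fit(master_seed)` runs, for each of five
base methods × `reps_per_method` repetitions, a clustering of a random
80% subsample (drawn without replacement). Per-run seeds are the first
four bytes of SHA-256 of `"master:method:rep"`, so an ensemble is
bit-reproducible from one integer. The base methods:

- **kmeans_lloyd** — Lloyd iterations from seeded k-means++ starts, best
  of 10 restarts by within-cluster sum of squares (scikit-learn).
- **hierarchical_ward** — agglomerative merges minimising the Ward
  variance increase, cut at k (scikit-learn; deterministic, so its
  ensemble diversity comes from the subsamples).
- **hsom** — a seeded self-organising map (8×8 grid, 500 epochs,
  Gaussian neighbourhood, linearly decaying radius and learning-rate
  factor) trained in *batch* mode: each epoch assigns all samples to
  their best-matching unit and moves every prototype toward its
  neighbourhood-weighted mean, damped by the decaying learning rate.
  Batch training is order-independent and vectorises; the decaying
  radius gives the usual global-then-local organisation. The trained
  codebook is Ward-clustered into k and items inherit their
  best-matching unit's cluster.
- **pam** — k-medoids with BUILD initialisation and steepest-descent
  SWAP on Euclidean distances; deterministic given the data (the seed
  only breaks exact ties).
- **gmm_bic** — Gaussian mixtures at fixed k fitted by EM over the four
  scikit-learn covariance families {full, tied, diag, spherical}; the
  best BIC wins and items take their maximum-responsibility component.
  Singular fits fall back to the diagonal family with a larger
  covariance floor.

Runs are aligned before voting: the reference run is the one with the
highest mean adjusted Rand index (ARI) to all others, and every other
run's labels are permuted by the optimal assignment (Hungarian method)
on its contingency table with the reference, over shared items. Each
practice's consensus label is the majority vote over aligned runs that
sampled it; vote share and vote count are recorded. Practices with tied
votes or never sampled (probability (1−0.8)^runs, negligible at default
settings) are assigned to the nearest consensus centroid, ties to the
lower label index. A co-association matrix is available as a diagnostic
but is not the consensus function: majority voting after alignment is
the rule, chosen for fidelity to a plain "majority vote" description.

Ensemble stability is the unweighted mean ARI over all unordered run
pairs, each computed on the pair's common items; pairs sharing fewer
than two items are skipped and counted. The ARI is the Hubert–Arabie
form; when the chance-corrected denominator vanishes (both partitions
trivial) it is 1 for identical partitions and 0 otherwise. The
implementation is cross-checked against scikit-learn's
`adjusted_rand_score` in tests (the library is never the implementation
path).

### Hold-out validation

The held-out month is ingested, cleaned and measured identically, scaled
on the *training* (min, max) ranges, and — by default — each practice's
vector is assigned to the nearest trained consensus centroid. Cluster
labels of the two runs are matched by the permutation maximising total
agreement (identity preferred on ties) and the report gives the share of
common practices keeping their cluster, plus the cross-tabulation.

Re-clustering the holdout month from scratch is available
(`assign_only=False`, CLI `--recluster`) and is the mode under which
"identical holdout + same seed ⇒ agreement 1.0" holds exactly. It is not
the default because measures defined per month become degenerate on a
single held-out month: the 0/1 triage flag, a proportion in the training
window, is binary in a single month, and a fresh clustering of the
holdout then tends to split on triage recording rather than on the
appointment-system structure — conflating cluster stability with a
month-resolution artefact. Centroid assignment measures what the
validation is after: whether practices' appointment systems still look
like their cluster a month later.

### Description

Cluster characterisation is purely descriptive: unweighted means with
sample (n−1) SDs for measures, list size, ethnicity share and age;
counts (%) over non-missing values for region, IMD quintile and
rural–urban status; workforce FTE summaries restricted to practices with
workforce data, with coverage reported. A single-practice group reports
its mean and a missing SD. No inferential tests are run — group
contrasts in the source material are not tied to a named test, so none
is invented. The same machinery serves included-vs-excluded comparisons.

## The synthetic generator

The generator emulates the study conditions the analysis assumes: a
mixture of two latent practice types with weight 1194/3480 ≈ 0.343 for
the same-day type, per-type means and SDs for the 12 measures and the
covariates taken from the published cluster characterisation (e.g.
telephone share 0.18 (SD 0.14) routine vs 0.33 (0.17) same-day; triage
use 80.7% vs 75.4%; appointment rate 488.5 (128.6) vs 462.7 (110.4) per
1000 per month), log-normal list sizes matched to means 9784/10 377 and
SDs 6335/7355, and per-type region, rurality, deprivation, ethnicity,
age-band and workforce distributions.

**Profile sampling.** Each proportion is drawn independently from a
normal truncated to [0, 1] with its cluster's mean and SD, then the
vector is projected onto the subset constraints (telephone-with-GP ≤
min(telephone, GP); GP/telephone same-day-annotated shares ≤ the
same-day-annotated share and the corresponding overall share; same-day +
routine annotated shares ≤ 1) by clipping only the dependent coordinate.
Independence-with-minimal-repair is deliberate: the published summaries
are marginal means/SDs with no covariance information, and any stronger
within-cluster dependence is an unsupported assumption. Because clipping
binds asymmetrically it would bias realised cluster means a few
hundredths below the stated values, so a short seeded fixed-point
calibration (simulate draws, measure the shift, compensate the raw draw
means; cached per parameter set) makes the realised per-cluster means
match the configured ones. A known consequence is that the realised SDs
of the most-constrained measures (the same-day-annotation family) come
out below their nominal values: with these marginals the subset
constraints cannot be satisfied while preserving both moments and
independence, and the means are the primary stated condition. The
between-cluster mean gaps — what the clustering consumes — are
reproduced; tests pin the gap on the same-day-annotated share to the
configured 0.27 within 15% of its standardised size.

**Triage.** Recording is an independent Bernoulli per practice-month
with the cluster's probability, matching the measure's definition as a
monthly 0/1. In a triage-free month the annotated label shares are
renormalised (no triage-labelled appointments exist); in a triage month
at least 2% of annotated appointments are triage-labelled so the flag is
realisable after rounding.

**Count realisation.** A month's total is round(rate × list size /
1000). Mass is allocated over (professional × mode × label × wait-band)
cells by a deterministic inversion of the measure definitions —
label shares from annotation coverage and the annotated-share targets,
professional and mode splits pinned inside the same-day label and
balanced elsewhere, wait bands allocated to satisfy the same-day-GP,
routine-within-one-day and booked->1-week targets, with the >1-week mass
spread over its four bands in fixed ratios (0.50/0.25/0.15/0.10) — and
rounded by largest remainder, so column sums are exact. The fidelity
contract, enforced by tests: measures recomputed from the emitted rows
match the month's target vector within 0.02 absolute at 2000+
appointments (typically within 0.005). Each month applies additive
truncated-normal noise (SD 0.02) to the proportion targets and 3%
relative noise to the rate; the holdout month uses SD 0.05, a tuning
default for the stability analogue rather than an observed quantity
(real within-practice month-to-month variance is not published).

**Defects.** Quality issues are injected one rule per designated
practice: list size redrawn in [200, 900) with counts rescaled to keep
the rate plausible; counts inflated to a monthly rate ≈1950 per 1000;
categories replaced by an off-list string for 20% of counts; annotated
categories diluted to below 50% coverage. A ground-truth ledger is
emitted, and the same alterations apply to the holdout month.

**What the generator does not emulate.** Within-cluster correlation
beyond the subset constraints (real same-day indicators co-move);
practice-level persistence of triage recording across months; seasonal
or trend structure; the real publication's file layouts and suppression
rules; any measure–covariate dependence within a cluster. Passing tests
therefore demonstrate that the pipeline recovers structure of the stated
two-cluster form, not that real NHS data carries exactly that structure.

## Problem sizes and defaults

Tests and the acceptance script run the study at 600 practices, three
training months plus one holdout month, and 5 methods × 20 repetitions
(100 ensemble runs) — enough for stable consensus behaviour at desk
scale; the full published protocol (100 repetitions per method) is the
library default for `ConsensusClustering` and the pipeline. k defaults
to 2 (the a-priori choice of two groups); k = 3 is supported. The SOM
grid (8×8) and epoch count (500) are conventional values, configurable,
as the source protocol does not specify them.

## Open design points

- **Rate-rule period.** The printed exclusion rule (">1500 per 1000 per
  year") contradicts the published monthly appointment-rate magnitudes
  (~490 per 1000 per month ≈ 5900 per year), under which the literal
  reading would exclude nearly every practice. The default treats the
  threshold as a monthly outlier screen; `rate_period="year"` gives the
  literal reading (a test demonstrates it empties a realistic dataset).
- **Repetition count.** The per-method protocol (5 methods × 100
  repetitions) is taken as authoritative; `reps_per_method` is
  configurable and the run count is whatever methods × reps yields.
- **Pairwise ARI scope.** Computed on each run pair's common subsample
  items, not on completed assignments — an assumption, recorded here.
- **Annotation keying.** The dictionary keys on the national category
  string alone; the schema carries one category per row, so any
  finer-grained (category × staff × mode) review collapses to
  category-level keys.
- **"400 iterations".** A stated total run count inconsistent with
  5 × 100 is treated as an internal inconsistency and ignored in favour
  of the per-method protocol.
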