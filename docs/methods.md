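# Methods

## Scope and data model

The package computes promiscuity statistics from three kinds of flat tables:
activity records (one measured compound–target interaction with a potency,
a relation qualifier, a 0–9 curation confidence level and a
direct-interaction flag), drug–target annotations (with approval status),
and confirmatory-assay outcomes (compound × assay → active/inactive).
Promiscuity here means *specific* multi-target activity; everything in the
pipeline exists to separate that signal from assay noise and weak curation.

Potencies are normalised to nanomolar on input (accepted units nM, µM, mM,
M) and carried as pPotency, p = −log10(mol/L) = 9 − log10(nM). A single
logarithmic scale makes replicate averaging and potency-spread computations
well behaved: potency errors are approximately log-normal, so replicates
combine by arithmetic mean of pPotencies, i.e. the geometric mean of
nanomolar values.

## Pipeline

Fixed stage order: read → filter → split by measurement type → aggregate
replicates → count targets → summarise → stratify (family, molecular
weight) → classify profiles → report.

**Filtering.** A record is kept iff confidence ≥ `min_confidence` (default
9, the top of a ChEMBL-like 0–9 scale, where 9 asserts a direct
single-protein interaction), the direct-interaction flag is set (default
required), and the relation qualifier is in the allowed set (default `eq`
only: a "<" or ">" value has no usable magnitude for spread analysis).
Raising the threshold can only shrink the kept set (tested property).

**Splitting.** Ki and IC50 measurements are never pooled: Ki values are
assay-independent equilibrium constants, IC50 values are assay-dependent.
A compound measured both ways is analysed in both subsets independently.

**Aggregation.** Replicates for one (compound, target) pair collapse to one
pair carrying the mean pPotency and the replicate count. Aggregation is
idempotent.

**Counting and summaries.** A compound's count is its number of *distinct*
target identifiers. A summary reports the overall average, the
promiscuous-only average and median (promiscuous = count ≥ 2), and the
probabilities P(≥ 2) and P(> 5) (strict). The median of an even-sized set
is the mean of the two middle values. Empty inputs produce an explicit
empty summary (NaN fields, `is_empty` true); a set with no promiscuous
compound leaves the promiscuous fields NaN, never zero.

Medians for drug and screening categories use category-specific promiscuity
thresholds (approved ≥ 5, experimental ≥ 2, screening actives ≥ 3,
bioactive ≥ 2) while the averages and probabilities always use ≥ 2, so the
mixture identity stays exact. Drug target counts use all annotations with
no confidence filtering — annotation tables carry no measurement-level
confidence. Screening counts use distinct targets of *active* outcomes
only; assay coverage is the fraction of confirmed-active compounds tested
in strictly more than 50 distinct assays (active or not).

**Mixture identity.** With threshold 2, avg_all = p_ge2·avg_prom +
(1 − p_ge2)·1 exactly, because non-promiscuous compounds contribute exactly
one target each. `PromiscuityResults.verify_consistency()` recomputes it
for every emitted summary and reports the absolute gaps; the pipeline
requires gaps < 1e−9 (observed ~1e−16, pure rounding noise). The identity
also reconstructs any published subset's overall average from its printed
probability and promiscuous-only average, which is what
`scripts/acceptance.py` does.

## Stratification conventions

Molecular-weight bins are lower-open/upper-closed with an inclusive first
bin: ≤ 200, (200, 300], …, (600, 700], > 700 Da. The published range
notation leaves boundary membership ambiguous; this convention is one
documented choice that makes the bins a partition of (0, ∞) — a weight of
exactly 300 falls in the (200, 300] bin. Compounds without a known weight
are excluded from MW stratification with a logged count.

Family stratification counts only a compound's within-family targets; its
cross-family targets are ignored for that family's summary, and a compound
active in several families appears in each family's summary independently.
Family restriction can therefore only reduce a compound's count (tested
property).

Family scope: `single` (one target), `intra_family` (≥ 2 targets, one
family), `cross_family` (≥ 2 families). Unlabeled target families are an
error, not a silent fourth class.

## Profile classification

The prevalent promiscuity profile is evaluated per compound on its
aggregated pairs of one measurement type, and only for promiscuous
compounds (≥ 2 pairs): 2–5 distinct targets, all potencies strictly sub-µM
(< 1000 nM, i.e. pPotency > 6), all targets in one family, and a potency
spread (max − min pPotency) ≤ 2 log units; spread ≤ 1 is reported
separately. Spread is max-minus-min rather than pairwise — the stricter
reading. The selectivity outlier is the opposite pattern: best pair ≤ 100
nM and every other pair ≥ 10 µM (both inclusive). The potent/weak
thresholds are conventions exposed in `ProfileRule` and the CLI; no
standard numeric values exist for them. With the default thresholds the
outlier and the prevalent profile are mutually exclusive, since a ≥ 10 µM
pair is never sub-µM.

## Synthetic data generator

No public accession backs desk-scale extracts of the real databases, so the
generator emulates their statistical structure with known ground truth:

- **Target counts**: truncated geometric on 1..K, P(N = k) ∝ q(1−q)^(k−1),
  defaults q = 0.62, K = 10, giving P(≥ 2) ≈ 0.380, P(> 5) ≈ 0.008 and
  counts concentrated at 1–3 with a thin tail — the regime the statistics
  are designed for. An explicit probability vector can replace the law.
  `expected_statistics` returns the exact mean, variance and tail
  probabilities by direct summation.
- **Family structure**: a compound's first target's family is drawn
  proportional to family size; each additional target stays in that family
  with probability 0.95, otherwise lands in a uniformly chosen other
  family. This reproduces the empirical picture in which roughly a third of
  compounds are intra-family promiscuous and only a few percent
  cross-family. Bias 1.0 yields exactly zero cross-family compounds.
- **Potencies**: pPotency ~ Normal(6.5, 1.0) per (compound, target,
  measurement type) — log-normal concentrations centred just below 1 µM,
  so most promiscuous compounds are sub-µM, as observed for bioactive
  compounds. The first measurement equals the true potency; with
  probability 0.2 a second replicate with Normal(0, 0.2) pPotency noise is
  added. Setting either replicate parameter to zero makes aggregation
  exact, which is what the profile-recovery checks use.
- **Measurement mix**: 45% of compounds Ki-only, 45% IC50-only, 10% both
  (all their targets measured in both subsets).
- **Curation flags**: 90% of records are confidence 9 + direct; the rest
  get confidence 4–8 and no direct flag. 5% of records carry a "<"/">"
  qualifier. Under default filtering these records are dropped, so observed
  counts can fall below truth — that is deliberate filtering, not
  estimation error.
- **Molecular weight**: Normal(400, 100) Da truncated at zero, a
  medicinal-chemistry-like range spanning all seven bins.
- **Drugs and screening**: approved/experimental drug annotation counts from
  truncated geometrics (q = 0.17, K = 30 and q = 0.76, K = 15), giving
  approved drugs ~5–6 targets on average with a heavy tail and experimental
  drugs mostly 1–2. A geometric law cannot simultaneously match the
  reported experimental-drug overall mean (~1.8) and promiscuity
  probability (~24%); the probability was matched, a known limitation.
  Screening: 120 assays over 40 targets; each compound is tested in
  ~Poisson(56) distinct assays — placing about three quarters of actives
  above the 50-assay coverage threshold — and its active-target count
  follows a q = 0.49, K = 15 law.
- **Determinism**: all streams spawn from one `numpy.random.SeedSequence`;
  identical config + seed gives byte-identical tables, reports included.

The ground truth carries each compound's true count, family scope and
per-measurement-type profile flags, computed inline from the drawn values
(independent of the analysis modules) so recovery tests compare two
separate code paths.

What the generator does *not* emulate: chemical structures, correlated
potencies across related targets, assay-incompleteness masking, frequent
hitters, or inter-database compound overlap. Passing recovery tests
therefore demonstrate correctness of the counting and classification
machinery under the assumed laws, not robustness to real-data artifacts.

## Verification strategy and problem sizes

- Unit tests freeze hand-computed examples; every summary-producing
  operation is additionally checked for exact equality against naive
  brute-force reimplementations (plain dicts and loops) on randomized
  instances — 100 instances of up to 1000 compounds for the main summary.
- Property tests (hypothesis, derandomized): filtering monotonicity,
  summary monotonicity under added annotations, the mixture identity,
  profile-rule monotonicity, outlier/prevalent exclusivity.
- Parameter recovery: 100 datasets of 10,000 compounds under the default
  count law with clean observation (confidence fraction 1, no qualifiers,
  no replicates) must land within 3 Monte-Carlo standard errors of the
  analytic law for ≥ 95% of seeds, for the average and both tail
  probabilities simultaneously. Clean observation isolates the estimator:
  under the default noisy curation flags the filter removes records by
  design, which would bias the comparison against the analytic law.
- End-to-end: written TSV cells equal the JSON full-precision values after
  the rounding contract (averages one decimal, probabilities one-decimal
  percent); repeated runs with one seed are byte-identical.

Problem sizes (10,000 × 100 for recovery, ≤ 1,500 compounds elsewhere) keep
the full suite around one to two minutes on a single CPU while leaving the
Monte-Carlo standard errors small enough to detect percent-level bias.

## Known limitations

- Target identifiers are opaque: no resolution of protein complexes or
  target hierarchies; whatever granularity the input uses is counted.
- Relation-qualified measurements are discarded rather than treated as
  censored data.
- No statistical inference (confidence intervals, tests) on the summaries.
- The MW-bin boundary convention and the profile potent/weak thresholds are
  documented conventions, configurable but not canonical.
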