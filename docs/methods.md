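# Methods

## Analysis unit and data model

Each hospitalization is treated as an independent observation carrying an age,
a sex, and a *set* of 3-character ICD-10 codes (duplicate diagnosis rows
collapse; co-occurrence is per record, not per diagnosis row). Raw codes are
uppercased, dot-stripped and truncated to the 3-character rubric. Codes with
unambiguous ICD-9 shape (numeric rubrics 001–999, external-cause codes
E800–E999) must resolve through a user-supplied two-column ICD-9→ICD-10 map;
the package deliberately ships no map, since general-equivalence tables are
licensed, versioned artifacts. V-codes are ambiguous between ICD-9
supplementary codes and ICD-10 chapter XX; they resolve through the map when
present and otherwise parse as ICD-10 (the chapter filter removes them from
analyses either way).

## Cleaning pipeline

Applied in a fixed order, each step logged with before/after counts:

1. keep records with age ≥ 18 **and** at least one thyroid code (E00–E07 or
   C73);
2. drop codes whose leading letter is O–Z (ICD-10 chapters XV–XXII:
   pregnancy, perinatal, congenital, symptom, injury, external-cause and
   health-status codes). The leading-letter rule is exactly the chapter
   boundary at the 3-character level, so no chapter lookup table is needed;
3. drop records with < 2 codes remaining (code counting happens after the
   chapter exclusion, matching the order the steps are applied);
4. drop diseases with prevalence < 2% in the cleaned cohort. The threshold is
   a point-estimate rule; an optional mode additionally removes diseases rare
   in any declared subgroup, since reasonable pipelines differ on whether the
   floor is enforced per stratum.

Thyroid codes define the cohort rather than its comorbidities: they are
excluded from prevalence/difference tables (`comorbidity_universe`) but kept
as network nodes by default (`include_td`), because the co-occurrence
structure around the index diseases is itself of interest.

Strata: sex (records with unrecodable sex stay in overall analyses and leave
sex strata), age bins 18–39 / 40–49 / 50–59 / 60–69 / ≥70, disease type
(malignancy-dominant: a record with both C73 and a benign code counts as
thyroid cancer, keeping the two strata disjoint; overridable), and
thyroid-disease subtype (nontoxic goiter E04, hypothyroidism E02∪E03,
hyperthyroidism E05 — these may overlap).

## Prevalence and subgroup contrasts

Crude prevalence n/N is reported with the Wald 95% interval
p̂ ± z·sqrt(p̂(1−p̂)/N), clamped to [0, 1]; this is the convention that
reproduces the intervals printed in large published prevalence tables of this
kind (e.g. 6435/18,311 → 35.1 [34.5–35.8]). A Wilson interval is available
behind a flag for small counts. At n = 0 or n = N the Wald interval is
degenerate and the exact one-sided bound replaces the clamped side.

Subgroup contrasts use the symmetric relative difference
d = 2(p_a − p_b)/(p_a + p_b) ∈ [−2, 2] and a pooled two-proportion z-test.
A comorbidity is *different* when |d| > 0.1 and p < α (α = 0.05, two-sided);
*enriched* additionally requires a prevalence ratio ≥ 1.5. "≥ 0.5-fold
increase" admits two readings — ratio ≥ 1.5 or d ≥ 0.5; the ratio reading is
the default, the other is a config switch. No multiple-testing correction is
applied by default (matching common practice in descriptive comorbidity
tables); Benjamini–Hochberg is available behind a flag. Contrasts with both
prevalences zero are skipped; a zero prevalence opposite a positive one counts
as an infinite ratio (enriched), logged.

Age structure: per-disease prevalence vectors over the five age bins, with
Spearman correlation between the **bin ordinal** and the prevalence (ordinals
rather than midpoints make the trend invariant to bin-width choices), plus the
mean comorbidity count per bin and its trend. K-means clusters the raw,
unscaled 5-vectors (magnitude is part of the signal: very common diseases
should separate from rare ones), with 50 restarts and a fixed seed; when k is
not given, the elbow of the inertia curve over k = 1..10 (largest second
difference) picks it.

## Network construction

For each unordered pair over N records: cosine index n_ab/sqrt(n_a·n_b), phi
coefficient (N·n_ab − n_a·n_b)/sqrt(n_a·n_b·(N−n_a)·(N−n_b)), and the t
transform t = phi·sqrt((N−2)/(1−phi²)) with a two-tailed Student-t p-value at
N−2 df. |phi| = 1 maps to p = 0 with an explicit infinite-t flag. Pairs with a
degenerate marginal (0 or N) are skipped, not zero-filled.

Cutoff calibration: K = #{pairs: phi > 0 and p < α}. Only positive
correlations count — edges represent coexistence, and the cosine index is
nonnegative, so a significant negative correlation has no cosine counterpart.
The cutoff is the K-th largest cosine over all pairs; all pairs tied at the
cutoff value enter the network (the provenance records when ties expand the
edge count). K = 0 yields an infinite cutoff and an empty edge set. Whether
the original significance count was one- or two-tailed on positive
correlations is not something the construction depends on strongly; the
two-tailed, positive-only choice is documented here and configurable through α.

## Structural metrics and comparison

Density 2E/(N(N−1)); degree and average neighbor degree (NaN for isolated
nodes) with median and IQR (linear-interpolation quantiles); betweenness
centrality on the **unweighted** thresholded graph, unnormalized — the
definition by raw shortest-path counts is what produces values like 47–385 on
a 72-node network. The mean degree 2E/N is always reported beside the median
because published summaries sometimes print the mean under a "median" label;
both are exposed, explicitly named.

PageRank: damping 0.85 (standard default), tolerance 1e-9, iteration cap
10,000, each undirected edge treated as two directed edges with transition
probability proportional to the cosine weight; scores sum to 1 and top-k ties
break lexicographically.

Node-removal experiments drop a named or top-k (by degree or betweenness)
node set and report the lost-edge share of the original edge count.

Abundant connections between two subgroup networks built over the same
universe: an edge present in only one network (*unique*), or present in both
with cosine ≥ 0.05 higher in one (*enriched*); anything else is shared. The
0.05 weight-difference threshold is exposed in config.

## Synthetic cohort generator

The generator emulates adult inpatient encounters of thyroid-disease
patients: every record gets exactly one thyroid indication drawn from a
subtype mix (default dominated by nontoxic goiter, with hypothyroidism,
hyperthyroidism, thyroid cancer and thyroiditis at realistic shares), an age
from a triangular distribution on [18, 95] peaked at 58, and a sex with 39%
male — magnitudes typical of large thyroid-disease inpatient cohorts.

Disease i enters a record through a logistic model:
logit p = logit(base) + β_sex·(male − sex_ratio) + β_age·(decades − mean
decades). Effects are centered on the cohort's sex mix and mean age so the
configured base prevalence stays the population marginal; the logistic
curvature still biases marginals slightly upward for strong age slopes
(Jensen's inequality, ~2 pp at a slope of 0.45/decade on a 35% disease), which
is why recovery tests plant their co-occurrence on effect-free diseases.

Pairwise co-occurrence is planted with one shared latent Bernoulli factor per
pair: disease fires if its (deflated) base draw **or** the factor fires. Under
this OR construction the attainable cosine runs from the independence baseline
sqrt(p_a·p_b) up to sqrt(min/max); the factor rate is solved by bisection so
the population cosine equals the target, the member base rates are deflated so
marginals are preserved, and targets outside the attainable range raise an
explicit infeasibility error (targets at or below the baseline simply mean
independence). A disease may join several pairs; each pair's factor is
independent, which keeps the pair-level expectation exact.

Each record derives its random stream from (seed, record index) via NumPy
`SeedSequence.spawn`, so cohorts are byte-identical across runs and stable
under parallel generation.

The bundled default configuration has 70 diseases spanning 2%–45% prevalence
(hypertension ~35%, liver disease ~22%, diabetes ~17%, atherosclerosis ~16%,
lipoprotein disorders ~15%, plus a reproducible mid/low-prevalence tail) and
eight planted cardiometabolic co-occurrences with cosine targets 0.22–0.42.

What the generator does *not* emulate: repeat hospitalizations of one patient,
temporal disease sequences, coding drift across years, correlated measurement
error in coding, and hospital-specific case mix. Passing recovery tests
therefore show that the estimators are correct under the stated generative
model, not that the model captures every feature of real discharge data.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of 3,000–20,000 records and
networks of ≤ 110 nodes — sizes at which every quantity is computed exactly
(dense indicator-matrix pair counting, exact betweenness) within seconds.
Bisection for factor rates runs to 1e-12; K-means uses 50 restarts with a
fixed seed; PageRank runs to 1e-9. Degenerate inputs fail loudly: empty
cohorts name the emptying filter step, zero marginals skip the pair, N ≤ 2
refuses the t transform, single-node networks refuse density.

## Known limitations

- The 2% prevalence rule is a point threshold; a test-based variant of the
  rule is not implemented because its null is under-determined.
- Wald intervals undercover for very rare diseases; the Wilson option exists
  but the default matches the convention of published tables of this kind.
- Cutoff calibration matches edge *counts*, not edge *sets*: the cosine and
  phi rankings usually agree closely but not perfectly, and the network keeps
  the cosine ranking.
- The generator's marginal bias under strong covariate effects (see above) is
  accepted in exchange for exact, invertible co-occurrence planting.
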