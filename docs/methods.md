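# Methods

## The ROB score

The ROB score grades post-SAH status in the circle-of-Willis perforation
(cWp) mouse model by summing three sub-scores, each on a 1–5 scale:

* **R — Rotarod.** Latency to fall from an accelerating rod (4–40 RPM),
  capped at the 300-s endpoint; three trials per animal-day are clamped
  to [0, 300] s and averaged arithmetically.
* **O — Open field.** Path length of an ear marker over a key-sampled
  video window, in raw tracker pixel units (no spatial calibration; the
  protocol reports "absolute value without unit").
* **B — Body-weight loss.** (pre − post)/pre × 100 %, measured daily
  against the pre-operative weight.

The composite total *R + O + B* ∈ [3, 15] maps to severity classes
severe (3–6), moderate (7–10) and mild (11–15).

### Band-edge conventions

The criteria table prints touching or ambiguous bin edges. The packaged
defaults (`src/robscore/criteria.yaml`) resolve them as follows and are
fully reconfigurable:

| component | bands (score: interval) |
|---|---|
| Rotarod (s) | 1: [0, 50] · 2: (50, 100] · 3: (100, 200] · 4: (200, 300) · 5: {300} |
| Open field | 1: [0, 300) · 2: [300, 500) · 3: [500, 800) · 4: [800, 1000] · 5: (1000, ∞) |
| BWL (%) | 5: (−∞, 5) · 4: [5, 10) · 3: [10, 15) · 2: [15, 20] · 1: (20, ∞) |

Rationale: every printed strict inequality is respected (open-field top
band is strictly "> 1000"; the BWL end bands are strictly "< 5" and
"> 20", which forces closure of the inner bands), remaining ties are
resolved lower-inclusive, and the 300-s cap is the only way to earn the
top Rotarod sub-score (the printed score-4 row ends at 299, so a latency
of, say, 299.5 s scores 4 here — flagged because the protocol text does
not settle it). Weight gain (negative BWL) scores 5: gaining weight is
less severe than any loss; the validation cohort never observed gain.
Criteria are validated on load: bands must tile each component's domain
exactly once and the severity bands must partition 3..15.

Sub-scores are always recomputed from raw measurements; accepting
pre-binned sub-scores requires an explicit override
(`RobScore.from_subscores`, CLI `--prescored`) so provenance stays
traceable.

## Open-field video analysis

Recording is 30 FPS; the analysis window is the 160 frames following the
user-supplied release frame (the protocol does not define the release
frame algorithmically, so it is an input here). Key frames sit at
five-frame intervals, inclusive of both window endpoints: 33 key
positions. 160 frames at 30 FPS is 5.33 s although the window is
nominally described as 5 s; the frame count is treated as authoritative
and the duration label as approximate. The scored quantity is the total
path length (sum of the 32 segment lengths between consecutive key
positions) — "distance covered", not net displacement; both are exposed
(`path_distance`, `net_displacement`).

`track_marker` re-implements the centroid tracking the protocol
delegates to a video-tracking GUI: frames are rescaled to [0, 1], dark
pixels (< `threshold`, default 0.5) are labelled into connected blobs
(scikit-image), and the blob centroid nearest the previous position
within `search_radius` (default 50 px, generous because an ear marker
can move tens of pixels between frames) becomes the new position; losing
the marker raises an error naming the frame. It is exercised only on
synthetic rendered stacks — it is not a general pose estimator and makes
no robustness claims about real video.

## Cohort analysis conventions

* **Exclusion workflow.** Exclusions unrelated to SAH severity (tumour,
  intra-operative death, suboptimal filament) remove an animal from the
  *valid* cohort; death/euthanasia before the first assessment or
  missing day-1 data keep it valid but unscored. A mortality event on
  day ≤ 1 is auto-classified as "died before first score". Peri-operative
  mortality is (intra-operative deaths + first-24-h deaths) over
  enrolled minus the non-procedural exclusions (tumour, filament).
* **Mortality vs. censoring.** Humane-endpoint euthanasia is a mortality
  event (the welfare endpoint is a death outcome); scheduled autopsy
  euthanasia is planned tissue harvest and is right-censoring.
* **Denominator rule.** Cumulative mortality at day *d* counts deaths on
  days ≤ *d* over cohort size minus scheduled removals strictly before
  *d*: animals harvested on day *d* itself were at risk that day. This
  is what reproduces 4/29 on day 3 (eight same-day autopsies do not
  shrink the denominator) and 8/21 from day 4 on.
* **Survival.** Kaplan–Meier product-limit estimates per severity class
  and the k-group log-rank test (df = k − 1) come from `lifelines`;
  deaths "on day d" occur at time d exactly, ties use the standard
  log-rank tie correction, and the p-value is asymptotic chi-square. A
  label-permutation oracle exists only in the test suite, as an
  independent check of the asymptotic p on small tables.
* **Decline detection.** The first decline day of a score series is the
  smallest day whose total is below the previous *scored* day's.
* **ANOVA.** One-way ANOVA (`scipy`) with pairwise comparisons adjusted
  by Tukey HSD by default (`statsmodels`); Bonferroni and Holm on pooled
  t-tests are available because the protocol does not specify the
  adjustment. All-constant input makes F undefined; this is reported as
  F = 0, p = 1 with a warning rather than an error.

### The bundled reconstructed ledger

`reference_cohort()` rebuilds a per-animal event ledger for the
40-mouse validation cohort from its published cohort-level counts. Two
details are reconstructions, not observed data: the severity composition
of the day-3 autopsy draw (5 moderate + 3 mild + 0 severe — the unique
composition consistent with every published denominator) and the split
of mortality events into found-death vs. humane-endpoint within the
severe group. `reference_decline_trends()` likewise carries synthetic
day-by-day totals; only its first-decline days (4, 4, 4, 4, 5, 5) are
meaningful.

## Autopsy grading

Six basal-cistern segments graded 0–3 (Sugawara convention), summed to
0–18. The severity cut-points for the total are not in the protocol's
main text; the defaults (mild 0–7, moderate 8–12, severe 13–18) follow
the common tertile-style reading and are fully configurable.
Concordance with ROB severity is exact label equality by default;
"similar severity-level evaluations" is not formally defined in the
protocol, so a `within_one_level` tolerance flag is provided and the
ambiguity documented.

## Synthetic cohort simulator

The simulator targets the *statistical shape* of the validation cohort,
not hemorrhage physiology:

* **Day-1 measurements** are truncated normals per latent severity
  class, parameterised by the class-wise summary statistics of the
  validation cohort (location = printed mean, scale = printed SD,
  truncation = printed range; e.g. severe Rotarod 38 ± 60 on [0, 154],
  mild open field 643 ± 169 on [492, 891], severe BWL 11.00 ± 5.36 on
  [3.21, 16.23]). The truncated-normal family is a modelling choice —
  only range/mean/SD were reported. Note that asymmetric truncation
  shifts the realised moments away from the latent parameters (severe
  Rotarod most visibly: the reported SD of 60 on [0, 154] is not
  attainable by any truncated normal with that mean, so the printed
  summaries are treated as latent parameters, and calibration tests
  compare sample means against the truncated distribution's theoretical
  mean). Pre-operative weights are uniform on the reported 25.3–35.5 g
  range; three Rotarod trials are constructed to average exactly to the
  drawn day-1 latency.
* **Trajectories.** Values fluctuate multiplicatively (SD 5 %) around
  day 1 until a per-animal decline day drawn from {4, 5} with
  probabilities {2/3, 1/3} (the reported 4-of-6 / 2-of-6 pattern), after
  which Rotarod and open-field values shrink by 20 % of day 1 per day
  and BWL grows 2 points/day — a minimal linear-decline reconstruction;
  all parameters live in `SimulationConfig`.
* **Mortality.** Daily hazards per latent class, defaults calibrated to
  the reported pattern: severe {day 2: 1/2, day 3: 1/3, day 4: 1}
  (cumulative 1/2, 2/3, 1 — i.e. certain death by day 4), moderate
  {day 4: 2/13}, mild none. A quarter of mortality events are recorded
  as humane-endpoint euthanasia (the split was not reported).
* **Design events.** Eight scheduled autopsies drawn uniformly among
  animals alive on day 3; all survivors harvested at the day-7 horizon;
  sham animals (default n = 3) harvested after day-1 assessment.
  Autopsy segment grades come from class-specific categorical
  distributions placing severe/moderate/mild totals in their respective
  default bands.
* **Severity labels.** By default the ledger severity is the day-1 ROB
  assignment computed from the simulated raw data — protocol-faithful,
  including misclassification (latent-vs-assigned agreement ≈ 0.75
  under the defaults; tests assert a deliberately loose 0.5 majority
  floor, a calibration sanity check rather than an empirical claim).
  `severity_from="truth"` instead labels animals by latent class, giving
  groups of exactly the configured sizes — the configuration used when
  reproducing the three-group log-rank result at n = 6/18/5.
* **Reproducibility.** One seeded NumPy generator stream per cohort;
  the CLI manifest records the seed and a config hash.

Open-field distances can be realised as random-walk tracks
(`make_track_fixture`): a Gaussian random walk rescaled about its start
so the key-frame path length equals the drawn distance to ~1e-6, with an
optional rendered frame stack for marker-tracking tests. Correlation
between RT, OT and BWL within an animal beyond the shared latent class
is not modelled (no within-animal correlations were reported).

What passing tests on simulated cohorts do **not** show: anything about
real video (lighting, occlusion, marker ambiguity), about physiological
coupling between the three measurements, or about the adequacy of the
truncated-normal family for real day-1 distributions.

## Problem sizes and numerical choices

The replicated log-rank checks use 200 (acceptance script) and 500
(test suite) simulated cohorts of n = 29, reporting the median p-value;
the permutation oracle uses 10⁴ label permutations on a 32-animal
two-group table with agreement asserted to 0.05 absolute (dominated by
the asymptotic-vs-exact gap, not Monte-Carlo error). Parameter-recovery
checks use n = 1000 draws per class with a 3-SE band; class-agreement
checks use n = 500 per class. Mortality percentages are exact rational
arithmetic, rounded to two decimals only for display. Marker-tracking
recovery is asserted to 1 px on rendered stacks (disk rasterisation
contributes ≲ 0.3 px centroid error at radius 4).

## Known limitations

* The reconstructed ledger reproduces cohort-level counts; per-animal
  measurement values for the validation cohort were never published, so
  Table-level means/SDs and the reported ANOVA p-values are covered by
  simulator calibration properties instead of replication.
* The log-rank invariance suite tests adding animals censored *before*
  the first event time (a true invariance); adding late-censored animals
  changes at-risk counts and therefore the statistic.
* Severity assignment uses day-1 scores only, as in the protocol;
  dynamic re-grading is supported for decline detection but does not
  reassign classes.
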