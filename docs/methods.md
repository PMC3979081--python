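# Methods

## Scoring model

The FASSS treats the spine as 23 disco-vertebral units (DVUs), C2/C3 to
L5/S1, each bounded by the midpoints of two adjacent vertebrae. Segment
membership is cervical C2/C3..C7/T1 (6 DVUs), thoracic T1/T2..T12/L1
(12), lumbar L1/L2..L5/S1 (5). The transitional units C7/T1 and T12/L1
are scored under cervical and thoracic rules respectively; this partition
is forced by the published global maximum (6·8 + 17·24 = 456, whereas a
5/18 split would give 472). Segmental sums use the same partition.

Each DVU exposes two endplates. Sites are keyed by DVU-relative endplate
labels: *cranial* = lower endplate of the DVU's upper vertebra, *caudal* =
upper endplate of the lower vertebra. The bijection to vertebra-relative
language ("upper endplate of L3" = caudal endplate of L2/L3) is exact and
used when entering published examples. Per endplate the scoreable sites
are anterior corner, posterior corner and noncorner on the central
slices, plus (thoracolumbar only) anterior/posterior corners on left and
right lateral slices: 14 sites per thoracolumbar DVU, 6 per cervical.
Which slice a lesion falls on is a reader judgement; no slice geometry is
computed here.

Site scores: corner present 1 (+1 if large, thoracolumbar central only);
noncorner present 2 (+2 if large, thoracolumbar only); lateral corner
present 1, never size-graded; cervical sites presence-only. A *combined*
corner lesion (>50 % of the AP diameter on a central slice) contributes a
corner component of 1 (+1 if ≥25 % of body height at the anterior or
posterior cortex) and a noncorner credit of 2 (+2 if ≥25 % of height at
the endplate midpoint). The base arithmetic of the combined category
(1 + 2 before size additions) is our reading: it is the unique choice
that keeps the per-endplate central maximum of 8 attainable and
consistent with the ordinary large corner (2) and large noncorner (4)
scores.

**Noncorner deduplication.** Per endplate the noncorner component is
counted once: the maximum credit among a direct noncorner annotation and
any combined corners on that endplate. Without this rule a wide corner
lesion plus a separate noncorner mark would exceed the printed per-DVU
maximum. Corner components always add.

**Exclusions.** DVUs with unequivocal ≥50 % disc-height reduction are not
assessed. Excluded DVUs score 0 but remain flagged in every output rather
than being dropped, so longitudinal pairs stay aligned; annotations on an
excluded DVU are validation errors. How exclusion should enter totals is
not specified anywhere we know of; contributing zero is the conservative
choice and is reported transparently.

Input is sparse — only observed lesions are rows; absence scores zero. A
cervical "combined" observation is rejected at validation (cervical
lesions are not size-assessed; the category is undefined there). Both
size additions of a combined lesion may co-occur; the dedup rule caps the
result. All scores are integers and no rounding occurs anywhere in the
engine.

## Reliability statistics

**ICC.** Two-way model, patients random, readers fixed, single measures,
absolute agreement — ICC(A,1):

ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

with MSR, MSC, MSE the subject, reader and residual mean squares of the
two-way ANOVA without replication. The residual sum of squares is
computed directly from the residuals (not by subtracting sums of
squares), so perfectly agreeing readers yield MSE = 0 and ICC exactly 1.
95 % confidence bounds use the F-distribution method with Satterthwaite
degrees of freedom (the McGraw–Wong convention); the implementation
matches `pingouin`'s ICC(A,1) estimate to machine precision and its CI to
printed rounding in cross-checks. A matrix with zero total variance
returns a flagged degenerate result (NaN estimate) instead of raising, so
batch stratified runs complete. Banding: <0.4 fair, 0.4–0.6 moderate,
0.6–0.8 good, 0.8–0.9 very good, ≥0.9 excellent, boundaries assigned
upward.

**Bland–Altman.** Differences d = x − y; limits at mean(d) ± z·SD(d)
(sample SD, n−1), z the standard-normal quantile at (1+coverage)/2.
Default coverage is 0.80 (z = 1.2816), the convention used when limits of
agreement feed a smallest-detectable-change estimate.

**SDC.** SDC = z(coverage) · SD(d) / √k with k = 2 readings, i.e.
1.2816·SD(d)/√2 by default. The √2 arises because d is a difference of
two readings. The exact arithmetic conventions in the cited methodology
literature vary, so the result object exposes z, SD(d), the coverage and
k for auditing, and all three knobs are parameters.

**Descriptives and plots.** Mean, sample SD, median, quartiles by linear
interpolation between order statistics, min/max. Cumulative-probability
plotting positions are (i − 0.5)/n on the sorted values; ties keep their
own points. Both conventions are fixed and documented because published
reports rarely state them.

**Stratification.** Change-score reliability is stratified by inter-scan
interval into (0, 1.0], (1.0, 1.5], (1.5, 2.0], (2.0, ∞) years —
boundaries inclusive on the right. Strata with fewer than two patients
are reported with n and flagged statistics rather than failing.

**Discrepancy adjudication.** For paired total change scores (d1, d2):
Rule A, |d1−d2| ≥ 10 **and** |d1−d2| > |(d1+d2)/2| (relative difference
above 100 % of the pair mean; a zero mean with nonzero difference
satisfies the criterion — the comparison is division-free); Rule B,
opposite directions with d ≤ −2 and d ≥ 2; Rule C, exactly one reader
scored 0 and the other |d| ≥ 3. A patient is flagged iff any rule fires;
all fired rules are listed.

## Synthetic cohort generator

The generator emulates the structure of a two-reader longitudinal reading
exercise, not any particular cohort's data (no per-site prevalence data
are published). Per patient a latent severity is log-normal
(meanlog = log 0.04, sdlog = 1.1); a site's baseline lesion probability
is 1 − exp(−severity · w_segment · w_type) with default segment weights
thoracic 1.0 > lumbar 0.7 > cervical 0.35 and site-type weights corner
1.0, lateral 0.6, noncorner 0.5. These defaults were set analytically so
that mean baseline totals land in the low tens with an SD of comparable
magnitude and the thoracic > lumbar > cervical segment ordering holds —
the qualitative features reading exercises report — and are not claimed
to reproduce any real cohort's magnitudes. Thoracolumbar central lesions
are large with p = 0.3 and corners combined with p = 0.1; inter-scan
intervals are uniform on [0.5, 3.0] years so all four strata populate;
2 % of DVUs are degenerate/excluded, fixed across timepoints. At
follow-up lesions persist (regression probability 0.05 — fat lesions
mostly persist, but observed cohorts do see decreases in a minority of
patients) and new lesions accrue as Poisson with mean 2·interval placed
at empty sites with the same weights.

Readers record true lesions with sensitivity 0.9, hallucinate lesions at
empty sites with rate 0.005, and misgrade sizes with probability 0.1
(combined misread as ordinary large); errors are independent Bernoulli
draws per site, exam and reader, conditional on truth, with per-reader
seed streams derived from (cohort seed, reader offset) so readers are
conditionally independent. The whole pipeline is a pure function of
parameters and seeds.

What the simulator does **not** model: spatial correlation of lesions or
of reader errors, inflammation-to-fat transition dynamics, treatment
effects, reader drift or calibration over time, and systematic reader
bias. Passing recovery tests therefore show that the scoring and
statistics stack measures what it claims under a clean misclassification
model — not that any particular reliability level will be attained on
real MRI reads.

## Numerical and design choices

- All randomness uses `numpy.random.Generator` seeded via `SeedSequence`
  chains; identical seeds reproduce outputs bit-for-bit, including CSVs.
- Statistics serialize at 4 decimal places, scores as integers.
- The sparse annotation CSV cannot represent a lesion-free exam, so
  writers emit a single `exam` marker row for such exams; readers accept
  and skip it. This keeps longitudinal pairing intact when a reader finds
  nothing.
- Interval years are computed from the two exam times when both are
  present; a supplied interval overrides only in the direct
  `change_score` call.
- Test-suite problem sizes (cohorts of 8–135 patients, 200 replicates for
  variance-component recovery) were chosen as the smallest sizes at which
  the estimators' sampling noise is well below the asserted tolerances.

## Known limitations

- The combined-lesion base arithmetic and the segmental attribution of
  the transitional DVUs are documented interpretations (see above), not
  printed rules.
- The SDC formula's √2/k convention is declared, not asserted as the only
  reading of the methodology it follows.
- ICC confidence bounds assume normality of the score distributions;
  FASSS totals are right-skewed counts, so the bounds are approximate —
  as they are in the applied literature using the same method.
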