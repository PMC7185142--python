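# Methods

`reliafc` implements a reliability-first resting-state functional
connectivity (FC) analysis for a fixed set of 43 task-defined regions of
interest (ROIs) grouped into three large-scale networks — default-mode
(DN, 16 regions), frontoparietal control (CN, 14) and dorsal attention
(AN, 13) — together with a synthetic two-group cohort generator that
reproduces the statistical structure the analysis assumes, so every stage
is testable without access to patient data.

## The analysis chain

1. **Connectivity.** For each subject, FC between two regions is the
   Pearson correlation of their ROI-averaged BOLD time series; the
   analysis studies the absolute variation in coupling, so matrices store
   `|r|` with a zero diagonal (self-connections never enter any mean,
   degree or filter). Edges are indexed by the canonical upper triangle
   (i < j), 903 pairs.
2. **Network assignment.** The two group-mean `|r|` matrices are
   clustered agglomeratively on the distance `d = 1 - |r|` (average
   linkage by default; complete and Ward available) and the tree is cut
   into exactly k = 3 clusters. Clusters are labeled DN/CN/AN by the
   permutation (of the 6 possible) maximizing total overlap with the
   shipped reference labeling — an automated, reproducible replacement for
   labeling by visual inspection; ties are broken lexicographically and
   flagged. Membership shifts between the two groups' partitions are
   reported per region.
3. **Edge reliability.** For each edge, the across-subject mean `|r|`
   receives a 95% bias-corrected and accelerated (BCa) bootstrap
   confidence interval (B = 10,000 resamples by default; tests and
   repeated-cohort studies use reduced B). A subject's edge value is
   preserved iff it lies inside the retention band derived from that
   interval and set to zero otherwise; a subject whose entire filtered
   matrix is zero is excluded from further analysis. Retained values are
   then Fisher z-transformed (`atanh`), under which zeros are fixed.
4. **Graph metric.** Weighted degree centrality Dc(i) = sum of node i's
   42 edge weights on the filtered Fisher-z matrix; network-level mean FC
   is the mean over the fixed within- or between-network edge set (120,
   91, 78, 224, 208, 182 edges for a 16/14/13 partition), zeros included
   by default because a zero encodes "unreliable" and dropping zeros would
   make denominators subject-specific.
5. **Statistics.** Age, gender (0/1), education and mean framewise
   displacement are regressed out of every measure by pooled OLS (no
   group indicator — including it would absorb the effect under test);
   residuals are compared between groups with a two-sample two-tailed
   Student t test (Welch by flag). Network-level tests use P < 0.05
   uncorrected; the 903 edge tests are Benjamini-Hochberg corrected at
   q = 0.05 (edges all-zero in both groups are untestable and leave the
   family, with the family size reported); the 43 Dc tests are Bonferroni
   corrected at 0.05/43. Demographics use t tests and a Pearson
   chi-square without continuity correction for gender. MMSE
   relationships are pooled Pearson correlations with the exact-t p value.

## BCa interval

With sample mean θ̂, bootstrap means θ*_b (b = 1..B) and jackknife
leave-one-out means θ_(i):

* bias term `z0 = Phi^-1(prop)` where `prop` is the fraction of bootstrap
  means below θ̂, with ties counted half (mid-rank convention; for
  continuous data this is almost surely identical to the strict count,
  and for tied/discrete bootstrap distributions it is the convention that
  makes z0 vanish on symmetric distributions) and the proportion clamped
  to [1/(2B), 1 − 1/(2B)];
* acceleration `a = Σ d_i^3 / (6 (Σ d_i^2)^{3/2})`, `d_i = mean(θ_(·)) − θ_(i)`;
* adjusted levels `Phi(z0 + (z0 + z_q)/(1 − a(z0 + z_q)))` for
  `z_q = Phi^-1(α/2), Phi^-1(1 − α/2)`; the denominator is floored at 0.1
  as a guard against pathological acceleration (never observed in use);
* bounds are the corresponding empirical quantiles of the bootstrap means
  under the linear-interpolation quantile definition (stated because at
  B = 10,000 conventions differ by at most one quantile step).

If the jackknife spread is zero up to summation round-off, all subject
values coincide and the interval degenerates at that shared value
(returned exactly, so the value always lies inside its own interval).

Per-edge resampling streams are seeded as `default_rng([master_seed,
edge_index])` and subject values are sorted before resampling, so
intervals depend only on the multiset of values, never on subject order.

## Retention-band design (`ci_mode`)

How the BCa interval becomes a per-subject retention band is the one
place where this package departs from a naive reading, because the naive
variants are measurably broken:

* **`per_group`** — each group's own interval. A CI of the mean has
  halfwidth ≈ 1.96σ/√n_g, so the smaller group retains systematically
  more values (≈ 0.31 of values at n = 25 vs ≈ 0.22 at n = 51). Group
  size masquerades as a group difference: under an exchangeable null the
  network-level tests reject essentially always. Provided for
  completeness, not usable for between-group comparison.
* **`pooled`** — one band from all subjects. Size artifacts vanish, but a
  fixed common band transmits only ~h²/3σ² of any true group mean shift
  (h band halfwidth, σ edge SD) and the retention-fraction asymmetry can
  reverse the sign of a planted increase. Calibrated but blind.
* **`matched_width`** (default) — the pooled interval's *shape* (offsets
  from the pooled mean, one width shared by construction) recentered on
  each group's leave-one-out mean per subject. Group-specific centers
  preserve group mean differences; the common width removes the
  sample-size artifact; leave-one-out centering removes the subject's own
  leverage on its band (which would otherwise widen effective bands by
  1/(1 − 1/n_g), reintroducing a size artifact).

A structural limitation remains and is worth stating plainly: any
group-centered band transmits the sampling noise of the group mean into
the retained values while the same clipping suppresses the corresponding
between-subject variance within groups. The resulting anticonservatism
scales like (z'/z)² — negligible for strong within-network edges
(null rejection ≈ 0.06 at nominal 0.05 in 400-cohort studies) but
appreciable for weak between-network edges (≈ 0.14). This is a property
of retain-or-zero filtering against a CI-of-the-mean band, not of the
implementation; between-network "significant" differences from this
method family should be read with that in mind.

For the same reason the filter annihilates individual differences: the
derivative of a subject's expected retained value with respect to a
subject-specific shift is P − 2hφ(h) ≈ 0. Correlations between a
subject-level measure and cognition therefore cannot survive the filter
at realistic parameters, and the pipeline computes MMSE score
correlations on the *unfiltered* Fisher-z matrices (both bases are
written to the correlations table; group comparisons of Dc use the
filtered matrices as designed).

## Synthetic cohort generator

The generator emulates what the analysis consumes, not raw imaging:

* **Signal.** Per subject, a stationary AR(1) Gaussian process
  `x_t = φ x_{t−1} + ε_t`, `ε_t ~ N(0, (1−φ²)Σ)`, so the cross-sectional
  covariance is exactly the target Σ; φ = 0.4 by default, standing in for
  the temporal autocorrelation left by band-pass filtering. Only
  second-order structure matters to a Pearson-correlation analysis, so no
  hemodynamic convolution, scanner noise physics or motion time series
  are modeled. T = 235 time points by default (a typical run length at
  TR = 2 s after discarding 5 equilibration volumes; the acquisition
  length is configurable, not inferred).
* **Coupling structure.** Σ is a correlation matrix with unit diagonal
  and constant blocks: within-network coupling 0.45 for all three
  networks and between-network coupling 0.12 — a realistic
  strong-within/weak-between resting-state contrast whose
  within-vs-between gap (0.33) supports clustering recovery. The patient
  group adds +0.10 on within-DN, within-CN, DN-CN and DN-AN blocks
  (directions matching the reported findings; configurable per block).
  Optional membership shifts rebuild selected regions' rows as if they
  belonged to another network in the patient group. Positive definiteness
  is checked by eigendecomposition; increments that break it trigger an
  eigenvalue floor at 1e-6 with diagonal renormalization, recorded in the
  cohort manifest (never triggered at the defaults).
* **Individual differences.** A per-subject latent u ~ N(0,1) adds
  `0.08·u` to the score node's (L.STS, a DN region) couplings and enters
  MMSE with loading ρ = −0.4, so the node-strength/MMSE correlation is
  planted at ρ. An optional global per-subject coupling offset
  (`subject_coupling_sd`, default 0) models stable individual differences
  in overall connectivity; it is the mechanism that produces whole-subject
  exclusions by the filter (with independent edge noise alone, the
  probability that all 903 edges leave the band is ≈ 0.78^903 ≈ 0) and is
  used by tests that exercise the exclusion rule. It defaults to 0
  because trait coupling variance interacts with the band filter's
  between/within asymmetry described above; turning it on makes the
  group tests anticonservative — a generator option, documented, not a
  default study condition.
* **Covariates.** Age, education, MMSE and mean framewise displacement
  are Gaussian with the published group moments (age 73.60 ± 7.26 vs
  70.67 ± 7.00 years; education 12.28 ± 3.12 vs 12.57 ± 3.08 years; MMSE
  27.52 ± 1.44 vs 28.33 ± 1.34; motion 0.12 ± 0.07 vs 0.11 ± 0.07 mm);
  gender is Bernoulli with the published 17/8 and 26/25 ratios. MMSE is
  clipped to its 0-30 range; because the group means sit ~1.2 SD below
  the ceiling, the latent mean is raised by the analytic ceiling bias so
  the *observed* clipped mean matches the published value. Covariates are
  independent of the FC signal except through the MMSE latent, so
  nuisance regression is exercised but cannot create effects.
* **Null mode.** `group_effect = {}` and `dc_score_rho = 0` make the two
  groups exchangeable by construction (only group sizes and covariate
  distributions differ); this is the basis of the Type-I calibration
  studies.
* **Determinism.** One integer seed; per-subject streams are spawned via
  `SeedSequence`, and cohort files (one TSV per subject, `covariates.csv`,
  `manifest.json`) are written with `%.17g` and parsed with round-trip
  float precision, so write→read is lossless and reruns are byte-identical.

What passing tests on this generator do *not* show: robustness to
hemodynamic variability, motion artifacts, non-Gaussian BOLD noise,
edge-specific trait variance, or misspecified ROI definitions — none of
which are modeled.

## Validation studies and the sizes used

The repeated-cohort studies (in `reliafc.experiments`, recomputed by
`scripts/acceptance.py`) use these problem sizes, chosen to pin each rate
with a useful Monte-Carlo error at desk scale: BCa coverage for the mean
of Normal(0.3, 0.1²) with n = 50, B = 2,000, 1,000 replicates; clustering
recovery and planted-shift recovery over 20 seeded cohorts; null
calibration over 1,000 cohorts at B = 100 (the band depends on B only
through quantile noise, which is symmetric between groups); effect
recovery over 20 (network FC) and 50 (Dc-MMSE) cohorts at B = 2,000.

## Known limitations

* The between/within anticonservatism of group-centered retention bands,
  quantified above, is inherent to the method family.
* The reference labeling's laterality expansion (18 bilateral pairs + 7
  unilateral regions → 43 labels) is a constructed convention; only block
  sizes and name-keyed ordering matter to any computation.
* Degenerate inputs: constant time series, duplicate subject ids, missing
  region columns, singular nuisance designs and all-excluded groups are
  rejected with named errors rather than repaired.
* The full-scale default B = 10,000 makes a full single run take a few
  tens of seconds; repeated studies reduce B, which widens nothing and
  biases nothing in expectation but adds quantile noise to individual
  bands.
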