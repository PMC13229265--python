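# Methods

`crewnet` implements the analysis pipeline for a small isolated crew monitored
over a long mission with wearable proximity sensors and repeated
questionnaires: four two-week sensor deployments (mission months 1, 3, 6, 9),
a 12-member crew drawn from two nationality groups plus one out-group medical
doctor, two mid-mission member replacements, and roughly nine stationary room
sensors. This note records the models, the conventions chosen where the
design was genuinely open, and what the synthetic data do and do not show.

## Contact streams and temporal conventions

Inputs are post-threshold contact intervals in the SocioPatterns tabular
convention: one row `(t, i, j)` asserts that sensors *i* and *j* were in
face-to-face range (~1–1.5 m) during the 10-s slot `[t, t+10)`. Radio-level
processing (RSSI filtering and smoothing) is upstream of this package.

All intervals and deployment windows are half-open, so a contact starting
exactly at a window boundary belongs to exactly one window and concatenating
the four windows never double-counts. Days are station-local with a
configurable day-start hour (default midnight); per-day summaries depend on
this boundary, which the source data do not pin down. Roster presence spans
are inclusive day ranges; a contact is kept only if both sensors are present
on its calendar day, which removes evacuated members after departure and
replacements before arrival.

## Network metrics

Each deployment is aggregated into a static weighted graph; the edge weight is
total co-proximity seconds. Per node we compute:

* **Strength centrality** — summed incident edge weight, reported in hours.
  Room edges are included by default (rooms live in the same networks); the
  person/room split of daily-strength distributions follows the sensor whose
  day is being summarized, not its partners.
* **Gini selectivity** — population Gini
  `G = Σᵢⱼ|wᵢ−wⱼ| / (2 n² w̄)` of a node's partner-weight vector. The partner
  scope is every other wearable sensor present in that deployment, with
  zero-weight pairs included: in a fully connected crew, dropping silent pairs
  would mask exactly the selectivity the coefficient is meant to measure.
  Rooms are excluded from the scope by default. No small-sample correction is
  applied (the biased population form; exposed in the function, not hidden).
  Zero total weight leaves the coefficient undefined — flagged missing, never
  coerced to 0. Shannon entropy of the partner-weight shares is available as
  an optional companion metric.
* **Daily strength** — one value per present sensor-day; absent days (roster
  presence) are marked unavailable and excluded from all denominators, which
  is what separates "not there" from "there but silent". The value of the
  daily-strength CDF at zero is therefore exactly the zero-contact-day
  proportion. First-vs-last-deployment distribution shifts are tested with
  the two-sample Kolmogorov–Smirnov test (asymptotic two-sided p; an exact
  variant is available for small samples).
* **Group contact matrices** — total person-person hours between and within
  nationality groups, plus the same rescaled by the number of possible pairs
  (`n_g·n_h` off-diagonal, `n_g(n_g−1)/2` on it). Singleton groups have an
  undefined diagonal; the out-group member can be excluded to obtain the
  two-group matrix. Category-collapsed networks conserve total edge weight.

## Questionnaire scoring

Five instruments per wave: 20-item loneliness (options 1–4, summed, 20–80),
two 16-item paranoid-thoughts subscales — ideas of reference and persecutory
ideation (options 1–5, summed, 16–80) — 6-item cohesion, 6-item conflict
(task + relationship halves averaged into an overall index), and 3-item
individual performance (options 1–5, item means, 1–5). Sum versus mean
aggregation follows each scale's reported range. Reverse-keyed item sets are
configuration, not hard-coded: the default config assumes already-recoded
responses (as anonymized deposits usually are) and a standard-keys variant
ships for raw loneliness data. Scores require complete item sets by default;
person-mean imputation up to 10% missing items is opt-in, because silent
imputation at n ≈ 12 would be misleading. Cronbach's alpha uses the sample
covariance form and is cross-checked against an independent implementation in
the tests. Paranoid-thoughts scores strictly above 40 are flagged as severe.

## Longitudinal models

* **Repeated-measures ANOVA** — one-way within-subject, complete cases only,
  uncorrected sphericity: `F = MS_time / MS_(time×subject)` with
  df `(k−1, (k−1)(n−1))`. The degenerate all-constant panel returns F = 0
  rather than 0/0.
* **Paired t tests** — on within-person differences; two-sided by default,
  with a directional option (half the two-sided p in the observed direction)
  reported alongside, since small-sample published p-values are often
  consistent with either convention.
* **Linear growth model** — `score_pt = (β₀+u0_p) + (β₁+u1_p)·t + ε_pt` with
  random person intercepts and slopes, the two-level equivalent of a latent
  growth model: with four waves and a dozen people a full SEM adds nothing
  identifiable, and the fixed slope β₁ is the quantity of interest. Default
  time coding is the wave index 0,1,2,3; month coding 0,2,5,8 is available by
  flag, and both are reported because slope estimates depend on the coding.
  Estimation is by maximum likelihood via `statsmodels` MixedLM, falling back
  to a random-intercept-only model when the slope variance is degenerate.

  **Inference.** For balanced complete panels the random-effect design equals
  the fixed design, so the ML fixed slope reduces exactly to the mean of
  per-person OLS slopes; the package then uses the exact between-person t
  statistic (df = n−1), which is correctly calibrated at any n. For
  unbalanced panels the Wald statistic from the mixed fit is referred to a t
  distribution with n_persons − 1 df instead of the asymptotic normal, which
  is badly anti-conservative at crew-sized samples. The suite verifies ~5%
  type-I error empirically.
* **Bootstrap** — Monte-Carlo person-level resampling (all of a person's
  waves move together), percentile interval of the refitted fixed slope,
  reproducible under a fixed seed recorded in the run manifest. The study
  convention is 2,000 resamples; the bundled drivers and acceptance runs use
  500, where percentile endpoints are already stable, and the count is a
  flag. For balanced panels the refit uses the exact closed form above
  (identical point estimate), which makes the resampling vectorizable.
* **Sensitivity analysis** — any participant flagged severe on a
  paranoid-thoughts subscale is dropped and the full battery re-run; the
  exclusion is recorded in the output options.

## Within/across-person correlations

Each repeated measure is decomposed as `x_p(t) = x̄_p + δ_p(t)` (person-mean
centering; missing waves are excluded from the person's mean, and persons with
fewer than two observed waves are excluded from the within scope).
Within-person correlations are Spearman's rho on the *pooled* deviations
across persons and waves — matching a single pooled N per cell (≈ 12 persons
× 4 waves) — not an average of per-person coefficients. Across-person
correlations use the person means. p-values are the standard large-sample
approximation, two-tailed, with no multiplicity correction; cells are marked
`***`/`**`/`*` at 0.001/0.01/0.05 and `†` below 0.10. Sensor measures enter
as per-deployment strength (hours, rooms included) and Gini (rooms excluded),
the metrics' default scopes.

## Synthetic missions

The generator is a deliberately minimal behavioural model — a fixed daily
block schedule (three cafeteria meals, two work blocks in assigned rooms,
evenings in the lounge or near quarters) with Bernoulli contact emission per
10-s slot — because its job is to induce, with known expectation, exactly the
structures the metrics measure. Defaults encode the study conditions:

| parameter | default | role |
|---|---|---|
| crew | 6 IT + 5 FR + 1 out-group; 2 replaced after deployment 1 | group sizes and churn |
| deployments | 4 × 14 days at days 0, 60, 150, 240 | measurement design |
| homophily ratio | 1.2 / 1.5 / 2.0 / 2.5 across deployments | rising same-group preference |
| activity multiplier | 1.0 / 0.9 / 0.8 / 0.7 | declining daily interaction time (scales pairwise contact probability and evening lounge attendance; meals unaffected) |
| nonwear probability | 0.38 per person-day | ≈40% person zero-contact days |
| contact probability | 0.03 per co-located pair-slot (×0.5 at work) | ≈1.5–3 h daily strength |
| room-sensor probability | 0.25 social / 0.04 work per person-slot | cafeteria/lounge dominance |

Work rooms are assigned by interleaving the nationality groups and chunking,
so work co-location is group-balanced and does not itself fake homophily.
Expected per-pair contact hours are computed analytically and stored with
every dataset; realized hours converge to them (law-of-large-numbers test at
a 10× horizon).

Questionnaire panels follow the growth model above with the study's published
slopes as generating values (2.42 loneliness, 1.35 / 2.35 paranoid subscales,
−0.42 cohesion, 0.35 conflict, −0.24 performance per wave) and noise scales
chosen so the complete-case F statistics land in the published range. Two
deliberate deviations from pure linearity mirror the study narrative: a
transient mid-winter bump in ideas of reference at the polar-night wave, and
one crew member whose paranoid-thoughts scores jump above the severity
threshold from mid-mission on (driving the sensitivity analysis and the
inflated Month-6 SD). One member omits the Month-9 individual battery, so
complete cases are 9 for individual outcomes and 10 for team outcomes,
reproducing the published degrees of freedom. Outcomes can be coupled
within-person to contact strength (residual correlation with the person's
standardized strength deviation), giving the correlation stage a known
monotone signal; couplings default to the signs of the published heatmap.
Item-level expansion uses parallel items whose noise variance is solved per
wave from a target Cronbach's alpha (inter-item correlation
`ρ = α/(k − α(k−1))`), rounded and clipped to the option range, so scored
items reproduce the input score without attenuation in expectation.

**What the synthetic data do not show.** The schedule model has no behaviour:
no roles, no temporal autocorrelation in nonwear (real nonwear episodes
cluster with withdrawal), no interaction quality, no circadian structure
inside blocks, and rooms detect occupants independently rather than by radio
geometry. Passing tests demonstrate that the *estimators* recover known
structure at study size, not that real crews behave like the generator.

## Numerical choices and degenerate inputs

Truncation to scale bounds happens at generation, so extreme generating
parameters attenuate recovered slopes — estimator-recovery tests therefore
place intercepts mid-scale. Zero-variance situations are surfaced, not
patched: Gini and entropy on zero total weight, alpha on constant totals, and
Spearman on constant vectors all raise; the paired t on zero-variance nonzero
differences reports an infinite statistic with a warning. Bootstrap runs
abort if more than 10% of refits fail. Ties in ranks use average ranks
throughout.

## Known limitations

Sphericity is not corrected (by design, matching the reported analysis);
growth models assume linear trajectories and Gaussian effects; the bootstrap
is percentile-only (no BCa); the KS p-value ignores the day-level dependence
of sensor-days within persons, as does pooling deviations across persons in
the within-person correlations. These match the conventions of the analysis
being implemented rather than improving on them.

Reproduction against the study's deposited anonymized CSVs requires
downloading them into `data/osf/` (they are not redistributable here); the
dedicated acceptance test fails until that deposit is present, by design.
The deposit's column naming is unknown, so the readers accept a
column-mapping configuration.
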