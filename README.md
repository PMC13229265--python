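# crewnet

Contact-network and longitudinal psychometric analysis for small, isolated
crews monitored with wearable proximity sensors — the kind of data produced
by an Antarctic overwintering team wearing SocioPatterns-style badges for
two-week deployments at mission months 1, 3, 6 and 9, alongside a repeated
questionnaire battery (loneliness, paranoid thoughts, team cohesion, team
conflict, individual performance).

The package is written for researchers studying team dynamics in isolated,
confined and extreme (ICE) settings who need to go from raw 10-s contact
intervals and item-level survey responses to the full set of published-style
results: per-deployment interaction networks, strength and selectivity
metrics, distributional comparisons, group mixing matrices, longitudinal
change estimates, and within-person links between behaviour and experience.

## What it computes

**Sensor side.** Contacts `(t, i, j)` at 10-s resolution are aggregated per
deployment into weighted graphs with edge weight = total co-proximity time.
Per node: strength centrality `s_i = Σ_j w_ij` (hours) and the Gini
coefficient of the partner-weight vector,
`G = Σ_jk |w_j − w_k| / (2 n² w̄)`, read as interaction selectivity. Daily
strength tables separate absent days from present-but-silent days, so the
CDF of daily strength evaluated at zero is exactly the zero-contact-day
proportion; deployments are compared with two-sample Kolmogorov–Smirnov
tests. Group contact matrices report total hours between/within nationality
groups, raw and rescaled by the number of possible pairs.

**Questionnaire side.** Item responses are scored into a person × wave
outcome panel (sum or mean aggregation per each scale's convention, with
configurable reverse keys), with Cronbach's alpha per scale/wave and a
severity flag for paranoid-thoughts scores above 40.

**Longitudinal.** Complete-case repeated-measures ANOVA
(`F = MS_time / MS_(time×subject)`), paired t tests, and a linear growth
model `y_pt = (β₀+u0_p) + (β₁+u1_p)·t + ε_pt` with random person intercepts
and slopes (maximum likelihood; the two-level equivalent of a latent growth
model), plus person-level Monte-Carlo bootstrap percentile CIs for β₁ and a
sensitivity re-analysis excluding flagged participants.

**Association.** Each repeated measure is person-mean centered,
`x_p(t) = x̄_p + δ_p(t)`; Spearman correlations on the pooled deviations
give within-person associations (does a person report more conflict in the
deployments where they accumulate more contact time?), and on the person
means give across-person associations.

**Synthetic missions.** `crewnet.simulate` generates ground-truthed crew
datasets — block-scheduled room gatherings, tunable nationality homophily
rising over deployments, declining activity, nonwear lapses, mid-mission
crew replacements, and questionnaire panels with prescribed growth slopes —
so the whole pipeline is testable without any data download. See
`docs/methods.md` for the model and every default.

## Worked example

Generate a mission and run the analysis chain (a console entry point
`crewnet simulate|validate|metrics` wraps the same library calls):

```sh
python analysis/01_simulate_mission.py --seed 7
python analysis/02_network_metrics.py
python analysis/03_score_questionnaires.py
python analysis/04_longitudinal.py --seed 7
python analysis/05_association.py
```

Step 02 prints the sensor-side summary:

```
  zero-contact days: person 39.6%, room 13.7%
  KS M1 vs M9 (person daily strength): D=0.190, p=0.0038
  M1: rescaled within/cross contact ratio 1.09
  M3: rescaled within/cross contact ratio 1.41
  M6: rescaled within/cross contact ratio 1.77
  M9: rescaled within/cross contact ratio 2.18
```

Two-fifths of wearable sensor-days record no contacts (nonwear plus true
silence) against ~14% for stationary room sensors; the daily-strength
distribution shifts down significantly between the first and last
deployment; and the within-group/cross-group contact rate ratio climbs from
parity to ~2.2 — the crew increasingly mixes along nationality lines.

Step 03 flags one simulated participant whose paranoid-thoughts scores cross
the severity threshold mid-mission:

```
  severe ideas_of_reference (> 40) for participant I at ['M6', 'M9']
```

Step 04 prints the longitudinal battery (complete cases N = 9 for individual
outcomes and N = 10 for team outcomes, growth models on all 14 crew members'
available waves, bootstrap CIs from 500 person-level resamples):

```
  loneliness: F(3, 24) = 2.50, p = 0.084 (N = 9)
  cohesion: F(3, 27) = 11.50, p = 0.000 (N = 10)
  performance: F(3, 27) = 3.04, p = 0.046 (N = 10)
  loneliness: slope 2.36 [1.35, 3.43], p = 0.009
  cohesion: slope -0.40 [-0.56, -0.27], p = 0.000
  conflict: slope 0.35 [0.25, 0.45], p = 0.000
```

Loneliness rises ~2.4 scale points per wave, cohesion falls and conflict
rises; the battery is automatically re-run excluding the severe scorer.
Step 05 prints the within-person Spearman heatmap with significance marks
(`†` p<0.10 … `***` p<0.001) and writes all tables under `results/`.

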