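# hivburden

Configurational analysis of HIV disclosure and social isolation for small-N
surveys of people living with HIV (PLHIV), aimed at researchers studying
stigma and disclosure in rural or otherwise hard-to-reach populations where
sample sizes preclude conventional regression modelling.

The package implements the full analysis chain developed on a 17-respondent
pilot survey of rural PLHIV:

- **Social Isolation Index** — the unweighted sum of 15 binary exclusion
  indicators across seven domains (Family, Community, Social Support,
  Healthcare, Housing, Workplace, LGBT Community), `S = Σᵢ xᵢ ∈ [0, 15]`,
  with a participant classified *isolated* when `S ≥ 7`. The same sum is
  read elsewhere as the cumulative burden score.
- **Disclosure coding** — `Told3Plus = 1[people_told ≥ 3]` and a
  partner-disclosure flag, plus one-hot identity (LGB/Straight,
  GayOrLesbian) and race (Black/White) conditions.
- **Typology** — the 2×2 of disclosure × isolation: Adaptive Disclosure
  (1,0), High Exposure (1,1), Concealed/Resilient (0,0), Hidden
  Vulnerability (0,1).
- **Burden profiling** — group means of the cumulative burden by
  disclosure pattern, seven-domain radar profiles, and group-by-indicator
  heatmap tallies (`count`, `100·count/n`).
- **Crisp-set QCA** — truth tables over 2–5 binary conditions: one row per
  observed configuration (minimum frequency 1), with per-outcome
  *consistency* = cases-with-outcome / cases-in-row, and standard
  *coverage* = cases-with-outcome-in-row / all-cases-with-outcome. Boolean
  minimisation is deliberately out of scope.
- **Robustness** — re-running typology and truth tables under stricter
  cutoffs (e.g. Told4Plus, isolation ≥ 8) with a monotone movement audit.
- **Synthetic data** — a constraint ledger of every published marginal of
  the pilot study, a seeded solver that reconstructs a 17-record fixture
  satisfying all of them (the deposited respondent-level data is not
  required or redistributed), and a parametric generator of arbitrary-n
  random surveys.

## Worked example

```sh
hivburden fixture --seed 1 --out participants.csv
hivburden burden --input participants.csv
```

prints the mean cumulative burden by disclosure group:

```json
{
  "high_partner": {"n": 9, "mean": 9.3},
  "high_nopartner": {"n": 1, "mean": 3.0},
  "low_partner": {"n": 0, "mean": null},
  "low_nopartner": {"n": 7, "mean": 6.6}
}
```

i.e. the nine participants who disclosed widely *and* informed their sexual
partners carry the heaviest average burden (9.3 of 15 exclusion
experiences), while the seven low-disclosure participants average 6.6 —
disclosure is not uniformly protective. The truth table by sexual identity:

```sh
hivburden qca --input participants.csv \
    --conditions told3plus,informed_sex_partners,lgb,straight
```

```
 told3plus  informed_sex_partners  lgb  straight  count family_rejects friends_reject called_names work_unfair moved_stigma
         0                      0    0         1      1       0 (0.0%)       0 (0.0%)     0 (0.0%)    0 (0.0%)     0 (0.0%)
         0                      0    1         0      6      3 (50.0%)      3 (50.0%)    4 (66.7%)   1 (16.7%)    3 (50.0%)
         1                      0    0         1      1       0 (0.0%)       0 (0.0%)     0 (0.0%)    0 (0.0%)     0 (0.0%)
         1                      1    0         1      2     2 (100.0%)     2 (100.0%)   2 (100.0%)  2 (100.0%)    1 (50.0%)
         1                      1    1         0      7      3 (42.9%)      3 (42.9%)    5 (71.4%)   4 (57.1%)    3 (42.9%)
```

Each row is one observed configuration; the percentage is the consistency
of that outcome within the configuration — e.g. 71.4% of the seven
high-disclosure LGB participants report being called names, and both
high-disclosure straight participants report every rejection outcome.

The same analyses are available as library calls (`build_fixture`,
`group_mean_burden`, `build_truth_table`, `typology_table`,
`indicator_heatmap`, `run_robustness`, …); see the module docstrings.

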