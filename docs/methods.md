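# Methods

## The measurement model

Each respondent answers 15 binary exclusion items spanning seven domains
(Family, Community, Social Support, Healthcare, Housing, Workplace, LGBT
Community). All items are stored *burden-coded*: 1 means the exclusion
experience is present. The one belonging-type item ("I feel part of the
LGBT community") is therefore stored already reversed (`not_part_lgbt`);
converting a raw instrument into burden coding is the user's
responsibility at ingestion.

The Social Isolation Index is the unweighted sum of the 15 items,
`S ∈ [0, 15]`. No item-response or weighting model is applied — the
instrument is explicitly an unweighted count, and the same sum serves as
the "cumulative burden" score in the group comparisons. A respondent is
classified isolated when `S ≥ isolation_min`. The default cutoff is the
constant 7 (described in the source analysis as above-average for that
sample); it is *not* recomputed from the data at hand, because the implied
sample mean was never published and recomputing it would silently change
the classification.

Disclosure is coded two ways: breadth (`told3plus = 1[people_told ≥ 3]`,
the inclusive "three or more" reading) and relational specificity (the
partner-disclosure flag, taken as given). Identity and race enter as
one-hot condition pairs (LGB/Straight; Black/White with "other" allowed as
(0, 0)) rather than single categorical variables, exactly mirroring the
condition columns of the published truth tables — this is what permits the
race-(0,0) configuration observed in the data.

## The default indicator catalog is a stand-in

Only a handful of the 15 item wordings and the five QCA outcome items
(family rejection, friend rejection, name-calling, workplace unfairness,
moving because of stigma) are published. The shipped catalog contains
every named item and fills the domains with plausibly worded companions
(10 non-outcome items). Consequences:

- every analysis that depends only on *sums*, *outcome items*, or
  *counts* is exact;
- the domain→item mapping of the 10 unnamed items is unverifiable, so the
  seven-domain radar values have no published ground truth and are not
  asserted anywhere.

Users with the true instrument can supply a YAML catalog.

## Crisp-set QCA

Cases with identical binary condition vectors form a configuration; the
truth table lists each observed configuration (minimum frequency 1, so
tables partition n) in ascending lexicographic order with per-outcome
tallies. Consistency is the within-row outcome proportion — the quantity
printed as a percentage in the study's tables. Coverage
(`P(configuration | outcome)`) goes beyond the published tables; it is
provided because it is standard csQCA practice, and marked as such.
`identify_consistent` takes its threshold explicitly — no default is
applied, since none was published. Boolean minimisation (Quine–McCluskey,
prime implicants, fuzzy-set calibration) is out of scope: the analysis
reports raw truth tables only.

Rounding everywhere follows the printed convention: half away from zero,
one decimal in tables (66.666… → 66.7), whole percents in prose-style
cells (7/9 → 78). Unrounded values are retained internally.

## Fixture reconstruction as constraint satisfaction

The respondent-level pilot data is not redistributed. Instead, every
usable published marginal is compiled into a 96-entry machine-checkable
ledger: n = 17; identity (11/2/4) and race (13/3/1) counts; the joint
disclosure cell counts (9/1/7/0); both truth tables in full (11
configuration counts + 55 outcome cells); eleven heatmap cells; the
isolated count (10); the quadrant counts (4/6/3/4); and the three group
burden sums. Printed one-decimal means are encoded as exact integer sums
by rounding inversion (9.3 over 9 → 84; 6.6 over 7 → 46; 3.0 over 1 → 3;
each is the unique integer in range), avoiding floating-point feasibility
ambiguity.

`build_fixture` solves the ledger by staged, seeded backtracking:

1. joint identity × race allocation within each disclosure cell
   (contingency-table enumeration with margins from the two truth tables);
2. outcome bits per cell as 2×3 transportation problems (identity-table
   row sums, race-table column sums, joint-cell caps), with all five
   outcomes placed on a shared per-cell prefix so all-zero profiles
   concentrate on the same respondents;
3. bisexual designation among LGB respondents whose called-names and
   family-rejection bits are both zero — the only placement compatible
   with the gay/lesbian heatmap cells (a forced deduction, discovered by
   the solver rather than hard-coded);
4. isolated/not splits and integer score vectors per disclosure group,
   hitting the burden sums and quadrant counts within per-person bounds
   (score ≥ outcome bits set; score ≤ outcome bits + 10 free items);
5. free-indicator placement realising each score, and disclosure counts
   drawn from {0,1,2} or {3,…,10} consistently with Told3Plus (the exact
   counts were never published, so the scatter median is
   fixture-dependent and not asserted).

Every candidate is verified against the complete ledger before being
returned (the ledger checks are independent brute-force loops, not
pipeline calls); infeasibility raises with the smallest violated
constraint set found. Output is deterministic per seed; the constrained
marginals are identical across seeds, only unconstrained degrees of
freedom vary. Typical solve time is well under a second.

Two published claims are deliberately *excluded* from the ledger: the
"about half" prose for straight participants' heatmap cells (too vague to
encode), and the stricter-threshold claim that no participant remains
isolated at cutoff ≥ 8 — the latter contradicts the high-disclosure
group's burden sum (84 over 9 forces several scores ≥ 8), an internal
inconsistency of the source analysis. The robustness module treats that
claim as narrative, checking instead the monotone property that no
participant moves *against* the threshold direction.

## The random survey generator

`generate_random` draws independent respondents: a disclosure-count
distribution (default: 7/17 mass on {0,1,2}, 10/17 on {3..10}, matching
the pilot's high-disclosure share), partner disclosure with probability
0.9 given high disclosure and 0.0 given low (the pilot observed 9 of 10
and 0 of 7), identity 11/17–2/17–4/17, race 13/17–3/17–1/17, and
Bernoulli indicators at the pilot's overall outcome prevalences
(8/17, 8/17, 11/17, 7/17, 7/17) with unnamed items at a flat 0.4.
Subgroup prevalence overrides are keyed to raw-field flags only
(indicator-derived flags such as `isolated` would be circular).

What these datasets emulate: the marginal composition the pipeline
assumes. What they do not: inter-item correlation, network-recruitment
dependence, or any real disclosure→exclusion mechanism — so a green
oracle test establishes that the tallying machinery is correct, not that
any substantive pattern generalises.

## Numerical and design choices

- **Thresholds are inclusive** (≥) for both disclosure and isolation.
- **Jitter** on the scatter is uniform ±0.15 on both axes from a seeded
  generator; the published figure says only "random jitter", so a fixed
  dialect and seed were chosen for reproducibility. The median reference
  line uses the *capped* disclosure values (the plotted variable).
- **Radar** defaults to the two dominant disclosure groups (n=7 and n=9),
  omitting the single-member group for clarity; all non-empty groups are
  computable on demand, empty groups raise.
- **Empty groups / empty data**: typology and burden summaries on an
  empty dataset raise (percentages undefined); empty heatmap groups
  report n=0 with `percent=None`.
- **Missing data** is not modelled; any empty or non-binary cell is a
  validation error (the source reports complete cases).
- **Row order**: records keyed by string pid, input order preserved; truth
  tables are order-invariant and sorted lexicographically by
  configuration.

## Known limitations

- The 15-item catalog and its domain mapping are a documented stand-in;
  radar-level conclusions depend on it.
- The fixture matches the published marginals, not the deposited
  respondent-level data bit-for-bit; analyses of unconstrained quantities
  (e.g. the disclosure-count median, per-domain profiles) vary by seed.
- Whether any respondent identified outside {gay/lesbian, bisexual,
  straight} is unpublished; the margins imply not, and the fixture
  follows the margins. Hispanic ethnicity overlaps race in an unpublished
  way and is not modelled.
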