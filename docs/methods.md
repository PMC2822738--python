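# Methods

## Data model

The unit of observation is one **practice**: a roster of internal
members (GPs `P`, practice assistants `A`, practice nurses `N`) plus a
fixed list of external provider *categories* (other GPs, other practice
nurses, cardiologists, internists, physiotherapists, others). Each
member answers six tick-box questions — three chronic conditions (CHF,
COPD, diabetes/`DM`) × two directions (receiving / providing
information) — ticking colleagues by name and external providers by
category. The model distinguishes three states per question:

- a tick set (possibly empty — "responded, no connections"),
- `missing` — the question was not answered,
- whole-member nonresponse — all six questions missing.

The survey CSV dialect makes absence explicit: every
(respondent, condition, direction) combination must carry either tick
rows, a `__NONE__` sentinel, or a `__MISSING__` sentinel. This keeps
"no ties" and "no answer" from ever being conflated, which matters
because the imputation rule applies only to the latter. A member who
answered some conditions but not others is treated as missing for the
unanswered (condition, direction) only; whole-member nonresponse is
what the response rate counts.

## Network construction and orientation

For each condition and direction a binary directed adjacency over the
internal members is built: entry `(i, j) = 1` iff respondent *i* ticked
*j*. Row *i* is always *i*'s own report; in a RECEIVE network the entry
reads "i receives information from j". All degree-based statistics use
this report orientation (so out-degree counts how many alters a member
reports). External ticks are stored member → category and never enter
the internal adjacency: external providers were not surveyed, so their
ties have no reciprocal report and are taken at face value.

Every adjacency entry carries a provenance tag — `reported`, `imputed`,
or `zero_filled` — so reports can state exactly how much of a network
was reconstructed.

## Reliability (agreement) before imputation

If *i* truly receives information from *j*, *i*'s RECEIVE report should
tick *j* and *j*'s PROVIDE report should tick *i*. Agreement is simple
matching over all ordered pairs `(i, j)`, `i ≠ j`, where **both**
reports exist: a match is `receive(i, j) == provide(j, i)` — mutual
agreement on presence *or* absence. Pairs involving a missing report
are excluded from the denominator rather than counted as disagreement
(structurally absent data is not evidence of unreliability), and the
number of evaluable pairs is reported alongside the proportion so the
choice is auditable. Zero evaluable pairs yields an explicit undefined
result, never 0. Agreement must be computed before imputation — imputed
entries copy the provider report, so computing it afterwards would
mechanically inflate the value — and the pipeline enforces this order.

## Imputation

For a member *i* whose RECEIVE report is missing, entry `(i, j)` is
substituted by *j*'s providing report about *i* when that report exists
(`imputed`), and set to 0 when *j* is also silent (`zero_filled`).
Reported rows are never altered; the operation is idempotent and leaves
no missing rows. This is the deterministic reciprocal substitution
standard in sociometric missing-data handling; no model-based
(stochastic) imputation is offered.

## Metrics

All metrics operate on internal members only, normally on the imputed
receiving network; internal values keep full floating precision and are
rounded only in the reporting layer.

- **Density** = tie count / `n(n−1)`; undefined (a raised
  `UndefinedMetricError`, not a silent 0) for `n < 2`.
- **Degree centralization** (Freeman, directed normalization):
  `100 · Σᵢ (c_max − cᵢ) / (n−1)²` with `cᵢ` the observed out- or
  in-degree and `c_max` their maximum. The `(n−1)²` denominator makes a
  perfect star score exactly 100%.
- **Hierarchy** (Krackhardt): reachability is the transitive closure of
  the digraph *as-is* (no symmetrizing or dichotomizing beyond the
  already-binary ties), computed by boolean Floyd–Warshall; the value
  is the share of reachable ordered pairs not reachable in reverse,
  with 0 by convention when no pair is reachable. This
  reachability-based variant matches the verbal definition ("one-way
  information flow = strong hierarchy") and reproduces the observed
  extremes: 1.0 in sparse one-way networks, 0.0 in dense reciprocal
  ones.
- **Most central actors**: all members attaining the maximal degree for
  the mode, with disciplines rendered `P;A;N`-style. Ties are returned
  and flagged, never silently broken.

## Overlap

- **Total overlap** (pairwise): simple matching over all `n(n−1)`
  ordered dyads — equivalently `1 −` normalized Hamming distance
  between the adjacencies. Sparse networks can score high through
  shared absence, hence the second measure.
- **Connected-individuals overlap** (2 or 3 networks): tie counts
  summed across networks (a tie appearing in two networks counts once
  per network) divided by the number of distinct members incident to at
  least one tie (in- or out-) in at least one network; 0 when no ties
  exist. The prose definition of this measure admits several readings;
  the implemented one is the most literal ("total number of connections
  in two (or more) networks") and is validated against an explicit
  set-union oracle rather than against published per-practice values,
  which cannot be reverse-engineered from published marginal counts.

## External (boundary-spanner) statistics

An external connection is one member ticking one category; several
categories count separately. Reported per condition: the external
count, the external share `100 · ext / (ext + int)` (undefined when
both counts are 0), and `held/total` — the external ties held by the
most out-central internal actor. When maximal centrality is tied the
maximum held among tied actors is reported and the tie is flagged.

## Synthetic survey generator

`GeneratorConfig` draws, per condition, a true directed network with
independent Bernoulli(`tie_prob[condition]`) ties, then derives each
member's two directional reports by flipping each true entry
independently with probability `report_flip` (ε), applies
whole-member nonresponse with probability `nonresponse_prob`, and
optionally boosts one designated hub's out-tie probabilities toward 1
(`centralization_bias`) to produce star-like networks. External ticks
are Bernoulli(`external_prob`) per member × category × condition and
reported faithfully (no reciprocal informant exists to disagree with).
All draws come from one `numpy.random.default_rng(seed)` stream in
fixed order, so equal seeds give byte-identical datasets.

Because the two sides of a dyad flip independently, expected observed
agreement is `ε² + (1−ε)²` and expected observed density is
`p(1−ε) + (1−p)ε`; the test suite verifies both within three
Monte-Carlo standard errors over 200 replicates.

Defaults are calibrated to the structure of the published
eight-practice study this pipeline is designed for: roster 2 GPs + 3
assistants + 1 nurse (the median practice size, 6), condition-dependent
true densities CHF 0.25 / COPD 0.33 / DM 0.36 (the published column
means, reproducing "diabetes densest, CHF sparsest"), ε = 0.15
(expected agreement ≈ 0.75, the published mean level), nonresponse 0.2
(13 of 67 members overall), `external_prob` 0.05 (published external
counts relative to members × 6 categories). These defaults are the
test-bench conditions, not fitted parameters.

What the generator does **not** emulate: informant bias that is
asymmetric (over-reporting receiving vs providing — the flip is
symmetric by default), degree-dependent or dyad-correlated noise,
partial (per-condition) nonresponse, and any dependence between the
three condition networks beyond the shared roster. Passing
parameter-recovery tests therefore show the pipeline's correctness
under independent-noise conditions, not robustness to structured
informant bias in real surveys.

## Numerical and reporting choices

- Rounding is half-away-from-zero, applied only in report tables:
  density and hierarchy to 2 decimals, agreement and overlap to 3,
  centralization and percentages to whole numbers.
- Degenerate inputs raise typed errors (`UndefinedMetricError`,
  `SurveyFormatError`, `SurveyValidationError`) rather than returning
  sentinel numbers; undefined agreement/external shares are `None` in
  JSON output.
- The analysis pipeline contains no randomness; byte-identical inputs
  give byte-identical outputs (tested).
- Problem sizes in the test and acceptance runs — practices of order
  4–20, 200 Monte-Carlo replicates for recovery, 500 random digraphs of
  order ≤ 6 for oracle equivalence — were chosen so that brute-force
  oracles stay exact and binomial standard errors are small enough to
  detect implementation errors of one dyad.

## Known limitations

- Binary ties only; the tick-box instrument has no tie strength.
- Single-practice scope: no pooling of rosters or inter-practice
  networks, and no inferential statistics (e.g. QAP permutation tests
  for overlap) — the pipeline is descriptive by design.
- The overall mean agreement of a multi-practice study depends on the
  averaging population (per-practice means vs pooled dyads); the
  package reports both and asserts neither as canonical.
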