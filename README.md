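# practicenet

Social-network analysis of **information exchange in small primary-care
teams**. Given roster-questionnaire responses from a general practice —
each GP, practice assistant and practice nurse ticks, per chronic
condition (chronic heart failure, COPD, diabetes) and per direction
(receiving / providing information), the colleagues and external
provider categories they exchange information with — `practicenet`
builds the directed condition-specific networks and computes the
descriptive statistics used to characterize them:

- **reliability** of the sociometric reports: simple-matching agreement
  between receiving and providing reports over all ordered dyads
  `(i, j)` where both reports exist — a match means the two sides agree
  on either *presence or absence* of the tie;
- **deterministic imputation** of missing receiving reports: a
  nonrespondent's row is reconstructed from colleagues' reciprocal
  providing reports, with a zero filled only when both sides are silent;
- **density** `L / n(n-1)` of each network (L present directed ties);
- **Freeman degree centralization**
  `C = 100 · Σᵢ (c_max − cᵢ) / (n−1)²` for out- and in-degree — 100% for
  a perfect star, 0% when all degrees are equal;
- **Krackhardt hierarchy**: among ordered pairs `(i, j)` with `j`
  reachable from `i` by a directed path, the proportion for which `i`
  is *not* reachable back — 1 for a DAG, 0 for a fully reciprocated
  network;
- **multiplex overlap** between condition networks: pairwise simple
  matching over all dyads ("total overlap") and the mean number of ties
  per connected individual across 2–3 networks;
- **boundary-spanner statistics**: counts of ties to external provider
  categories, their share of all ties, and the share held by the most
  out-central internal actor.

A seeded **synthetic survey generator** produces rosters, true networks,
noisy directional reports (independent per-report flip probability ε,
so expected agreement is `ε² + (1−ε)²`) and whole-member nonresponse,
with ground truth retained for parameter-recovery testing.

## Worked example

```python
from practicenet import GeneratorConfig, generate_practice, analyze_practice
from practicenet.report import table2

ds, truth = generate_practice(GeneratorConfig(seed=7), practice_id="demo")
report = analyze_practice(ds)
print("nonresponders:", report.nonresponders,
      "response rate:", round(report.response_rate, 2))
for c, block in report.conditions.items():
    a = block.agreement
    print(f"{c.value}: ties={block.internal_ties}/{block.theoretical_max} "
          f"agreement={a.proportion:.3f} ({a.n_pairs} pairs) "
          f"imputed={block.imputed_entries}")
print(table2(report).to_string(index=False))
```

prints

```
nonresponders: ['m04'] response rate: 0.83
CHF: ties=11/30 agreement=0.600 (20 pairs) imputed=5
COPD: ties=10/30 agreement=0.650 (20 pairs) imputed=5
DM: ties=11/30 agreement=0.800 (20 pairs) imputed=5
practice_id condition  density  hierarchy  centralization_out_pct  centralization_in_pct central_disciplines
       demo       CHF     0.37       0.43                      52                     28                   N
       demo      COPD     0.33       0.65                      32                     32                   A
       demo        DM     0.37       0.00                      28                     52                 P;A
```

One member (`m04`) returned nothing, so their five receiving-row
entries per condition were imputed from colleagues' providing reports.
Agreement is evaluated *before* imputation over the 20 dyads with both
reports present. The CHF network holds 11 of 30 possible directed ties
(density 0.37); its out-degree centralization of 52% says ties
concentrate on one actor — here a nurse (`N`) is the most out-central
member. The DM network's hierarchy of 0.00 means every reachable pair
is reachable in both directions (fully reciprocal information flow).

The same pipeline runs from the shell on survey/roster CSV pairs:

```sh
practicenet simulate -o fixture --seed 7
practicenet analyze fixture/survey.csv fixture/roster.csv -o out
practicenet validate fixture/survey.csv fixture/roster.csv
practicenet export fixture/survey.csv fixture/roster.csv -o maps --fmt dot
```

`analyze` writes four summary tables (roster/agreement, network
metrics, overlap, external connections), a full-precision
`report.json`, and GraphML/DOT/edge-list exports per condition and
direction.

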