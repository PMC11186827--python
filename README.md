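# hazprio

Semi-quantitative food-safety hazard prioritisation for circular food
systems: ordinal (low/medium/high) scoring of occurrence, persistence,
transfer/accumulation and human-health severity; rule-based combination
matrices yielding presence and final priority; and a batch-mixing
Monte-Carlo simulation comparing short (single-field) and conventional
(mixed-field) supply chains.

## Layout

| module | role |
|---|---|
| `hazprio.model` | domain types, hazard registry CSV I/O, rule-set / matrix configuration |
| `hazprio.classify` | evidence → level classifiers (DT50, log K_OC, BAF, concentrations, exceedance, HBGV, DALY) |
| `hazprio.combine` | presence and priority matrices, end-to-end prioritisation, one-level sensitivity |
| `hazprio.chain_sim` | short-chain vs conventional mixing Monte Carlo, processing factors |
| `hazprio.pool_synth` | synthetic concentration pools calibrated to published summary statistics |
| `hazprio.fixtures` | the three worked case studies as code + CSV writers |
| `hazprio.cli` | `hazprio` command-line tool |

All thresholds (class bounds, the 3% exceedance rule, the 10 µg/kg bw/day
guidance-value cutoff, DALY cutoffs ...) live in a YAML-configurable
`ClassificationRuleSet`; the combination matrices are likewise data and can
be replaced via `--matrices`.

## CLI

```sh
hazprio fixtures fixtures/                 # write case-study registries + configs
hazprio classify fixtures/case1_manure_horticulture.csv --out levels.csv
hazprio prioritize fixtures/case1_manure_horticulture.csv --out prio.csv --sensitivity
hazprio simulate fixtures/wheat_pool_targets.yaml --reps 100000 --seed 1 --out table7.csv
hazprio synthesize-pool fixtures/wheat_pool_targets.yaml --seed 1 --out pools/
```

`simulate` accepts either a pool CSV (one concentration per field) or a
targets YAML, in which case a pool is synthesized first.  `--seed` is
mandatory wherever randomness is involved.

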