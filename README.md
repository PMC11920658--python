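# plurivote

Reliability analysis of machine annotations against human labels via
plurality voting over resampled response instances.

Given a pool of N independent label responses per message (default N=20,
five sentiment categories: ANTI, PRO, NEU, MIX, IR), a *machine decision* at
a given m is the plurality label among m instances drawn from the pool with
replacement, with ties broken by redrawing single instances from the pool
until one lands in the tied set. Per-message *accuracy* is the probability
that this decision matches the human label — estimated by Monte Carlo
(1000 iterations by default) or computed exactly by enumerating count
compositions of the m draws. The package aggregates these into
category-level K_m means with standard errors and ratios to the full-pool
reference K_20, builds confusion tables and misclassification-flow
percentages, and compares categories with Mann–Whitney rank tests. A
Dirichlet–multinomial generator produces synthetic corpora with tunable
expected single-instance concurrence per (platform × category) stratum, so
the whole pipeline is testable without any LLM call; an optional adapter
layer collects real pools from a pluggable backend.

## Layout

| Module | Contents |
|---|---|
| `plurivote.model` | label vocabulary, strict `parse_label`, messages, pools, corpora |
| `plurivote.io` | CSV readers/writers (messages, response pools, summaries, confusion) |
| `plurivote.engine` | resampling, plurality decisions, Monte Carlo and exact accuracy |
| `plurivote.stats` | K_m aggregation, ratios, confusion flows, Mann–Whitney U |
| `plurivote.synthetic` | Dirichlet–multinomial profiles and corpus generation |
| `plurivote.adapter` | prompt building and instance collection with mock backends |
| `plurivote.cli` | `plurivote` command-line pipeline |

## CLI

```sh
# synthetic corpus at the reference scale (1000 messages, pools of 20)
plurivote simulate --profile gpt4turbo_like --seed 7 --out runs/demo

# K_m summaries across m, confusion table, per-message accuracies
plurivote evaluate --corpus runs/demo --m 1,3,5,7,9,11,20 --iterations 1000 --seed 7
plurivote evaluate --corpus runs/demo --exact   # enumeration instead of Monte Carlo

# pairwise between-category rank tests per platform per m
plurivote compare --corpus runs/demo

# table rendering (rows = m, column blocks = category) and curves
plurivote report --summary runs/demo/summary.csv --format md --plot runs/demo/curves.png
```

Profiles are named (`gpt35_like`, `gpt4turbo_like`) or loaded from a YAML
file (see `profile.yaml` written by `simulate`). Every command writes a
`run_*.yaml` sidecar recording the resolved configuration, the seed, and
input file hashes; reruns with the same seed are byte-identical.

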