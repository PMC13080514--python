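# seedprox

Network proximity of GWAS candidate-gene sets to a seed protein on a
protein–protein interaction (PPI) network, with significance from a
degree-matched resampling null.

## The problem

Given a curated human interactome (e.g. a HIPPIE-style scored edge list), a
seed protein *s* (such as the innate-immunity adaptor MyD88), and one gene
set per GWAS study, seedprox asks whether the gene products reported by the
studies sit unexpectedly close to the seed in the network. Closeness is
summarized by three statistics over a gene set *G*:

- **level-1 interactors** — `L1 = N(s) ∩ G`, gene-set members directly
  adjacent to the seed;
- **level-2 interactors** — `L2 = {v ∈ G : d(s, v) = 2}`, members at
  shortest-path distance exactly two (the two classes partition *G* by
  distance);
- **bridging proteins** — `B = {u ∈ N(s) : ∃ v ∈ L2, (u, v) ∈ E}`, the
  intermediaries on length-2 paths. Bridging is topological, so a bridging
  protein may itself be a level-1 interactor.

Hubs make raw counts meaningless, so each observed count is compared with
`n` random gene sets of the same size whose members are drawn from the same
node-degree strata as *G* (default: exact degree, 1000 samples). For each
statistic `T` the package reports the fold change `T_obs / mean(T_null)`
and the add-one empirical upper-tail p-value

```
p = (1 + #{ T_null >= T_obs }) / (1 + n)
```

with ties counted toward the tail. A multi-study workflow flags the studies
with `min(p_L1, p_L2, p_B) < α`, pools the genes of the flagged studies,
and re-runs the analysis on the union, attributing each level-1 interactor
back to its contributing studies.

A synthetic-data module generates heavy-tailed PPI-like networks
(preferential-attachment or power-law configuration model) and gene sets
interpolating between uniform (`π = 0`, the null) and fully planted in the
seed's 2-neighborhood (`π = 1`), so calibration and power of the whole
pipeline are measurable without any download.

## Worked example

```python
import numpy as np
from seedprox import NullConfig, run_null_test
from seedprox.synthetic import (SyntheticScenario, choose_seed_node,
                                generate_network, plant_gene_set)

scenario = SyntheticScenario(n_nodes=500, rng_seed=7)
network = generate_network(scenario)
seed = choose_seed_node(network, scenario.seed_ball_coverage)
gene_set = plant_gene_set(network, seed, set_size=30, planting_prob=0.8,
                          rng=np.random.default_rng(7))
results = run_null_test(network, seed, gene_set, NullConfig(n_samples=1000, rng_seed=7))
```

prints, via `examples/02_null_model.py`:

```
seed P0030 (degree 15), gene set of 30
level1    observed=  2  null mean=  0.62  fold= 3.24  p=0.1299
level2    observed= 25  null mean=  6.89  fold= 3.63  p=0.000999
bridging  observed= 14  null mean=  7.06  fold= 1.98  p=0.000999
```

25 of the 30 planted genes land at distance two from the seed versus ~6.9
expected for degree-matched random sets (fold 3.6), and no null sample
reached the observed count (p at its floor of 1/1001): the planted
proximity is detected. The level-1 count (2 vs 0.6) is too small to be
individually significant — small counts carry little evidence.

The same analysis runs from the shell on user-supplied files:

```
seedprox run --network hippie.tsv --dialect hippie --min-score 0.7 \
    --gene-sets studies.gmt --seed-protein MYD88_HUMAN \
    --n-null 1000 --alpha 0.05 --rng-seed 1 --out results/
```

writing a per-study report (TSV + JSON), the union's level-1 member table,
the resolved configuration and a log. `seedprox simulate` and
`seedprox benchmark` generate synthetic inputs and calibration tables; the
`examples/` scripts walk through each capability.

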