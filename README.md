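# hypermem

Tools for quantifying **memory in temporal hypergraphs**: how group
interactions of a given size persist in time (intra-order correlations), how
groups of different sizes drive each other (cross-order correlations and the
cross-order gap), and generative models that reproduce those patterns.

## What it does

- **Represent** a system of time-varying group interactions as a temporal
  hypergraph (a node set plus a sequence of hyperedge sets) and project each
  order `d` onto `N x N` co-membership adjacency matrices with their annealed
  (time-averaged) matrix.
- **Measure** lag-`tau` intra-order auto-correlation functions `c(d)(tau)`,
  directed cross-order correlations `c(d1,d2)(tau)`, the normalized
  `(D-1) x (D-1)` interaction matrix `K(tau)`, and the cross-order gap
  `delta(d1,d2)(tau)` whose sign reveals a preferred temporal direction of
  group growth vs fragmentation. Raw series can be log- or linearly binned
  with per-bin means and standard deviations.
- **Compare** against a time-shuffle null model (random permutation of the
  snapshot sequence, applied to all orders jointly), including ensembles of
  reshuffled realizations.
- **Simulate** hypergraphs with tunable memory: every candidate hyperedge is
  a binary autoregressive process that either redraws Bernoulli(`y`) or
  copies a uniformly chosen past state (probability `q`, reach `m_s`); the
  cross-memory variant additionally copies from the recent past of
  *overlapping* hyperedges of other orders (probability `p`, reach `m_c`).
- **Reconstruct** group interactions from pairwise contact streams
  (`t i j` records, e.g. 20 s proximity frames) by promoting each maximal
  clique of simultaneous contacts to a hyperedge.
- **Generate fixtures** with planted, machine-checkable structure
  (i.i.d. baselines, periodic hyperedges, planted cross-order lags, toy
  contact streams).

## Command line

All commands write a JSON manifest (parameters, seeds, input digests) next to
their outputs. Exit codes: 0 ok, 2 input/config error, 1 internal error.

```sh
# promote a contact list to a hyperedge event file
hypermem reconstruct --contacts contacts.tsv --resolution 20 --out events.tsv

# correlation analysis: intra/cross/gap series + interaction matrices as CSV
hypermem analyze --events events.tsv --max-lag 1000 --bins 15 \
    --k-lags 1,30 --out-dir run/

# null-model ensemble for one statistic
hypermem null --events events.tsv --statistic gap --orders 2,3 \
    --realizations 20 --seed 7 --out null.csv

# simulate the memory models from a YAML/JSON config
hypermem simulate --model cdarh --config run.yaml --out sim.tsv

# synthetic fixtures with known ground truth
hypermem fixtures make --kind planted_cross_lag --lag 5 --seed 1 --out toy.tsv

# contact stream -> reconstruction -> analysis -> null, in one run
hypermem pipeline --contacts contacts.tsv --out-dir run/
```

A simulation config looks like:

```yaml
N: 10
D: 3
T: 30000
seed: 1
q: 0.9              # scalar, or per-order map {2: ..., 3: ...}
y: 0.2
p: {2: 0.0, 3: 0.6} # cross-copy probability per order
m_s_max: {2: 40, 3: 10}   # per-hyperedge memory sampled uniform{1..max}
m_c: {"2,3": 60}    # order-3 hyperedges read 60 past states of order-2 ones
```

Event files are plain TSV, one hyperedge per line: `t<TAB>n1,n2,...,nk`,
with `#` comments; contact streams are `t i j` lists (whitespace, tab or
comma separated, extra columns ignored).

## Package layout

| module                 | contents                                              |
|------------------------|-------------------------------------------------------|
| `hypermem.core`        | `Hyperedge`, `TemporalHypergraph`, adjacency projections, event-file I/O |
| `hypermem.correlations`| correlation/gap estimators, interaction matrix, binning, CSV round trips |
| `hypermem.nulls`       | time-shuffle null model and null ensembles            |
| `hypermem.models`      | memory-model configs and the two simulators           |
| `hypermem.reconstruct` | contact-stream parsing and maximal-clique promotion   |
| `hypermem.fixtures`    | synthetic inputs with planted ground truth            |
| `hypermem.cli`         | the `hypermem` command line                           |
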