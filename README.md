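# attractorctl

Selective control of gene-regulatory signaling modeled as an asymmetric
Hopfield network.

## The problem

A cell's expression profile can be viewed as a stable attractor of signaling
dynamics on its gene regulatory network. A cancer cell sits in a different
attractor than a healthy cell of the same tissue. Targeted interventions
(e.g. kinase inhibitors) act as strong local fields on a few genes. The
question this package answers: **which small set of genes, when forced, pushes
a cell out of the cancer attractor while leaving the normal attractor
untouched?**

It is aimed at computational/systems biologists who have a directed gene
interaction network (Entrez-ID edge list) and binarized expression profiles
of a normal and a cancer cell type, and want ranked, simulation-backed target
sets.

## The model

Each gene *i* carries a spin σ_i ∈ {−1, +1} (off/on). Two attractor patterns
ξⁿ (normal) and ξᶜ (cancer) are stored in signed couplings on the network's
directed edges (J_ij is the influence of *j* on *i*):

    p = 1:   J_ij = A_ij ξ_i ξ_j
    p = 2:   J_ij = A_ij (ξⁿ_i ξⁿ_j + ξᶜ_i ξᶜ_j) / 2

Spins follow deterministic zero-temperature updates, σ_i(t+1) =
sign(h_i(t)) with h_i = Σ_j J_ij σ_j + h_i^ext, ties resolved by a fair coin.
The overlap m^μ(t) = (1/N) Σ_i ξ^μ_i σ_i(t) measures how close the cell is to
pattern μ. In the two-pattern system a coupling vanishes exactly when its
endpoints are of unlike type (one *similarity* node with ξⁿ = ξᶜ, one
*differential* node with ξⁿ ≠ ξᶜ), so the network decouples into independent
similarity and differential subnetworks — targeting differential nodes can
never disturb the normal cell.

On top of the dynamics the package implements the network-control machinery:

- **size-1 bottlenecks** (nodes whose removal strictly halves someone's
  indegree), their iterated **control sets** and **impact** (guaranteed flips);
- **cycle clusters** (strongly connected subnetworks) acting as hysteretic
  bottlenecks, with bounds ⌈z/2⌉ ≤ N_c ≤ min(|C|, |R_red ∪ U|) on the
  critical number of nodes that must be forced, plus an enumeration search
  with simulation-based verification;
- **critical/optimal efficiencies** to rank bottlenecks of different kinds;
- target-selection **strategies**: pure/mixed efficiency-ranked, greedy
  best+1, Monte Carlo subset sampling and exhaustive search, under
  therapeutic constraints (differential-only, kinase-only, inhibit-only).

## Worked example

`examples/03_target_strategies.py` builds a 30-node random network with a
50% differential attractor pair and compares three strategies at up to four
targets (p = 2, 200 replicates for the reported curves):

```
best+1                   targets=[11, 2, 9, 14] m_cancer per k: +0.676 +0.302 +0.172 +0.103
efficiency-ranked-pure   targets=[11, 1, 13, 20] m_cancer per k: +0.676 +0.539 +0.437 +0.368
monte-carlo              targets=[1, 2, 12, 16] m_cancer per k: +0.625 +0.425 +0.236 +0.241
normal-cell magnetization stayed at +1 for every plan
```

Each column is the steady cancer magnetization after fixing the first *k*
targets: +1 means the cancer cell is unperturbed, −1 fully flipped; lower is
better. Greedy best+1 exploits synergy between targets and wins at equal
*k*, the structural efficiency ranking is cheaper but blind to overlap, and
the budget-limited Monte Carlo search sits in between here. Because every
target is a differential node, the normal cell's magnetization stays exactly
+1 — the selectivity guarantee of the two-attractor encoding.

The other examples show the toy dynamics (`01`), bottleneck/critical-number
analysis on a planted clique fixture (`02`) and the TSV/CLI round trip
(`04`).

## Command line

A thin CLI wraps the library for file-based runs:

```bash
attractorctl synth --generator clique --n 5 --outdir fixtures/clique5
attractorctl stats --edges fixtures/clique5/edges.tsv
attractorctl bounds --edges fixtures/clique5/edges.tsv --exact
attractorctl plan --edges edges.tsv --attractors attractors.tsv \
    --strategy best+1 --p 2 --max-targets 10 --out plan.json
```

Subcommands: `stats`, `partition`, `bottlenecks`, `bounds`, `plan`,
`simulate`, `synth`; all accept `--seed` and honor a YAML `--config`.

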