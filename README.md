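# rhsminer

Mining **recurrent heavy subgraphs** (RHSs) in stacks of weighted networks.

Given many weighted networks over the same gene universe — for example one
co-expression network per microarray or RNA-seq dataset — `rhsminer` finds
gene sets whose pairwise edges are *heavy* (high weight) in *many* of the
networks at once. Such recurrent patterns are far stronger evidence of a
functional module than density in any single noisy network, and keeping the
edge weights (instead of thresholding networks to binary graphs first)
preserves the signal that dichotomization destroys.

## The method in brief

The `D` networks over `N` genes form a third-order tensor
`W[i, j, k]` = weight of edge *(i, j)* in network *k* (each slice symmetric,
non-negative, zero-diagonal). An RHS is scored by its **heaviness**: the mean
edge weight over all `|networks| * C(|genes|, 2)` slots, with absent edges
counting as zero.

The discrete search is relaxed to a continuous program: find a gene
membership vector `g >= 0` and a network membership vector `d >= 0`
maximizing

```
H(g, d) = sum_k d_k * sum_{i<j} W[i, j, k] * g_i * g_j
```

subject to a sparse mixed-norm constraint on `g` (an l_p ball with `p < 1`
pushes most memberships to zero) and an l_q constraint on `d`. The non-convex
`p`-norm is handled by **multi-stage convex relaxation**: each stage solves a
weighted convex surrogate (per-gene quadratic penalties `lambda_i * g_i^2`),
then refreshes the weights at the current solution. Within a stage, the
solver alternates a closed-form update of `d` with a generalized eigenvector
power iteration for `g`. The regularized objective is non-decreasing across
stages by construction (this is tested).

From the continuous solution, discrete patterns are read off by sweeping
prefixes of the gene and network rankings and keeping every Pareto-maximal
combination that clears a heaviness filter. Each solve therefore yields a
nested **family** of RHSs — e.g. a tight 4-gene core recurring in 8 networks
inside a looser 6-gene module recurring in 7. Found patterns are masked out
and mining repeats until the tensor is exhausted.

Supporting components:

- **coexpr** — co-expression networks from expression matrices: a
  leave-one-out minimum-|r| Pearson estimator (robust to single-sample
  outliers), Fisher z-transform, per-dataset standardization, and back-
  transformation to weights in [0, 1).
- **sparsify** — probabilistic edge sampling with bias-corrected weights
  (`w/p` on kept edges) so mining on the sparsified tensor is unbiased.
- **pattern_mining** — tower extraction, family merging, binarization
  baseline.
- **enrichment** — hypergeometric tests of mined modules against gene-set
  collections (GMT), per-module Benjamini–Hochberg control, and phenotype
  enrichment of the network sets patterns recur in.
- **second_order** — module activity profiles across all networks and the
  thresholded module–module "cooperativity" correlation network.
- **synth** — seeded null tensors, planted heavy blocks, and factor-model
  expression data for validation.

See [docs/methods.md](docs/methods.md) for the mathematical details, the
parameter defaults and how they were calibrated, and known limitations.

## Worked example

Simulate a 60-gene, 12-network stack with one planted 6-gene x 6-network
block of mean weight 0.9, then mine it:

```sh
$ rhsminer simulate --n-genes 60 --n-networks 12 --block-genes 6 \
      --block-networks 6 --block-heaviness 0.9 --seed 7 --out-dir sim
sim/manifest.tsv

$ rhsminer mine sim/manifest.tsv --out families.jsonl --gmt-out modules.gmt \
      --min-genes 4 --min-networks 4 --min-heaviness 0.85 --max-patterns 1
INFO found 1 families

$ cat modules.gmt
RHS_0_0	recurs_in_8_networks_heaviness_0.855	G0013	G0018	G0039	G0057
RHS_0_1	recurs_in_7_networks_heaviness_0.859	G0010	G0013	G0018	G0019	G0039	G0057
```

The family is a two-level tower: a 4-gene core heavy in 8 networks and the
full 6-gene module heavy in 7. The planted genes (see
`sim/ground_truth.json`) are exactly `G0010 G0013 G0018 G0019 G0039 G0057` —
the module is recovered. Activity profiles and the cooperativity network for
the mined modules:

```sh
$ rhsminer second-order sim/manifest.tsv modules.gmt \
      --profiles-out profiles.tsv --edges-out coop.tsv
$ cat coop.tsv
RHS_0_0	RHS_0_1	0.90554
```

The same pipeline through the Python API:

```python
import rhsminer as rm

bg = rm.background_tensor(60, 12, seed=7)
t, truth = rm.plant_rhs(bg, rm.PlantSpec(n_genes=6, n_networks=6,
                                         heaviness=0.9, seed=8))
pair, state = rm.solve(t)
fam = rm.extract_family(t, pair, rm.RHSFilter(min_genes=4, min_networks=4,
                                              min_heaviness=0.85))
for r in fam.tower:
    print(sorted(r.genes), len(r.networks), round(r.heaviness, 3))
```

prints (deterministically):

```
['G0013', 'G0018', 'G0039', 'G0057'] 8 0.855
['G0010', 'G0013', 'G0018', 'G0019', 'G0039', 'G0057'] 7 0.859
```

Starting from expression data instead of prebuilt networks:

```sh
rhsminer simulate-expression -n 50 -s 30 --module-size 8 --seed 1 --out d1.tsv
rhsminer simulate-expression -n 50 -s 30 --module-size 8 --seed 2 --out d2.tsv
rhsminer build-networks d1.tsv d2.tsv --out-dir nets
rhsminer mine nets/manifest.tsv --out families.jsonl
```

Other subcommands: `sparsify` (edge sampling), `enrich` (gene-set
enrichment), `phenotype` (label enrichment of recurrence sets). Every run
writes a manifest with config, seeds and input hashes. Exit codes: 0 success,
2 usage error, 3 data error, 4 convergence failure.

## Reproducing results

- **Test suite** (unit, property-based and acceptance tests):

  ```sh
  python -m pytest -q tests/
  ```

  Two acceptance tests (`test_null_behavior`,
  `test_weighted_beats_unweighted`) encode aspirational targets that the
  implemented estimator provably cannot meet on Gaussian-null backgrounds
  and fail by design; see the docstring in `tests/test_acceptance.py` and
  the "Limitations" section of `docs/methods.md`. All other tests pass.

- **Verification metrics** (oracle errors, planted-block recovery rate, null
  behavior, sampling bias, weighted-vs-binarized comparison) as JSON:

  ```sh
  python scripts/acceptance.py --seed 1 --out results/acceptance.json
  ```

  All randomness in the script derives from `--seed`; repeated runs with the
  same seed are bit-identical.
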