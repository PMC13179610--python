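# regprobe

Stochastic probing of regulators in bipartite TF-gene networks.

Identifying a small set of transcription factors (TFs) with maximal joint
influence on a gene set is a combinatorial problem — already 3 TFs out of
400 give over 10 million candidate triplets. `regprobe` casts it as a
stochastic probing problem on a weighted complete bipartite graph: TFs
(*regulators*, set A) face genes (*positions*, set B), each edge `(a, b)`
carries a discrete weight distribution `D_{a,b}` over `{0, ..., V}`, and a
policy may probe up to `k` regulators (revealing their realized incident
weights) before selecting at most `l <= k` of them. Selections are scored
by the weighted maximum-coverage objective

    f_cov(S) = Σ_b max_{a∈S} w_{a,b}

(each gene credited to its best selected TF) or by the additive-separable
objectives `f_max` / `f_sum`. The library implements adaptive and
non-adaptive myopic greedy policies (Amp, Namp, AmpCov, NampCov), offline
references (submodular greedy, max-coverage IP, LP-relaxation bound), a
reproducible simulation harness, construction of deterministic TF-gene
networks from regulatory-element (RE) data with enrichment-gated edge
weights `w = |c_TF|/|C_G| · 1[p ≤ α]`, and a triplet-search application
layer with co-expression scoring. It is aimed at computational biologists
prioritizing TF sets for perturbation studies, and at anyone with a
bipartite influence network (miRNA-mRNA, ligand-receptor, ...) and a
coverage-type objective.

## Worked example

The 4×4 deterministic instance that witnesses the failure of parent
submodularity for coverage (weights in {0, 1}, `l = 2`):

```python
>>> import regprobe as rp
>>> fx = rp.counterexample_fixture()
>>> fx.weights
array([[1., 0., 0., 0.],
       [0., 1., 0., 0.],
       [0., 0., 1., 0.],
       [1., 1., 0., 1.]])
>>> rp.parent_value(fx.weights, 2, "cov", "exact")
(4.0, frozenset({2, 3}))
>>> rp.greedy_select(fx.weights, 2)
([3, 2], 4.0)
>>> rp.offline_ip(fx.weights, 2), rp.offline_lp_bound(fx.weights, 2)
(4.0, 4.0)
```

The best pair is regulators 3 and 4 (0-based 2 and 3) with coverage 4;
greedy, IP and LP all agree here. Restricting the probed set shows the
non-submodular parent: its value on {1,2}, {1,2,3}, {1,2,4}, {1,2,3,4} is
2, 2, 3, 4 — adding regulator 4 gains 1 early but 2 late.

A stochastic Network-setting run (16 TFs × 400 genes, truncated-Poisson
edges), comparing the non-adaptive coverage policy against the LP bound:

```python
>>> import numpy as np
>>> inst = rp.generate_instance("network", z=1, rng=np.random.default_rng(0))
>>> real = rp.sample_realization(inst, np.random.default_rng(1))
>>> probe_set = rp.nampcov(inst, k=8, l=4)
>>> run = rp.evaluate_probe_set(probe_set, real, l=4)
>>> lp = rp.offline_lp_bound(real.weights, 4)
>>> round(run.value, 1), round(lp, 1), round(run.value / lp, 3)
(1267.0, 1325.7, 0.956)
```

Probing 8 of 16 TFs and keeping the best 4 achieves 95.6% of an upper
bound on the best possible offline selection.

The same machinery runs from the shell:

```sh
regprobe probe --fixture counterexample --algorithm nampcov -k 4 -l 2 --out run.tsv
regprobe simulate --config spec.yaml --out results.csv
regprobe summarize --results results.csv --out summary.csv
regprobe build-network --links links.tsv --hits hits.tsv --out net.tsv
regprobe triplets --network net.tsv -k 30,40,50 -l 3 --iterations 500 \
    --seed 1 --out tally.csv
```

`build-network` consumes headered TSVs (`re_id  gene_id` links,
`re_id  tf_id` motif hits) such as those produced by enhancer-gene
prediction and motif scanning; `triplets` tallies the TF sets repeatedly
selected by a policy on the resulting deterministic network.

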