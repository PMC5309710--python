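# ibdnet

Population structure from identity-by-descent (IBD) networks.

When two people share a recent common ancestor they carry long identical
chromosome segments inherited from that ancestor. `ibdnet` turns the
pairwise totals of such segments into a weighted network and mines that
network for fine-scale population structure, following a pipeline built
for very large direct-to-consumer genotype cohorts:

1. **Segment detection** (`ibdnet.ibdseg`) — a GERMLINE-style
   word-hashing detector on phased haplotypes (non-overlapping words of
   `bits = 96` SNPs seed exact matches that are extended with zero
   mismatch tolerance; segments ≥ 5 cM are reported).
2. **Network construction** (`ibdnet.network`) — each pair with total
   IBD > 12 cM becomes an edge with weight
   `w(t) = BetaCDF(t / s; α = 2, β = 200)` ∈ [0, 1], an estimate of the
   probability that the pair's sharing reflects a common ancestor within
   ≤ 8 meioses; edges with total > 72 cM (close family) are removed
   before structure analysis. The curve can be recalibrated on
   simulations where the true meiosis count of every pair is known.
3. **Hierarchical clustering** (`ibdnet.cluster`) — recursive
   multi-level (Louvain) modularity maximization: partition the network,
   induce each large cluster's subgraph, partition again.
4. **Spectral analysis** (`ibdnet.spectral`) — Laplacian eigenmaps on
   `L = D^{-1/2} W D^{-1/2}` with unit self-weights `W(i,i) = 1`; the top
   `m = 40` eigenvectors embed the network. Clusters whose members
   project away from the origin in a rotated 2-d eigenvector view are
   extracted as *stable subsets* by a half-plane rule; a second-pass
   embedding of the residual subgraph reveals structure masked by the
   dominant blocks, and a Nyström extension projects outside samples
   onto an existing embedding.
5. **Annotation** (`ibdnet.annotate`) — birth-location grids (0.5°) with
   member/non-member odds ratios, kernel PCA of region-level IBD with
   kernel `K(i,j) = t(i,j) / √(d(i) d(j))`, Hudson ratio-of-averages
   F_ST between clusters, and the closed-form single-ancestor IBD
   probability `(1/2)^{g_a+g_b-1}`.

Because real cohorts of this kind are proprietary, the package ships a
first-class synthetic-data module (`ibdnet.simpop`): multi-deme pedigrees
with migration, gene-dropped genomes with ground-truth IBD segments,
Balding–Nichols genotypes painted onto the mosaics, and genealogical
birth annotations — everything needed to exercise and validate every
stage end to end.

## Worked example

```python
from ibdnet.pipeline import desk_config, run_all, evaluate_recovery

cfg = desk_config(seed=1)
cfg.simulation.demes = ["D0", "D1", "D2"]   # three planted populations
cfg.simulation.deme_size = 80               # per generation and deme
cfg.simulation.n_generations = 5
cfg.simulation.n_snps = 1000
cfg.clustering.min_cluster_size = 30
results = run_all(cfg, "out/")
report = evaluate_recovery(results)
print(results["manifest"]["counts"])
print(report["ari_level1"])
```

prints

```
{'individuals': 1440, 'samples': 240, 'truth_segments': 73002,
 'pairs_over_min_total': 10027, 'vertices': 240, 'edges': 3592,
 'largest_component': 240, 'clusters_level1': 3, 'stable_subsets': 3}
0.9272110969160731
```

Reading: the simulation produced a 1,440-node pedigree whose 240
genotyped individuals share 73,002 ground-truth segments ≥ 5 cM; 10,027
pairs exceed 5 cM total, and after the 12 cM inclusion / 72 cM family
thresholds the network has 3,592 edges in a single connected component.
Top-level clustering finds exactly the three planted demes (adjusted
Rand index 0.93 against the true deme labels — a few recent-migrant
lineages sit between demes), and all three clusters separate from the
origin in the spectral embedding as stable subsets with false-positive
rates ≤ 0.05. Hudson F_ST between the two largest clusters comes out at
0.038 for this run, and kernel PCA places the three demes at distinct
positions on PC1/PC2 (`results["kernel_scores"]`).

The same pipeline is scriptable from the shell:

```bash
ibdnet run --seed 1 --out out/                 # full desk-scale pipeline
ibdnet simulate --demes 5 --deme-size 200 --out sim/
ibdnet detect-ibd --vcf sim/genotypes.vcf --map sim/genotypes.map --out sim/detected.match
ibdnet build-network --match sim/detected.match --out sim/edges.tsv
ibdnet cluster --edges sim/edges.tsv --levels 2 --out sim/clusters.tsv
```

## Documentation

`docs/methods.md` describes the models, parameters, numerical choices
and limitations in detail.
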