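# snpig

Information-theoretic detection of pairwise and high-order SNP
interactions in case/control genotype data.

Single-locus association tests miss loci whose effect on a complex disease
is mostly epistatic — visible only jointly with another locus.  `snpig`
scores every SNP pair with the **interaction gain**

    IG(X; Y; P) = I(X; Y | P) − I(X; Y)

where X, Y are genotypes coded as minor-allele counts {0, 1, 2} and P is
the case/control label.  IG (in bits) is the information about the
phenotype carried jointly by the pair beyond the two loci separately: 0
for independent SNPs, up to 1 bit for a pure XOR penetrance pattern, and —
crucially — large even when both marginal effects are absent.  No disease
model needs to be specified.

On top of the exhaustive pair scan the package provides:

* **LD pruning** of high-IG pairs driven by linkage rather than epistasis
  (genotype-correlation r² > 0.8 discarded) and classification of each
  pair into five location forms (within-gene, gene–gene,
  intergenic–intergenic, gene–intergenic, cross-chromosome);
* the **SNP–SNP interaction network** of pairs with IG > α (default 0.1),
  with degree / shortest-path distributions and main-effect SNP ranking by
  degree and betweenness centrality;
* **high-order interactions** as dense network modules, via a
  deterministic reimplementation of the MCODE seed-expansion algorithm;
* **permutation validation**: a column-permutation null, empirical
  p-values, Bonferroni thresholds (both C(M,2) and self-inclusive M²
  test-count conventions) and per-threshold empirical FDR;
* a **simulator** of case/control datasets under four classical two-locus
  epistatic odds models (multiplicative, two epistatic patterns, XOR) with
  (δ, t) solved numerically from prevalence and heritability, plus a
  **power harness** over the model × MAF grid.

## Worked example

Simulate a 100-SNP dataset under the XOR model (disease-SNP MAF 0.4,
prevalence 0.1, heritability 0.02; the interacting pair is planted at the
first and last index), scan all pairs, and rank:

```python
from snpig import (SimulationConfig, simulate_dataset, scan_all_pairs,
                   ScanConfig, filter_pairs, build_network)

ds = simulate_dataset(SimulationConfig(model_id=4, maf_disease=0.4,
                                       heritability=0.02, n_cases=800,
                                       n_controls=800, n_snps=100, seed=7))
print(ds.model.delta, ds.model.t)          # 0.0612, 1.7167 (solved odds params)
rec = scan_all_pairs(ds.genotypes, ds.phenotype)
print(rec.sort_values("ig", ascending=False).head(3))
```

```
snp_a snp_b       ig    mi_xy      cmi       r2
   x1  x100 0.048394 0.029534 0.077928 0.000330
 x100   x45 0.009829 0.001036 0.010865 0.000133
  x30   x70 0.008748 0.000856 0.009604 0.000007
```

The planted pair (x1, x100) tops the ranking at IG ≈ 0.048 bits —
five times the best null pair — with `cmi` (I(X;Y|P)) and `mi_xy`
(I(X;Y)) showing the gain comes from phenotype-conditional dependence,
not LD (r² ≈ 0.0003).  Filtering at α = 0.01 keeps exactly this pair and
`build_network` turns the survivors into the interaction network used for
module detection and centrality ranking.

The same pipeline from the shell:

```sh
snpig simulate --model 4 --maf 0.4 --snps 100 --seed 7 --out data/
snpig scan data/ --alpha 0.01 --out records.tsv --filtered-out kept.tsv
snpig network kept.tsv --edges-out edges.tsv --centrality-out centrality.tsv
snpig modules kept.tsv --out modules.tsv
snpig power --model 1 --maf 0.1 --replicates 100 --out power.tsv
```

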