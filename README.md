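# qttnet

Covariate-adjusted association of plasma metabolites with tissue
transcriptomes, and the co-expression network analyses built on top of it.

`qttnet` is aimed at systems-biology studies that profile a small cohort
(tens of animals, several breeds/lines and both sexes) across multiple
tissues with expression arrays, alongside a panel of blood metabolites. It
implements, as a tested library plus a thin CLI:

* **QTT calling** — for each probeset *i*, trait *t* and tissue, the linear
  model `y_t = μ + sex + breed + x_i + e`; probeset *i* is a *quantitative
  trait transcript* (QTT) when the two-sided t-test on its coefficient gives
  nominal p < 0.01. Equivalently, with `r` the partial correlation of
  sex/breed-residualized trait and expression, `t = r√df / √(1−r²)` at
  `df = n − p − 1` (p = design rank). The false discovery rate is estimated
  by re-assigning whole phenotype rows (trait + covariates) to samples for
  20 permutations: `FDR = mean permuted QTT count / observed count`.
* **Cross-tissue overlap** — hypergeometric (one-sided Fisher) enrichment of
  the QTT shared by two tissues against the expectation |A||B|/N over the
  array universe, Bonferroni-corrected across all (trait, tissue-pair)
  tests.
* **GSEA** — probesets collapsed to genes by averaging; genes ranked by
  partial correlation with the trait (conditional on sex and breed);
  weighted Kolmogorov–Smirnov enrichment score per gene set; NES, nominal p
  and FDR q from phenotype-row permutations.
* **Weighted co-expression networks** — unsigned adjacency `a_ij = |r_ij|^β`
  on sex/breed residuals, β chosen by the scale-free criterion
  `P(K) ∝ K^−γ`; topological-overlap dissimilarity; adaptive dendrogram cut
  into modules; whole-network and intramodular connectivity.
* **Multi-tissue network** — the QTT of one trait from all tissues pooled as
  tissue-tagged nodes, with standardized inter-tissue connectivity (mean
  adjacency to external-tissue nodes), tissue-pair connection strength,
  module–tissue enrichment, top-10% intramodular hubs, and signed hub edges
  at nominal p < 1e-4 with BH FDR < 0.05.
* **Synthetic cohorts** — a generator planting breed/sex effects, latent-
  factor co-expression modules and trait-associated probesets with known
  partial correlation, so every stage is testable without any download.

## Worked example

```python
from qttnet import (SimulationDesign, simulate_cohort, QTTModel, RunConfig,
                    residualize, MultiTissueNetwork)
from qttnet.overlap import overlap_scan, overlap_table

design = SimulationDesign(n_probesets=500, n_tissues=3, n_traits=4, n_true_qtt=40)
pheno, expr, truth = simulate_cohort(design, seed=1)
cfg = RunConfig(rng_seed=1, min_module_size=20)

qtt, resid = {}, {}
for tissue, mat in expr.items():
    results = QTTModel(mat, pheno, tissue).fit(traits=["NEFA"], config=cfg)
    qtt[tissue] = results["NEFA"]
    resid[tissue] = residualize(mat, pheno)
    print(results.summary().to_string(index=False))
```

```
tissue trait  n_qtt  alpha  n_permutations  permuted_mean      fdr
  FATB  NEFA     35   0.01              20            3.8 0.108571
  GONA  NEFA     39   0.01              20           3.55 0.091026
  AHYP  NEFA     74   0.01              20            3.6 0.048649
```

35–74 probesets associate with the NEFA-like trait per tissue at p < 0.01;
permutations of the phenotype labels yield only ~3.6–3.8 hits, so the
estimated FDR is 5–11% — most calls are real, as expected with 40 planted
associations per tissue. The shared planted signal shows up as cross-tissue
overlap far above chance:

```python
scan = overlap_scan({(t, "NEFA"): q for t, q in qtt.items()}, universe=500)
print(overlap_table(scan[:3]).to_string(index=False))
```

```
trait tissue1 tissue2  observed  expected      fold        p_raw  p_bonferroni
 NEFA    FATB    GONA        29     2.730 10.622711 9.891969e-33  2.967591e-32
 NEFA    AHYP    GONA        33     5.772  5.717256 4.767265e-25  1.430179e-24
 NEFA    AHYP    FATB        28     5.180  5.405405 1.168801e-19  3.506404e-19
```

29 probesets are QTT in both backfat and gonad where 2.7 are expected — a
10.6-fold enrichment. Finally the pooled multi-tissue network:

```python
net = MultiTissueNetwork(qtt, resid, pheno=pheno).fit(cfg)
print(net.summary().to_string(index=False))
print(net.median_inter_tissue_connectivity().round(3).to_string())
```

```
 module  size  n_hubs
      1   106      11
      2    38       4
tissue
FATB    0.097
GONA    0.085
AHYP    0.014
```

The 148 pooled QTT nodes split into two modules (hubs = top 10% by
intramodular connectivity), and the per-tissue median standardized
inter-tissue connectivity ranks which tissue is most strongly wired to the
others.

A full run (simulation → metabolite models → QTT → overlap → GSEA →
networks → multi-tissue network) is driven by one YAML file:

```bash
qttnet run-all --config run.yaml --outdir out --seed 1
```

See `docs/methods.md` for the model details, defaults and limitations.

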