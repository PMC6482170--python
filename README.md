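# ibnra

Prediction of lncRNA–protein interactions by a similarity-weighted
bipartite-network recommender with second-order correlation elimination.

Long non-coding RNAs act largely by binding proteins, but testing candidate
partners experimentally is slow and expensive. Given a catalogue of known
lncRNA–protein interactions — optionally enriched with protein–protein
interaction (PPI) scores and lncRNA tissue-expression profiles — this
package ranks, for each lncRNA, the proteins it is most likely to interact
with. It is aimed at computational biologists doing network-based
association prediction; everything is driven from Python, with a thin
`ibnra` command line for file-based runs.

## The method

Known interactions form a binary matrix *I* (proteins × lncRNAs). Two
similarity matrices are built:

- **Proteins** — degree-normalized PPI scores
  *AP′(i,j) = AP(i,j)/√(R(i)R(j))*, integrated with a Gaussian
  interaction-profile kernel *KP(i,j) = exp(−β‖X(pᵢ)−X(pⱼ)‖²)* over the rows
  of *I* (averaged where a PPI score exists, kernel-only elsewhere).
- **lncRNAs** — absolute Pearson correlation of expression profiles,
  averaged with the same kernel over the columns of *I*.

The kernel bandwidth is β = β′ / (mean squared profile norm), β′ = 1 by
default.

Each known edge receives an initial score from both views,
*S_ini = γS^P + (1−γ)S^L* (γ = 0.5), and a two-round resource allocation —
proteins push score to their lncRNAs, which push it back — collapses into a
column-stochastic protein–protein weight matrix

  *W(i,j) = (1/d(pⱼ)) Σₖ S_ini(i,k) S_ini(j,k)/d(lₖ)*.

Proteins sharing an lncRNA are also correlated indirectly through
intermediary proteins; this redundancy is subtracted with

  *W′ = W + αW²*, α ∈ (−1, 0] (default −0.70),

and the final scores are *S_fin′ = W′ S_ini*, ranked per lncRNA in
descending order. Collaborative filtering, random walk with restart on the
protein similarity network, and the classical unweighted two-round
allocation (LPBNI-style) are included as baselines, and a leakage-safe
LOOCV / k-fold cross-validation harness computes ROC/PR curves, AUC, AUPR
and thresholded confusion metrics.

## Worked example

No external data is needed: the `synthetic` module plants block structure
(functional communities) into all three input kinds.

```python
from ibnra.evaluation import make_folds, run_cv
from ibnra.synthetic import PlantedBlockSpec, generate_dataset

net, expr, ppi, _ = generate_dataset(PlantedBlockSpec(seed=7))
plan = make_folds(net, "kfold", k=10, seed=7)
for method in ("ibnra", "lpbni", "rwr", "cf"):
    report = run_cv(net, plan, method, expr, ppi)
    print(f"{method:8s} {report.auc:7.4f} {report.aupr:7.4f}")
```

prints

```
ibnra     0.8838  0.1602
lpbni     0.8853  0.1624
rwr       0.7555  0.0714
cf        0.6596  0.0658
```

AUC is the probability that a held-out true interaction outranks a random
non-interaction (0.5 = chance); AUPR weighs early precision, which matters
because true partners are rare. The two bipartite-allocation methods
recover most hidden edges on this benchmark, while the neighbourhood
methods trail. `examples/` holds runnable scripts for dataset simulation,
candidate ranking, cross-validation and the α sweep; the same workflows
are available from the shell:

```bash
ibnra simulate --out-dir data --seed 7
ibnra predict  --interactions data/interactions.tsv --ppi data/ppi.tsv \
               --expression data/expression.tsv --out-dir run
ibnra evaluate --interactions data/interactions.tsv --scheme kfold --k 10 \
               --seed 7 --out-dir eval
```

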