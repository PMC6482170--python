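# Methods

## Model

The data are a bipartite graph: a binary matrix *I* with one row per
protein and one column per lncRNA, *I(i,j) = 1* when the pair is an
experimentally supported interaction. The prediction task is a
recommender problem — for each lncRNA, rank the proteins not yet linked to
it — solved by resource allocation (mass spreading) over the graph, with
three refinements over the classical unweighted scheme:

1. **Weighted edges.** Instead of giving every known edge one unit of
   resource, each edge (pᵢ, lⱼ) is weighted by how typical it looks under
   two independent views: the fraction of proteins similar to pᵢ that bind
   lⱼ (protein view, S^P) and the total similarity of lⱼ to the lncRNAs
   bound by pᵢ, normalized by lⱼ's total similarity (lncRNA view, S^L).
   The initial score matrix is the blend S_ini = γS^P + (1−γ)S^L. Both
   S^P and S^L are supported exactly on the known edges; entries lie in
   [0, 1].
2. **Two-round allocation.** For a target lncRNA, each protein starts with
   its S_ini entry, distributes it over its lncRNA neighbours in
   proportion to edge weight over the protein's weighted degree d(p), and
   the lncRNAs return the collected mass to proteins in proportion to edge
   weight over lncRNA degree d(l). The two rounds collapse into the
   protein–protein matrix W(i,j) = (1/d(pⱼ)) Σₖ S_ini(i,k)S_ini(j,k)/d(lₖ)
   applied to each S_ini column. W is column-stochastic over proteins with
   positive degree, so each column's mass is conserved — a convenient
   invariant that the tests assert numerically.
3. **Second-order elimination.** Two proteins sharing an lncRNA are also
   connected at second order through intermediary proteins; this
   redundancy inflates scores of promiscuous hubs. W′ = W + αW² with
   α ∈ (−1, 0] subtracts it. Column sums become 1 + α and individual
   entries of W′ (hence final scores) may go negative; ranking uses the
   raw scores without clipping, since the transform is applied as-is and
   only the order matters.

Final scores are S_fin′ = W′S_ini. With identity similarity matrices the
initial scores reduce to *I* itself and α = 0 recovers the classical
unweighted two-round allocation exactly — this reduction doubles as a
cross-check against an independently coded projection oracle in the test
suite.

## Similarities

- **PPI normalization** divides each score by the geometric mean of the
  two proteins' total scores; proteins absent from the PPI table keep zero
  rows rather than triggering a division by zero.
- **Gaussian interaction-profile kernel**: K(i,j) = exp(−β‖Xᵢ−Xⱼ‖²) with
  profiles X taken from *I* and β = β′/(mean squared profile norm). β′ = 1
  on both axes by default — the standard convention for interaction-profile
  kernels; both are exposed as parameters. The kernel is built from
  whatever interaction matrix is current: during cross-validation that is
  the fold's masked matrix (see Leakage below).
- **Expression similarity** is |Pearson r| between tissue profiles. A
  constant profile has undefined correlation; it gets similarity 0 to all
  others (the least-informative choice) with its diagonal forced to 1. The
  sample-covariance convention is used for intermediates; |r| is identical
  under either convention.
- **Integration**: the protein matrix averages normalized PPI with the
  kernel where a PPI score exists and falls back to the kernel elsewhere
  (the existence test is per entry); the lncRNA matrix is the plain
  average. When no PPI table or expression table is supplied, the affected
  axis uses the kernel alone.

One printed form of the lncRNA-side normalizer is ambiguous (its index is
unbound); this implementation normalizes by the total similarity to the
scored lncRNA, which makes S^L a proper convex weight in [0, 1]. A
`literal_denominator` switch reproduces the mechanical alternative reading
(row index reused as a column index) for comparison only.

## Parameters

| name | default | meaning |
|------|---------|---------|
| γ (`gamma`) | 0.5 | protein- vs lncRNA-view weight in S_ini; 0.5 weighs them equally |
| α (`alpha`) | −0.70 | second-order elimination strength; 0 disables |
| β′ protein / lncRNA | 1.0 | kernel bandwidth adjustments |
| RWR restart r | 0.5 | baseline only; tol 1e-8, max 1000 iterations |
| threshold rule | max-F1 | cutoff for the scalar confusion metrics; `youden` and `fixed:<x>` available |

The α default follows the reference choice for this method family; on any
new dataset the `alpha_sweep` utility (or `ibnra evaluate --sweep-alpha`)
reprofiles it cheaply, because W is α-independent and each fold is only
rescored.

## Evaluation protocol

Folds partition the known edges (LOOCV: one per fold; k-fold: seeded
shuffle, near-even split). Per fold the test edges are zeroed in *I* and
**everything** — both kernels, both integrated similarities, S^P, S^L,
S_ini, W — is recomputed from the masked matrix. Test edges are the
positives; the negatives are all pairs absent from the *full* network,
restricted to lncRNAs that have a test edge in the fold (this keeps LOOCV
to one candidate list per held-out edge, the standard recommender
protocol). Scores are pooled across folds.

- AUC is computed by trapezoidal integration of the ROC curve; it equals
  the Mann–Whitney pairwise statistic with ties counted ½ (asserted
  against a brute-force pair counter).
- AUPR is the non-interpolated average-precision summation
  Σ (Rₙ−Rₙ₋₁)Pₙ.
- Scalar metrics (precision, sensitivity, accuracy, F1, Matthews
  correlation) use the standard confusion-matrix formulas at the chosen
  threshold, with MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN));
  zero denominators yield 0 with a degeneracy flag.

**Leakage guard.** Masking can only remove support, so every matrix whose
support should equal the training interactions (I, S^P, S^L, S_ini) is
asserted to be exactly zero at held-out positions in every fold; the
maximum observed value is recorded in the report (0.0 in a correct run).

**Cold nodes.** Masking can leave a protein or lncRNA with zero training
degree. All degree-normalized quantities treat zero-degree terms as
contributing nothing (no division occurs); such nodes receive zero scores
and a warning. Resource allocation cannot score an lncRNA with no
remaining training edges — an inherent limit of the method family.

## Synthetic data

The planted-block generator is the package's test bed. Proteins and
lncRNAs are assigned round-robin to blocks (deterministic ground truth);
pairs interact with probability `p_in` within a block and `p_out` across;
the raw draw is degree-2 filtered like any real input. Expression profiles
are a per-block standard-normal tissue signature plus i.i.d. noise
(sd 0.5 against unit signal by default, giving within-block |r| ≈ 0.8 —
strong but noisy, like co-regulated transcripts in a tissue atlas). PPI
scores cover all within-block pairs at U(0.5, 1] and a 5% background of
half-scale cross-block scores. Defaults (60 proteins, 200 lncRNAs, 4
blocks, p_in = 0.5, p_out = 0.02, 24 tissues) produce ~1,700 interactions
— small enough that a full 10-fold CV with per-fold refits runs in well
under a second, while leaving a planted signal strong enough that
recovering it (cross-validated AUC far above chance) is a meaningful
correctness check.

What the generator does *not* emulate: the heavy-tailed degree
distributions of curated interaction databases, correlated noise across
tissues, sequence or structure features, and score calibration of real
PPI channels. Passing tests therefore demonstrate that the algorithm
recovers planted community structure under its own assumptions, not any
particular performance level on curated catalogues.

## Numerical and design choices

- Degree-1 filtering of input networks is iterated to a fixed point:
  removing a node can drop a neighbour to degree 1, and only the fixed
  point is idempotent and self-consistent with the "every node has ≥ 2
  interactions" contract.
- Axis order everywhere is first appearance in the edge list; reruns are
  byte-identical. Rank ties break by protein id, lexicographically.
- All matrices are dense; at the intended scales (tens of proteins,
  hundreds to thousands of lncRNAs) dense BLAS beats sparse bookkeeping.
  The explicit per-column loop form of the allocation is kept as a
  readable oracle for the matrix path (they agree to 1e-10 on random
  instances) and is not used in production.
- The RWR baseline zeroes the similarity diagonal before column
  normalization (self-loops would dampen propagation) and its fixed-point
  iteration is a contraction for r ∈ (0, 1], checked by a residual test.
- Randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; there is no global random state.

## Known limitations

- Cold-start lncRNAs (no known partner) cannot be scored by any
  allocation-based method here.
- The negative class in evaluation treats unobserved pairs as
  non-interactions; undiscovered true interactions deflate measured
  precision.
- Elimination is second-order only; higher-order terms (αW² + α′W³ + …)
  are out of scope, as are lncRNA-side projections (proteins are ranked
  for lncRNAs, not vice versa).
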