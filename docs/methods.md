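# Methods

## Model

`pbmda` scores miRNA–disease pairs on a three-layer heterogeneous graph.
The bipartite layer is the binary association matrix `Y` (`Y[i,j] = 1` iff
miRNA *i* is known to be associated with disease *j*). The two
within-type layers are integrated similarity matrices:

* `Sm` for miRNAs: the precomputed functional similarity `FS` wherever a
  pair is *covered* by it, else the Gaussian interaction-profile kernel
  `KM` computed from `Y`;
* `Sd` for diseases: DAG-based semantic similarity `SS` wherever both
  diseases carry an ontology DAG, else the kernel `KD`.

Coverage is knowledge-presence, not non-zeroness: an explicit 0 in `FS`
is kept as 0, while an absent pair falls back to the kernel. (The
alternative reading, nonzero ⇒ covered, is available via
`integrate_similarity(..., coverage_from_nonzero=True)`.)

**Semantic similarity.** A disease's DAG consists of the disease term and
its ancestors. The contribution of term *t* to disease *D* is 1 for
*t = D* and `Δ · max over t's DAG-internal children` otherwise; a term
reachable at several depths takes its max-path value, computed by
memoized dynamic programming (the max is otherwise ill-defined on diamond
motifs). The similarity of two diseases is the sum of both contributions
over shared terms, normalized by the sum of the two semantic values.
`Δ = 0.5` by default.

**Kernel similarity.** `K(i,j) = exp(−γ ‖IP_i − IP_j‖²)` with
`γ = γ′ / mean‖IP‖²` and `γ′ = 1`. For binary profiles `‖IP‖²` is the
association count, so `γ` adapts to the network's density. An all-zero
profile is legal (its kernel row is still defined); only an entirely
empty `Y` is an error, since the bandwidth would be undefined.

**Path score.** Similarity edges with weight `< T` (default 0.5) are
dropped — a weight equal to `T` survives — and the diagonals are zeroed,
since a self-loop step would revisit a node. Association edges are binary
and never thresholded. Then

`score(m, d) = Σ_p (∏ w_e)^(α · len(p))`

over simple paths `p` from `m` to `d` with at most `L` edges. Defaults
`T = 0.5`, `L = 3`, `α = 2.26` follow the established parameterization of
this model family. All path shapes allowed by acyclicity are admitted,
including miRNA→disease→miRNA→disease.

## Engines

The `dfs` engine enumerates simple paths with an explicit stack, a
per-branch visited set, and deterministic lexicographic child ordering
(reproducible path lists, no recursion-depth limits). The `matrix` engine
evaluates the same sum for `L ≤ 3` from elementwise-powered weight
matrices — each length-`l` shape uses weights raised to `α·l` — combined
over the shapes MD; MM·MD, MD·DD; MM·MM·MD, MM·MD·DD, MD·DD·DD,
MD·MDᵀ·MD, with walk-revisit corrections: length-3 walks that re-enter
the start miRNA (`diag(M₃²)·Y`), leave through the terminal disease
(`Y·diag(D₃²)`), and the inclusion–exclusion corrections for the
m-d-m-d shape (`deg_m·Y`, `Y·deg_d`, plus `Y` added back for the doubly
degenerate walks). The corrections are validated solely by elementwise
equivalence with the dfs engine, which is the reference implementation;
tests additionally check dfs against an independent `networkx`
simple-path enumerator.

## Evaluation

Each held-out positive is reduced to its normalized rank
`u = (#candidates above + ½ #ties) / #candidates` within its own
iteration's candidate pool (all pairs with no known association; other
held-out positives of the same fold are never used as negatives). Pooling
the `u` values gives a single ROC — `TPR(x) = frac(u ≤ x)` against
`FPR(x) = x` — whose area is `mean(1 − u)`, the pairwise-comparison AUC
with the mid-probability tie convention. Normalized ranks make diseases
with different candidate counts commensurable, which is what local LOOCV
needs; a per-disease-average variant is available via
`CVConfig(average_per_disease=True)` for sensitivity checks. The
stand-alone `roc_auc` operation (threshold sweep over raw scores) is
backed by scikit-learn's ROC machinery.

Kernels are recomputed from the training `Y` in every iteration/fold by
default: the kernels derive from `Y`, and leaving test edges in place
would leak labels. `recompute_kernels=False` is an explicit escape hatch
for speed comparisons only. In k-fold CV, each repeat draws its division
from a counter-based substream `default_rng([seed, repeat])`, so repeats
are independent and order-insensitive; the reported sd is over the
repeat-level AUCs. Identical configurations (including seed) produce
bit-identical results.

A disease whose miRNAs are all known positives has no local candidate
pool; its test samples are skipped with a logged warning and counted in
`n_skipped`.

## Synthetic data

The generator plants the assumption the model exploits: functionally
similar miRNAs associate with similar diseases. miRNAs and diseases are
assigned round-robin to `n_blocks` blocks; associations are Bernoulli
with probability 0.3 within a matched block pair and 0.02 across
(defaults: 60 miRNAs × 40 diseases, 4 blocks — roughly 200 associations,
~8% density, comparable in sparsity to curated association catalogs).
Similarities are clipped-normal draws (sd 0.1) around a within-block mean
of 0.8 and a cross-block mean of 0.15, chosen so that within-block edges
clear the default threshold `T = 0.5` and cross-block edges do not; 70%
of miRNA pairs are covered by the primary similarity so the kernel
fallback is exercised end-to-end. An optional DAG generator hangs every
disease of a block under two block-shared ancestors below a common root,
which puts same-block semantic similarity at 5/9 (above `T`) and
cross-block at 1/9.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real association databases, literature ascertainment
bias, and correlated noise between the similarity sources. Passing the
synthetic-recovery tests therefore demonstrates that the implementation
recovers planted signal under the model's own assumptions, not that the
model is well calibrated on any particular real catalog.

## Numerical and design notes

* Similarity values are validated to [0, 1] and symmetry to 1e-8; mild
  file asymmetry is averaged out with a warning. All math is double
  precision.
* Ranked candidate lists sort by descending score with ties broken by
  miRNA label ascending, so output is deterministic.
* The two scoring engines agree elementwise to well below 1e-10; tests
  assert 1e-10.
* Cross-validation at full catalog scale (≈5400 associations over
  495 × 383) uses the matrix engine inside the loops; the dfs engine is
  for audits (`pbmda explain`). Desk-scale tests run the 60 × 40 default
  generator (about 200 LOOCV iterations in well under a second) and a
  30 × 20 system for the 50-permutation null, keeping the whole suite in
  the tens of seconds.
* The toy network's d1–d4 weight is stated only as sub-threshold by the
  construction it illustrates; the fixture pins it to 0.3, and the exact
  value is irrelevant as long as it is below `T`.

## Limitations

* The matrix engine does not extend to `L = 4`; the dfs engine supports
  any `L` but enumerates paths explicitly and scales accordingly.
* No MeSH descriptor-file parsing: disease DAGs are supplied as a flat
  per-disease edge list, pre-merged by the user if a disease has several
  tree positions (the package treats one DAG per disease).
* The candidate ("negative") pool treats all unverified pairs as
  negatives, as is conventional; truly associated but undiscovered pairs
  depress the measured AUC.
* No approximate or top-k path search, no alternative decay schemes, and
  no learning of `α`.
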