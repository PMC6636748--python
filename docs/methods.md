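# Methods

## Model

The method treats disease-gene prioritization as semi-supervised label
propagation on the interactome. The premise is guilt-by-association:
genes whose perturbation produces similar phenotypes aggregate in
network neighborhoods (disease modules), and modules of phenotypically
similar diseases lie close to each other. The scoring vector `F` is the
minimizer of the quadratic consistency cost

```
C(F) = ½ ( Σ_ij W_ij ‖F_i/√D_ii − F_j/√D_jj‖² + μ Σ_i ‖F_i − Y_i‖² )
```

whose first term rewards smoothness of labels over (degree-normalized)
edges and whose second anchors labels to the seed vector `Y`; the
package computes it as `F = β(I − αS)⁻¹Y` with `S = D^{−1/2}WD^{−1/2}`,
`α = 1/(1+μ)`, `β = 1 − α`.

**A factor-of-two convention.** With the edge sum written over both
orientations, as above, the exact stationarity condition of `C(·; μ)` is
`((2+μ)I − 2S)F = μY`, which is the displayed closed form evaluated at
half the regularization: `argmin C(·; μ) = β′(I − α′S)⁻¹Y` with
`α′ = 1/(1 + μ/2)`. Since `μ` is a free tunable and only the rank order
of `F` is consumed, the package standardizes on the closed form
parametrized directly by `α` and treats the factor as a
reparametrization; `cost()` evaluates the displayed formula literally,
and the solver-vs-minimizer tests use the `μ ↦ 2μ` correspondence.

**Isolated nodes** stay in the gene universe. Their rows of `S` are
zero, so the closed form retains `F_i = βY_i` there (pure seed
retention). Note this is the one place the cost/closed-form duality
degenerates: the cost's own minimum at an isolated node is `Y_i`, since
no smoothness term touches it. Solver-equivalence checks therefore run
on fixtures where every degree is positive; the ranking consequences
are nil because a constant factor on an isolated node's seed does not
cross module scores.

## Phenotype similarity

Similarity is Resnik-style over an ontology DAG: `IC(t) = −log`
(fraction of annotated diseases whose ancestor-closed term set contains
`t`), in nats, and `sim(d₁,d₂)` is the maximum, over term pairs drawn
from the two diseases, of the IC of the pair's most informative common
ancestor. The corpus unit is the disease (not the publication): counts
are up-propagated to all ancestors, which makes IC anti-monotone along
edges and similarity symmetric with dominant self-similarity. The
phrase "common ancestor of the two term *sets*" is also implementable
as the most informative ancestor common to *every* term (mode
`"union"`); that variant collapses toward the root for multi-topic
diseases, so the pairwise form is the default.

Diseases with no annotations raise by default; a `fallback_zero` switch
degrades them to all-zero similarity (pure-background seeds) for batch
runs.

## Seed construction

The Query Weight Set enforces a strict evidence hierarchy: own genes at
exactly 1, transferred genes at `h·logistic(a(s−b)) < h < 1`, everything
else 0. A gene associated with several diseases uses its *highest*
similarity to the query. Defaults: `h = 0.5`, `a = 1`, and `b` = the
median of the query's nonzero similarities (resolved per query) — these
are artifact defaults chosen so the sigmoid is centered on the observed
similarity scale, not trained values. `fit_sigmoid_params` provides a
deterministic grid search (mean leave-one-out recall@100 on a training
set, lexicographic tie-break over `(h, a, b, α)`) for users who want
data-driven values; the diffusion default is `α = 0.9`, standard for
consistency-method propagation.

## Evaluation protocols

* **Leave-one-out**: each association is removed and predicted back;
  charted mode needs ≥2 genes, uncharted mode removes the only gene of
  single-gene diseases. The query's remaining known genes are excluded
  from the candidate list (config flag to disable). Recall@k is
  reported per case; a per-disease aggregation is available when one
  disease contributes several cases.
* **Time-lapse**: prediction uses only the earlier snapshot; test genes
  are the later snapshot's gains restricted to network genes, with each
  exclusion counted and reported, stratified by charted/uncharted status
  at t0. Earlier-only associations are reported as snapshot violations,
  never silently dropped.
* **Module reconstruction**: for each module, kept fraction `f`, and
  repetition, `⌈f·|module|⌉` genes are kept (`f = 0` keeps none) as the
  query's known genes, the background association table supplies
  similarity-derived seeds, and recovery of the removed genes is scored
  by the truncated normalized AUC. All sampling flows from one seed
  through per-module `SeedSequence` sub-streams.

**Truncated normalized AUC**: walk the ranking, plot the fraction of
positives recovered against the count of false positives, stop at the
cap (default 200), and divide the area by the cap. If a ranking runs
out of negatives before the cap, the curve continues flat at its final
value. A perfect ranking scores 1; uniformly random rankings score
`(cap/(n−P))/2` in expectation — about 0.01 at `n = 10⁴`, `P = 50`,
cap 200, which the test suite verifies by Monte-Carlo.

## Synthetic worlds

`make_world` plants the exact structure the method assumes: a
planted-partition graph (`m = 8` modules × `s = 25` genes,
`p_in = 0.3`, `p_out = 0.01`, i.e. within-module degree ≈ 7.2 vs
background ≈ 1.75), three charted diseases per module with six genes
each drawn from the home module, and a rooted ontology with one branch
per module whose leaf terms annotate that module's diseases (with a 20%
chance of one off-module noise term). Same-module disease pairs
therefore share rare (high-IC) terms while cross-module pairs meet only
at the root, giving a strong, verifiable phenotype signal. The earlier
association snapshot hides each association independently with
probability 0.25. The weighted variant draws within-module weights from
U(0.6, 1) and cross-module weights from U(0.05, 0.3).

What the worlds do **not** emulate: scale-free degree heterogeneity,
hub proteins, study bias (better-studied genes having more edges and
more annotations), inter-module phenotype gradations, and annotation
noise beyond the single off-module term. Passing benchmarks here shows
the pipeline is correct and that the method exploits phenotype signal
when it exists; it does not certify performance on real interactomes,
where the module signal is far weaker and confounded.

Scale choices: benchmark worlds use n = 200 (default) and n = 1000
(with `p_out` scaled to hold the expected background degree constant);
the module-reconstruction experiments cap false positives at 100 rather
than the 200 used at genome scale, so that truncation is active when
only ~175 negatives exist. Fixture sizes keep every experiment
deterministic and fast while leaving the planted signal detectable.

## Numerical choices

* Gene order is lexicographic; ranking ties break lexicographically by
  gene id — output is bit-reproducible.
* Duplicate edges keep the maximum weight (warning); self-loops are
  dropped; a zero-weight self-loop line in an edge-list file declares an
  isolated node so gene universes round-trip through TSV.
* Direct sparse factorization up to n = 2·10⁴, the contraction
  iteration above; both satisfy the same tolerance contract, so the
  choice is invisible to callers.
* The iteration stops when the sup-norm update falls below
  `tol·(1 + ‖F‖∞)` and raises (carrying the last iterate and residual)
  at the iteration cap.
* Similarity matrices are validated symmetric to 1e−9 on load.

## Limitations

* The pairwise-MICA similarity saturates: one shared rare term fixes the
  similarity regardless of how many other terms disagree.
* No gene-identifier mapping is attempted; inputs must share one
  namespace.
* Scores are reported raw (no probability calibration); only the rank
  order is meaningful.
* The grid-search parameter fitter optimizes a single criterion
  (LOO recall@100) and will overfit tiny training sets.
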