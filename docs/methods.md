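# Methods

## Model and assumptions

`hept` ranks the proteins of an undirected PPI network by essentiality
using a random-walk model on a multi-relational tensor rather than on the
raw network. The premises are the classical ones of network-based
essential-protein prediction: PPI networks are approximately scale-free;
essential proteins tend to sit in dense neighborhoods, to carry more domain
types, to be conserved across many species, and to concentrate in a few
compartments; and high-throughput interaction data is noisy enough that
topology alone under-performs, so orthogonal evidence (domains, GO,
orthology, localization) should enter the model as *separate* relation
types whose relative importance is learned by the iteration itself (the VE
vector) instead of being fixed by hand.

All three relation slices are symmetric by construction, have weights in
[0, 1], and exclude the diagonal: the input network carries no
self-interactions, and a self-relation would inflate a protein's own fiber
during transition normalization. Relations are computed between *any*
protein pair sharing the relevant item, not only between pairs that
directly interact; `restrict_to_ppi` provides the conservative variant.

## Numerical choices

* **Fiber normalization with implicit uniform fallback.** All-zero fibers
  of the transition tensors take the uniform value 1/n (or 1/m for the
  edge-type mode). These fibers are never materialized: a uniform fiber
  contributes the same amount to every output coordinate, so its effect is
  a scalar computed from the zero-fiber masks. At n ≈ 5000 a dense n×n×3
  tensor would hold 75M entries per mode; the implicit form is exact (the
  test suite checks equality with a dense triple-loop reference to 1e-10)
  and keeps the per-iteration cost proportional to the stored entries.
* **Co-neighbor weights above 1** are possible in the defining formula
  (two shared neighbors, both degrees 2 → 4). They are clipped to 1.0 by
  default (logged, and disableable) so every tensor weight stays
  interpretable as a probability.
* **Per-iteration L1 normalization** of VA, VH, VE is on by default. The
  iteration initializes all three as distributions and mixes VA with the
  probability vector D, which is only scale-consistent if the vectors stay
  L1-normalized; classical HITS likewise renormalizes to prevent growth or
  decay. A flag disables it for fidelity experiments. The restart vector D
  is itself L1-normalized (uniform fallback when identically zero, so the
  restart semantics survive degenerate inputs).
* **Convergence** uses the summed L1 change of the three vectors,
  consistent with their probability semantics, with ε = 1e-8 and a
  1000-iteration cap; hitting the cap returns `converged=False` with a
  warning rather than raising. On the reference synthetic networks the
  iteration converges in ~12–13 steps.
* **Degenerate inputs.** All domain scores equal (e.g. no annotations) →
  scores set to 0 with a warning, which empties the co-domain slice; no
  ortholog counts → orthology scores 0; unannotated proteins get
  localization score 0. Each case degrades one evidence channel without
  breaking the iteration, because the uniform fiber fallback keeps every
  transition tensor stochastic.
* **Tie-breaking** in all rankings is ascending-lexicographic on the
  protein ID, making output deterministic.
* **GO frequency filter** (terms annotating 10–200 proteins, inclusive) is
  applied after restricting annotations to network proteins; both bounds
  and the ordering are configurable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.3 | weight of the tensor term in the VA update; 1−α goes to the restart vector. 0 reduces the ranking to the orthology/localization prior, 1 removes the prior entirely. |
| `epsilon` | 1e-8 | L1 convergence threshold (dimensionless; the vectors are distributions). |
| `max_iter` | 1000 | iteration cap. |
| `go_min`, `go_max` | 10, 200 | GO term frequency window (proteins per term). |
| `normalize_state`, `normalize (jump)` | on | the L1 normalizations described above. |

## The synthetic generator

`synthetic_data` produces the six input files from a single seed, one named
RNG stream per data type (so changing the GO configuration never perturbs
the topology draw). Defaults — 200 proteins, 20 planted essentials,
attachment 3, 40 domain types, 30 GO terms, 8 compartments, 100 reference
genomes, bias 5 — are sized so a full pipeline run takes well under a
second while the network still has a heavy-tailed degree distribution and
annotation densities of a few items per protein, roughly matching the
per-protein annotation counts of real yeast resources at 1/25 scale.

The `essential_bias` multiplier controls every signal channel: attachment
fitness in the preferential-attachment graph, the mean domain count
(Poisson rate 1.5·bias vs 1.5), the GO draw weight toward a small "module"
of terms, the ortholog-presence probability per genome (0.15·bias, capped
at 0.95, vs 0.15), and the draw weight of one favored compartment. At
bias = 1 every distribution is identical for essentials and
non-essentials, giving an exact null model.

What the generator does **not** emulate: false-positive/false-negative
interaction noise, correlated annotation errors, multi-domain architecture
structure, GO term hierarchy (terms are independent labels), or the
specific degree distribution of any real interactome. Passing recovery
tests therefore demonstrates that the implementation ranks proteins by the
signals the model assumes, under clean conditions — not that the method
attains any particular accuracy on real data.

## Evaluation conventions

Precision–recall curves are swept over every cutoff K = 1..n with no
interpolation. The jackknife curve is the cumulative count of true
essentials down the ranking; we report the raw trapezoid area and the area
normalized by the perfect ranking's (so 1.0 means all essentials first),
plus the analytic diagonal of a random ordering for reference, and express
method-to-method comparisons as relative raw-area improvements (a−b)/b.
In the top-K overlap analysis, a "low-scored" protein is interpreted as one
outside the top 25% of a ranking (a rank-percentile reading of a threshold
that is otherwise scale-ambiguous; configurable).

## Known limitations

* VE receives no restart term (only VA does), so with very sparse tensors
  the edge-type scores are driven entirely by the current VA/VH outer
  product.
* The co-domain score treats domains as unordered sets; domain copy number
  and architecture are ignored.
* Orthology and localization enter only through the restart vector; a
  protein lacking both is reachable only through the tensor term (logged).
* At bias values near 1 the planted-essential recovery of the generator is
  by design indistinguishable from chance; intermediate biases interpolate
  noisily, so monotonicity holds in the mean over seeds, not per seed.
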