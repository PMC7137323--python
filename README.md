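# hept — essential-protein prediction by tensor-extended HITS

Essential proteins are proteins whose loss kills the cell or leaves it
infertile. Knockout screens that identify them are expensive, so a long line
of computational methods ranks the proteins of a protein–protein interaction
(PPI) network by how essential they look. Purely topological centralities
(degree, betweenness, …) are limited by the noise of high-throughput PPI
data; `hept` is for computational biologists who want to fold several
heterogeneous evidence sources — domain content, GO annotation, orthology
conservation, subcellular localization — into a single ranking without
collapsing them into one aggregate network.

## The model

The method represents the proteome as a three-way tensor
*T* ∈ ℝ^(n×n×3): one n×n slice per relation type between proteins
*p_i*, *p_j*:

* **co-neighbor** (topology):
  `|N_i ∩ N_j|² / ((|N_i|−1)(|N_j|−1))` if both degrees exceed 1, else 0;
* **co-domain**: `P_D(i) · P_D(j)` for pairs sharing a domain type, where
  `P_D` is the min–max-scaled rarity-weighted domain count
  `Σ_d t_id / NP_d`;
* **co-annotation**: `|F_i ∩ F_j| / √(|F_i||F_j|)` over GO term sets
  (terms pre-filtered to those annotating 10–200 proteins).

Fiber-normalizing *T* along each mode gives three transition tensors, and a
HITS-style power iteration couples an **authority** vector VA (length n), a
**hub** vector VH (length n) and an **edge-type importance** vector VE
(length 3):

    VA_t(i) = (1−α)·D(i) + α·Σ_jk T^(a)(i,j,k) VH_{t−1}(j) VE_{t−1}(k)
    VH_t(j) =             Σ_ik T^(h)(i,j,k) VA_t(i)     VE_{t−1}(k)
    VE_t(k) =             Σ_ij T^(e)(i,j,k) VA_t(i)     VH_t(j)

until the summed L1 change falls below ε. The restart vector
`D ∝ I(i)·S(i)` personalizes the walk toward conserved (`I` = normalized
ortholog count) and well-localized (`S` = best compartment score) proteins;
α (default 0.3) mixes the tensor term against the restart. Proteins are
reported in descending VA order; VE tells you how much each relation type
drove the ranking.

## Worked example

```sh
python examples/01_rank_synthetic_network.py
```

generates a 200-protein scale-free network with 20 planted essentials
(enriched in degree, domains, shared GO terms, orthologs and one favored
compartment) and prints:

```
converged in 13 iterations
edge-type importance (VE):
  co_neighbor     0.6103
  co_domain       0.1351
  co_annotation   0.2547

top 10 proteins by authority score (VA); * = planted essential
   1. P0102 * VA=0.02363
   2. P0148 * VA=0.02042
   ...
18/20 planted essentials recovered in the top 40
```

VE says the shared-neighborhood slice carried ~61% of the ranking signal on
this network; every protein in the top 10 is a planted essential, and 18 of
the 20 appear in the top 40. `examples/02_compare_with_degree_baseline.py`
scores the same ranking against plain degree centrality (jackknife AUC
0.983 vs 0.800, a +22.9% raw-area improvement), and
`examples/03_files_and_cli.py` shows the on-disk formats and the equivalent
`hept synth` / `hept run` shell commands.

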