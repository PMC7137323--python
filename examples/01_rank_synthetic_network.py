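"""Rank proteins on a synthetic PPI network with planted essentials.

Generates a 200-protein scale-free network bundle in which 20 planted
essential proteins are enriched for degree, domains, GO co-annotation,
orthologs and a favored compartment (bias 5), runs the tensor-HITS
ranking, and prints the top of the list.
"""

from hept import SyntheticConfig, generate_bundle, rank_bundle

bundle = generate_bundle(SyntheticConfig(rng_seed=1))
result = rank_bundle(bundle)

print(f"converged in {result.iterations} iterations")
print("edge-type importance (VE):")
for name, v in result.edge_type_importance.items():
    print(f"  {name:15s} {v:.4f}")

print("\ntop 10 proteins by authority score (VA); * = planted essential")
for rank, (pid, score) in enumerate(zip(result.ranking.ids, result.ranking.scores), 1):
    if rank > 10:
        break
    mark = "*" if pid in bundle.essential else " "
    print(f"  {rank:2d}. {pid} {mark} VA={score:.5f}")

hits = sum(1 for p in result.ranking.top(40) if p in bundle.essential)
print(f"\n{hits}/20 planted essentials recovered in the top 40")
# VE shows which relation slice carried the ranking; VA is the restart-mixed
# authority score each protein ends up with.
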