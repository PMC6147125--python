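"""Family co-occurrence network from a synthetic community.

Generates a modular community (three temporal guilds, 8 families each,
5 sampling days x 3 replicates), runs the network pipeline (prevalence
filter, all-pairs Spearman, BH-FDR, 0.6 <= rho <= 0.9 & q < 0.01 edge
rule, greedy modularity partition) and compares the recovered modules
with the planted ones.
"""

from collections import Counter

from sklearn.metrics import adjusted_rand_score

from paddyweb import conet, synth

scenario = synth.mesophilic_30c(seed=7)
table, planted = synth.simulate_modular_community(scenario, seed=7)

filtered = conet.prevalence_filter(table)
relab = filtered.relative_abundance()
corr = conet.spearman_all_pairs(relab)
net = conet.build_network(corr, abundances=relab.mean(axis=1).to_dict())
net = conet.partition_modules(net, algorithm="greedy")

fams = sorted(net.graph.nodes)
ari = adjusted_rand_score([planted[f] for f in fams],
                          [net.graph.nodes[f]["module"] for f in fams])

print(f"nodes: {net.graph.number_of_nodes()}  edges: {net.graph.number_of_edges()}")
print(f"modularity Q = {net.modularity_score:.3f}")
print("module sizes:", dict(sorted(Counter(net.modules.values()).items())))
print(f"adjusted Rand index vs planted modules: {ari:.3f}")
print()
print("Q ~ 0.5-0.65 indicates a clearly modular food web; ARI = 1 means the")
print("partition recovered the planted temporal guilds exactly.")
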