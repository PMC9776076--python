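"""Hub detection and the strongest hub-to-hub pathways.

Hubs are the nodes in the top 30% of betweenness centrality (9 of 29
channels); the strongest 30% of connections among them (11 of 36 edges)
are the dominant information pathways. This example uses the
occipital-hub preset, whose task stage couples O2 to distant channels on
top of a random background connectome, so betweenness is informative.
"""

from eegfc import (BAND_BY_NAME, band_limited_epochs, detect_hubs,
                   generate_stage, graph_metrics, hub_pathways,
                   normalize_weights, occipital_lateralized_config,
                   stage_mi_matrix)

config = occipital_lateralized_config(seed=7)
rec = generate_stage(config, stage=3)
es = band_limited_epochs(rec, BAND_BY_NAME["high_gamma"])
m = normalize_weights(stage_mi_matrix(es))
gm = graph_metrics(m.values, labels=m.labels)

hubs = detect_hubs(gm.bc, labels=gm.labels, q=0.3, stage=3,
                   band="high_gamma")
print(f"{len(hubs)} hubs (top 30% betweenness):")
for label, bc in hubs.hubs:
    print(f"  {label:>5s}  BC = {bc:.4f}")

edges = hub_pathways(m, hubs, q=0.3)
print(f"\n{len(edges)} strongest hub-to-hub pathways:")
for a, b, w in edges[:5]:
    print(f"  {a}-{b}: weight {w:.3f}")
print("  ...")
# High-betweenness channels mediate many shortest paths; with the task-
# stage star couplings active, the boosted occipital channel should rank
# among the hubs.
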