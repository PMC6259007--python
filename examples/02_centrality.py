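"""Node centrality: which symptoms are most embedded in the network.

Prints raw and z-standardized centrality indices.  Expected influence (the
signed sum of a node's edges) is the index of choice for symptom networks
with mostly positive edges; trauma-related amnesia (D1) should rank last.
"""
import symnet as sn

data = sn.sample_ordinal(sn.preset_ptsd17("clinical", n=2000, seed=2))
net = sn.estimate_network(data).network

table = sn.centrality_table(net)
z = sn.standardize(table)
print(table.round(3).to_string())
print()
ei = table["expected_influence"]
print(f"most central (EI):  {ei.idxmax()}  ({ei.max():.3f})")
print(f"least central (EI): {ei.idxmin()}  ({ei.min():.3f})")
print(f"z-score of {ei.idxmax()}: {z.loc[ei.idxmax(), 'expected_influence']:+.2f} SD above the mean node")
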