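"""Infer the directed regulator-target network with both backends.

COEN builds |Pearson correlation|^beta adjacency and converts it to the
topological overlap measure (TOM); GRN regresses each gene on the
regulators with random forests.  Both rank candidate regulator->gene
edges and keep the top fraction; we check how many planted target edges
each recovers, plus the out-degree/out-closeness hub view.
"""

from keyreg import SimulationSpec, hub_metrics, infer_network, simulate_regulators

ds = simulate_regulators(SimulationSpec(
    n_samples=60, n_regulators=10, n_bona_fide=5, targets_min=4, targets_max=8,
    effect_size=3.0, target_noise_sd=0.5, seed=5))
n_true = sum(len(t) for t in ds.target_map.values())
n_candidates = 10 * (ds.expression.n_genes - 1)
frac = 1.3 * n_true / n_candidates  # keep roughly the planted edge density

for method in ("coen", "grn"):
    net = infer_network(ds.expression, ds.regulators, method=method,
                        edge_fraction=frac, n_trees=200, seed=0)
    sets = net.target_sets()
    recovered = sum(
        len(set(sets.get(r, [])) & set(ts)) for r, ts in ds.target_map.items())
    print(f"{method.upper():4s}: {net.n_edges} edges kept, "
          f"{recovered}/{n_true} planted regulator->target edges recovered")

hubs = hub_metrics(net)
print("\nhub metrics (GRN network, top out-degree):")
print(hubs.sort_values("out_degree", ascending=False).head(3).round(3))
# out_degree counts targets pointed to; out_closeness summarizes how short
# the outgoing paths to the reachable part of the network are.
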