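"""Topological module detection: Louvain and Incremental Louvain.

Simulates a planted-partition network (8 blocks of 50 genes), detects
modules by modularity maximization, and shows how the incremental variant
subdivides modules that exceed a size threshold.
"""

from funcspec import (
    SyntheticConfig, incremental_louvain, louvain, simulate_ppin, size_distribution,
)

cfg = SyntheticConfig(seed=1)  # 8 blocks x 50, p_in 0.6, p_out 0.02
net, blocks = simulate_ppin(cfg)
print(f"network: {net.node_count} nodes, {net.edge_count} edges")

part = louvain(net, seed=1)
dist = size_distribution(part, threshold=10)
print(f"Louvain: Q = {part.modularity:.4f}, modules = {len(part.modules)}, "
      f"sizes = {dist.sizes}, mesoscale (>10) = {dist.mesoscale_count}")

inc = incremental_louvain(net, max_module_size=30, seed=1)
print(f"Incremental (threshold 30): Q = {inc.modularity:.4f}, "
      f"modules = {len(inc.modules)}, sizes = {sorted(inc.sizes.values())}")
print("sample lineage ids:", sorted(inc.modules)[:4])

print("\nQ near 0.7 with exactly 8 modules of 50 means the planted blocks were")
print("recovered perfectly. Forcing modules under 30 nodes trades modularity for")
print("resolution: sub-modules keep lineage ids like '3.1' so the hierarchy is")
print("traceable.")
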