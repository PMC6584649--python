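"""Degree-distribution and subnetwork analysis of a PPI network.

Scale-free PPI networks follow p(k) ~ k^(-gamma); gamma is estimated by
log-log least squares on the degree histogram.  Connected components
identify candidate complexes/pathway subnetworks.
"""

from phytoppi.network import (
    connected_components, degree_distribution, fit_power_law,
    powerlaw_graph_edges,
)

edges = powerlaw_graph_edges(gamma=2.0, n=5000, seed=1)
dist = degree_distribution(edges)
gamma = fit_power_law(dist)
print(f"{len(dist.degree_of)} proteins, {len(edges)} interactions")
print(f"degree histogram head: {dict(list(dist.histogram.items())[:5])}")
print(f"fitted degree exponent gamma = {gamma:.3f} (R^2 = {dist.fit_r2:.3f})")
# close to the generating exponent 2.0; low gamma would mean more hubs

comps = connected_components(edges)
print(f"\n{len(comps)} subnetworks; largest sizes: "
      f"{[c.size for c in comps[:4]]}")
frac = sum(c.size for c in comps[:4]) / len(dist.degree_of)
print(f"fraction of proteins in the four largest: {100 * frac:.1f}%")
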