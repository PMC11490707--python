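"""Trait networks across a simulated extinction event.

Fossil occurrence data lack site structure, so trait values are
correlated directly across species (the phi coefficient on the one-hot
matrix). This script generates a fossil-shaped assemblage (115 taxa,
four traits, 18 trait values), applies a trait-targeted extinction that
hits one life-history strategy hard, and contrasts the pre- and
post-extinction networks.
"""

import warnings

import traitnets as tn
from traitnets.simulate import block_signature

scenario = tn.SyntheticScenario.fossil_default()
# extinction concentrated on strategy block 0: its signature trait
# values drop to 15% survival, everything else to 90%
extinction = {f"{t}:{lv}": 0.15 for t, lv in block_signature(scenario, 0).items()}
fossil = tn.generate_fossil(scenario, extinction, base_survival=0.9, seed=21)
print(f"pre-extinction taxa:  {len(fossil.pre_species)}")
print(f"post-extinction taxa: {len(fossil.post_species)}\n")

for bin_name in ("pre", "post"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tvm = tn.expand_traits(fossil.table_for(bin_name))
        network = tn.build_trait_network(tn.direct_trait_matrix(tvm))
        report = tn.compute_metrics(network)
    print(f"{bin_name:>4}-extinction network: {report.n_nodes} trait values, "
          f"{report.n_edges} edges, edge density {report.edge_density:.3f}, "
          f"Q {report.modularity_Q:.3f}")

print("\nA drop in edge density and the loss of trait-value nodes after the "
      "event signal reduced functional redundancy, hence lower resilience.")
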