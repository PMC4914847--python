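"""Reconstruct ancestral pathway complements on the bundled species tree.

Dollo parsimony places single gains and minimal losses for presence/absence;
Sankoff parsimony assigns ancestral copy numbers and exposes lineage-specific
expansions.
"""

from egfrc import (
    bundled_complement_matrix,
    bundled_species_tree,
    matrix_from_complements,
    scenario_report,
)

tree = bundled_species_tree()
characters = matrix_from_complements(bundled_complement_matrix("MERGED"))
events, roots = scenario_report(tree, characters)

for name, counts in roots.items():
    print(f"reconstructed {name} complement: {counts}")

print("\nreceptor gains/losses/expansions:")
print(events[events.character == "EGFR"].to_string(index=False))
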