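"""Cluster the ligands of two chordates by local-alignment similarity.

NRG-type ligands share a conserved immunoglobulin I-set domain, so they
connect into one component; EGF-type ligands share only the short six-cysteine
skeleton and stay apart at the default 0.5 bits/residue threshold.
"""

import re

from egfrc import (
    build_graph,
    fixture_for,
    generate_species_set,
    pairwise_scores,
)

records = []
for species in ("H_sapiens", "B_floridae"):
    for record in generate_species_set(fixture_for(species), seed=1):
        if re.match(r"(egf|nrg)\d+$", record.id.split("|")[1]):
            records.append(record)

scores = pairwise_scores(records)
graph = build_graph(scores, threshold=0.5, normalization="BITS_PER_SHORTER")

print(f"{len(records)} ligands, {graph.graph.number_of_edges()} edges, "
      f"{len(graph.components)} components")
for i, component in enumerate(graph.components):
    members = ", ".join(m.split("|")[0] + ":" + m.split("|")[1] for m in component)
    print(f"  component {i}: {members}")
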