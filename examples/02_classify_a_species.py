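"""Round-trip one species: generate its synthetic proteome, scan, classify.

The per-species fixtures are built from the transcribed survey tables, so the
classifier's counts should land exactly on the published complement.
"""

from egfrc import (
    build_complement_matrix,
    bundled_complement_matrix,
    classify_record,
    fixture_for,
    generate_species_set,
    scan_record,
)

species = "H_sapiens"
records = generate_species_set(fixture_for(species), seed=1)
calls = [classify_record(r, scan_record(r)) for r in records]
matrix, qc = build_complement_matrix(
    calls, {r.id: r.species for r in records}, {r.species: r.clade for r in records}
)

print(f"{species}: {len(records)} synthetic proteins")
for call in calls:
    label = call.record_id.split("|")[1]
    extra = f" ({call.rejection_reason})" if call.category == "REJECTED" else ""
    extra = extra or (f" [{call.tk_status}]" if call.tk_status != "NONE" else "")
    print(f"  {label:<16} -> {call.category}{extra}")

print("\nscanned complement row:")
print(matrix.df.loc[[species]].to_string())
print("\npublished complement row:")
print(bundled_complement_matrix("MERGED").df.loc[[species]].to_string())
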