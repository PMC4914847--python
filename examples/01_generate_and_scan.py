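"""Generate a synthetic ligand and locate its planted domains.

An architecture spec lists elements in N-to-C order; the generator embeds
them in scanner-silent random linkers, so scanning recovers exactly what was
planted.
"""

from egfrc import ArchitectureSpec, Element, generate_protein, scan_record

spec = ArchitectureSpec(
    (
        Element("SIGNAL"),
        Element("EGF_MOTIF"),
        Element("IG_ISET"),
        Element("TM"),
    ),
    label="demo_nrg",
)

record = generate_protein(spec, seed=7, species="demo_species")
print(f"{record.id}  ({len(record.sequence)} residues)")
for hit in scan_record(record):
    print(f"  {hit.kind:<10} [{hit.start:>4}, {hit.end:>4})  score={hit.score:.1f}")
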