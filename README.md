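# egfrc

Rule-based identification of EGF-receptor (EGFR) pathway components from
protein domain architecture, and parsimony reconstruction of how the pathway's
component complement evolved across the animal kingdom.

## The scientific problem

The EGFR signalling module — a receptor tyrosine kinase plus a family of
EGF-motif ligands — is one of the most intensively studied pathways in
bilaterian model organisms, yet its deep evolutionary history is poorly
resolved. Outside their six conserved cysteines, EGF ligands are so
sequence-variable that homology searches alone cannot delimit the family;
receptor complements vary wildly between lineages (single receptors in
nematodes, large lineage-specific expansions in flatworms and leeches, and
outright losses in other groups). A practical survey therefore has to work
from *domain architecture* rather than raw sequence similarity: a protein is
a receptor or a ligand because of the parts it is built from and their order,
not because it aligns well to a reference.

`egfrc` implements that architecture-first survey as a library:

- **Scanners** locate the relevant parts in an amino-acid sequence: EGF
  motifs (the six-cysteine skeleton `C-x(3,14)-C-x(3,7)-C-x(1,16)-C-x(1,2)-
  C-x(4,15)-C`), transmembrane segments (Kyte–Doolittle sliding window),
  N-terminal signal peptides, cysteine-rich clusters, immunoglobulin I-set
  domains, and tyrosine-kinase domains with an audit of the catalytic
  residues (glycine loop, VAIK lysine, HRD aspartate, DFG aspartate).
- **The classifier** applies conservative inclusion rules: an EGFR must have
  a TK domain, a transmembrane segment and a cysteine-rich ectodomain (the TK
  audit flags pseudokinase receptors such as human ErbB3 as INACTIVE); a
  ligand must be full length with exactly one EGF motif, at most two
  transmembrane segments and no TK domain; ligands carrying an Ig I-set
  domain plus a membrane anchor are typed neuregulin-like (NRG-type).
  Everything else is rejected with an explicit reason.
- **Clustering** builds an all-vs-all Smith–Waterman similarity graph
  (BLOSUM62, gap 11/1) over ligand calls and reports connected components at
  a bits-per-residue threshold — a small-scale stand-in for cluster-map
  analyses of the full ligand family.
- **Ancestral reconstruction** places gains, losses and copy-number
  expansions on a fixed 35-species metazoan tree: Dollo parsimony
  (single-gain, minimal-loss) for presence/absence, Sankoff parsimony with
  linear copy-number costs for counts. Polytomies are handled natively.

Because real proteome surveys depend on dozens of external genome resources,
the package ships **synthetic fixtures**: a deterministic generator that
plants architecture elements into scanner-silent random linkers, plus
transcribed per-species complement tables (35 species, 19 clades, 74
receptors, 93 ligands) and the species tree. Generating, scanning and
classifying the synthetic proteomes reproduces the transcribed complements
exactly — a full round-trip test of the rule system.

## Worked example

Round-trip one species (from `examples/02_classify_a_species.py`):

```python
from egfrc import (
    build_complement_matrix, classify_record,
    fixture_for, generate_species_set, scan_record,
)

records = generate_species_set(fixture_for("H_sapiens"), seed=1)
calls = [classify_record(r, scan_record(r)) for r in records]
matrix, qc = build_complement_matrix(calls, {r.id: r.species for r in records})
```

Actual output:

```
H_sapiens: 18 synthetic proteins
  egfr1            -> EGFR [ACTIVE]
  egfr2            -> EGFR [ACTIVE]
  egfr3            -> EGFR [INACTIVE]
  egfr4            -> EGFR [ACTIVE]
  egf1             -> EGF_TYPE_LIGAND
  ...
  nrg4             -> NRG_TYPE_LIGAND
  decoy_multi_egf  -> REJECTED (MULTIPLE_EGF_MOTIFS)
  decoy_truncated  -> REJECTED (NOT_FULL_LENGTH)
  decoy_tk_only    -> REJECTED (TK_WITHOUT_ECTODOMAIN)

scanned complement row:
              clade  egfr_count  inactive_tk_count  egf_like_count  nrg_like_count
H_sapiens  Chordata           4                  1               7               4
```

Ancestral reconstruction (from `examples/04_ancestral_complements.py`):

```
reconstructed Metazoa complement: {'EGFR': 1, 'EGF_TYPE': 1, 'NRG_TYPE': 0}
reconstructed Bilateria complement: {'EGFR': 1, 'EGF_TYPE': 1, 'NRG_TYPE': 1}

receptor gains/losses/expansions (excerpt):
     EGFR expansion       H_robusta           1         6
     EGFR expansion       M_lignano           3         8
     EGFR      gain         Metazoa           0         1
     EGFR      loss     T_adhaerens           1         0
```

The other scripts in `examples/` walk through scanning, clustering and the
end-to-end pipeline. The same stages are exposed on the command line:

```
egfrc run --seed 1 --out-dir out/        # fixtures -> scan -> classify ->
egfrc report out/                        #   cluster -> ancestral -> report
```

Every run writes a `manifest.json` with SHA-256 checksums of all artifacts;
reruns with the same configuration are byte-identical.

## Repository layout

- `src/egfrc/` — the library (`scan`, `classify`, `cluster`, `evolution`,
  `fixtures`, `io`, `pipeline`, `cli`); bundled data under `src/egfrc/data/`.
- `tests/` — unit, property and acceptance tests; `tests/oracles.py` holds
  independent brute-force reference implementations.
- `examples/` — five short narrative scripts, one per capability.
- `docs/methods.md` — a methods note describing the rules and algorithms.
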