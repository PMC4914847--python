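# Methods

This note describes, in the package's own terms, the rules and algorithms
implemented in `egfrc`. Coordinates are 0-based half-open internally and
1-based inclusive in GFF3 output.

## 1. Domain scanners (`egfrc.scan`)

**EGF motif.** The six-cysteine skeleton is matched by the pattern
`C-x(3,14)-C-x(3,7)-C-x(1,16)-C-x(1,2)-C-x(4,15)-C`, implemented with lazy
regex quantifiers: matches are found greedily left to right, and within a
match the smallest consistent spacings are preferred. A hit spans first to
last cysteine inclusive; successive scans start after the previous hit, so
EGF hits never overlap. The test suite verifies exact equivalence with an
independent backtracking search (`tests/oracles.egf_sites`).

**Transmembrane segments.** Mean Kyte–Doolittle hydropathy over a sliding
19-residue window; windows with mean ≥ 1.6 are merged, and merged segments
shorter than 15 residues are discarded.

**Signal peptide.** Present iff, within the first 35 residues, a hydrophobic
stretch of ≥ 8 residues with mean hydropathy ≥ 2.0 begins at index ≤ 10. The
longest qualifying stretch is reported, and transmembrane hits overlapping it
are suppressed (a signal peptide is not a membrane anchor).

**Cysteine-rich clusters.** A 60-residue window "fires" when it contains ≥ 6
cysteines outside masked regions (EGF motifs and the TK domain are masked
first, so their cysteines are not double-counted). Two cysteines belong to
the same cluster iff a single fired window contains both; each cluster is
trimmed to its first/last contributing cysteine. Merging fired windows by
mere positional overlap would chain clusters no window actually spans, so it
is deliberately avoided.

**Ig I-set domain.** Exact-tag matching against a fixed 90-residue tag with
up to 10% mismatches — a deliberately simple stand-in for profile-based
domain detection, sufficient for the synthetic fixtures.

**Tyrosine-kinase domain.** The ordered motifs `G-x-G-x-x-G` (glycine loop),
`[LIVMF]-A-[IV]-x` (VAIK), `H-R-x` (HRD) and `x-F-G` (DFG) must occur within
a span of 200–350 residues. Every glycine-loop anchor is tried and the most
compact valid chain wins (spurious anchors in linkers or hydrophobic
stretches produce longer spans than the genuine fold). The audit records
whether the catalytic residues — VAIK lysine, HRD aspartate, DFG aspartate —
are canonical; a domain missing any of them is a pseudokinase and the
receptor is flagged INACTIVE.

## 2. Classification rules (`egfrc.classify`)

Decision order, first match wins:

1. **EGFR** — has a TK domain, ≥ 1 transmembrane segment, and ≥ 1
   cysteine-rich cluster entirely N-terminal of the first transmembrane
   segment. Any other TK-bearing protein is rejected
   (`TK_WITHOUT_ECTODOMAIN`).
2. **Ligand** — full length, exactly one EGF motif, ≤ 2 transmembrane
   segments, no TK domain. Typed **NRG_TYPE** when an Ig I-set domain and at
   least one transmembrane segment are present, otherwise **EGF_TYPE**.
3. **Rejected** — with reason `NO_EGF_MOTIF`, `MULTIPLE_EGF_MOTIFS`,
   `NOT_FULL_LENGTH` or `INCOHERENT_ARCHITECTURE` (in that priority).

Per-species calls are aggregated into a complement matrix with columns
`egfr_count`, `inactive_tk_count`, `egf_like_count`, `nrg_like_count`;
rejections go to a QC side table.

## 3. Ligand similarity clustering (`egfrc.cluster`)

All-vs-all Smith–Waterman local alignment (BLOSUM62, gap open 11 / extend 1)
via biotite, cross-checked in the tests against a quadratic pure-Python Gotoh
implementation. BLOSUM62 raw scores are half-bits; an edge connects two
sequences when `(raw / 2) / min(len_a, len_b)` ≥ 0.5 bits per residue of the
shorter sequence (raw-score thresholding is also available). Clusters are the
connected components of this graph, reported in deterministic lexicographic
order.

## 4. Ancestral reconstruction (`egfrc.evolution`)

**Dollo parsimony** (presence/absence): the character is gained exactly once,
at the most recent common ancestor of all taxa possessing it (on the tip edge
itself when only one taxon is present). Within the gain clade a node is
present iff its subtree contains a present taxon; a loss is charged to the
root edge of every maximal absent subtree. This placement provably minimizes
the loss count under the single-gain constraint, and the tests confirm it
against exhaustive enumeration of all internal-state assignments on random
trees (with polytomies) up to 8 tips.

**Sankoff parsimony** (copy numbers): dynamic programming over states
`0..max_count` with cost `|parent − child|` (one duplication and one loss
cost the same; the cost function is pluggable). Ties break toward the smaller
ancestral count — a conservative convention that avoids inflating ancestral
complements. Verified against exhaustive assignment enumeration on trees up
to 6 tips over 20 random seeds. Edges where the count rises from an already
nonzero ancestor are reported as **expansions**; Dollo gains/losses and
Sankoff expansions are merged into one event table, together with the
reconstructed complements at the root ("Metazoa") and Bilateria nodes.

## 5. Synthetic fixtures (`egfrc.fixtures`)

Each species' proteome is generated from declarative architecture specs
(ordered element lists). Only the features the scanners rely on are conserved
between proteins — the six-cysteine EGF skeleton, the Ig tag, the kinase
catalytic motifs, a fixed cysteine-rich block whose internal spacings can
never satisfy the EGF pattern. Everything else (linkers of 45–60 residues,
EGF inter-cysteine residues and spacings, hydrophobic cores) is drawn from a
seeded RNG, mirroring the extreme variability of real EGF ligands outside
their conserved cysteines. Linkers are scanner-silent by construction: no
cysteine, no 8-residue hydrophobic stretch, none of the residues the kinase
patterns need, and a letter composition whose expected BLOSUM62 pairwise
score is negative, so unrelated linkers do not accumulate alignment score
with length. Three decoys per species (multi-EGF, truncated fragment, TK
without ectodomain) exercise the rejection rules.

The bundled tables transcribe a 35-species survey (19 clades, 74 receptors
with 3 pseudokinase receptors, 93 ligands across 34 species; the one species
without a ligand row is carried with zero ligands). Receptor fixtures follow
per-receptor architecture transcriptions; entries not stated in the source
material are instantiated with modal values (one transmembrane segment,
signal peptide present, three cysteine-rich clusters) and flagged in the
`assumed` column of `receptor_architectures.tsv`. The species tree is rooted
with ctenophores as the sister group to all other animals, Xenacoelomorpha as
sister to Nephrozoa, and multi-species clades attached as polytomies.

## 6. Determinism

Generation is keyed by `(seed, species, label, architecture signature)`
through a string-seeded RNG, so results are independent of process hash
randomization. The pipeline writes a manifest of SHA-256 checksums; two runs
with the same configuration produce byte-identical artifacts.
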