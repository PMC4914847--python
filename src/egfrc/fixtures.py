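"""Deterministic synthetic proteomes built from declarative architecture specs.

The generator plants sequence elements (signal peptide, cysteine-rich
clusters, EGF motifs, Ig I-set tags, transmembrane segments, tyrosine-kinase
domains) in scanner-silent random linkers, so that scanning a generated
protein recovers exactly the planted architecture. Variable regions (linker
residues, EGF inter-cysteine residues and spacings, hydrophobic cores) are
drawn from a seeded RNG: only the features the scanners rely on -- the
six-cysteine skeleton, the Ig tag, the kinase catalytic motifs -- are
conserved between proteins, mirroring the extreme sequence variability of
real EGF ligands outside their conserved cysteines.

Also bundled here: the transcribed species x complement tables of the
metazoan survey (35 species, 19 clades) and the rooted species-tree topology
(ctenophore-first; Bilateria = Xenacoelomorpha + (Protostomia +
Deuterostomia); multi-species clades attached as polytomies).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import pandas as pd

from .classify import MATRIX_COLUMNS, ComplementMatrix
from .records import InvalidSpecError, ProteinRecord
from .scan import IG_ISET_TAG

ELEMENT_KINDS = ("SIGNAL", "CYS_RICH", "EGF_MOTIF", "IG_ISET", "TM", "TK", "LINKER")

#: Linker alphabet: no cysteine, hydropathy-negative apart from alanine, and
#: compositionally broad enough that unrelated linkers align with negative
#: expected score (W/Y keep the BLOSUM62 drift below zero). Excludes every
#: residue the kinase catalytic patterns need (K, R, H, F, L/I/V/M).
LINKER_ALPHABET = "AGSTNQDEPWY"
_POLAR = "QNST"
_SP_CORE = "LV"
_TM_ALPHABET = "LIVFA"
#: EGF inter-cysteine spacing ranges used by the generator (mid-range within
#: the scanner's C-x(3,14)-C-x(3,7)-C-x(1,16)-C-x(1,2)-C-x(4,15)-C envelope).
EGF_GEN_SPACINGS = ((5, 10), (3, 7), (4, 10), (1, 2), (6, 12))
#: Fixed cysteine-rich block: six cysteines, all inter-cysteine gaps of 3
#: residues, so no six-cysteine EGF spacing pattern can fire inside it.
CYS_RICH_BLOCK = "C" + "STSC" * 5


def _tk_filler(n: int) -> str:
    cycle = "QNSTGAED"
    return (cycle * (n // len(cycle) + 1))[:n]


def _tk_template(active: bool) -> str:
    vaik = "LAIK" if active else "LAIR"
    hrd = "HRD" if active else "HRN"
    body = (
        _tk_filler(10)
        + "GSGAEG"
        + _tk_filler(60)
        + vaik
        + _tk_filler(90)
        + hrd
        + _tk_filler(60)
        + "DFG"
        + _tk_filler(37)
    )
    return body


@dataclass(frozen=True)
class Element:
    """One architecture element; ``active`` applies to TK, ``length`` to LINKER."""

    kind: str
    active: bool = True
    length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise InvalidSpecError(f"unknown element kind {self.kind!r}")
        if self.kind == "LINKER" and (self.length is None or self.length < 1):
            raise InvalidSpecError("LINKER elements need a positive length")

    @property
    def code(self) -> str:
        if self.kind == "TK":
            return "TKa" if self.active else "TKi"
        return {
            "SIGNAL": "SP",
            "CYS_RICH": "CYS",
            "EGF_MOTIF": "EGF",
            "IG_ISET": "IG",
            "TM": "TM",
            "LINKER": "LNK",
        }[self.kind]


@dataclass(frozen=True)
class ArchitectureSpec:
    """An ordered element list plus completeness flag and free-text label."""

    elements: tuple
    is_full_length: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if not self.elements:
            raise InvalidSpecError("architecture spec needs at least one element")
        n_tk = sum(1 for e in self.elements if e.kind == "TK")
        if n_tk > 1:
            raise InvalidSpecError("at most one TK element per architecture")

    @property
    def signature(self) -> str:
        return "-".join(e.code for e in self.elements)


@dataclass(frozen=True)
class SpeciesFixtureSpec:
    """All architecture specs for one species: receptors, ligands, decoys."""

    species: str
    clade: str
    receptor_specs: tuple = ()
    ligand_specs: tuple = ()
    decoy_specs: tuple = ()

    def all_specs(self):
        return list(self.receptor_specs) + list(self.ligand_specs) + list(self.decoy_specs)


def _linker(rng: random.Random, lo: int = 45, hi: int = 60) -> str:
    """Scanner-silent random linker: no cysteine, no 8-residue hydrophobic
    stretch (alanine runs are capped), no kinase catalytic motifs (the
    alphabet lacks K, R, H and all of L/I/V/M/F)."""
    length = rng.randint(lo, hi)
    out = []
    a_run = 0
    for _ in range(length):
        choices = LINKER_ALPHABET if a_run < 6 else LINKER_ALPHABET.replace("A", "")
        ch = rng.choice(choices)
        a_run = a_run + 1 if ch == "A" else 0
        out.append(ch)
    return "".join(out)


def _signal_peptide(rng: random.Random) -> str:
    core = "".join(rng.choice(_SP_CORE) for _ in range(10))
    return "M" + rng.choice(_POLAR) + rng.choice(_POLAR) + core + "A" + rng.choice(_POLAR) + "A"


def _tm_segment(rng: random.Random) -> str:
    return "".join(rng.choice(_TM_ALPHABET) for _ in range(21))


def _egf_motif(rng: random.Random) -> str:
    parts = ["C"]
    for lo, hi in EGF_GEN_SPACINGS:
        gap = rng.randint(lo, hi)
        parts.append("".join(rng.choice(LINKER_ALPHABET.replace("A", "")) for _ in range(gap)))
        parts.append("C")
    return "".join(parts)


def _element_sequence(element: Element, rng: random.Random) -> str:
    if element.kind == "SIGNAL":
        return _signal_peptide(rng)
    if element.kind == "CYS_RICH":
        return CYS_RICH_BLOCK
    if element.kind == "EGF_MOTIF":
        return _egf_motif(rng)
    if element.kind == "IG_ISET":
        return IG_ISET_TAG
    if element.kind == "TM":
        return _tm_segment(rng)
    if element.kind == "TK":
        return _tk_template(element.active)
    if element.kind == "LINKER":
        return _linker(rng, element.length, element.length)
    raise InvalidSpecError(element.kind)


def generate_protein(
    spec: ArchitectureSpec,
    seed: int,
    species: str = "",
    clade: str = "",
    record_id: str | None = None,
) -> ProteinRecord:
    """Generate one protein from an architecture spec, deterministically.

    Identical ``(spec, seed)`` pairs yield byte-identical sequences. Elements
    appear in spec order, separated by random linkers long enough (>= 45
    residues) that no scanner can bridge two planted elements into one hit.
    A leading linker is added unless the architecture starts with a signal
    peptide (which must sit at the N-terminus to be recognized).
    """
    rng = random.Random(f"{seed}|{species}|{spec.label}|{spec.signature}")
    parts = []
    for i, element in enumerate(spec.elements):
        if i == 0:
            if element.kind != "SIGNAL":
                parts.append(_linker(rng, 18, 25))
        else:
            parts.append(_linker(rng))
        parts.append(_element_sequence(element, rng))
    parts.append(_linker(rng, 20, 30))
    sequence = "".join(parts)
    rid = record_id or f"{species or 'synthetic'}|{spec.label or 'protein'}|{spec.signature}"
    return ProteinRecord(
        id=rid,
        species=species,
        clade=clade,
        sequence=sequence,
        is_full_length=spec.is_full_length,
    )


def generate_species_set(fixture: SpeciesFixtureSpec, seed: int):
    """Generate one record per receptor/ligand/decoy spec of a species.

    Per-protein seeds are derived from ``seed`` and the spec label, so the
    whole set is deterministic yet every protein's variable regions differ.
    """
    records = []
    for spec in fixture.all_specs():
        records.append(
            generate_protein(spec, seed, species=fixture.species, clade=fixture.clade)
        )
    return records


# ---------------------------------------------------------------------------
# Bundled survey data
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("egfrc.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t", dtype=str).fillna("")


def bundled_complement_matrix(which: str) -> ComplementMatrix:
    """Return a transcribed complement matrix.

    ``which`` is ``"EGFR_TABLE"`` (35 species, receptor and inactive-TK
    counts), ``"LIGAND_TABLE"`` (34 species, EGF-type and NRG-type counts; the
    phoronid has no ligand row in the printed survey), or ``"MERGED"`` (union
    of species, all four count columns; missing ligand rows filled with 0).
    """
    egfr = _read_tsv("egfr_table.tsv").set_index("species")
    lig = _read_tsv("ligand_table.tsv").set_index("species")
    for df in (egfr, lig):
        for c in df.columns:
            if c != "clade":
                df[c] = df[c].astype(int)

    if which == "EGFR_TABLE":
        df = egfr.copy()
        df["egf_like_count"] = 0
        df["nrg_like_count"] = 0
    elif which == "LIGAND_TABLE":
        df = lig.copy()
        df["egfr_count"] = 0
        df["inactive_tk_count"] = 0
    elif which == "MERGED":
        df = egfr.copy()
        df["egf_like_count"] = lig["egf_like_count"].reindex(df.index).fillna(0).astype(int)
        df["nrg_like_count"] = lig["nrg_like_count"].reindex(df.index).fillna(0).astype(int)
    else:
        raise KeyError(f"unknown table key {which!r}")
    df = df.reindex(columns=MATRIX_COLUMNS)
    df.index.name = "species"
    return ComplementMatrix(df, provenance="TRANSCRIBED")


def bundled_ligand_totals() -> pd.Series:
    """Printed per-species total ligand counts (for transcription checks)."""
    lig = _read_tsv("ligand_table.tsv").set_index("species")
    return lig["ligand_count"].astype(int)


def bundled_species_tree() -> dendropy.Tree:
    """The rooted survey species tree (polytomies retained)."""
    with resources.as_file(_data_path("species_tree.nwk")) as p:
        tree = dendropy.Tree.get(
            path=str(p),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    tree.is_rooted = True
    return tree


def _receptor_spec_from_row(row) -> ArchitectureSpec:
    elements = [Element("SIGNAL")]
    elements += [Element("CYS_RICH")] * int(row.cys_rich_count)
    elements += [Element("TM")] * int(row.tm_count)
    elements.append(Element("TK", active=row.tk_active == "yes"))
    return ArchitectureSpec(tuple(elements), label=row.label)


def _decoy_specs():
    """Three decoys, each exercising one rejection rule."""
    return (
        ArchitectureSpec(
            (Element("SIGNAL"), Element("EGF_MOTIF"), Element("EGF_MOTIF"), Element("TM")),
            label="decoy_multi_egf",
        ),
        ArchitectureSpec(
            (Element("EGF_MOTIF"), Element("TM")),
            is_full_length=False,
            label="decoy_truncated",
        ),
        ArchitectureSpec((Element("TK", active=True),), label="decoy_tk_only"),
    )


#: Transmembrane counts cycled over a species' EGF-type ligands, covering the
#: observed range of zero (soluble) to two membrane anchors.
_EGF_TYPE_TM_CYCLE = (1, 0, 2)


def bundled_species_fixtures(include_decoys: bool = True):
    """Build one :class:`SpeciesFixtureSpec` per surveyed species.

    Receptor architectures follow the per-receptor transcription (with '?'
    entries instantiated as TM=1, signal peptide present, 3 cysteine-rich
    clusters -- the survey's modal values -- and flagged in the data file).
    EGF-type ligands cycle transmembrane counts 1, 0, 2; NRG-type ligands are
    signal peptide + EGF motif + Ig I-set + one transmembrane segment.
    """
    receptors = _read_tsv("receptor_architectures.tsv")
    merged = bundled_complement_matrix("MERGED")
    fixtures = []
    for species in merged.species:
        clade = merged.row(species)["clade"]
        rec_specs = tuple(
            _receptor_spec_from_row(r)
            for r in receptors[receptors.species == species].itertuples()
        )
        lig_specs = []
        n_egf = int(merged.row(species)["egf_like_count"])
        n_nrg = int(merged.row(species)["nrg_like_count"])
        for i in range(n_egf):
            tm = _EGF_TYPE_TM_CYCLE[i % len(_EGF_TYPE_TM_CYCLE)]
            elements = (Element("SIGNAL"), Element("EGF_MOTIF")) + (Element("TM"),) * tm
            lig_specs.append(ArchitectureSpec(elements, label=f"egf{i + 1}"))
        for i in range(n_nrg):
            elements = (
                Element("SIGNAL"),
                Element("EGF_MOTIF"),
                Element("IG_ISET"),
                Element("TM"),
            )
            lig_specs.append(ArchitectureSpec(elements, label=f"nrg{i + 1}"))
        fixtures.append(
            SpeciesFixtureSpec(
                species=species,
                clade=clade,
                receptor_specs=rec_specs,
                ligand_specs=tuple(lig_specs),
                decoy_specs=_decoy_specs() if include_decoys else (),
            )
        )
    return fixtures


def fixture_for(species: str, include_decoys: bool = True) -> SpeciesFixtureSpec:
    for fx in bundled_species_fixtures(include_decoys=include_decoys):
        if fx.species == species:
            return fx
    raise KeyError(f"no bundled fixture for species {species!r}")
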