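"""Standard-format I/O: FASTA, Newick, TSV matrices, GFF3 feature dumps.

FASTA headers follow the ``species|label|element-signature`` convention with
``full_length=0/1`` carried in the description; bare ids parse gracefully
(empty species/clade, assumed full length). GFF3 coordinates are 1-based
inclusive (protein space); internal coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import MATRIX_COLUMNS, ComplementMatrix
from .records import DomainHit, ProteinRecord


class FormatError(ValueError):
    pass


def read_fasta(path) -> list:
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        parts = rec.id.split("|")
        species = parts[0] if len(parts) >= 3 else ""
        full_length = "full_length=0" not in rec.description
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence in record {i + 1} ({rec.id})")
        records.append(
            ProteinRecord(
                id=rec.id,
                species=species,
                clade="",
                sequence=seq,
                is_full_length=full_length,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=f"full_length={int(r.is_full_length)}",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_newick(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def read_matrix_tsv(path) -> ComplementMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "clade": str})
    if "species" not in df.columns:
        raise FormatError(f"{path}: missing 'species' column")
    df = df.set_index("species")
    df = df.reindex(columns=MATRIX_COLUMNS)
    df["clade"] = df["clade"].fillna("")
    for c in MATRIX_COLUMNS:
        if c != "clade":
            df[c] = df[c].fillna(0).astype(int)
    return ComplementMatrix(df, provenance="TRANSCRIBED")


def write_matrix_tsv(matrix: ComplementMatrix, path) -> None:
    matrix.df.to_csv(path, sep="\t")


def write_gff3(hits_by_record: Mapping[str, Iterable[DomainHit]], path) -> None:
    """One feature line per hit; coordinates converted to 1-based inclusive."""
    lines = ["##gff-version 3"]
    for record_id in hits_by_record:
        for hit in hits_by_record[record_id]:
            attrs = [f"ID={record_id}:{hit.kind}:{hit.start + 1}"]
            for key, value in sorted(hit.annotations.items()):
                attrs.append(f"{key}={str(value).lower()}")
            lines.append(
                "\t".join(
                    [
                        record_id,
                        "egfrc",
                        hit.kind,
                        str(hit.start + 1),
                        str(hit.end),
                        f"{hit.score:.2f}",
                        ".",
                        ".",
                        ";".join(attrs),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> dict:
    """Parse a feature dump back into per-record hit lists."""
    hits: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
        record_id, _, kind, start, end, score, _, _, attrs = fields
        annotations = {}
        for item in attrs.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                if k != "ID":
                    annotations[k] = {"true": True, "false": False}.get(v, v)
        hits.setdefault(record_id, []).append(
            DomainHit(
                kind=kind,
                start=int(start) - 1,
                end=int(end),
                score=float(score),
                annotations=annotations,
            )
        )
    return hits
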