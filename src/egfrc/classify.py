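"""Rule-based classification of scanned proteins into pathway components.

The inclusion rules mirror a conservative domain-architecture screen:

* a receptor (EGFR) must carry a tyrosine-kinase domain, at least one
  transmembrane segment, and at least one cysteine-rich cluster N-terminal of
  the first transmembrane segment; its TK domain is audited for catalytic
  residues and flagged ACTIVE or INACTIVE (pseudokinase);
* a ligand candidate must be full length, carry exactly one EGF motif, no TK
  domain, and a coherent architecture (zero to two transmembrane segments);
  candidates that additionally carry an immunoglobulin I-set domain and a
  transmembrane segment are typed as neuregulin-like (NRG-type), all others
  as EGF-type;
* everything else is rejected with an explicit reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .records import ContractViolationError, DomainHit, ProteinRecord
from .scan import assess_tk_activity

CATEGORIES = ("EGFR", "EGF_TYPE_LIGAND", "NRG_TYPE_LIGAND", "REJECTED")
REJECTION_REASONS = (
    "TK_WITHOUT_ECTODOMAIN",
    "NO_EGF_MOTIF",
    "MULTIPLE_EGF_MOTIFS",
    "NOT_FULL_LENGTH",
    "INCOHERENT_ARCHITECTURE",
)

MATRIX_COLUMNS = [
    "clade",
    "egfr_count",
    "inactive_tk_count",
    "egf_like_count",
    "nrg_like_count",
]


@dataclass
class ComponentCall:
    """The classifier's verdict for one protein."""

    record_id: str
    category: str
    cys_rich_count: int = 0
    tm_count: int = 0
    has_signal: bool = False
    tk_status: str = "NONE"  # ACTIVE, INACTIVE, NONE
    egf_motif_count: int = 0
    ig_iset_count: int = 0
    rejection_reason: str = ""


@dataclass
class ComplementMatrix:
    """Species x component-count table (the computational complement survey).

    ``df`` is indexed by species with columns ``clade``, ``egfr_count``,
    ``inactive_tk_count``, ``egf_like_count``, ``nrg_like_count``.
    """

    df: pd.DataFrame
    provenance: str = "SCANNED"  # SCANNED or TRANSCRIBED

    def __post_init__(self) -> None:
        count_cols = [c for c in MATRIX_COLUMNS if c != "clade"]
        if (self.df[count_cols] < 0).any().any():
            raise ContractViolationError("complement counts must be non-negative")

    @property
    def species(self) -> list:
        return list(self.df.index)

    def row(self, species: str) -> pd.Series:
        return self.df.loc[species]

    def total_ligands(self, species: str) -> int:
        r = self.df.loc[species]
        return int(r["egf_like_count"] + r["nrg_like_count"])


def classify_record(record: ProteinRecord, hits: Iterable[DomainHit]) -> ComponentCall:
    """Apply the inclusion and typing rules to one scanned record.

    ``hits`` must come from scanning the same record; out-of-range
    coordinates raise :class:`ContractViolationError`. The decision order is
    receptor rules first (a TK domain always dominates), then ligand rules,
    then rejection.
    """
    hits = list(hits)
    n = len(record.sequence)
    for h in hits:
        if h.end > n:
            raise ContractViolationError(
                f"hit [{h.start}, {h.end}) exceeds sequence length {n} of {record.id!r}"
            )

    by_kind: dict = {}
    for h in hits:
        by_kind.setdefault(h.kind, []).append(h)

    sp_hits = by_kind.get("SIGNAL", [])
    sp = sp_hits[0] if sp_hits else None
    tms = [t for t in by_kind.get("TM", []) if sp is None or not t.overlaps(sp)]
    tms.sort(key=lambda h: h.start)
    cys = by_kind.get("CYS_RICH", [])
    egf = by_kind.get("EGF_MOTIF", [])
    ig = by_kind.get("IG_ISET", [])
    tk_hits = by_kind.get("TK", [])
    tk = tk_hits[0] if tk_hits else None

    call = ComponentCall(
        record_id=record.id,
        category="REJECTED",
        cys_rich_count=len(cys),
        tm_count=len(tms),
        has_signal=sp is not None,
        tk_status=assess_tk_activity(tk) if tk is not None else "NONE",
        egf_motif_count=len(egf),
        ig_iset_count=len(ig),
    )

    if tk is not None:
        ecto_cys = [c for c in cys if tms and c.end <= tms[0].start]
        if tms and ecto_cys:
            call.category = "EGFR"
        else:
            call.rejection_reason = "TK_WITHOUT_ECTODOMAIN"
        return call

    if len(egf) == 1 and record.is_full_length and len(tms) <= 2:
        if ig and len(tms) >= 1:
            call.category = "NRG_TYPE_LIGAND"
        else:
            call.category = "EGF_TYPE_LIGAND"
        return call

    if len(egf) == 0:
        call.rejection_reason = "NO_EGF_MOTIF"
    elif len(egf) > 1:
        call.rejection_reason = "MULTIPLE_EGF_MOTIFS"
    elif not record.is_full_length:
        call.rejection_reason = "NOT_FULL_LENGTH"
    else:
        call.rejection_reason = "INCOHERENT_ARCHITECTURE"
    return call


def build_complement_matrix(
    calls: Iterable[ComponentCall],
    species_of: Mapping[str, str],
    clade_of: Mapping[str, str] | None = None,
):
    """Aggregate per-record calls into a per-species complement matrix.

    Returns ``(matrix, qc)`` where ``qc`` is a side table of rejected records
    (one row per rejection, with the reason). Every record id must appear in
    ``species_of``.
    """
    clade_of = clade_of or {}
    counts: dict = {}
    qc_rows = []
    for call in calls:
        if call.record_id not in species_of:
            raise ContractViolationError(f"record {call.record_id!r} has no species mapping")
        sp = species_of[call.record_id]
        row = counts.setdefault(
            sp,
            {
                "clade": clade_of.get(sp, ""),
                "egfr_count": 0,
                "inactive_tk_count": 0,
                "egf_like_count": 0,
                "nrg_like_count": 0,
            },
        )
        if call.category == "EGFR":
            row["egfr_count"] += 1
            if call.tk_status == "INACTIVE":
                row["inactive_tk_count"] += 1
        elif call.category == "EGF_TYPE_LIGAND":
            row["egf_like_count"] += 1
        elif call.category == "NRG_TYPE_LIGAND":
            row["nrg_like_count"] += 1
        else:
            qc_rows.append(
                {
                    "record_id": call.record_id,
                    "species": sp,
                    "rejection_reason": call.rejection_reason,
                }
            )
    df = pd.DataFrame.from_dict(counts, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=MATRIX_COLUMNS)
    df = df.reindex(columns=MATRIX_COLUMNS).sort_index()
    df.index.name = "species"
    qc = pd.DataFrame(qc_rows, columns=["record_id", "species", "rejection_reason"])
    return ComplementMatrix(df, provenance="SCANNED"), qc
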