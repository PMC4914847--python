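"""Core record types shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class InvalidSpecError(ValueError):
    """An architecture specification violates its constraints."""


class ContractViolationError(ValueError):
    """An operation received inputs that break its preconditions."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with species/clade labels and a completeness flag.

    ``is_full_length`` is carried as metadata (set by the generator or parsed
    from the FASTA description); no attempt is made to infer completeness from
    the sequence itself.
    """

    id: str
    species: str
    clade: str
    sequence: str
    is_full_length: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ContractViolationError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ContractViolationError(
                f"record {self.id!r} contains non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DomainHit:
    """A located sequence feature call.

    Coordinates are 0-based, half-open (``[start, end)``) internally;
    human-readable reports (GFF3) convert to 1-based inclusive.
    """

    kind: str  # EGF_MOTIF, IG_ISET, TM, SIGNAL, CYS_RICH, TK
    start: int
    end: int
    score: float = 0.0
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ContractViolationError(
                f"bad hit coordinates [{self.start}, {self.end}) for kind {self.kind}"
            )

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start < other.end and other.start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start
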