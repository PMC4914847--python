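"""Lightweight protein-domain scanners.

These detectors stand in for heavyweight profile-based annotation: they locate
EGF motifs (the six-cysteine skeleton), immunoglobulin I-set tags,
transmembrane segments (Kyte-Doolittle sliding window), signal peptides,
cysteine-rich clusters, and tyrosine-kinase domains with an audit of the
catalytic residues (glycine loop, VAIK lysine, HRD aspartate, DFG aspartate).

The TK audit is the basis for calling pseudokinase ("inactive") receptors:
a kinase fold that has lost the ATP-binding lysine or a catalytic aspartate
is flagged INACTIVE, mirroring receptors such as human ErbB3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .records import ContractViolationError, DomainHit, ProteinRecord

#: Kyte-Doolittle hydropathy scale.
HYDROPATHY = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Fixed 90-residue immunoglobulin I-set tag recognized by exact-tag matching.
#: Cysteine-free, no hydrophobic runs, no kinase catalytic motifs.
IG_ISET_TAG = (
    "DPYTWHENRGSQYDTPWNHRYGSDETQPHWYNRDGSTEPQ"
    "WHYDNRSGTEQPWYHDRNGSETPQWDYHRNSGTEPQWYHDRN"
    "GSTEPQWY"
)

# Tyrosine-kinase catalytic motif patterns. Each tolerates substitution at the
# catalytic position; the canonical residue is recorded as a presence flag.
_GLY_LOOP_RE = re.compile(r"G.G..G")
_VAIK_RE = re.compile(r"[LIVMF]A[IV].")
_HRD_RE = re.compile(r"HR.")
_DFG_RE = re.compile(r".FG")


@dataclass(frozen=True)
class ScanProfile:
    """Tunable scanner parameters (all residue units)."""

    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 15
    sp_search_len: int = 35
    sp_min_stretch: int = 8
    sp_threshold: float = 2.0
    sp_max_start: int = 10
    cys_window: int = 60
    cys_min: int = 6
    egf_spacings: tuple = ((3, 14), (3, 7), (1, 16), (1, 2), (4, 15))
    tk_min_span: int = 200
    tk_max_span: int = 350
    ig_max_mismatch_frac: float = 0.10

    def __post_init__(self) -> None:
        for w in (self.tm_window, self.sp_search_len, self.cys_window):
            if w < 1:
                raise ContractViolationError("scan windows must be >= 1")
        for lo, hi in self.egf_spacings:
            if lo > hi:
                raise ContractViolationError("EGF spacing min exceeds max")


DEFAULT_PROFILE = ScanProfile()


def _egf_regex(profile: ScanProfile) -> re.Pattern:
    gaps = "".join(f"C.{{{lo},{hi}}}?" for lo, hi in profile.egf_spacings)
    return re.compile(gaps + "C")


def scan_egf_motifs(record: ProteinRecord, profile: ScanProfile = DEFAULT_PROFILE):
    """Locate six-cysteine EGF motifs.

    Matches are found greedily left to right with a shortest-match tie-break
    (lazy quantifiers); each hit spans from the first to the last cysteine of
    the motif, inclusive. Hits of this kind never overlap.
    """
    pattern = _egf_regex(profile)
    seq = record.sequence
    hits = []
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            break
        hits.append(
            DomainHit("EGF_MOTIF", m.start(), m.end(), score=float(m.end() - m.start()))
        )
        pos = m.end()
    return hits


def _hydropathy_array(seq: str) -> np.ndarray:
    return np.array([HYDROPATHY[aa] for aa in seq], dtype=float)


def _merge_windows(fired_starts, window: int):
    """Merge overlapping fixed-width windows into (start, end) segments."""
    segments = []
    for s in fired_starts:
        e = s + window
        if segments and s <= segments[-1][1]:
            segments[-1][1] = max(segments[-1][1], e)
        else:
            segments.append([s, e])
    return segments


def predict_tm_segments(record: ProteinRecord, profile: ScanProfile = DEFAULT_PROFILE):
    """Sliding-window Kyte-Doolittle transmembrane prediction.

    Windows whose mean hydropathy reaches ``tm_threshold`` are merged; merged
    segments shorter than ``tm_min_len`` residues are discarded. A sequence
    shorter than the window yields an empty list.
    """
    seq = record.sequence
    w = profile.tm_window
    if len(seq) < w:
        return []
    h = _hydropathy_array(seq)
    means = np.convolve(h, np.ones(w) / w, mode="valid")
    fired = np.nonzero(means >= profile.tm_threshold)[0]
    hits = []
    for s, e in _merge_windows(fired.tolist(), w):
        if e - s >= profile.tm_min_len:
            seg_mean = float(h[s:e].mean())
            hits.append(DomainHit("TM", s, e, score=seg_mean))
    return hits


def detect_signal_peptide(record: ProteinRecord, profile: ScanProfile = DEFAULT_PROFILE):
    """N-terminal signal-peptide call, or ``None``.

    Present iff, within the first ``sp_search_len`` residues, a hydrophobic
    stretch of at least ``sp_min_stretch`` residues (mean hydropathy >=
    ``sp_threshold``) begins at residue index <= ``sp_max_start``.
    Returns the longest qualifying stretch.
    """
    seq = record.sequence[: profile.sp_search_len]
    if len(seq) < profile.sp_min_stretch:
        return None
    h = _hydropathy_array(seq)
    best = None
    for start in range(0, min(profile.sp_max_start, len(seq) - profile.sp_min_stretch) + 1):
        for end in range(start + profile.sp_min_stretch, len(seq) + 1):
            mean = h[start:end].mean()
            if mean >= profile.sp_threshold:
                if best is None or (end - start) > (best[1] - best[0]):
                    best = (start, end, float(mean))
    if best is None:
        return None
    return DomainHit("SIGNAL", best[0], best[1], score=best[2])


def detect_cys_rich(
    record: ProteinRecord,
    mask=(),
    profile: ScanProfile = DEFAULT_PROFILE,
):
    """Windowed cysteine-density clusters outside masked regions.

    ``mask`` lists hits (typically EGF motifs and the TK domain) whose
    cysteines must not be double-counted. Windows of ``cys_window`` residues
    containing at least ``cys_min`` unmasked cysteines are merged, and each
    merged cluster is trimmed to its first/last contributing cysteine.
    """
    seq = record.sequence
    is_cys = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("C")
    masked = np.zeros(len(seq), dtype=bool)
    for hit in mask:
        if hit.end > len(seq):
            raise ContractViolationError("mask hit exceeds sequence bounds")
        masked[hit.start : hit.end] = True
    counted = is_cys & ~masked
    w = min(profile.cys_window, len(seq))
    counts = np.convolve(counted.astype(int), np.ones(w, dtype=int), mode="valid")
    fired = np.nonzero(counts >= profile.cys_min)[0]
    cys_pos = np.nonzero(counted)[0]
    # Two cysteines belong to one cluster iff a single qualifying window
    # contains both; merging fired windows directly would chain clusters that
    # no window actually spans.
    clusters = []  # [first_cys, last_cys] inclusive
    for s in fired.tolist():
        in_win = cys_pos[(cys_pos >= s) & (cys_pos < s + w)]
        first, last = int(in_win[0]), int(in_win[-1])
        if clusters and first <= clusters[-1][1]:
            clusters[-1][1] = max(clusters[-1][1], last)
        else:
            clusters.append([first, last])
    hits = []
    for first, last in clusters:
        n_cys = int(counted[first : last + 1].sum())
        hits.append(DomainHit("CYS_RICH", first, last + 1, score=float(n_cys)))
    return hits


def detect_ig_iset(record: ProteinRecord, profile: ScanProfile = DEFAULT_PROFILE):
    """Immunoglobulin I-set detection by tag matching.

    A stand-in for profile-based domain detection: every window of the tag's
    length is compared against :data:`IG_ISET_TAG` and windows within
    ``ig_max_mismatch_frac`` mismatches are reported (merged if overlapping).
    """
    seq = record.sequence
    tag = IG_ISET_TAG
    n, m = len(seq), len(tag)
    if n < m:
        return []
    max_mm = int(profile.ig_max_mismatch_frac * m)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    tag_arr = np.frombuffer(tag.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mismatches = (windows != tag_arr).sum(axis=1)
    fired = np.nonzero(mismatches <= max_mm)[0]
    hits = []
    for s, e in _merge_windows(fired.tolist(), m):
        # a merged run of near-identical windows still represents one tag copy
        hits.append(DomainHit("IG_ISET", s, e, score=float(m - mismatches[s])))
    return hits


def detect_tk_domain(record: ProteinRecord, profile: ScanProfile = DEFAULT_PROFILE):
    """Tyrosine-kinase domain call with a catalytic-residue audit, or ``None``.

    Present iff the ordered motifs G-x-G-x-x-G, [LIVMF]-A-[IV]-K (or a
    substituted residue at the lysine position), H-R-D (or substituted) and
    D-F-G (or substituted) occur in order within a span of
    ``tk_min_span``..``tk_max_span`` residues. Annotations record, per
    catalytic position, whether the canonical residue is present.
    """
    seq = record.sequence
    best = None
    # Consider every glycine-loop anchor and take the most compact valid
    # chain: hydrophobic stretches or linker glycines can mimic single
    # motifs, but the genuine kinase fold packs all four most tightly.
    for g in _GLY_LOOP_RE.finditer(seq):
        v = _VAIK_RE.search(seq, g.end())
        if v is None:
            continue
        h = _HRD_RE.search(seq, v.end())
        if h is None:
            continue
        d = _DFG_RE.search(seq, h.end())
        if d is None:
            continue
        span = d.end() - g.start()
        if profile.tk_min_span <= span <= profile.tk_max_span:
            if best is None or span < best[0]:
                best = (span, g, v, h, d)
    if best is None:
        return None
    span, g, v, h, d = best
    annotations = {
        "gly_loop": True,
        "vaik_K": seq[v.start() + 3] == "K",
        "hrd_D": seq[h.start() + 2] == "D",
        "dfg_D": seq[d.start()] == "D",
    }
    return DomainHit("TK", g.start(), d.end(), score=float(span), annotations=annotations)


def assess_tk_activity(hit: DomainHit) -> str:
    """Classify a TK hit as ACTIVE or INACTIVE (pseudokinase).

    INACTIVE iff any of the audited catalytic residues (VAIK lysine, HRD
    aspartate, DFG aspartate) is substituted.
    """
    if hit.kind != "TK":
        raise ContractViolationError(f"assess_tk_activity requires a TK hit, got {hit.kind}")
    a = hit.annotations
    if a.get("vaik_K") and a.get("hrd_D") and a.get("dfg_D"):
        return "ACTIVE"
    return "INACTIVE"


def scan_record(record: ProteinRecord, profile: ScanProfile = DEFAULT_PROFILE):
    """Run all scanners on one record and return hits sorted by position.

    EGF motifs and the TK domain are masked before cysteine-cluster counting,
    and TM segments overlapping the signal peptide are dropped (the signal
    peptide is not counted as a transmembrane segment).
    """
    hits = []
    egf = scan_egf_motifs(record, profile)
    hits.extend(egf)
    tk = detect_tk_domain(record, profile)
    if tk is not None:
        hits.append(tk)
    mask = list(egf) + ([tk] if tk is not None else [])
    hits.extend(detect_cys_rich(record, mask, profile))
    sp = detect_signal_peptide(record, profile)
    if sp is not None:
        hits.append(sp)
    for tm in predict_tm_segments(record, profile):
        if sp is not None and tm.overlaps(sp):
            continue
        hits.append(tm)
    hits.extend(detect_ig_iset(record, profile))
    hits.sort(key=lambda h: (h.start, h.end, h.kind))
    return hits
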