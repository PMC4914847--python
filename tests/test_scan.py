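"""Unit and property tests for the domain scanners."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egfrc import (
    DEFAULT_PROFILE,
    ProteinRecord,
    ScanProfile,
    assess_tk_activity,
    detect_cys_rich,
    detect_ig_iset,
    detect_signal_peptide,
    detect_tk_domain,
    predict_tm_segments,
    scan_egf_motifs,
    scan_record,
)
from egfrc.fixtures import CYS_RICH_BLOCK, _linker, _signal_peptide, _tk_template, _tm_segment
from egfrc.records import ContractViolationError
from egfrc.scan import IG_ISET_TAG

from . import oracles


def rec(seq: str, full: bool = True) -> ProteinRecord:
    return ProteinRecord(id="x", species="s", clade="c", sequence=seq, is_full_length=full)


def linker(seed: int, lo: int = 50, hi: int = 50) -> str:
    return _linker(random.Random(seed), lo, hi)


# ---------------------------------------------------------------------------
# EGF motif
# ---------------------------------------------------------------------------

CANONICAL_EGF = "CSSSSSCTTTCQQQQCNCSSSSSC"  # gaps 5,3,4,1,5


class TestEgfMotifs:
    def test_single_planted_motif(self):
        seq = linker(1) + CANONICAL_EGF + linker(2)
        hits = scan_egf_motifs(rec(seq))
        assert len(hits) == 1
        (h,) = hits
        assert seq[h.start] == "C" and seq[h.end - 1] == "C"
        assert seq[h.start : h.end].count("C") == 6

    def test_cysteine_free_sequence_has_no_motif(self):
        assert scan_egf_motifs(rec(linker(3, 200, 200))) == []

    def test_two_motifs_found_in_order(self):
        seq = linker(4) + CANONICAL_EGF + linker(5) + CANONICAL_EGF + linker(6)
        hits = scan_egf_motifs(rec(seq))
        assert len(hits) == 2
        assert hits[0].end <= hits[1].start

    def test_matches_backtracking_oracle_on_planted(self):
        seq = linker(7) + CANONICAL_EGF + linker(8) + CANONICAL_EGF + linker(9)
        hits = scan_egf_motifs(rec(seq))
        assert [(h.start, h.end) for h in hits] == oracles.egf_sites(seq)

    def test_spacing_out_of_range_rejected(self):
        # second gap of 8 exceeds the (3,7) envelope
        seq = linker(10) + "CSSSSSCTTTTTTTTCQQQQCNCSSSSSC" + linker(11)
        assert scan_egf_motifs(rec(seq)) == []

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="CSTQNAG", min_size=1, max_size=80))
    def test_equivalent_to_backtracking_oracle(self, seq):
        hits = scan_egf_motifs(rec(seq))
        assert [(h.start, h.end) for h in hits] == oracles.egf_sites(seq)

    def test_hits_never_overlap_and_stay_in_bounds(self):
        rng = random.Random(12)
        for _ in range(50):
            seq = "".join(rng.choice("CSTQNAG") for _ in range(120))
            hits = scan_egf_motifs(rec(seq))
            for a, b in zip(hits, hits[1:]):
                assert a.end <= b.start
            for h in hits:
                assert 0 <= h.start < h.end <= len(seq)


# ---------------------------------------------------------------------------
# Transmembrane prediction and signal peptide
# ---------------------------------------------------------------------------

class TestTmAndSignal:
    def test_planted_tm_detected(self):
        seq = linker(20) + _tm_segment(random.Random(21)) + linker(22)
        hits = predict_tm_segments(rec(seq))
        assert len(hits) == 1
        assert hits[0].end - hits[0].start >= DEFAULT_PROFILE.tm_min_len

    def test_all_glycine_has_no_tm(self):
        assert predict_tm_segments(rec("G" * 120)) == []

    def test_two_planted_tms_detected(self):
        rng = random.Random(23)
        seq = linker(24) + _tm_segment(rng) + linker(25) + _tm_segment(rng) + linker(26)
        assert len(predict_tm_segments(rec(seq))) == 2

    def test_short_sequence_yields_nothing(self):
        assert predict_tm_segments(rec("LLLLL")) == []

    def test_signal_peptide_template_detected(self):
        seq = _signal_peptide(random.Random(27)) + linker(28, 100, 100)
        sp = detect_signal_peptide(rec(seq))
        assert sp is not None
        assert sp.start <= DEFAULT_PROFILE.sp_max_start
        assert oracles.has_signal_peptide(seq)

    def test_polar_nterminus_has_no_signal(self):
        seq = "M" + "STQN" * 10 + linker(29, 100, 100)
        assert detect_signal_peptide(rec(seq)) is None
        assert not oracles.has_signal_peptide(seq)

    def test_hydrophobic_stretch_at_position_50_is_not_a_signal(self):
        seq = linker(30, 50, 50) + "L" * 20 + linker(31, 50, 50)
        assert detect_signal_peptide(rec(seq)) is None
        assert not oracles.has_signal_peptide(seq)

    def test_signal_matches_direct_rule_on_random_heads(self):
        rng = random.Random(32)
        for _ in range(100):
            seq = "".join(rng.choice("LIVFASTQNGM") for _ in range(60))
            assert (detect_signal_peptide(rec(seq)) is not None) == oracles.has_signal_peptide(
                seq
            )


# ---------------------------------------------------------------------------
# Cysteine-rich clusters
# ---------------------------------------------------------------------------

class TestCysRich:
    def test_three_planted_blocks_counted_separately(self):
        seq = (
            linker(40)
            + CYS_RICH_BLOCK
            + linker(41)
            + CYS_RICH_BLOCK
            + linker(42)
            + CYS_RICH_BLOCK
            + linker(43)
        )
        hits = detect_cys_rich(rec(seq))
        assert len(hits) == 3
        assert [(h.start, h.end) for h in hits] == oracles.cys_clusters(seq)
        assert all(h.score == 6 for h in hits)

    def test_cysteine_free_sequence_has_no_cluster(self):
        assert detect_cys_rich(rec(linker(44, 200, 200))) == []

    def test_masked_egf_cysteines_not_counted(self):
        seq = linker(45) + CANONICAL_EGF + linker(46)
        egf_hits = scan_egf_motifs(rec(seq))
        assert len(egf_hits) == 1
        assert detect_cys_rich(rec(seq), mask=egf_hits) == []

    def test_five_cysteines_below_threshold(self):
        seq = linker(47) + "CSTSCSTSCSTSCSTSC" + linker(48)
        assert detect_cys_rich(rec(seq)) == []

    def test_matches_window_union_oracle_on_random_sequences(self):
        rng = random.Random(49)
        for _ in range(40):
            seq = "".join(rng.choice("CSTQNAG") for _ in range(250))
            hits = detect_cys_rich(rec(seq))
            assert [(h.start, h.end) for h in hits] == oracles.cys_clusters(seq)

    def test_mask_beyond_bounds_raises(self):
        from egfrc.records import DomainHit

        with pytest.raises(ContractViolationError):
            detect_cys_rich(rec("CCCCCC"), mask=[DomainHit("EGF_MOTIF", 0, 100)])


# ---------------------------------------------------------------------------
# Ig I-set tag
# ---------------------------------------------------------------------------

class TestIgIset:
    def test_exact_tag_detected(self):
        seq = linker(50) + IG_ISET_TAG + linker(51)
        hits = detect_ig_iset(rec(seq))
        assert len(hits) == 1
        assert seq[hits[0].start : hits[0].start + len(IG_ISET_TAG)] == IG_ISET_TAG

    def test_tag_with_few_mismatches_detected(self):
        mutated = "A" * 5 + IG_ISET_TAG[5:]
        hits = detect_ig_iset(rec(linker(52) + mutated + linker(53)))
        assert len(hits) == 1

    def test_tag_with_many_mismatches_rejected(self):
        mutated = "A" * 20 + IG_ISET_TAG[20:]
        assert detect_ig_iset(rec(linker(54) + mutated + linker(55))) == []

    def test_plain_linker_has_no_tag(self):
        assert detect_ig_iset(rec(linker(56, 300, 300))) == []


# ---------------------------------------------------------------------------
# Tyrosine-kinase domain
# ---------------------------------------------------------------------------

class TestTkDomain:
    def test_active_template_detected_with_all_flags(self):
        seq = linker(60) + _tk_template(True) + linker(61)
        hit = detect_tk_domain(rec(seq))
        assert hit is not None
        assert hit.annotations == {
            "gly_loop": True,
            "vaik_K": True,
            "hrd_D": True,
            "dfg_D": True,
        }
        assert assess_tk_activity(hit) == "ACTIVE"

    def test_inactive_template_flags_substitutions(self):
        hit = detect_tk_domain(rec(linker(62) + _tk_template(False) + linker(63)))
        assert hit is not None
        assert hit.annotations["vaik_K"] is False
        assert hit.annotations["hrd_D"] is False
        assert hit.annotations["dfg_D"] is True
        assert assess_tk_activity(hit) == "INACTIVE"

    def test_motifs_spread_beyond_max_span_rejected(self):
        seq = (
            linker(64)
            + "GSGAEG"
            + linker(65, 200, 200)
            + "LAIK"
            + linker(66, 200, 200)
            + "HRD"
            + linker(67, 150, 150)
            + "DFG"
            + linker(68)
        )
        assert detect_tk_domain(rec(seq)) is None

    def test_motifs_out_of_order_rejected(self):
        seq = (
            linker(69)
            + "DFG"
            + linker(70, 60, 60)
            + "HRD"
            + linker(71, 60, 60)
            + "LAIK"
            + linker(72, 60, 60)
            + "GSGAEG"
            + linker(73)
        )
        assert detect_tk_domain(rec(seq)) is None

    def test_linker_only_sequence_has_no_tk(self):
        assert detect_tk_domain(rec(linker(74, 400, 400))) is None

    def test_assess_requires_tk_hit(self):
        from egfrc.records import DomainHit

        with pytest.raises(ContractViolationError):
            assess_tk_activity(DomainHit("TM", 0, 21))

    def test_span_within_configured_bounds(self):
        hit = detect_tk_domain(rec(linker(75) + _tk_template(True) + linker(76)))
        span = hit.end - hit.start
        assert DEFAULT_PROFILE.tk_min_span <= span <= DEFAULT_PROFILE.tk_max_span


# ---------------------------------------------------------------------------
# Orchestration and profile validation
# ---------------------------------------------------------------------------

class TestScanRecord:
    def test_hits_sorted_and_in_bounds(self):
        rng = random.Random(80)
        seq = (
            _signal_peptide(rng)
            + linker(81)
            + CYS_RICH_BLOCK
            + linker(82)
            + _tm_segment(rng)
            + linker(83)
            + _tk_template(True)
            + linker(84)
        )
        hits = scan_record(rec(seq))
        assert [h.kind for h in hits] == ["SIGNAL", "CYS_RICH", "TM", "TK"]
        assert hits == sorted(hits, key=lambda h: (h.start, h.end, h.kind))
        assert all(0 <= h.start < h.end <= len(seq) for h in hits)

    def test_signal_peptide_not_double_counted_as_tm(self):
        rng = random.Random(85)
        seq = _signal_peptide(rng) + linker(86) + _tm_segment(rng) + linker(87)
        hits = scan_record(rec(seq))
        assert sum(1 for h in hits if h.kind == "TM") == 1
        assert sum(1 for h in hits if h.kind == "SIGNAL") == 1

    def test_scanners_silent_on_random_linkers(self):
        for seed in range(30):
            seq = _linker(random.Random(seed), 300, 400)
            assert scan_record(rec(seq)) == []

    def test_invalid_profile_rejected(self):
        with pytest.raises(ContractViolationError):
            ScanProfile(tm_window=0)
        with pytest.raises(ContractViolationError):
            ScanProfile(egf_spacings=((5, 3),))
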