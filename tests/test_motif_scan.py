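"""Histidine-box scanning, signature matching and subfamily classification."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pufatyper as pt
from pufatyper.motif_scan import (
    DEFAULT_SPACING,
    PatternError,
    UNCLASSIFIED,
    BoxPattern,
)
from pufatyper.synthetic_data import SimConfig, derive_rng, mutate, synth_family_protein


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def regex_hits(sequence: str, pattern: str):
    """Sliding-window oracle for box scanning, built on re lookahead."""
    out = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "X":
            out.append(".")
            i += 1
        elif pattern[i] == "[":
            j = pattern.index("]", i)
            out.append(pattern[i:j + 1])
            i = j + 1
        else:
            out.append(re.escape(pattern[i]))
            i += 1
    rx = re.compile(f"(?=({''.join(out)}))")
    return [(m.start(), m.group(1)) for m in rx.finditer(sequence)]


def exhaustive_signature_oracle(sequence: str, signature):
    """Enumerate every ordered non-overlapping box combination; minimal span wins."""
    per_box = [regex_hits(sequence, box.pattern) for box in signature.boxes]
    if any(not hits for hits in per_box):
        return None
    best = None
    for combo in itertools.product(*per_box):
        starts = [c[0] for c in combo]
        ends = [c[0] + len(c[1]) for c in combo]
        if any(starts[i + 1] < ends[i] for i in range(len(combo) - 1)):
            continue
        span = ends[-1] - starts[0]
        if best is None or span < best[0]:
            best = (span, tuple(starts))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Patterns and scanning
# ---------------------------------------------------------------------------

class TestBoxPattern:
    @pytest.mark.parametrize("bad", [
        "HH",            # too short
        "HXXHHXX",       # too long
        "HAAAA",         # only one literal H/Q
        "H[EDCGH",       # unclosed bracket
        "HXZHH",         # illegal residue
        "H[]CGH",        # empty alternative set
    ])
    def test_rejects_malformed(self, bad):
        with pytest.raises(PatternError):
            BoxPattern.parse(bad)

    def test_bracket_alternatives(self):
        pat = BoxPattern.parse("H[ED]CGH")
        assert pat.matches_at("HECGH", 0)
        assert pat.matches_at("HDCGH", 0)
        assert not pat.matches_at("HACGH", 0)
        assert pat.literal_count == 5

    def test_wildcard_count(self):
        assert BoxPattern.parse("HXXHH").literal_count == 3


class TestScanBoxes:
    def test_planted_pattern(self):
        hits = pt.scan_boxes("AAHDAGHAA", "HDXGH")
        assert [(h.start, h.matched_text) for h in hits] == [(2, "HDAGH")]

    def test_two_plants(self):
        seq = "HQQHHXHQQHH"
        assert [h.start for h in pt.scan_boxes(seq, "HQQHH")] == [0, 6]
        assert [h.start for h in pt.scan_boxes(seq, "HXXHH")] == [0, 6]

    def test_overlapping_hits_reported(self):
        assert [h.start for h in pt.scan_boxes("HHHHHH", "HXXHH")] == [0, 1]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACDEGHQNRSVW", min_size=0, max_size=200),
           pattern=st.sampled_from(["H[ED]CGH", "HXXHH", "QXXHH", "HRLWSH", "HXXXHH"]))
    def test_matches_bruteforce_oracle(self, seq, pattern):
        ours = [(h.start, h.matched_text) for h in pt.scan_boxes(seq, pattern)]
        assert ours == regex_hits(seq, pattern)


# ---------------------------------------------------------------------------
# Signature matching
# ---------------------------------------------------------------------------

def _first_desaturase_sequence(gap1: int, gap2: int) -> str:
    return ("A" * 30 + "HRLWSH" + "A" * gap1 + "HRAHH" + "A" * gap2
            + "HNAHH" + "A" * 40)


class TestMatchSignature:
    def test_planted_boxes_with_legal_gaps(self, registry):
        match = pt.match_signature(_first_desaturase_sequence(40, 40), registry["DES_D9A"])
        assert match is not None
        assert match.spacing_ok
        assert [b.matched_text for b in match.box_matches] == ["HRLWSH", "HRAHH", "HNAHH"]

    def test_gap_beyond_max_flags_spacing(self, registry):
        match = pt.match_signature(_first_desaturase_sequence(40, 500), registry["DES_D9A"])
        assert match is not None
        assert not match.spacing_ok

    def test_missing_box_returns_none(self, registry):
        assert pt.match_signature("A" * 200, registry["DES_D9A"]) is None

    def test_repetitive_sequence_hits_enumeration_cap(self, registry):
        with pytest.raises(pt.InputError, match="cap"):
            pt.match_signature("H" * 300, registry["ELO_C16"])

    def test_agrees_with_exhaustive_oracle_on_random_sequences(self, registry):
        """Sequences with a random number of planted box copies at random
        offsets: the best-candidate choice must equal exhaustive enumeration."""
        rng = np.random.default_rng(11)
        sig = registry["DES_w3"]
        alphabet = np.array(list("ACDEGKQRSVW"))
        box_instances = ["HDCGH", "HWAHH", "HWLHH", "HVWHH"]
        checked_with_match = 0
        for _ in range(300):
            parts = []
            for _segment in range(rng.integers(2, 7)):
                parts.append("".join(alphabet[rng.integers(0, len(alphabet),
                                                           size=rng.integers(5, 60))]))
                if rng.random() < 0.8:
                    parts.append(box_instances[rng.integers(0, len(box_instances))])
            seq = "".join(parts)
            ours = pt.match_signature(seq, sig)
            oracle = exhaustive_signature_oracle(seq, sig)
            if oracle is None:
                assert ours is None
            else:
                assert ours is not None
                assert tuple(b.start for b in ours.box_matches) == oracle
                checked_with_match += 1
        assert checked_with_match > 15  # the comparison actually exercised matches


class TestNtermDomain:
    def test_planted_core_motif_inside_window(self):
        seq = "A" * 30 + "HPGG" + "A" * 300
        assert pt.detect_nterm_domain(seq, "cytb5", window=150)

    def test_motif_beyond_window(self):
        seq = "A" * 400 + "HPGG" + "A" * 50
        assert not pt.detect_nterm_domain(seq, "cytb5", window=150)

    def test_tag_none_always_true(self):
        assert pt.detect_nterm_domain("A" * 10, "none")

    def test_unconfigured_domains_skipped(self):
        assert pt.detect_nterm_domain("A" * 10, "DUF3474")

    def test_unknown_tag_is_config_error(self):
        with pytest.raises(pt.ConfigError):
            pt.detect_nterm_domain("AAAA", "PH")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class TestClassification:
    def test_all_ten_desaturase_families_self_consistent(self, panel, registry):
        """Zero-mutation synthetic members classify to their own family."""
        config = SimConfig(seed=7)
        for gene in panel.desaturases:
            rec = synth_family_protein(gene.name, registry, config)
            family, match = pt.classify_desaturase(rec.sequence, registry)
            assert family == gene.name
            assert match.spacing_ok and match.nterm_ok

    def test_all_seven_elongase_signatures_self_consistent(self, panel, registry):
        """Every elongase member fully matches its own single-box signature."""
        config = SimConfig(seed=7)
        for gene in panel.elongases:
            rec = synth_family_protein(gene.name, registry, config)
            match = pt.match_signature(rec.sequence, registry[gene.signature_id])
            assert match is not None and match.spacing_ok

    def test_delta4_box2_retained_with_relaxed_flanks(self, registry):
        """The Δ4 group keeps the canonical 6-residue second box."""
        config = SimConfig(seed=3)
        rec = synth_family_protein("DES_D4", registry, config)
        family, match = pt.classify_desaturase(rec.sequence, registry)
        assert family == "DES_D4"
        assert len(match.box_matches[1].matched_text) == 6

    def test_elongase_c20_candidate(self, registry):
        seq = "A" * 80 + "QAAHH" + "A" * 150
        label, match = pt.classify_elongase(seq, registry)
        assert label == "ELO_C20"
        assert match.box_matches[0].matched_text == "QAAHH"

    def test_elongase_generic_candidate_unresolved(self, registry):
        seq = "A" * 80 + "HTLHH" + "A" * 150
        label, _ = pt.classify_elongase(seq, registry)
        assert label == pt.ELONGASE_CANDIDATE

    def test_no_box_unclassified(self, registry):
        label, match = pt.classify_elongase("A" * 200, registry)
        assert label == UNCLASSIFIED and match is None
        family, _ = pt.classify_desaturase("A" * 200, registry)
        assert family == UNCLASSIFIED

    def test_empty_registry_is_config_error(self):
        empty = pt.SignatureRegistry(())
        with pytest.raises(pt.ConfigError):
            pt.classify_desaturase("A" * 50, empty)
        with pytest.raises(pt.ConfigError):
            pt.classify_elongase("A" * 50, empty)

    def test_invariant_to_cterminal_extension(self, panel, registry):
        """Appending random residues after the last box never flips the call."""
        config = SimConfig(seed=19)
        rng = derive_rng(19, "cterm")
        tail = "".join(np.array(list(pt.AMINO_ACIDS))[rng.integers(0, 20, size=100)])
        for gene in panel.desaturases[:5]:
            rec = synth_family_protein(gene.name, registry, config)
            base, _ = pt.classify_desaturase(rec.sequence, registry)
            extended, _ = pt.classify_desaturase(rec.sequence + tail, registry)
            assert base == extended == gene.name

    def test_expected_score_monotone_in_mutation_rate(self, registry):
        """More point mutations never raise the expected signature score."""
        config = SimConfig(seed=23, box_preservation_prob=0.0)
        rec = synth_family_protein("DES_D5", registry, config)
        sig = registry["DES_D5"]
        rates = [0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9]
        means = []
        for rate in rates:
            rng = derive_rng(31, f"mono:{rate}")
            scores = []
            for _ in range(60):
                seq = mutate(rec.sequence, rate, config, rng)
                match = pt.match_signature(seq, sig)
                scores.append(0 if match is None or not match.spacing_ok else match.score)
            means.append(float(np.mean(scores)))
        assert means[0] == sig.literal_count  # rate 0: always a full match
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi + 0.5  # non-increasing up to Monte-Carlo noise
        assert means[-1] < means[0]
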