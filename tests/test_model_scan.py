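"""Profile construction, domain/motif scanning, and their brute-force oracles."""

import math
import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tppplike import (
    build_model,
    detect_extension,
    find_rossmann_motifs,
    scan_fragments,
    scan_profile,
)
from tppplike._aa import ALPHABET, AA_INDEX


def brute_force_scan(seq, profile, min_normalized):
    """Independent all-offsets enumeration with the documented overlap rule."""
    L = len(profile.consensus)
    maxscore = profile.max_score
    candidates = []
    for o in range(len(seq) - L + 1):
        s = 0.0
        for k in range(L):
            s += profile.columns[k, AA_INDEX.get(seq[o + k], 20)]
        if s / maxscore >= min_normalized:
            candidates.append((o, s))
    chosen = []
    for o, s in sorted(candidates, key=lambda t: (-t[1], t[0])):
        if all(o + L <= co or o >= co + L for co, _ in chosen):
            chosen.append((o, s))
    return sorted(chosen)


class TestBuildModel:
    def test_single_sequence_consensus(self):
        aln = {"core": ["MKLV" * 30], "partial_core": ["A" * 22 + "GAGAGAAGR"],
               "extension": ["E" * 14]}
        m = build_model(aln)
        assert m["core"].consensus == "MKLV" * 30

    def test_pure_column_score_closed_form(self):
        # 100% G column, pseudocount -> 0: log-odds -> log(20)
        aln = {"core": ["G" * 120], "partial_core": ["A" * 22 + "GAGAGAAGR"],
               "extension": ["A" * 14]}
        m = build_model(aln, pseudocount=1e-9)
        g_scores = m["core"].columns[:, AA_INDEX["G"]]
        assert np.allclose(g_scores, math.log(20), atol=1e-6)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_model({"core": ["AAA", "AA"]})

    def test_length_bounds_validated(self):
        bad = {"core": ["A" * 200], "partial_core": ["A" * 22 + "GAGAGAAGR"],
               "extension": ["A" * 14]}
        with pytest.raises(ValueError, match=r"\[140,160\]"):
            build_model(bad)
        bad_ext = {"core": ["A" * 119], "partial_core": ["A" * 22 + "GAGAGAAGR"],
                   "extension": ["A" * 10]}
        with pytest.raises(ValueError, match="extension"):
            build_model(bad_ext)

    def test_packaged_model_geometry(self, model):
        n_core = len(model["core"])
        n_part = len(model["partial_core"])
        assert 140 <= n_core + n_part <= 160
        assert n_part in (31, 32)
        assert len(model["extension"]) == 14
        assert len(model["ntail"]) == 50


class TestScanProfile:
    def test_self_match(self, model):
        for segment in ("core", "partial_core", "extension"):
            consensus = model[segment].consensus
            hits = scan_profile(consensus, model, segment, 0.5)
            assert len(hits) == 1
            assert hits[0].start == 0 and hits[0].normalized_score == pytest.approx(1.0)
            assert hits[0].tier == "strong"

    def test_random_background_null(self, model):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list(ALPHABET), size=500))
        assert scan_profile(seq, model, "core", 0.8) == []

    def test_two_planted_copies(self, model):
        consensus = model["core"].consensus
        seq = consensus + "A" * 20 + consensus
        hits = scan_profile(seq, model, "core", 0.8)
        assert [(h.start, h.end) for h in hits] == [
            (0, 119), (139, 258),
        ]

    def test_segment_longer_than_sequence(self, model):
        assert scan_profile("MKR", model, "core", 0.5) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_brute_force_oracle_agreement(self, model, seed):
        """Scans of sequences <= 60 aa agree exactly with offset enumeration."""
        profile = model["extension"]  # 14 columns fit inside 60 aa
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(10, 61))
            seq = "".join(rng.choice(list(ALPHABET), size=n))
            if rng.random() < 0.5 and n >= 14:  # plant a hit half the time
                o = int(rng.integers(0, n - 13))
                seq = seq[:o] + profile.consensus + seq[o + 14:]
            for floor in (0.3, 0.55, 0.8):
                got = [(h.start, h.score) for h in scan_profile(seq, model, "extension", floor)]
                expected = brute_force_scan(seq, profile, floor)
                assert [g[0] for g in got] == [e[0] for e in expected]
                assert np.allclose([g[1] for g in got], [e[1] for e in expected])

    def test_planted_domain_recovery(self, model):
        rng = np.random.default_rng(7)
        consensus = model["core"].consensus
        for _ in range(5):
            k = int(rng.integers(0, 200))
            background = "".join(rng.choice(list(ALPHABET), size=400))
            seq = background[:k] + consensus + background[k:]
            hits = scan_profile(seq, model, "core", 0.8)
            assert hits and max(hits, key=lambda h: h.score).start == k

    def test_monotonic_in_floor(self, model):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(ALPHABET), size=300)) + model["core"].consensus
        counts = [
            len(scan_profile(seq, model, "core", f)) for f in (0.0, 0.3, 0.55, 0.8, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRossmannMotif:
    def test_pattern_instance(self):
        (hit,) = find_rossmann_motifs("GAGAGAAGR")
        assert (hit.start, hit.end, hit.matched) == (0, 9, "GAGAGAAGR")

    def test_negative(self):
        assert find_rossmann_motifs("AAAAAAAAA") == []
        assert find_rossmann_motifs("") == []

    def test_overlapping_hits_reported(self):
        seq = "GAGAGAAGAGAGAAGR"  # overlapping windows both matching
        starts = [h.start for h in find_rossmann_motifs(seq)]
        assert starts == [m.start() for m in re.finditer(r"(?=(G.G.G..GR))", seq)]

    @given(st.text(alphabet="GRA", min_size=9, max_size=200))
    def test_enumeration_oracle(self, seq):
        """Regex matcher equals the brute-force 9-mer check at every offset."""

        def is_match(w):
            return (
                w[0] == "G" and w[2] == "G" and w[4] == "G"
                and w[7] == "G" and w[8] == "R"
            )

        expected = [i for i in range(len(seq) - 8) if is_match(seq[i : i + 9])]
        assert [h.start for h in find_rossmann_motifs(seq)] == expected


class TestExtension:
    def test_self_match_follows_motif(self, model):
        seq = model["partial_core"].consensus + model["extension"].consensus
        (motif,) = find_rossmann_motifs(seq)
        region = detect_extension(seq, motif, model)
        assert region is not None
        assert (region.start, region.end) == (motif.end, motif.end + 14)
        assert region.normalized_score == pytest.approx(1.0)

    def test_no_room_at_terminus(self, model):
        seq = "A" * 20 + "GAGAGAAGR"
        (motif,) = find_rossmann_motifs(seq)
        assert detect_extension(seq, motif, model) is None

    def test_random_downstream_rejected(self, model):
        rng = np.random.default_rng(5)
        seq = "GAGAGAAGR" + "".join(rng.choice(list(ALPHABET), size=14))
        (motif,) = find_rossmann_motifs(seq)
        assert detect_extension(seq, motif, model, 0.5) is None


class TestFragments:
    def test_exact_length_recovery(self, model):
        long_consensus = model["core"].consensus + model["partial_core"].consensus
        for frag_len in (70, 95, 120, 140):
            # pad guaranteed to mismatch the consensus continuation, so the
            # longest-on-ties rule cannot absorb coincidental matches
            tail = "".join(
                "A" if c != "A" else "E" for c in long_consensus[frag_len : frag_len + 30]
            ).ljust(30, "A")
            lead = "E" if long_consensus[0] != "E" else "A"
            seq = lead * 30 + long_consensus[:frag_len] + tail
            hits = scan_fragments(seq, model)
            assert len(hits) == 1
            assert (hits[0].start, len(hits[0])) == (30, frag_len)

    def test_two_fragments(self, model):
        long_consensus = model["core"].consensus + model["partial_core"].consensus
        seq = long_consensus[:80] + "E" * 15 + long_consensus[:100]
        hits = scan_fragments(seq, model)
        assert [(h.start, len(h)) for h in hits] == [(0, 80), (95, 100)]
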