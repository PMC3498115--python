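"""Subfamily classification, alignment statistics and orthology helpers."""

import numpy as np
import pytest

from tppplike import (
    ProteinRecord,
    SynthSpec,
    classify_architecture,
    count_domain_copies,
    detect_nterminal_tail,
    generate_batch,
    generate_class_sequence,
    pairwise_align_stats,
    reciprocal_best_hits,
)
from tppplike.architecture import alignment_score
from tppplike.scan import DomainHit
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(s1, s2, gap_open=11.0, gap_extend=1.0):
    """Quadratic-space affine-gap global alignment score oracle."""
    n, m = len(s1), len(s2)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in s2
    Y = np.full((n + 1, m + 1), neg)  # gap in s1
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = BLOSUM62[s1[i - 1], s2[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestClassification:
    @pytest.mark.parametrize(
        "label",
        ["long_type", "short_type", "truncated", "partial_only", "multidomain", "apicortin"],
    )
    def test_zero_noise_round_trip(self, label, model, parts):
        rng = np.random.default_rng(17)
        for _ in range(3):
            rec, truth, foreign = generate_class_sequence(
                SynthSpec(label), parts, rng
            )
            call = classify_architecture(rec, model, foreign)
            assert call.label == truth.label
            assert call.n_partial_copies == truth.n_partial_copies
            assert call.n_p25_copies == truth.n_p25_copies

    def test_long_type_flags(self, model, parts):
        rec, truth, foreign = generate_class_sequence(
            SynthSpec("long_type"), parts, np.random.default_rng(0)
        )
        call = classify_architecture(rec, model, foreign)
        assert call.has_ntail and call.has_extension and call.has_rossmann == [True]

    def test_long_type_without_ntail(self, model, parts):
        rec, _, foreign = generate_class_sequence(
            SynthSpec("long_type", include_ntail=False), parts, np.random.default_rng(0)
        )
        call = classify_architecture(rec, model, foreign)
        assert call.label == "long_type" and not call.has_ntail

    def test_random_background_is_none(self, model):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=400))
        assert classify_architecture(seq, model).label == "none"

    def test_partial_triplicate_copy_count(self, model, parts):
        rec, truth, foreign = generate_class_sequence(
            SynthSpec("partial_only", n_partial_copies=3), parts, np.random.default_rng(2)
        )
        call = classify_architecture(rec, model, foreign)
        assert (call.label, call.n_partial_copies) == ("partial_only", 3)

    def test_partial_copies_without_motif_flagged(self, model, parts):
        rec, truth, foreign = generate_class_sequence(
            SynthSpec("partial_only", n_partial_copies=2, rossmann_flags=(True, False)),
            parts, np.random.default_rng(4),
        )
        call = classify_architecture(rec, model, foreign)
        assert call.has_rossmann == [True, False]

    def test_short_vs_truncated_needs_taxon(self, model, parts):
        rec, _, _ = generate_class_sequence(
            SynthSpec("truncated"), parts, np.random.default_rng(6)
        )
        metazoan = classify_architecture(rec, model, taxon="Drosophila melanogaster")
        assert metazoan.label == "truncated"
        protist = classify_architecture(rec, model, taxon="Giardia lamblia")
        assert protist.label == "short_type"
        assert any("defaulting to short_type" in n for n in protist.notes)

    def test_total_function(self, model):
        for seq in ("M", "MK" * 400, "X" * 50):
            call = classify_architecture(seq, model)
            assert call.label in {
                "long_type", "short_type", "truncated", "partial_only",
                "multidomain", "apicortin", "none",
            }


class TestCopyCounting:
    def test_empty(self):
        assert count_domain_copies([]) == 0

    def test_adjacent_copies(self):
        hits = [
            DomainHit("partial_core", 0, 31, 10.0, 0.9, "strong"),
            DomainHit("partial_core", 32, 63, 10.0, 0.9, "strong"),
        ]
        assert count_domain_copies(hits) == 2

    def test_quadruplicate_from_generator(self, model, parts):
        rec, _, foreign = generate_class_sequence(
            SynthSpec("partial_only", n_partial_copies=4), parts, np.random.default_rng(8)
        )
        call = classify_architecture(rec, model, foreign)
        assert call.n_partial_copies == 4

    def test_overlap_is_contract_violation(self):
        hits = [
            DomainHit("core", 0, 119, 10.0, 0.9, "strong"),
            DomainHit("core", 100, 219, 10.0, 0.9, "strong"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            count_domain_copies(hits)


class TestNTail:
    @pytest.mark.parametrize("start,expected", [(50, True), (0, False), (39, False), (40, True)])
    def test_boundaries(self, start, expected):
        hit = DomainHit("core", start, start + 119, 10.0, 0.9, "strong")
        assert detect_nterminal_tail("A" * (start + 119), hit, 40) is expected


class TestPairwiseStats:
    def test_identical(self):
        assert pairwise_align_stats("MKRDEFG", "MKRDEFG") == (100.0, 100.0)

    def test_hand_computed_four_columns(self):
        # AAAA/AAAT aligns gaplessly over 4 columns; A<->T earns no group credit
        assert pairwise_align_stats("AAAA", "AAAT") == (75.0, 75.0)

    def test_similarity_counts_group_substitutions(self):
        # I<->L are in the strong group ILVM: similar but not identical
        identity, similarity = pairwise_align_stats("MKIV", "MKLV")
        assert (identity, similarity) == (75.0, 100.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_score_matches_dp_oracle(self, seed):
        """Aligner score equals an independent Gotoh DP on short sequences."""
        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            s1 = "".join(rng.choice(aa, size=int(rng.integers(5, 31))))
            s2 = "".join(rng.choice(aa, size=int(rng.integers(5, 31))))
            assert alignment_score(s1, s2) == pytest.approx(gotoh_score(s1, s2))

    def test_stats_recomputable_from_alignment(self):
        identity, similarity = pairwise_align_stats("MKRDEFGHIKL", "MKRDEGHIKL")
        assert 0 <= identity <= similarity <= 100


class TestReciprocalBestHits:
    def test_identical_singletons(self):
        x = ProteinRecord(id="x", sequence="MKRDEFGHIK")
        y = ProteinRecord(id="x2", sequence="MKRDEFGHIK")
        assert reciprocal_best_hits([x], [y]) == [("x", "x2")]

    def test_planted_ortholog_pairs(self, parts):
        rng = np.random.default_rng(13)
        base = [parts["segments"]["core"], parts["variants"]["short_core"],
                parts["segments"]["ntail"] * 3]

        def mutate(s):
            out = list(s)
            for i in rng.choice(len(s), size=max(1, len(s) // 20), replace=False):
                out[i] = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
            return "".join(out)

        set_a = [ProteinRecord(id=f"a{i}", sequence=mutate(s)) for i, s in enumerate(base)]
        set_b = [ProteinRecord(id=f"b{i}", sequence=mutate(s)) for i, s in enumerate(base)]
        assert sorted(reciprocal_best_hits(set_a, set_b)) == [
            ("a0", "b0"), ("a1", "b1"), ("a2", "b2"),
        ]

    def test_asymmetric_best_excluded_and_brute_force(self):
        # constructed score table: a0's best is b0, but b0's best is a1
        table = {("a0", "b0"): 10, ("a0", "b1"): 5,
                 ("a1", "b0"): 20, ("a1", "b1"): 1}
        recs_a = [ProteinRecord(id=k, sequence="M") for k in ("a0", "a1")]
        recs_b = [ProteinRecord(id=k, sequence="M") for k in ("b0", "b1")]

        def scorer(x, y):
            return table[(x.id, y.id)] if (x.id, y.id) in table else table[(y.id, x.id)]

        got = reciprocal_best_hits(recs_a, recs_b, scorer)
        # brute-force double argmax
        expected = []
        for a in recs_a:
            best_b = max(recs_b, key=lambda b: (scorer(a, b), b.id))
            best_a = max(recs_a, key=lambda x: (scorer(x, best_b), x.id))
            if best_a.id == a.id:
                expected.append((a.id, best_b.id))
        assert got == expected
        assert ("a0", "b0") not in got

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_best_hits([], [ProteinRecord(id="x", sequence="M")])
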