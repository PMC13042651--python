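"""Sequence design, top-fraction filtering, identity, and clustering."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from segremodel.backbone import synthetic_inpaint
from segremodel.seqdesign import (HELIX_FORMERS, MockSequenceBackend,
                                  SequenceVariant, adapt_min_seq_id,
                                  design_sequences, filter_top_fraction,
                                  greedy_cluster, mock_design_backend,
                                  pairwise_identity)


@pytest.fixture(scope="module")
def backbone(scaffold, scaffold_spec_h):
    cand = synthetic_inpaint(scaffold, scaffold_spec_h, "H", 5.0, seed=2)
    return cand


def make_variants(sequences, scores=None):
    scores = scores if scores is not None else list(range(len(sequences)))
    return [SequenceVariant(f"v{i:04d}", "bb", s, float(sc), 0.2)
            for i, (s, sc) in enumerate(zip(sequences, scores))]


class TestMockBackend:
    def test_determinism(self, backbone):
        a = mock_design_backend(backbone, 20, 0.2, seed=5)
        b = mock_design_backend(backbone, 20, 0.2, seed=5)
        assert [(v.sequence, v.global_score) for v in a] == \
               [(v.sequence, v.global_score) for v in b]

    def test_zero_temperature_gives_argmax_sequence(self, backbone):
        variants = mock_design_backend(backbone, 10, 0.0, seed=1)
        segments = {v.sequence[10:22] for v in variants}
        assert len(segments) == 1  # argmax at every designed position
        scores = [v.global_score for v in variants]
        assert np.std(scores) > 0  # noise still varies the score

    def test_helix_former_enrichment(self, backbone):
        """Designed helical segments are enriched in helix formers relative
        to the uniform background (Monte-Carlo, fixed seed)."""
        variants = mock_design_backend(backbone, 200, 0.2, seed=3)
        seg_idx = range(10, 22)
        content = np.mean([
            sum(v.sequence[i] in HELIX_FORMERS for i in seg_idx) / 12
            for v in variants])
        assert content > 6 / 20  # background frequency of the favored set

    def test_design_positions_only_in_segment(self, backbone):
        wild = backbone.structure.chain("A").sequence()
        for v in mock_design_backend(backbone, 5, 0.2, seed=4):
            assert v.sequence[:10] == wild[:10]
            assert v.sequence[22:] == wild[22:]


class TestDesignSequences:
    def test_contract_and_determinism(self, backbone):
        kept1, rej1 = design_sequences(MockSequenceBackend(), backbone, 50,
                                       seed=9)
        kept2, _ = design_sequences(MockSequenceBackend(), backbone, 50,
                                    seed=9)
        assert len(kept1) == 50 and not rej1
        assert [v.sequence for v in kept1] == [v.sequence for v in kept2]

    def test_constraint_violation_rejected(self, backbone):
        class MutatingBackend(MockSequenceBackend):
            def design(self, bb, n, t, pos, seed):
                out = super().design(bb, n, t, pos, seed)
                s = out[0].sequence
                out[0].sequence = ("W" if s[0] != "W" else "Y") + s[1:]
                return out

        kept, rejected = design_sequences(MutatingBackend(), backbone, 3,
                                          seed=1)
        assert len(kept) == 2
        assert len(rejected) == 1 and "constrained" in rejected[0].reason

    def test_zero_samples_rejected(self, backbone):
        with pytest.raises(ValueError):
            design_sequences(MockSequenceBackend(), backbone, 0)


class TestTopFraction:
    def test_half_of_thousand_is_five_hundred(self, backbone):
        variants = mock_design_backend(backbone, 1000, 0.2, seed=7)
        assert len(filter_top_fraction(variants, 0.5)) == 500

    def test_ceil_rounding(self):
        variants = make_variants(["AAA", "AAC", "ACC"])
        assert len(filter_top_fraction(variants, 0.5)) == 2

    def test_matches_brute_force_selection(self, rng):
        variants = make_variants(
            ["AA"] * 40, scores=rng.normal(size=40).tolist())
        out = filter_top_fraction(variants, 0.3)
        expected = sorted(variants,
                          key=lambda v: (v.global_score, v.variant_id))
        assert [v.variant_id for v in out] == \
               [v.variant_id for v in expected[:math.ceil(0.3 * 40)]]

    def test_idempotent_at_full_fraction(self, rng):
        variants = make_variants(["AA"] * 9, scores=rng.normal(size=9))
        once = filter_top_fraction(variants, 0.4)
        again = filter_top_fraction(once, 1.0)
        assert [v.variant_id for v in once] == [v.variant_id for v in again]


class TestIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("AAAA", "AAAA", 1.0),
        ("AAAA", "WWWW", 0.0),
        ("AAAAAAAAAA", "AAAAAAAWWW", 0.7),
    ])
    def test_direct_counts(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_identity("AA", "AAA")


class TestClustering:
    def test_identical_sequences_single_representative(self):
        variants = make_variants(["AAAA"] * 5, scores=[3, 1, 2, 5, 4])
        reps, membership = greedy_cluster(variants, 0.8)
        assert len(reps) == 1
        assert reps[0].variant_id == "v0001"  # the best-scoring one
        assert set(membership.values()) == {"v0001"}

    def test_all_distinct_all_representatives(self):
        variants = make_variants(["AAAA", "CCCC", "DDDD", "EEEE"])
        reps, _ = greedy_cluster(variants, 0.25)
        assert len(reps) == 4

    def test_matches_brute_force_rule(self, rng):
        seqs = ["".join(rng.choice(list("AC"), 12)) for _ in range(200)]
        variants = make_variants(seqs, scores=rng.normal(size=200).tolist())
        reps, membership = greedy_cluster(variants, 0.75)

        ordered = sorted(variants, key=lambda v: (v.global_score, v.variant_id))
        expected_reps, expected_members = [], {}
        for v in ordered:
            for rep in expected_reps:
                if pairwise_identity(v.sequence, rep.sequence) >= 0.75:
                    expected_members[v.variant_id] = rep.variant_id
                    break
            else:
                expected_reps.append(v)
                expected_members[v.variant_id] = v.variant_id
        assert [r.variant_id for r in reps] == \
               [r.variant_id for r in expected_reps]
        assert membership == expected_members

    def test_cluster_invariants(self, rng):
        seqs = ["".join(rng.choice(list("ACD"), 10)) for _ in range(80)]
        variants = make_variants(seqs, scores=rng.normal(size=80).tolist())
        thr = 0.6
        reps, membership = greedy_cluster(variants, thr)
        by_id = {v.variant_id: v for v in variants}
        for member, rep in membership.items():
            if member != rep:
                assert pairwise_identity(by_id[member].sequence,
                                         by_id[rep].sequence) >= thr
        for i, r1 in enumerate(reps):
            for r2 in reps[:i]:
                assert pairwise_identity(r1.sequence, r2.sequence) < thr


class TestAdaptiveThreshold:
    def test_in_range_threshold_chosen(self):
        # family-structured population: 8 parents, children mutated at
        # varying rates, so representative counts cross the target band
        rng = np.random.default_rng(77)
        alpha = list("ACDEFGHIKL")
        parents = ["".join(rng.choice(alpha, 20)) for _ in range(8)]
        seqs = []
        for k in range(300):
            child = list(parents[k % 8])
            rate = rng.uniform(0.02, 0.35)
            for i in range(20):
                if rng.random() < rate:
                    child[i] = rng.choice(alpha)
            seqs.append("".join(child))
        variants = make_variants(seqs, scores=rng.normal(size=300).tolist())
        result = adapt_min_seq_id(variants, target_range=(50, 200))
        assert result.in_range
        assert 50 <= len(result.representatives) <= 200
        # oracle: exhaustive grid evaluation picks the same threshold
        for thr in sorted(result.counts_by_threshold, reverse=True):
            n = result.counts_by_threshold[thr]
            if 50 <= n <= 200:
                assert thr == result.min_seq_id
                break

    def test_infeasible_target_flagged(self):
        variants = make_variants(["AAAA", "CCCC"], scores=[1, 2])
        result = adapt_min_seq_id(variants, target_range=(100, 500))
        assert not result.in_range
        assert len(result.representatives) == 2

    def test_representative_count_monotone_in_threshold(self, rng):
        seqs = ["".join(rng.choice(list("AC"), 15)) for _ in range(150)]
        variants = make_variants(seqs, scores=rng.normal(size=150).tolist())
        grid = (0.95, 0.9, 0.8, 0.7, 0.6, 0.5)
        counts = [len(greedy_cluster(variants, t)[0]) for t in grid]
        assert counts == sorted(counts, reverse=True)
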