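"""MSA handling, redundancy filtering, Neff/conservation, segment nomination."""

import itertools

import numpy as np
import pytest

from segremodel.core import Chain, Residue, Structure
from segremodel.fixtures import make_toy_msa
from segremodel.profiling import (MSA, MSAError, ResidueProfile,
                                  column_neff, conservation_from_neff,
                                  filter_redundancy, map_query_to_structure,
                                  read_msa, select_designable_segments,
                                  sequence_weights, _pair_identity)

QUERY = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"


def brute_force_greedy(rows, threshold, query_index=0):
    """Independent re-implementation of the greedy redundancy rule."""
    order = [query_index] + [i for i in range(len(rows)) if i != query_index]
    kept = []
    for i in order:
        if i == query_index or all(
                _pair_identity(rows[i], rows[j]) < threshold for j in kept):
            kept.append(i)
    return sorted(kept)


def poly_structure(seq, chain_id="A", start=1):
    from segremodel.core import ONE_TO_THREE

    residues = []
    for i, aa in enumerate(seq):
        base = np.array([i * 3.8, 0.0, 0.0])
        residues.append(Residue(chain_id, start + i, ONE_TO_THREE[aa], {
            "N": base, "CA": base + [1.46, 0, 0], "C": base + [2.2, 1.3, 0],
            "O": base + [2.2, 2.5, 0],
        }))
    return Structure("poly", [Chain(chain_id, residues)])


class TestReadMSA:
    def test_single_sequence_fasta_identity_mapping(self, tmp_path):
        path = tmp_path / "single.fasta"
        path.write_text(f">query\n{QUERY}\n")
        msa = read_msa(path)
        assert msa.n_rows == 1
        assert msa.query == QUERY
        st = poly_structure(QUERY, start=50)
        mapping = map_query_to_structure(msa, st, "A")
        assert mapping[0] == 50
        assert mapping[len(QUERY) - 1] == 50 + len(QUERY) - 1

    def test_query_gap_columns_dropped_other_gaps_kept(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">q\nAC-DE\n>h1\nACXDE\n>h2\nA-Y-E\n")
        msa = read_msa(path)
        assert msa.width == 4            # query-frame: query gap column gone
        assert msa.rows[0] == "ACDE"
        assert msa.rows[2] == "A--E"     # other rows keep their gaps

    def test_stockholm_format(self, tmp_path):
        path = tmp_path / "aln.sto"
        path.write_text(
            "# STOCKHOLM 1.0\n"
            "q    ACDEF\n"
            "h1   ACDEY\n"
            "//\n")
        msa = read_msa(path)
        assert msa.n_rows == 2 and msa.width == 5

    def test_a2m_lowercase_normalized(self, tmp_path):
        path = tmp_path / "aln.a2m"
        path.write_text(">q\nAcDE\n>h\nA.DE\n")
        msa = read_msa(path, format="a2m")
        assert msa.rows[0] == "ACDE"
        assert msa.rows[1] == "A-DE"

    def test_query_structure_mismatch_reports_position(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">q\nAAAA\n")
        st = poly_structure("AATA")
        with pytest.raises(MSAError, match="position 3"):
            map_query_to_structure(read_msa(path), st, "A")


class TestRedundancy:
    def test_exact_duplicate_removed(self):
        msa = MSA(ids=["q", "d"], rows=[QUERY, QUERY])
        out = filter_redundancy(msa, 0.80)
        assert out.n_rows == 1

    def test_distant_rows_kept(self):
        a = "AAAAAAAAAA"
        b = "AAAAAWWWWW"  # 50% identity
        out = filter_redundancy(MSA(ids=["q", "h"], rows=[a, b]), 0.80)
        assert out.n_rows == 2

    def test_matches_brute_force_on_synthetic_family(self):
        msa = make_toy_msa(QUERY, n=20, mutation_rates=0.3, seed=7,
                          n_duplicates=5)
        out = filter_redundancy(msa, 0.80)
        expected = brute_force_greedy(msa.rows, 0.80, msa.query_index)
        assert sorted(msa.ids.index(i) for i in out.ids) == expected

    def test_idempotent(self):
        msa = make_toy_msa(QUERY, n=15, mutation_rates=0.25, seed=3,
                          n_duplicates=3)
        once = filter_redundancy(msa, 0.80)
        twice = filter_redundancy(once, 0.80)
        assert once.ids == twice.ids


class TestWeights:
    def test_all_identical_rows_share_weight(self):
        msa = MSA(ids=list("abcd"), rows=[QUERY] * 4)
        w = sequence_weights(msa, 0.80)
        assert np.allclose(w, 0.25)

    def test_all_distinct_rows_weight_one(self):
        rows = ["AAAAAAAAAA", "WWWWWWWWWW", "CCCCCCCCCC"]
        w = sequence_weights(MSA(ids=list("abc"), rows=rows), 0.80)
        assert np.allclose(w, 1.0)

    def test_matches_brute_force_single_linkage(self):
        msa = make_toy_msa(QUERY, n=12, mutation_rates=0.15, seed=11,
                          n_duplicates=4)
        w = sequence_weights(msa, 0.80)
        # oracle: exhaustive single-linkage via transitive closure
        n = msa.n_rows
        adj = {i: {i} for i in range(n)}
        for i, j in itertools.combinations(range(n), 2):
            if _pair_identity(msa.rows[i], msa.rows[j]) >= 0.80:
                adj[i].add(j)
                adj[j].add(i)
        clusters = []
        seen = set()
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            clusters.append(comp)
        expected = np.empty(n)
        for comp in clusters:
            for k in comp:
                expected[k] = 1.0 / len(comp)
        assert np.allclose(w, expected)


class TestNeff:
    def test_single_state_column(self):
        msa = MSA(ids=list("abc"), rows=["A", "A", "A"])
        neff, empty = column_neff(msa, np.ones(3), 0)
        assert neff == pytest.approx(1.0)
        assert not empty
        assert conservation_from_neff(neff) == pytest.approx(1.0)

    def test_uniform_twenty_states(self):
        rows = list("ACDEFGHIKLMNPQRSTVWY")
        msa = MSA(ids=[f"s{i}" for i in range(20)], rows=rows)
        neff, _ = column_neff(msa, np.ones(20), 0)
        assert neff == pytest.approx(20.0)
        assert conservation_from_neff(neff) == pytest.approx(0.0)

    def test_gap_only_column_flagged(self):
        msa = MSA(ids=["a", "b"], rows=["A-", "C-"])
        neff, empty = column_neff(msa, np.ones(2), 1)
        assert neff == 1.0 and empty

    def test_matches_direct_entropy_computation(self, rng):
        rows = ["".join(rng.choice(list("ACDE"), 1)) for _ in range(10)]
        weights = rng.uniform(0.1, 1.0, 10)
        msa = MSA(ids=[f"s{i}" for i in range(10)], rows=rows)
        neff, _ = column_neff(msa, weights, 0)
        freqs = {}
        for r, w in zip(rows, weights):
            freqs[r[0]] = freqs.get(r[0], 0.0) + w
        p = np.array(list(freqs.values()))
        p = p / p.sum()
        expected = np.exp(-np.sum(p * np.log(p)))
        assert neff == pytest.approx(expected)

    def test_bounds_on_random_alignments(self):
        msa = make_toy_msa(QUERY, n=50, mutation_rates=0.5, seed=13)
        w = sequence_weights(msa)
        for col in range(msa.width):
            neff, _ = column_neff(msa, w, col)
            assert 1.0 <= neff <= 20.0
            assert 0.0 <= conservation_from_neff(neff) <= 1.0


class TestSegmentNomination:
    @staticmethod
    def profiles_from(ss3, neffs, start=1):
        return [ResidueProfile(res_num=start + i, aa="A", ss3=s, neff=n,
                               conservation=conservation_from_neff(n))
                for i, (s, n) in enumerate(zip(ss3, neffs))]

    def test_conserved_helical_chain_yields_nothing(self):
        profiles = self.profiles_from("H" * 40, [1.5] * 40)
        assert select_designable_segments(profiles, "A") == []

    def test_single_high_neff_coil_run_found(self):
        ss3 = "H" * 20 + "C" * 16 + "H" * 20
        neffs = [2.0] * 20 + [12.0] * 16 + [2.0] * 20
        out = select_designable_segments(self.profiles_from(ss3, neffs), "A")
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (21, 36)
        # exhaustive check: every residue satisfies all predicates
        threshold = np.quantile(neffs, 0.5)
        for num in range(out[0].start, out[0].end + 1):
            i = num - 1
            assert ss3[i] == "C" and neffs[i] > threshold

    def test_exclusion_splits_run(self):
        ss3 = "H" * 10 + "C" * 15 + "H" * 10
        neffs = [2.0] * 10 + [12.0] * 15 + [2.0] * 10
        out = select_designable_segments(
            self.profiles_from(ss3, neffs), "A", min_len=6,
            exclusions={18})
        # equal scores: tie broken by start position
        assert [(c.start, c.end) for c in out] == [(11, 17), (19, 25)]

    def test_short_split_halves_dropped(self):
        # excluding the middle of an 11-residue run leaves two 5-runs,
        # both below min_len
        ss3 = "H" * 10 + "C" * 11 + "H" * 10
        neffs = [2.0] * 10 + [12.0] * 11 + [2.0] * 10
        out = select_designable_segments(
            self.profiles_from(ss3, neffs), "A", min_len=6,
            exclusions={16})
        assert out == []

    def test_ranked_by_mean_neff_times_length(self):
        ss3 = "C" * 8 + "H" * 4 + "C" * 10
        neffs = [9.0] * 8 + [2.0] * 4 + [15.0] * 10
        out = select_designable_segments(self.profiles_from(ss3, neffs), "A",
                                         neff_quantile=0.1)
        assert [(c.start, c.end) for c in out] == [(13, 22), (1, 8)]
        assert out[0].score > out[1].score
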