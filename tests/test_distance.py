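import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hbdest as h
from hbdest.io import ESTRecord
from oracles import naive_min_d2, random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def rec(seq, rid="r"):
    return ESTRecord(rid, seq)


class TestCountWords:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("AAAT", 1, {"A": 3, "T": 1}),
            ("ACGT", 4, {"ACGT": 1}),
            ("ANAA", 2, {"AA": 1}),  # words containing N are excluded
            ("ACG", 4, {}),  # k longer than the sequence
            ("acgt", 2, {"AC": 1, "CG": 1, "GT": 1}),
        ],
    )
    def test_examples(self, seq, k, expected):
        assert dict(h.count_words(seq, k)) == expected

    @given(seq=st.text(alphabet="ACGTN", min_size=1, max_size=80), k=st.integers(1, 6))
    @settings(deadline=None)
    def test_matches_direct_substring_scan(self, seq, k):
        expected = {}
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= set("ACGT"):
                expected[w] = expected.get(w, 0) + 1
        assert dict(h.count_words(seq, k)) == expected


class TestWordFreqs:
    def test_normalization(self):
        assert h.word_freqs("AAAT", 1) == {"A": 0.75, "T": 0.25}
        f = h.word_freqs("ACGT", 2)
        assert f == pytest.approx({"AC": 1 / 3, "CG": 1 / 3, "GT": 1 / 3})

    @given(seq=dna, k=st.integers(1, 4))
    @settings(deadline=None)
    def test_sums_to_one(self, seq, k):
        if len(seq) < k:
            with pytest.raises(ValueError):
                h.word_freqs(seq, k)
        else:
            assert sum(h.word_freqs(seq, k).values()) == pytest.approx(1.0)

    def test_no_valid_word_is_error(self):
        with pytest.raises(ValueError, match="valid"):
            h.word_freqs("NNNN", 2)


class TestD2Distance:
    def test_single_window_pair(self):
        p = h.HybridParams(k=1, window=4)
        assert h.d2_distance(rec("AAAA"), rec("AAAT"), p) == 2  # (4-3)^2 + (0-1)^2

    def test_identical_sequences_are_zero(self):
        p = h.HybridParams(k=3, window=10)
        assert h.d2_distance(rec("ACGTACGTACGT"), rec("ACGTACGTACGT"), p) == 0

    def test_shared_window_gives_zero(self):
        p = h.HybridParams(k=1, window=2)
        assert h.d2_distance(rec("AATT"), rec("TTAA"), p) == 0

    def test_shorter_than_k_is_error(self):
        with pytest.raises(ValueError, match="shorter"):
            h.d2_distance(rec("AC"), rec("ACGTAC"), h.HybridParams(k=3, window=5))

    @pytest.mark.parametrize("k", [1, 2, 3, 6])
    def test_matches_bruteforce_small(self, rng, k):
        """Exact integer agreement with naive all-window-pairs recounting."""
        for _ in range(12):
            lp, lq = rng.integers(max(k, 8), 120, size=2)
            window = int(rng.integers(k, 101))
            p, q = random_dna(rng, lp, 0.05), random_dna(rng, lq, 0.05)
            params = h.HybridParams(k=k, window=window)
            assert h.d2_distance(rec(p), rec(q), params) == naive_min_d2(
                p, q, k, window
            )

    def test_symmetry(self, rng):
        params = h.HybridParams(k=2, window=20)
        for _ in range(20):
            p = rec(random_dna(rng, int(rng.integers(5, 80))), "p")
            q = rec(random_dna(rng, int(rng.integers(5, 80))), "q")
            assert h.d2_distance(p, q, params) == h.d2_distance(q, p, params)

    def test_default_window_default_word_size(self):
        assert h.HybridParams() == h.HybridParams(
            k=6, window=100, weight_local=0.9, weight_global=0.1
        )


class TestGred:
    def test_identical_is_zero(self):
        assert h.gred_distance(rec("ACGTACGT"), rec("ACGTACGT"), k=2) == 0.0

    def test_equal_frequency_vectors_are_zero(self):
        # different sequences, same 1-mer frequencies
        assert h.gred_distance(rec("AC"), rec("CA"), k=1) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_are_one(self):
        assert h.gred_distance(rec("AAAA"), rec("CCCC"), k=1) == pytest.approx(1.0)

    def test_hand_checked_value(self):
        # {A:1} vs {A:1/2, C:1/2}: base-2 JS divergence = 1 - 0.75*log2(3) + 0.5
        expected = 0.5 * np.log2(4 / 3) + 0.5 * (
            0.5 * np.log2(2 / 3) + 0.5 * np.log2(2.0)
        )
        assert expected == pytest.approx(0.3113, abs=5e-5)
        assert h.gred_distance(rec("AA"), rec("AC"), k=1) == pytest.approx(
            expected, abs=1e-12
        )

    def test_bounds_and_symmetry(self, rng):
        for _ in range(40):
            p = rec(random_dna(rng, int(rng.integers(10, 120))), "p")
            q = rec(random_dna(rng, int(rng.integers(10, 120))), "q")
            k = int(rng.integers(1, 4))
            d = h.gred_distance(p, q, k)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(h.gred_distance(q, p, k), abs=1e-12)

    def test_matrix_route_matches_pairwise_route(self, small_dataset):
        """Vectorized mixture-entropy matrix equals the per-pair scipy form."""
        ds, _ = small_dataset
        sub = h.ESTDataset(ds.records[:8])
        m = h.gred_matrix(sub, k=3)
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                assert m.values[i, j] == pytest.approx(
                    h.gred_distance(sub[i], sub[j], k=3), abs=1e-10
                )


class TestMinMaxNormalize:
    def test_endpoints_and_interior(self):
        raw = h.DistanceMatrix(
            ids=list("abc"),
            values=np.array([[0, 2, 4], [2, 0, 10], [4, 10, 0]], dtype=float),
            kind="raw_d2",
        )
        nd = h.minmax_normalize(raw)
        assert nd.values[0, 1] == 0.0  # min -> 0
        assert nd.values[1, 2] == 1.0  # max -> 1
        assert nd.values[0, 2] == pytest.approx(0.25)  # (4-2)/(10-2)
        assert np.all(np.diag(nd.values) == 0)

    def test_degenerate_equal_matrix_warns_and_zeroes(self):
        raw = h.DistanceMatrix(
            ids=list("abc"), values=np.full((3, 3), 5.0) - 5 * np.eye(3), kind="raw_d2"
        )
        with pytest.warns(RuntimeWarning, match="equal"):
            nd = h.minmax_normalize(raw)
        assert np.all(nd.values == 0)

    def test_monotone(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 12))
            v = rng.random((n, n)) * 50
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            raw = h.DistanceMatrix(ids=[str(i) for i in range(n)], values=v, kind="raw_d2")
            nd = h.minmax_normalize(raw)
            off = ~np.eye(n, dtype=bool)
            order_raw = np.argsort(v[off], kind="stable")
            order_new = np.argsort(nd.values[off], kind="stable")
            assert np.array_equal(order_raw, order_new)

    def test_needs_two_sequences(self):
        raw = h.DistanceMatrix(ids=["a"], values=np.zeros((1, 1)), kind="raw_d2")
        with pytest.raises(ValueError):
            h.minmax_normalize(raw)


class TestHybridMatrix:
    def test_weighted_combination_entrywise(self):
        ids = ["a", "b"]
        nd2 = h.DistanceMatrix(ids=ids, values=np.array([[0, 0.4], [0.4, 0]]), kind="normalized_d2")
        gred = h.DistanceMatrix(ids=ids, values=np.array([[0, 0.8], [0.8, 0]]), kind="gred")
        hyb = h.combine(nd2, gred, h.HybridParams(weight_local=0.9, weight_global=0.1))
        assert hyb.values[0, 1] == pytest.approx(0.44)  # 0.9*0.4 + 0.1*0.8

    def test_local_only_equals_normalized_d2(self, small_dataset):
        ds, _ = small_dataset
        params = h.HybridParams(weight_local=1.0, weight_global=0.0)
        hyb = h.hybrid_matrix(ds, params)
        local = h.hybrid_matrix(ds, feature="local")
        assert np.array_equal(hyb.values, local.values)

    def test_linearity(self, small_dataset):
        ds, _ = small_dataset
        nd2 = h.hybrid_matrix(ds, feature="local")
        gred = h.gred_matrix(ds, 6)
        params = h.HybridParams(weight_local=0.85, weight_global=0.15)
        hyb = h.hybrid_matrix(ds, params)
        expected = 0.85 * nd2.values + 0.15 * gred.values
        assert np.allclose(hyb.values, expected, atol=1e-12)

    def test_entries_bounded_and_valid(self, small_dataset):
        ds, _ = small_dataset
        m = h.hybrid_matrix(ds)
        m.validate()
        assert m.values.min() >= 0 and m.values.max() <= 1

    def test_identical_sequences_have_zero_distance(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 200))
        other = "".join(rng.choice(list("ACGT"), 200))
        ds = h.ESTDataset(
            [ESTRecord("a", seq), ESTRecord("b", seq), ESTRecord("c", other)]
        )
        m = h.hybrid_matrix(ds)
        assert m.values[0, 1] == 0.0

    def test_reverse_complement_option(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 200))
        ds = h.ESTDataset([ESTRecord("f", seq), ESTRecord("r", h.reverse_complement(seq))])
        params = h.HybridParams(k=6, window=100, weight_local=1.0, weight_global=0.0)
        fwd = h.d2_matrix(ds, params).values[0, 1]
        rc = h.d2_matrix(ds, params, rc=True).values[0, 1]
        assert rc == 0.0
        assert fwd > 0


class TestHybridParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"weight_local": 0.5, "weight_global": 0.6},
            {"k": 0},
            {"k": 8, "window": 4},
            {"weight_local": 1.2, "weight_global": -0.2},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            h.HybridParams(**kwargs)

    def test_named_combos(self):
        p = h.HybridParams.from_combo("cb3")
        assert (p.weight_local, p.weight_global) == (0.85, 0.15)
        assert set(h.WEIGHT_COMBOS) == {f"CB{i}" for i in range(1, 7)}
        with pytest.raises(ValueError, match="unknown"):
            h.HybridParams.from_combo("CB9")
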