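"""Unit tests for the DP engine on small, hand-checkable instances.

The heavyweight oracle-equivalence sweeps live in the acceptance suite;
here each algorithm is pinned against closed forms computed directly
from the model definition, plus small cross-checks.
"""

import math

import numpy as np
import pytest

from profscan import dp, _kernels
from profscan.profile import ProfileHMM, configure_local
from profscan.seqio import encode

from conftest import random_search_profile, random_dna

LN2 = math.log(2.0)


def deterministic_profile(emissions, trans_row=(0.9, 0.05, 0.05, 0.6, 0.4, 0.6, 0.4)):
    """Profile with specified match emissions per node."""
    M = len(emissions)
    me = np.array(emissions, dtype=float)
    tr = np.tile(trans_row, (M, 1))
    hmm = ProfileHMM("det", me, np.tile([0.25] * 4, (M, 1)), tr,
                     np.full(4, 0.25), "A" * M)
    return configure_local(hmm)


def ssv_brute_force(sp, x):
    """Exhaustive scorer over all (diagonal, start, end) segments."""
    t = dp.core_tables(sp)
    lod = t.msc / LN2
    M, L = t.M, len(x)
    best = {}
    for d in range(-(M - 1), L):
        for k0 in range(M):
            i0 = d + k0
            if not 0 <= i0 < L:
                continue
            s = 0.0
            for k in range(k0, M):
                i = d + k
                if i >= L:
                    break
                s += lod[k, x[i]]
                if d not in best or s > best[d]:
                    best[d] = s
    return best


class TestClosedForms:
    """M=1 model with e(A)=1 on target 'A': every path weight by hand."""

    def setup_method(self):
        self.sp = deterministic_profile([[1.0, 0, 0, 0]])
        # L=1: flank loop = null ext = 1/2, flank move = 1/2, null term 1/2
        self.ln_null = math.log(0.25)
        # (a) N emits A (flank loop); N->B; B->E (empty); C->T
        self.pa = (math.log(1 / 2) + math.log(1 / 2) + math.log(0.5)
                   + math.log(1 / 2) - self.ln_null)
        # (b) B at 0; empty; C emits A (loop); C->T  (same weight as (a))
        self.pb = self.pa
        # (c) N->B at 0; B->M1 (0.5 * entry 1.0); M1 emits A (odds 4); exit q=1; C->T
        self.pc = (math.log(1 / 2) + math.log(0.5 * 1.0) + math.log(4.0)
                   + 0.0 + math.log(1 / 2) - self.ln_null)

    def test_forward_is_logsum_of_three_paths(self):
        expect = np.logaddexp(np.logaddexp(self.pa, self.pb), self.pc) / LN2
        assert math.isclose(dp.forward(self.sp, "A"), expect, abs_tol=1e-12)

    def test_viterbi_is_best_core_path(self):
        score, path = dp.viterbi(self.sp, "A")
        assert math.isclose(score, self.pc / LN2, abs_tol=1e-12)
        assert path == [("B", 0), ("M", 1, 1), ("E", 1)]

    def test_oracle_agrees_and_counts_three_paths(self):
        en = dp.enumerate_paths(self.sp, "A")
        assert len(en.paths) == 3
        expect = np.logaddexp(np.logaddexp(self.pa, self.pb), self.pc) / LN2
        assert math.isclose(en.total_bits, expect, abs_tol=1e-12)

    def test_posterior_match_is_path_weight_ratio(self):
        fm = dp.forward_matrix(self.sp, "A")
        bm = dp.backward_matrix(self.sp, "A")
        post = dp.posterior_decode(self.sp, "A", fm, bm)
        tot = np.exp(self.pa) + np.exp(self.pb) + np.exp(self.pc)
        assert math.isclose(post.match[0, 0], np.exp(self.pc) / tot, abs_tol=1e-12)
        assert math.isclose(post.flank[0], (np.exp(self.pa) + np.exp(self.pb)) / tot,
                            abs_tol=1e-12)


class TestSSV:
    def test_perfect_single_state_match(self):
        sp = deterministic_profile([[1.0, 0, 0, 0]])
        hits = dp.ssv_scan(sp, "A", min_score=1.0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.target_start, h.target_end, h.model_start) == (0, 1, 0)
        assert math.isclose(h.score, 2.0, abs_tol=1e-9)   # log2(1/0.25)

    def test_null_emissions_give_no_positive_hits(self):
        sp = deterministic_profile([[0.25] * 4] * 3)
        assert dp.ssv_scan(sp, "ACGTACGT", min_score=1e-6) == []
        all_hits = dp.ssv_scan(sp, "ACGTACGT", min_score=-1.0)
        assert all(abs(h.score) < 1e-9 for h in all_hits)

    def test_matches_exhaustive_segment_scorer(self, rng):
        for _ in range(15):
            sp = random_search_profile(rng, int(rng.integers(1, 6)))
            x = encode(random_dna(rng, int(rng.integers(5, 31))))
            brute = ssv_brute_force(sp, x)
            hits = dp.ssv_scan(sp, x, -1e20)
            got = {h.target_start - h.model_start: h.score for h in hits}
            assert set(got) == set(brute)
            for d, s in brute.items():
                assert math.isclose(got[d], s, abs_tol=1e-9)

    def test_fast_single_precision_path_agrees(self, rng):
        sp = random_search_profile(rng, 12)
        x = encode(random_dna(rng, 500))
        slow = {(h.target_start, h.target_end): h.score
                for h in dp.ssv_scan(sp, x, 2.0)}
        fast = {(h.target_start, h.target_end): h.score
                for h in dp.ssv_scan(sp, x, 2.0, fast=True)}
        assert set(slow) == set(fast)
        for k in slow:
            assert math.isclose(slow[k], fast[k], abs_tol=1e-4)


class TestViterbi:
    def test_forced_ungapped_path(self):
        sp = deterministic_profile([[1, 0, 0, 0], [0, 1, 0, 0]],
                                   trans_row=(0.98, 0.01, 0.01, 0.6, 0.4, 0.6, 0.4))
        score, path = dp.viterbi(sp, "AC")
        core = [el for el in path if el[0] in "MID"]
        assert core == [("M", 1, 1), ("M", 2, 2)]
        assert path[0] == ("B", 0) and path[-1] == ("E", 2)

    def test_viterbi_never_exceeds_forward(self, rng):
        for _ in range(30):
            sp = random_search_profile(rng, int(rng.integers(1, 6)))
            seq = random_dna(rng, int(rng.integers(1, 10)))
            assert dp.viterbi(sp, seq)[0] <= dp.forward(sp, seq) + 1e-9

    def test_window_cap_directs_to_pipeline(self, rng):
        sp = random_search_profile(rng, 2)
        x = np.ones(dp.WINDOW_CAP + 1, dtype=np.uint8)
        with pytest.raises(ValueError, match="pipeline"):
            dp.viterbi(sp, x)
        with pytest.raises(ValueError, match="pipeline"):
            dp.forward(sp, x)


class TestForwardBackward:
    def test_empty_target_returns_empty_alignment_score(self, rng):
        sp = random_search_profile(rng, 3)
        f = dp.forward(sp, "")
        b = dp.backward(sp, "")
        assert math.isclose(f, b, abs_tol=1e-12)
        assert math.isclose(f, math.log2(0.5))   # lone B->E path at L=0

    def test_uninformative_profile_scores_nonpositive(self):
        # emissions equal to null carry no evidence: only transition mass
        sp = deterministic_profile([[0.25] * 4] * 4)
        for L in (1, 5, 20):
            assert dp.forward(sp, "A" * L) <= 0.0

    def test_equality_on_random_cases(self, rng):
        for _ in range(30):
            sp = random_search_profile(rng, int(rng.integers(1, 7)))
            seq = random_dna(rng, int(rng.integers(0, 12)))
            assert abs(dp.forward(sp, seq) - dp.backward(sp, seq)) < 1e-6


class TestPosterior:
    def test_rows_sum_to_one(self, rng):
        for _ in range(10):
            sp = random_search_profile(rng, int(rng.integers(1, 7)))
            seq = random_dna(rng, int(rng.integers(1, 12)))
            fm = dp.forward_matrix(sp, seq)
            bm = dp.backward_matrix(sp, seq)
            post = dp.posterior_decode(sp, seq, fm, bm)
            rows = post.match.sum(1) + post.insert.sum(1) + post.flank
            assert np.allclose(rows, 1.0, atol=1e-6)

    def test_mismatched_matrices_rejected(self, rng):
        sp = random_search_profile(rng, 3)
        fm = dp.forward_matrix(sp, "ACGT")
        bm = dp.backward_matrix(sp, "ACG")
        with pytest.raises(ValueError):
            dp.posterior_decode(sp, "ACGT", fm, bm)


class TestOracle:
    def test_size_guard(self, rng):
        sp = random_search_profile(rng, 7)
        with pytest.raises(ValueError):
            dp.enumerate_paths(sp, "ACGT")

    def test_path_count_m2_l2(self, rng):
        """Hand enumeration for M=2, L=2, all transitions finite:
        3 empty-alignment placements (B after 0, 1 or 2 N-emissions),
        3 one-residue structures {M1, M2, M1-D2} x 2 placements,
        and the single two-residue alignment M1-M2: 10 paths."""
        sp = random_search_profile(rng, 2)
        en = dp.enumerate_paths(sp, "AC")
        assert len(en.paths) == 10

    def test_determinism(self, rng):
        sp = random_search_profile(rng, 3)
        seq = "ACGTA"
        a = dp.forward(sp, seq), dp.viterbi(sp, seq)[0]
        b = dp.forward(sp, seq), dp.viterbi(sp, seq)[0]
        assert a == b


class TestKernels:
    """Compiled kernels against the log-space reference implementations."""

    def test_scores_agree_with_reference(self, rng):
        for M in (1, 3, 24):
            sp = random_search_profile(rng, M)
            X = np.stack([encode(random_dna(rng, 40)) for _ in range(12)])
            kv = _kernels.viterbi_scores(sp, X)
            kf = _kernels.forward_scores(sp, X)
            for i in range(12):
                assert abs(kv[i] - dp.viterbi(sp, X[i])[0]) < 1e-6
                assert abs(kf[i] - dp.forward(sp, X[i])) < 1e-6

    def test_batch_and_scalar_paths_agree(self, rng):
        sp = random_search_profile(rng, 11)
        X = np.stack([encode(random_dna(rng, 100)) for _ in range(16)])
        scalar_v = _kernels._viterbi_scores(*_kernels.log_pack(sp), X)
        scalar_f = _kernels._forward_scores(*_kernels.lin_pack(sp), X)
        assert np.allclose(_kernels.viterbi_scores(sp, X), scalar_v, atol=1e-9)
        assert np.allclose(_kernels.forward_scores(sp, X), scalar_f, atol=1e-9)

    def test_ssv_best_scores_match_scan(self, rng):
        sp = random_search_profile(rng, 8)
        X = np.stack([encode(random_dna(rng, 60)) for _ in range(6)])
        batch = _kernels.ssv_best_scores(sp, X)
        for i in range(6):
            hits = dp.ssv_scan(sp, X[i], -1e20)
            assert math.isclose(batch[i], max(h.score for h in hits), abs_tol=1e-4)
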