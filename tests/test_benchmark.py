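import math

import numpy as np
import pytest

from profscan import benchmark as bm
from profscan.benchmark import (
    BackgroundHMM,
    FamilyParams,
    Instance,
    classify_hits,
    fpw_merge,
    generate_benchmark,
    pairwise_identity,
    roc_curve,
    sample_background,
    sensitivity_at,
    simulate_family,
    split_family,
    train_background,
)
from profscan.pipeline import Hit
from profscan.seqio import MultipleAlignment, SequenceRecord


def msa(*rows):
    return MultipleAlignment([(f"r{i+1}", s) for i, s in enumerate(rows)])


def make_hit(target="t", strand="+", start=0, end=100, evalue=1e-3, score=20.0,
             query="q"):
    return Hit(
        query_name=query, target_id=target, strand=strand,
        env_start=start, env_end=end, ali_start=start, ali_end=end,
        hmm_start=1, hmm_end=10, score=score, raw_score=score, bias=0.0,
        pvalue=evalue, evalue=evalue, alignment=("", "", ""),
    )


class TestSplit:
    def test_identical_rows_cannot_split(self):
        res = split_family(msa("ACGTACGT", "ACGTACGT"))
        assert not res.ok

    def test_fully_diverged_rows_split_one_each(self):
        res = split_family(msa("AAAAAAAA", "CCCCCCCC"), identity_threshold=0.6)
        assert res.ok
        assert res.query_msa.n_rows == 1 and len(res.test_seqs) == 1

    def test_two_clusters_split_along_cluster_boundary(self):
        # cluster A: rows 1-3 identical; cluster B: rows 4-6 identical,
        # 50% identical to A -> single linkage at >0.6 keeps them apart
        a = "AAAA" * 4
        b = "AAAA" * 2 + "CCCC" * 2
        res = split_family(msa(a, a, a, b, b, b), identity_threshold=0.6)
        assert res.ok
        assert res.query_msa.n_rows == 3 and len(res.test_seqs) == 3
        ids = set(res.query_msa.ids)
        assert ids in ({"r1", "r2", "r3"}, {"r4", "r5", "r6"})
        # no cross pair above the threshold
        ident = pairwise_identity(msa(a, a, a, b, b, b))
        for i in (0, 1, 2):
            for j in (3, 4, 5):
                assert ident[i, j] <= 0.6

    def test_identity_uses_mutually_ungapped_columns(self):
        ident = pairwise_identity(msa("AC-T", "ACG-"))
        # only columns 1,2 are mutually ungapped: both match -> 1.0
        assert math.isclose(ident[0, 1], 1.0)

    def test_single_row_family_fails(self):
        assert not split_family(msa("ACGT")).ok


class TestSimulator:
    def test_family_shape_and_alphabet(self):
        fam = simulate_family(FamilyParams(), np.random.default_rng(0))
        assert fam.n_rows == 6
        assert all(set(r) <= set("ACGT-") for _, r in fam.rows)

    def test_deterministic_given_rng_state(self):
        a = simulate_family(FamilyParams(), np.random.default_rng(5))
        b = simulate_family(FamilyParams(), np.random.default_rng(5))
        assert a.rows == b.rows

    def test_remote_homology_regime(self):
        """Cross-group identities must sit below the split threshold and
        most families must be splittable (the benchmark's premise)."""
        rng = np.random.default_rng(2)
        ok = 0
        for _ in range(12):
            fam = simulate_family(FamilyParams(), rng)
            if split_family(fam).ok:
                ok += 1
        assert ok >= 8


class TestBackground:
    def test_single_state_recovers_frequencies(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=20_000))
        hmm, _ = train_background([SequenceRecord("t", seq)], n_states=1,
                                  iterations=3, seed=1)
        freqs = np.array([seq.count(b) / len(seq) for b in "ACGT"])
        assert np.allclose(hmm.emit[0], freqs, atol=1e-9)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        _, logliks = train_background([SequenceRecord("t", seq)], n_states=3,
                                      iterations=6, seed=2)
        assert all(b >= a - 1e-6 for a, b in zip(logliks, logliks[1:]))

    def test_invalid_state_count(self):
        with pytest.raises(ValueError):
            train_background([SequenceRecord("t", "ACGT" * 100)], n_states=0)

    def test_sample_deterministic(self):
        bg = BackgroundHMM(start=[1.0], trans=[[1.0]], emit=[[0.25] * 4])
        a = sample_background(bg, 500, seed=4).residues
        b = sample_background(bg, 500, seed=4).residues
        assert a == b

    def test_uniform_single_state_frequencies(self):
        bg = BackgroundHMM(start=[1.0], trans=[[1.0]], emit=[[0.25] * 4])
        s = sample_background(bg, 100_000, seed=0).residues
        for b in "ACGT":
            assert abs(s.count(b) / 100_000 - 0.25) < 0.0041  # 3 sigma

    def test_sticky_two_state_at_fraction_bounded(self):
        bg = BackgroundHMM(
            start=[0.5, 0.5],
            trans=[[0.99, 0.01], [0.01, 0.99]],
            emit=[[0.45, 0.05, 0.05, 0.45],      # AT-rich state
                  [0.05, 0.45, 0.45, 0.05]],     # GC-rich state
        )
        s = sample_background(bg, 50_000, seed=1).residues
        at = (s.count("A") + s.count("T")) / len(s)
        assert 0.1 + 0.03 < at < 0.9 - 0.03   # strictly between state AT levels


class TestEmbedding:
    def _bg(self):
        return BackgroundHMM(start=[1.0], trans=[[1.0]], emit=[[0.25] * 4])

    def test_zero_families_pure_decoy(self):
        bset = generate_benchmark([], self._bg(), decoy_length=5000, seed=0)
        assert bset.truth == [] and bset.queries == {}
        assert sum(len(r) for r in bset.decoy_db) == 5000

    def test_single_instance_inside_bounds(self):
        fam = msa("A" * 100, "C" * 100)   # splits into one query, one test
        bset = generate_benchmark([fam], self._bg(), decoy_length=10_000, seed=1)
        assert len(bset.truth) == 1
        inst = bset.truth[0]
        rec = {r.id: r for r in bset.decoy_db}[inst.target_id]
        assert 0 <= inst.start < inst.end <= len(rec)
        assert inst.end - inst.start == 100
        emb = rec.residues[inst.start:inst.end]
        assert emb in ("A" * 100, "C" * 100, "G" * 100, "T" * 100)

    def test_emitted_length_and_disjoint_strand_balance(self):
        rng = np.random.default_rng(0)
        fams = []
        while len(fams) < 10:
            f = simulate_family(FamilyParams(), rng)
            if split_family(f).ok:
                fams.append(f)
        bset = generate_benchmark(fams, self._bg(), decoy_length=200_000, seed=5)
        total_test = sum(i.length for i in bset.truth)
        assert sum(len(r) for r in bset.decoy_db) == 200_000 + total_test
        # disjoint per target
        by_t = {}
        for i in bset.truth:
            by_t.setdefault(i.target_id, []).append((i.start, i.end))
        for ivs in by_t.values():
            ivs.sort()
            assert all(a1 <= b0 for (_, a1), (b0, _) in zip(ivs, ivs[1:]))
        # strand balance, binomial 3 sigma
        n = len(bset.truth)
        frac = sum(1 for i in bset.truth if i.strand == "+") / n
        assert abs(frac - 0.5) <= 3 * 0.5 / math.sqrt(n)

    def test_too_small_decoy_rejected(self):
        fam = msa("A" * 400, "C" * 400)
        with pytest.raises(ValueError, match="decoy_length"):
            generate_benchmark([fam], self._bg(), decoy_length=500, seed=0)


class TestSanityCeiling:
    def test_query_member_planted_is_recovered_strongly(self):
        """A planted instance identical to a query-side member must be
        found by the family profile at E <= 1e-3."""
        from profscan import pipeline, profile as prof, stats

        rng = np.random.default_rng(17)
        sr = None
        while sr is None or not sr.ok:
            fam = simulate_family(FamilyParams(), rng)
            sr = split_family(fam)
        sp = prof.configure_local(bm.prof.build_profile(sr.query_msa, name="f"))
        stats.calibrate(sp, n=100, L=2000, seed=1)
        member = sr.query_msa.degapped()[0].residues
        bg = "".join(rng.choice(list("ACGT"), size=50_000))
        target = SequenceRecord(id="t", residues=bg[:25_000] + member + bg[25_000:])
        hits = pipeline.search_one(sp, [target])
        assert hits and hits[0].evalue <= 1e-3
        assert hits[0].ali_start < 25_000 + len(member) and hits[0].ali_end > 25_000


class TestFpwMerge:
    def test_overlapping_keep_best_evalue(self):
        a = make_hit(start=0, end=100, evalue=1e-5)
        b = make_hit(start=50, end=150, evalue=1e-3)
        merged = fpw_merge([[a], [b]])
        assert merged == [a]

    def test_disjoint_both_kept(self):
        a = make_hit(start=0, end=100)
        b = make_hit(start=200, end=300)
        assert len(fpw_merge([[a], [b]])) == 2

    def test_three_mutually_overlapping_one_survivor(self):
        a = make_hit(start=0, end=100, evalue=1e-2)
        b = make_hit(start=50, end=150, evalue=1e-6)
        c = make_hit(start=90, end=200, evalue=1e-4)
        merged = fpw_merge([[a], [b], [c]])
        assert merged == [b]

    def test_chained_overlap_is_transitive(self):
        # a-b overlap, b-c overlap, a-c do not: still one survivor
        a = make_hit(start=0, end=100, evalue=1e-2)
        b = make_hit(start=90, end=210, evalue=1e-3)
        c = make_hit(start=200, end=300, evalue=1e-4)
        merged = fpw_merge([[a, c], [b]])
        assert merged == [c]

    def test_strands_do_not_merge(self):
        a = make_hit(start=0, end=100, strand="+")
        b = make_hit(start=0, end=100, strand="-")
        assert len(fpw_merge([[a], [b]])) == 2


class TestClassification:
    TRUTH = [Instance(family="famA", target_id="t", start=1000, end=1200, strand="+")]

    def test_majority_coverage_detects(self):
        h = make_hit(start=1099, end=1300)   # covers 101 of 200
        lab = classify_hits([("famA", h)], self.TRUTH)[0]
        assert lab.label == "true" and lab.detected == [0]

    def test_exact_half_coverage_does_not_detect(self):
        h = make_hit(start=1100, end=1200)   # exactly 50%: strict >
        lab = classify_hits([("famA", h)], self.TRUTH)[0]
        assert lab.detected == []

    def test_hit_mostly_in_decoy_is_false(self):
        h = make_hit(start=1150, end=1400)   # 50/250 in instance, 80% decoy
        lab = classify_hits([("famA", h)], self.TRUTH)[0]
        assert lab.label == "false"

    def test_wrong_family_hit_is_ignored(self):
        h = make_hit(start=1000, end=1200)
        lab = classify_hits([("famB", h)], self.TRUTH)[0]
        assert lab.label == "ignored"


class TestRoc:
    def test_all_true_single_point(self):
        truth = [Instance("f", "t", 0, 100, "+"), Instance("f", "t", 500, 600, "+")]
        hits = [("f", make_hit(start=0, end=100, evalue=1e-6))]
        pts = roc_curve(classify_hits(hits, truth), 2, decoy_mb=1.0, n_searches=1)
        assert pts[-1].fp_per_mb_per_search == 0.0
        assert pts[-1].sensitivity == 0.5

    def test_hand_enumerated_sweep(self):
        truth = [Instance("f", "t", 0, 100, "+"), Instance("f", "t", 500, 600, "+")]
        hits = [
            ("f", make_hit(start=0, end=100, evalue=1e-6)),       # T
            ("f", make_hit(start=5000, end=5100, evalue=1e-4)),   # F (decoy)
            ("f", make_hit(start=500, end=600, evalue=1e-2)),     # T
        ]
        pts = roc_curve(classify_hits(hits, truth), 2, decoy_mb=1.0, n_searches=1)
        coords = [(p.fp_per_mb_per_search, p.sensitivity) for p in pts]
        assert coords == [(0.0, 0.5), (1.0, 0.5), (1.0, 1.0)]

    def test_sensitivity_monotone_along_sweep(self, rng):
        truth = [Instance("f", "t", i * 1000, i * 1000 + 100, "+") for i in range(5)]
        hits = []
        for i in range(30):
            s = int(rng.integers(0, 20000))
            hits.append(("f", make_hit(start=s, end=s + 120,
                                       evalue=float(rng.random()))))
        pts = roc_curve(classify_hits(hits, truth), 5, 1.0, 1)
        sens = [p.sensitivity for p in pts]
        assert sens == sorted(sens)

    def test_sensitivity_at_uses_largest_reached_rate(self):
        pts = [bm.RocPoint(0.0, 0.2), bm.RocPoint(0.05, 0.4), bm.RocPoint(0.5, 0.9)]
        assert sensitivity_at(pts, 0.1) == 0.4
        assert sensitivity_at(pts, 1.0) == 0.9
        assert sensitivity_at([], 0.1) == 0.0
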