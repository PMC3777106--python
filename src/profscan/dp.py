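"""Log-space dynamic programming kernels for profile-HMM local search.

This module holds the *reference* implementations: SSV ungapped diagonal
scan, gapped Viterbi with traceback, Forward, Backward, posterior
decoding, and a brute-force path-enumeration oracle for small problems.
Throughput-critical batch variants (compiled with numba) live in
:mod:`profscan._kernels`; they compute the same quantities and are
cross-checked against this module in the test suite.

Scores are reported in bits (log2 odds against the null model).  The
recursions run in natural-log space with an explicit -inf sentinel;
log-sum-exp uses numpy's ``logaddexp``.

Model topology (uni-hit local):

    S -> N(loop, emits null) -> B -> {M_k entry | E} -> core -> E
      -> C(loop, emits null) -> T

The flanking states N and C emit with null1 (log-odds 0 per residue) and
loop with probability L/(L+2); the null model extends with probability
L/(L+1).  From B the core is entered with probability ``p_core`` (entry
distributed over match states by the uniform-fragment rule) and E is
reached directly with 1 - p_core, which is the "no alignment" path: the
Forward score therefore sums over all alignments *including* the empty
one, and has a floor near the empty-path odds.  Exit from M_k to E has
probability q_k = 1/(M-k+1); the last delete state exits to E freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .profile import SearchProfile, T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD
from .seqio import SequenceRecord, encode

LN2 = math.log(2.0)
NEG_INF = -np.inf

#: targets longer than this must go through the windowed pipeline
WINDOW_CAP = 60_000


@dataclass
class DiagonalHit:
    """Best single ungapped segment on one diagonal (SSV seed).

    Coordinates are 0-based half-open on the scanned sequence;
    ``model_start`` is the 0-based node index aligned to
    ``target_start``.  The score is the plain sum of match log-odds
    (bits) along the segment; no transition terms are included.
    """

    target_start: int
    target_end: int
    model_start: int
    score: float


class CoreTables:
    """Natural-log parameter tables for the DP recursions."""

    def __init__(self, sp: SearchProfile):
        hmm = sp.hmm
        M = hmm.M
        q = sp.exit_q
        t = hmm.transitions
        with np.errstate(divide="ignore"):
            self.msc = np.array(sp._msc16, dtype=float)           # (M,16) nats
            one_minus_q = np.where(q < 1.0, 1.0 - q, 0.0)
            self.ln_tmm = np.log(one_minus_q * t[:, T_MM])
            self.ln_tmi = np.log(one_minus_q * t[:, T_MI])
            self.ln_tmd = np.log(one_minus_q * t[:, T_MD])
            self.ln_tim = np.log(t[:, T_IM])
            self.ln_tii = np.log(t[:, T_II])
            self.ln_tdm = np.log(t[:, T_DM])
            self.ln_tdd = np.log(t[:, T_DD])
            self.ln_entry = np.log(sp.p_core * sp.entry)
            self.ln_exit = np.log(q)
            self.ln_be = math.log(1.0 - sp.p_core)
        # transitions out of the last node lead nowhere
        self.ln_tmm[M - 1] = self.ln_tmi[M - 1] = self.ln_tmd[M - 1] = NEG_INF
        self.ln_tim[M - 1] = self.ln_tii[M - 1] = NEG_INF
        self.ln_tdm[M - 1] = self.ln_tdd[M - 1] = NEG_INF
        # cumulative DD costs for the in-row delete chain trick
        self.cum_tdd = np.concatenate([[0.0], np.cumsum(self.ln_tdd[:-1])])
        self.M = M

    _cache_key = None


def core_tables(sp: SearchProfile) -> CoreTables:
    tbl = getattr(sp, "_core_tables", None)
    if tbl is None:
        tbl = CoreTables(sp)
        sp._core_tables = tbl
    return tbl


def flank_params(L: int) -> tuple[float, float, float]:
    """(ln t_NN == ln t_CC, ln t_NB == ln t_CT, ln P_null_transitions).

    The flank self-loop probability is set equal to the null model's
    extension probability L/(L+1), so every flank-emitted residue is
    exactly score-neutral and a model with null emissions can never
    accumulate positive evidence from the length model alone; the only
    model-vs-null cost is the begin/end bookkeeping, about
    -(log2 L + 1) bits for the empty alignment.
    """
    ln_loop = math.log(L / (L + 1.0)) if L > 0 else NEG_INF
    ln_move = math.log(1.0 / (L + 1.0))
    ln_null = L * math.log(L / (L + 1.0)) + math.log(1.0 / (L + 1.0)) if L > 0 else 0.0
    return ln_loop, ln_move, ln_null


def _check_len(seq_len: int) -> None:
    if seq_len > WINDOW_CAP:
        raise ValueError(
            f"target of length {seq_len} exceeds the DP window cap "
            f"({WINDOW_CAP}); run it through the windowed pipeline instead"
        )


def _codes(seq) -> np.ndarray:
    if isinstance(seq, SequenceRecord):
        return seq.encoded()
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


def _lse_accumulate(v: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        out = np.logaddexp.accumulate(v)
    # accumulate over leading -inf is fine; NaN can only arise from inf - inf
    return np.where(np.isnan(out), NEG_INF, out)


# ------------------------------------------------------------------- Forward

def forward_matrix(sp: SearchProfile, seq) -> dict:
    """Fill the Forward matrix; returns all state rows plus the total.

    Rows are indexed 0..L (row i = after emitting residue i).  All values
    are ln odds relative to null1 emissions; the reported score subtracts
    the null model's transition term.
    """
    x = _codes(seq)
    L = len(x)
    _check_len(L)
    t = core_tables(sp)
    M = t.M
    ln_loop, ln_move, ln_null = flank_params(L)

    fM = np.full((L + 1, M), NEG_INF)
    fI = np.full((L + 1, M), NEG_INF)
    fD = np.full((L + 1, M), NEG_INF)
    fN = np.full(L + 1, NEG_INF)
    fB = np.full(L + 1, NEG_INF)
    fE = np.full(L + 1, NEG_INF)
    fC = np.full(L + 1, NEG_INF)

    fN[0] = 0.0
    fB[0] = ln_move
    fE[0] = fB[0] + t.ln_be
    fC[0] = fE[0]

    for i in range(1, L + 1):
        xc = int(x[i - 1])
        em = t.msc[:, xc]
        prevM, prevI, prevD = fM[i - 1], fI[i - 1], fD[i - 1]
        # match
        fromM = np.concatenate([[NEG_INF], prevM[:-1] + t.ln_tmm[:-1]])
        fromI = np.concatenate([[NEG_INF], prevI[:-1] + t.ln_tim[:-1]])
        fromD = np.concatenate([[NEG_INF], prevD[:-1] + t.ln_tdm[:-1]])
        fromB = fB[i - 1] + t.ln_entry
        m = em + np.logaddexp(np.logaddexp(fromM, fromI), np.logaddexp(fromD, fromB))
        fM[i] = m
        # insert (emission log-odds 0; degenerate codes also 0)
        fI[i] = np.logaddexp(prevM + t.ln_tmi, prevI + t.ln_tii)
        # delete chain within the row
        a = np.concatenate([[NEG_INF], m[:-1] + t.ln_tmd[:-1]])
        fD[i] = t.cum_tdd + _lse_accumulate(a - t.cum_tdd)
        # specials
        fN[i] = fN[i - 1] + ln_loop
        fB[i] = fN[i] + ln_move
        e = _lse_reduce(m + t.ln_exit)
        e = np.logaddexp(e, fD[i, M - 1])
        e = np.logaddexp(e, fB[i] + t.ln_be)
        fE[i] = e
        fC[i] = np.logaddexp(fC[i - 1] + ln_loop, fE[i])

    total_core = fC[L] + ln_move
    return {
        "M": fM, "I": fI, "D": fD, "N": fN, "B": fB, "E": fE, "C": fC,
        "total_core": total_core, "ln_null": ln_null,
        "score_bits": (total_core - ln_null) / LN2,
        "L": L, "x": x,
    }


def _lse_reduce(v: np.ndarray) -> float:
    m = np.max(v)
    if m == NEG_INF:
        return NEG_INF
    return float(m + np.log(np.sum(np.exp(v - m))))


def forward(sp: SearchProfile, seq) -> float:
    """Forward bit score: log2 odds summed over all paths vs null1."""
    return float(forward_matrix(sp, seq)["score_bits"])


# ------------------------------------------------------------------ Backward

def backward_matrix(sp: SearchProfile, seq) -> dict:
    """Backward matrix: value at (state, i) = ln odds of completing the
    path after having emitted i residues in that state."""
    x = _codes(seq)
    L = len(x)
    _check_len(L)
    t = core_tables(sp)
    M = t.M
    ln_loop, ln_move, ln_null = flank_params(L)

    bM = np.full((L + 1, M), NEG_INF)
    bI = np.full((L + 1, M), NEG_INF)
    bD = np.full((L + 1, M), NEG_INF)
    bN = np.full(L + 1, NEG_INF)
    bB = np.full(L + 1, NEG_INF)
    bE = np.full(L + 1, NEG_INF)
    bC = np.full(L + 1, NEG_INF)

    bC[L] = ln_move                      # C -> T
    bE[L] = bC[L]
    bM[L] = t.ln_exit + bE[L]
    # delete chain at the boundary row: only egress is down to D_M -> E
    dlast = bE[L]
    bD[L, M - 1] = dlast
    for k in range(M - 2, -1, -1):
        bD[L, k] = t.ln_tdd[k] + bD[L, k + 1]
        bM[L, k] = np.logaddexp(bM[L, k], t.ln_tmd[k] + bD[L, k + 1])
    bB[L] = t.ln_be + bE[L]
    bN[L] = ln_move + bB[L]

    for i in range(L - 1, -1, -1):
        xc = int(x[i])                    # residue i+1 (0-based x[i])
        em_next = t.msc[:, xc]
        nextM = bM[i + 1]
        bC[i] = ln_loop + bC[i + 1]
        bE[i] = bC[i]
        # core rows
        up = np.concatenate([em_next[1:] + nextM[1:], [NEG_INF]])  # to M_{k+1}
        m = np.logaddexp(t.ln_tmm + up, t.ln_tmi + bI[i + 1])
        # reverse delete chain: bD[k] = LSE_{j>=k} a2[j] + sum(tdd[k..j-1]),
        # with a2[j] the direct D_j egress (to M_{j+1}, or E at the last node);
        # up[k] already includes the emission of x_{i+1} at node k+1
        a2 = np.concatenate([t.ln_tdm[:-1] + up[:-1], [bE[i]]])
        bD_row = _lse_accumulate((a2 + t.cum_tdd)[::-1])[::-1] - t.cum_tdd
        m = np.logaddexp(m, t.ln_exit + bE[i])
        dshift = np.concatenate([bD_row[1:], [NEG_INF]])
        m = np.logaddexp(m, t.ln_tmd + dshift)
        bM[i] = m
        bI[i] = np.logaddexp(t.ln_tim + up, t.ln_tii + bI[i + 1])
        bD[i] = bD_row
        bB[i] = np.logaddexp(
            _lse_reduce(t.ln_entry + em_next + nextM), t.ln_be + bE[i]
        )
        bN[i] = np.logaddexp(ln_loop + bN[i + 1], ln_move + bB[i])

    total_core = bN[0]
    return {
        "M": bM, "I": bI, "D": bD, "N": bN, "B": bB, "E": bE, "C": bC,
        "total_core": total_core, "ln_null": ln_null,
        "score_bits": (total_core - ln_null) / LN2,
        "L": L, "x": x,
    }


def backward(sp: SearchProfile, seq) -> float:
    return float(backward_matrix(sp, seq)["score_bits"])


# ----------------------------------------------------------------- posterior

@dataclass
class Posterior:
    """Per-position state posteriors: P(state emitted x_i | sequence)."""

    match: np.ndarray    # (L, M)
    insert: np.ndarray   # (L, M)
    flank: np.ndarray    # (L,) N or C emitted the residue

    @property
    def aligned(self) -> np.ndarray:
        """P(residue i is emitted by the core model) per position."""
        return self.match.sum(axis=1) + self.insert.sum(axis=1)


def posterior_decode(sp: SearchProfile, seq, fwd: dict, bwd: dict) -> Posterior:
    """Combine Forward and Backward matrices into emission posteriors."""
    x = _codes(seq)
    L = len(x)
    if fwd["L"] != L or bwd["L"] != L or fwd["M"].shape != bwd["M"].shape:
        raise ValueError("forward/backward matrices do not match this sequence")
    total = fwd["total_core"]
    ln_loop, _, _ = flank_params(L)
    pm = np.exp(fwd["M"][1:] + bwd["M"][1:] - total)
    pi = np.exp(fwd["I"][1:] + bwd["I"][1:] - total)
    # N's only inbound edge is its own (emitting) loop, so F_N(i) already
    # means "N emitted x_i"; C additionally collects E->C entries that emit
    # nothing, so the emitting component is the loop term alone.
    pn = np.exp(fwd["N"][1:] + bwd["N"][1:] - total)
    pc = np.exp(fwd["C"][:-1] + ln_loop + bwd["C"][1:] - total)
    return Posterior(match=pm, insert=pi, flank=pn + pc)


# ------------------------------------------------------------------- Viterbi

def viterbi(sp: SearchProfile, seq) -> tuple[float, list]:
    """Best single alignment path: (bit score, state path).

    Viterbi maximizes over paths that pass through the core model (at
    least one match emission); the empty B->E path is excluded, since
    including it would floor every null score at the same constant and
    make extreme-value calibration degenerate.  (Forward, by contrast,
    sums over all paths including the empty one.)  If no core path
    exists — an empty target — the empty-alignment score is returned.

    The path lists the core visit as ``("B", i)``, then
    ``(state, node_1based, i)`` entries with ``i`` the 1-based target
    position of the emission (for D, the position before which the node
    is skipped), then ``("E", i)``.  Flanking N/C emissions are omitted.
    """
    x = _codes(seq)
    L = len(x)
    _check_len(L)
    t = core_tables(sp)
    M = t.M
    ln_loop, ln_move, ln_null = flank_params(L)

    vM = np.full(M, NEG_INF)
    vI = np.full(M, NEG_INF)
    vD = np.full(M, NEG_INF)
    vN = 0.0
    vB = ln_move
    vC = NEG_INF

    ptrM = np.zeros((L + 1, M), dtype=np.int8)
    ptrI = np.zeros((L + 1, M), dtype=np.int8)
    ptrD = np.zeros((L + 1, M), dtype=np.int8)
    eptr = np.full(L + 1, M, dtype=np.int32)       # M -> D_last exit
    cptr = np.zeros(L + 1, dtype=np.int8)          # 1 = from E at this row

    idx = np.arange(M)
    for i in range(1, L + 1):
        xc = int(x[i - 1])
        em = t.msc[:, xc]
        cand = np.stack([
            np.concatenate([[NEG_INF], vM[:-1] + t.ln_tmm[:-1]]),
            np.concatenate([[NEG_INF], vI[:-1] + t.ln_tim[:-1]]),
            np.concatenate([[NEG_INF], vD[:-1] + t.ln_tdm[:-1]]),
            vB + t.ln_entry,
        ])
        ptrM[i] = np.argmax(cand, axis=0)
        m = em + cand[ptrM[i], idx]
        candI = np.stack([vM + t.ln_tmi, vI + t.ln_tii])
        ptrI[i] = np.argmax(candI, axis=0)
        nI = candI[ptrI[i], idx]
        # delete chain: best over j<k of (M_j -> D_{j+1} -> ... -> D_k)
        a = np.concatenate([[NEG_INF], m[:-1] + t.ln_tmd[:-1]])
        v = a - t.cum_tdd
        run = np.maximum.accumulate(v)
        arg = np.maximum.accumulate(np.where(v >= run, idx, -1))
        nD = t.cum_tdd + run
        ptrD[i] = np.where(arg == idx, 0, 1)   # 0: direct from M_{k-1}; 1: from D_{k-1}
        vM, vI, vD = m, nI, nD
        vN = vN + ln_loop
        vB = vN + ln_move
        exits = vM + t.ln_exit
        best_k = int(np.argmax(exits))
        e, ek = exits[best_k], best_k
        if vD[M - 1] > e:
            e, ek = vD[M - 1], M
        eptr[i] = ek
        if e >= vC + ln_loop:
            vC, cptr[i] = e, 1
        else:
            vC = vC + ln_loop

    if vC == NEG_INF:   # no core path (e.g. empty target): empty alignment
        score = (L * ln_loop + 2 * ln_move + t.ln_be - ln_null) / LN2 \
            if L > 0 else (2 * ln_move + t.ln_be - ln_null) / LN2
        return float(score), [("B", L), ("E", L)]

    score = (vC + ln_move - ln_null) / LN2

    # traceback
    i = L
    while i > 0 and cptr[i] == 0:
        i -= 1
    ek = int(eptr[i])
    path: list = [("E", i)]
    if True:
        # re-run the rows up to i to recover the vectors is unnecessary:
        # pointers alone determine the path.
        if ek == M:
            k = M - 1
            state = "D"
        else:
            k = ek
            state = "M"
        while True:
            if state == "M":
                path.append(("M", k + 1, i))
                p = ptrM[i][k]
                i -= 1
                if p == 3:
                    path.append(("B", i))
                    break
                k -= 1
                state = {0: "M", 1: "I", 2: "D"}[int(p)]
            elif state == "I":
                path.append(("I", k + 1, i))
                p = ptrI[i][k]
                i -= 1
                state = "M" if p == 0 else "I"
            else:  # D, consumes no residue
                path.append(("D", k + 1, i))
                p = ptrD[i][k]
                k -= 1
                state = "M" if p == 0 else "D"
    path.reverse()
    return float(score), path


def viterbi_score(sp: SearchProfile, seq) -> float:
    return viterbi(sp, seq)[0]


# ----------------------------------------------------------------------- SSV

def ssv_scan(sp: SearchProfile, seq, min_score: float, fast: bool = False) -> list[DiagonalHit]:
    """Single-segment ungapped Viterbi scan.

    For every diagonal, finds the maximal-scoring contiguous run of
    match log-odds cells (length <= M by construction) and returns the
    per-diagonal best segments scoring >= ``min_score`` bits.  With
    ``fast=True`` the scan runs in single precision (the pipeline's
    seeding mode); the default is double precision.
    """
    from . import _kernels

    x = _codes(seq)
    L = len(x)
    if L == 0:
        return []
    t = core_tables(sp)
    if fast:
        lod_bits = _kernels.ssv_pack(sp)
    else:
        lod_bits = np.maximum(t.msc / LN2, -1e30)
    dis, score, bst, ben = _kernels.ssv_diagonals(lod_bits, x, min_score)
    M = t.M
    hits = []
    for j, di in enumerate(dis):
        d = int(di) - (M - 1)
        s, e = int(bst[j]), int(ben[j])
        hits.append(DiagonalHit(
            target_start=s, target_end=e, model_start=s - d, score=float(score[j]),
        ))
    hits.sort(key=lambda h: (-h.score, h.target_start))
    return hits


# -------------------------------------------------------------------- oracle

@dataclass
class PathEnumeration:
    total_bits: float
    best_bits: float        # max over all paths (incl. the empty alignment)
    best_path: list
    best_core_bits: float   # max over paths with >= 1 match emission (= Viterbi)
    best_core_path: list
    paths: list             # list of (bits, path)


def enumerate_paths(sp: SearchProfile, seq) -> PathEnumeration:
    """Explicit recursion over every legal state path (test oracle).

    Guarded to M <= 6 and L <= 8.  Returns exact log-sum and max over
    path odds, matching :func:`forward` and :func:`viterbi`.
    """
    x = _codes(seq)
    L = len(x)
    t = core_tables(sp)
    M = t.M
    if M > 6 or L > 8:
        raise ValueError("enumerate_paths is limited to M <= 6 and L <= 8")
    ln_loop, ln_move, ln_null = flank_params(L)
    results: list[tuple[float, list]] = []

    def fin(i: int, s: float, path: list) -> None:
        # in C having emitted i residues; all L residues must be out before T
        if i < L:
            if ln_loop > NEG_INF:
                fin(i + 1, s + ln_loop, path + [("C", i + 1)])
        else:
            results.append((s + ln_move - ln_null, path))

    def from_E(i: int, s: float, path: list) -> None:
        fin(i, s, path + [("E", i)])

    def go(fn, k, i, s, path) -> None:
        if s > NEG_INF:
            fn(k, i, s, path)

    def from_M(k: int, i: int, s: float, path: list) -> None:
        if t.ln_exit[k] > NEG_INF:
            from_E(i, s + t.ln_exit[k], path)
        if i < L and k + 1 < M:
            go(from_M, k + 1, i + 1, s + t.ln_tmm[k] + t.msc[k + 1, x[i]],
               path + [("M", k + 2, i + 1)])
        if i < L and t.ln_tmi[k] > NEG_INF:
            from_I(k, i + 1, s + t.ln_tmi[k], path + [("I", k + 1, i + 1)])
        if k + 1 < M:
            go(from_D, k + 1, i, s + t.ln_tmd[k], path + [("D", k + 2, i)])

    def from_I(k: int, i: int, s: float, path: list) -> None:
        if i < L and k + 1 < M:
            go(from_M, k + 1, i + 1, s + t.ln_tim[k] + t.msc[k + 1, x[i]],
               path + [("M", k + 2, i + 1)])
        if i < L and t.ln_tii[k] > NEG_INF:
            from_I(k, i + 1, s + t.ln_tii[k], path + [("I", k + 1, i + 1)])

    def from_D(k: int, i: int, s: float, path: list) -> None:
        if k == M - 1:
            from_E(i, s, path)
            return
        if i < L:
            go(from_M, k + 1, i + 1, s + t.ln_tdm[k] + t.msc[k + 1, x[i]],
               path + [("M", k + 2, i + 1)])
        go(from_D, k + 1, i, s + t.ln_tdd[k], path + [("D", k + 2, i)])

    def from_B(i: int, s: float, path: list) -> None:
        from_E(i, s + t.ln_be, path + [("B", i)])
        if i < L:
            for k in range(M):
                go(from_M, k, i + 1, s + t.ln_entry[k] + t.msc[k, x[i]],
                   path + [("B", i), ("M", k + 1, i + 1)])

    def from_N(i: int, s: float, path: list) -> None:
        if i < L and ln_loop > NEG_INF:
            from_N(i + 1, s + ln_loop, path + [("N", i + 1)])
        from_B(i, s + ln_move, path)

    from_N(0, 0.0, [])

    scores = np.array([s for s, _ in results])
    total = _lse_reduce(scores) / LN2
    bi = int(np.argmax(scores))
    core = [(s, p) for s, p in results if any(el[0] == "M" for el in p)]
    if core:
        cs, cp = max(core, key=lambda sp_: sp_[0])
    else:
        cs, cp = results[bi]
    return PathEnumeration(
        total_bits=float(total),
        best_bits=float(scores[bi] / LN2),
        best_path=results[bi][1],
        best_core_bits=float(cs / LN2),
        best_core_path=cp,
        paths=[(s / LN2, p) for s, p in results],
    )
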