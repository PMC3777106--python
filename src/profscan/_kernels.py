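"""Compiled scoring kernels (numba) for the throughput-critical paths.

These compute the same quantities as the reference implementations in
:mod:`profscan.dp` — SSV diagonal scan, Viterbi score, Forward score —
but as tight scalar loops over encoded sequences, suitable for scanning
megabase targets and for calibration batches.  The Forward kernel works
in scaled linear space (per-row renormalization with an accumulated log
scale) to avoid transcendental calls per cell.  Agreement with the
log-space reference implementations is asserted in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .dp import LN2, core_tables

_NEG = -1.0e300
_NEG32 = np.float32(-1.0e30)


# -------------------------------------------------------------- profile packs

def log_pack(sp):
    """Natural-log parameter tuple for the Viterbi kernel (cached)."""
    pack = getattr(sp, "_log_pack", None)
    if pack is None:
        t = core_tables(sp)
        clip = lambda a: np.maximum(a, _NEG)
        pack = (
            clip(t.msc), clip(t.ln_tmm), clip(t.ln_tmi), clip(t.ln_tmd),
            clip(t.ln_tim), clip(t.ln_tii), clip(t.ln_tdm), clip(t.ln_tdd),
            clip(t.ln_entry), clip(t.ln_exit), max(t.ln_be, _NEG),
        )
        sp._log_pack = pack
    return pack


def lin_pack(sp):
    """Linear-odds parameter tuple for the scaled Forward kernel (cached)."""
    pack = getattr(sp, "_lin_pack", None)
    if pack is None:
        t = core_tables(sp)
        e = lambda a: np.exp(a)
        pack = (
            e(t.msc), e(t.ln_tmm), e(t.ln_tmi), e(t.ln_tmd),
            e(t.ln_tim), e(t.ln_tii), e(t.ln_tdm), e(t.ln_tdd),
            e(t.ln_entry), e(t.ln_exit), math.exp(t.ln_be),
        )
        sp._lin_pack = pack
    return pack


def ssv_pack(sp):
    """Match log-odds in bits, float32, for the SSV kernels (cached)."""
    pack = getattr(sp, "_ssv_pack", None)
    if pack is None:
        t = core_tables(sp)
        pack = np.maximum(t.msc / LN2, _NEG32).astype(np.float32)
        sp._ssv_pack = pack
    return pack


# ----------------------------------------------------------------------- SSV

@njit(cache=True)
def _ssv_best(lod, x):
    """Best Kadane segment score per diagonal (no coordinates).

    Bulk diagonals (full k range) are processed four at a time so the
    four independent Kadane recurrences pipeline; edge diagonals use a
    plain scalar loop.
    """
    M = lod.shape[0]
    L = x.shape[0]
    nd = L + M - 1
    zero = lod.dtype.type(0.0)
    neg = lod.dtype.type(_NEG32)
    best = np.full(nd, neg, dtype=lod.dtype)
    n_full = L - M + 1 if L >= M else 0   # diagonals with the full k range
    nbulk = (n_full // 4) * 4
    # edge + remainder diagonals, scalar
    for d in range(-(M - 1), L):
        if 0 <= d < nbulk:
            continue
        kmin = -d if d < 0 else 0
        kmax = M if L - d > M else L - d
        r = zero
        bb = neg
        i = d + kmin
        for k in range(kmin, kmax):
            s = lod[k, x[i]]
            r = s if r <= 0.0 else r + s
            if r > bb:
                bb = r
            i += 1
        best[d + M - 1] = bb
    # bulk diagonals, 4-way interleaved
    d = 0
    while d < nbulk:
        r0 = zero; r1 = zero; r2 = zero; r3 = zero
        b0 = neg; b1 = neg; b2 = neg; b3 = neg
        for k in range(M):
            i = d + k
            v0 = lod[k, x[i]]
            v1 = lod[k, x[i + 1]]
            v2 = lod[k, x[i + 2]]
            v3 = lod[k, x[i + 3]]
            r0 = v0 if r0 <= 0.0 else r0 + v0
            r1 = v1 if r1 <= 0.0 else r1 + v1
            r2 = v2 if r2 <= 0.0 else r2 + v2
            r3 = v3 if r3 <= 0.0 else r3 + v3
            if r0 > b0:
                b0 = r0
            if r1 > b1:
                b1 = r1
            if r2 > b2:
                b2 = r2
            if r3 > b3:
                b3 = r3
        di = d + M - 1
        best[di] = b0
        best[di + 1] = b1
        best[di + 2] = b2
        best[di + 3] = b3
        d += 4
    return best


@njit(cache=True)
def _ssv_extract(lod, x, dis):
    """Re-run Kadane with coordinate tracking on selected diagonals."""
    M = lod.shape[0]
    L = x.shape[0]
    n = dis.shape[0]
    zero = lod.dtype.type(0.0)
    neg = lod.dtype.type(_NEG32)
    score = np.empty(n, dtype=np.float64)
    bst = np.zeros(n, dtype=np.int64)
    ben = np.zeros(n, dtype=np.int64)
    for j in range(n):
        d = dis[j] - (M - 1)
        kmin = -d if d < 0 else 0
        kmax = M if L - d > M else L - d
        r = zero
        rs = 0
        bb = neg
        bs = 0
        be = 0
        i = d + kmin
        for k in range(kmin, kmax):
            s = lod[k, x[i]]
            if r <= 0.0:
                r = s
                rs = i
            else:
                r = r + s
            if r > bb:
                bb = r
                bs = rs
                be = i + 1
            i += 1
        score[j] = bb
        bst[j] = bs
        ben[j] = be
    return score, bst, ben


def ssv_diagonals(lod_bits: np.ndarray, x: np.ndarray, min_score: float = -1e29):
    """Best ungapped segment per diagonal scoring >= min_score.

    Returns (diagonal_index, score, start, end) arrays; the diagonal
    index is ``d + M - 1``.
    """
    lod = np.ascontiguousarray(lod_bits)
    x = np.ascontiguousarray(x, dtype=np.uint8)
    best = _ssv_best(lod, x)
    dis = np.flatnonzero(best >= min_score)
    score, bst, ben = _ssv_extract(lod, x, dis)
    return dis, score, bst, ben


@njit(cache=True)
def _ssv_best_scores(lod, X):
    n, L = X.shape
    M = lod.shape[0]
    out = np.empty(n, dtype=np.float64)
    for t in range(n):
        bb = _NEG32
        for d in range(-(M - 1), L):
            kmin = -d if d < 0 else 0
            kmax = M if L - d > M else L - d
            r = np.float32(0.0)
            for k in range(kmin, kmax):
                s = lod[k, X[t, d + k]]
                if r <= 0.0:
                    r = s
                else:
                    r = r + s
                if r > bb:
                    bb = r
        out[t] = bb
    return out


def ssv_best_scores(sp, X: np.ndarray) -> np.ndarray:
    """Best single ungapped segment score (bits) per target in the batch."""
    return _ssv_best_scores(ssv_pack(sp), np.ascontiguousarray(X, dtype=np.uint8))


# ------------------------------------------------------------------- Viterbi

@njit(cache=True)
def _viterbi_scores(msc, tmm, tmi, tmd, tim, tii, tdm, tdd, entry, exitq, ln_be, X):
    n, L = X.shape
    M = msc.shape[0]
    out = np.empty(n, dtype=np.float64)
    ln_loop = math.log(L / (L + 1.0)) if L > 0 else _NEG
    ln_move = math.log(1.0 / (L + 1.0))
    ln_null = L * math.log(L / (L + 1.0)) if L > 0 else 0.0
    ln_null += math.log(1.0 / (L + 1.0))
    vm = np.empty(M)
    vi = np.empty(M)
    vd = np.empty(M)
    nm = np.empty(M)
    ni = np.empty(M)
    nd_ = np.empty(M)
    for t in range(n):
        for k in range(M):
            vm[k] = _NEG
            vi[k] = _NEG
            vd[k] = _NEG
        vN = 0.0
        vB = ln_move
        vC = _NEG           # empty B->E path excluded from Viterbi
        for i in range(L):
            c = X[t, i]
            for k in range(M):
                best = vB + entry[k]
                if k > 0:
                    v = vm[k - 1] + tmm[k - 1]
                    if v > best:
                        best = v
                    v = vi[k - 1] + tim[k - 1]
                    if v > best:
                        best = v
                    v = vd[k - 1] + tdm[k - 1]
                    if v > best:
                        best = v
                nm[k] = msc[k, c] + best
                a = vm[k] + tmi[k]
                b = vi[k] + tii[k]
                ni[k] = a if a > b else b
            nd_[0] = _NEG
            for k in range(1, M):
                a = nm[k - 1] + tmd[k - 1]
                b = nd_[k - 1] + tdd[k - 1]
                nd_[k] = a if a > b else b
            vN = vN + ln_loop
            vB = vN + ln_move
            e = nd_[M - 1]
            for k in range(M):
                v = nm[k] + exitq[k]
                if v > e:
                    e = v
            c2 = vC + ln_loop
            vC = e if e > c2 else c2
            tmp = vm; vm = nm; nm = tmp
            tmp = vi; vi = ni; ni = tmp
            tmp = vd; vd = nd_; nd_ = tmp
        if vC <= _NEG:     # no core path: fall back to the empty alignment
            vC = L * ln_loop + ln_move + ln_be
        out[t] = (vC + ln_move - ln_null) / LN2
    return out


@njit(cache=True)
def _viterbi_scores_batch(msc, tmm, tmi, tmd, tim, tii, tdm, tdd, entry, exitq,
                          ln_be, XT):
    """Transposed-layout Viterbi batch: state arrays are (M, n) so the
    innermost loop runs over independent targets and vectorizes."""
    L, n = XT.shape
    M = msc.shape[0]
    ln_loop = math.log(L / (L + 1.0)) if L > 0 else _NEG
    ln_move = math.log(1.0 / (L + 1.0))
    ln_null = (L * math.log(L / (L + 1.0)) if L > 0 else 0.0) + math.log(1.0 / (L + 1.0))
    vm = np.full((M, n), _NEG)
    vi = np.full((M, n), _NEG)
    vd = np.full((M, n), _NEG)
    nm = np.empty((M, n))
    ni = np.empty((M, n))
    nd_ = np.empty((M, n))
    vB = ln_move
    vC = np.full(n, _NEG)
    e = np.empty(n)
    for i in range(L):
        vN = (i + 1) * ln_loop
        for k in range(M):
            ek = entry[k] + vB
            if k > 0:
                for t in range(n):
                    best = ek
                    v = vm[k - 1, t] + tmm[k - 1]
                    if v > best:
                        best = v
                    v = vi[k - 1, t] + tim[k - 1]
                    if v > best:
                        best = v
                    v = vd[k - 1, t] + tdm[k - 1]
                    if v > best:
                        best = v
                    nm[k, t] = msc[k, XT[i, t]] + best
            else:
                for t in range(n):
                    nm[k, t] = msc[k, XT[i, t]] + ek
            for t in range(n):
                a = vm[k, t] + tmi[k]
                b = vi[k, t] + tii[k]
                ni[k, t] = a if a > b else b
            if k == 0:
                for t in range(n):
                    nd_[0, t] = _NEG
            else:
                for t in range(n):
                    a = nm[k - 1, t] + tmd[k - 1]
                    b = nd_[k - 1, t] + tdd[k - 1]
                    nd_[k, t] = a if a > b else b
        vB = vN + ln_move
        for t in range(n):
            e[t] = nd_[M - 1, t]
        for k in range(M):
            q = exitq[k]
            for t in range(n):
                v = nm[k, t] + q
                if v > e[t]:
                    e[t] = v
        for t in range(n):
            c2 = vC[t] + ln_loop
            vC[t] = e[t] if e[t] > c2 else c2
        tmp = vm; vm = nm; nm = tmp
        tmp = vi; vi = ni; ni = tmp
        tmp = vd; vd = nd_; nd_ = tmp
    out = np.empty(n)
    for t in range(n):
        c = vC[t]
        if c <= _NEG:
            c = L * ln_loop + ln_move + ln_be
        out[t] = (c + ln_move - ln_null) / LN2
    return out


def viterbi_scores(sp, X: np.ndarray) -> np.ndarray:
    """Uni-hit local Viterbi bit score per target in the batch."""
    X = np.ascontiguousarray(X, dtype=np.uint8)
    if X.shape[0] >= 8:
        XT = np.ascontiguousarray(X.T)
        return _viterbi_scores_batch(*log_pack(sp), XT)
    return _viterbi_scores(*log_pack(sp), X)


def viterbi_score_single(sp, x: np.ndarray) -> float:
    return float(viterbi_scores(sp, x[None, :])[0])


# ------------------------------------------------------------------- Forward

@njit(cache=True)
def _forward_scores(om, Tmm, Tmi, Tmd, Tim, Tii, Tdm, Tdd, entry, exitq, be, X):
    n, L = X.shape
    M = om.shape[0]
    out = np.empty(n, dtype=np.float64)
    loop = L / (L + 1.0)
    move = 1.0 / (L + 1.0)
    ln_null = L * math.log(L / (L + 1.0)) if L > 0 else 0.0
    ln_null += math.log(1.0 / (L + 1.0))
    m = np.empty(M)
    ii = np.empty(M)
    d = np.empty(M)
    nm = np.empty(M)
    ni = np.empty(M)
    nd_ = np.empty(M)
    for t in range(n):
        for k in range(M):
            m[k] = 0.0
            ii[k] = 0.0
            d[k] = 0.0
        N = 1.0
        B = move
        C = B * be
        log_acc = 0.0
        for i in range(L):
            c = X[t, i]
            for k in range(M):
                s = B * entry[k]
                if k > 0:
                    s += m[k - 1] * Tmm[k - 1] + ii[k - 1] * Tim[k - 1] + d[k - 1] * Tdm[k - 1]
                nm[k] = om[k, c] * s
                ni[k] = m[k] * Tmi[k] + ii[k] * Tii[k]
            nd_[0] = 0.0
            for k in range(1, M):
                nd_[k] = nm[k - 1] * Tmd[k - 1] + nd_[k - 1] * Tdd[k - 1]
            N = N * loop
            B = N * move
            E = nd_[M - 1] + B * be
            for k in range(M):
                E += nm[k] * exitq[k]
            C = C * loop + E
            # renormalize the row to keep everything in double range
            s = C + N + B
            for k in range(M):
                s += nm[k] + ni[k] + nd_[k]
            inv = 1.0 / s
            log_acc += math.log(s)
            C *= inv
            N *= inv
            B *= inv
            for k in range(M):
                m[k] = nm[k] * inv
                ii[k] = ni[k] * inv
                d[k] = nd_[k] * inv
        out[t] = (math.log(C * move) + log_acc - ln_null) / LN2
    return out


@njit(cache=True)
def _forward_scores_batch(om, Tmm, Tmi, Tmd, Tim, Tii, Tdm, Tdd, entry, exitq,
                          be, XT):
    """Transposed-layout scaled Forward batch (innermost loop over targets)."""
    L, n = XT.shape
    M = om.shape[0]
    loop = L / (L + 1.0)
    move = 1.0 / (L + 1.0)
    ln_null = (L * math.log(L / (L + 1.0)) if L > 0 else 0.0) + math.log(1.0 / (L + 1.0))
    m = np.zeros((M, n))
    ii = np.zeros((M, n))
    d = np.zeros((M, n))
    nm = np.empty((M, n))
    ni = np.empty((M, n))
    nd_ = np.empty((M, n))
    N = np.full(n, 1.0)
    B = np.full(n, move)
    C = np.full(n, move * be)
    log_acc = np.zeros(n)
    E = np.empty(n)
    s = np.empty(n)
    for i in range(L):
        for k in range(M):
            ek = entry[k]
            if k > 0:
                for t in range(n):
                    nm[k, t] = om[k, XT[i, t]] * (
                        B[t] * ek
                        + m[k - 1, t] * Tmm[k - 1]
                        + ii[k - 1, t] * Tim[k - 1]
                        + d[k - 1, t] * Tdm[k - 1]
                    )
                    ni[k, t] = m[k, t] * Tmi[k] + ii[k, t] * Tii[k]
                    nd_[k, t] = nm[k - 1, t] * Tmd[k - 1] + nd_[k - 1, t] * Tdd[k - 1]
            else:
                for t in range(n):
                    nm[0, t] = om[0, XT[i, t]] * B[t] * ek
                    ni[0, t] = m[0, t] * Tmi[0] + ii[0, t] * Tii[0]
                    nd_[0, t] = 0.0
        for t in range(n):
            N[t] *= loop
            B[t] = N[t] * move
            E[t] = nd_[M - 1, t] + B[t] * be
        for k in range(M):
            q = exitq[k]
            for t in range(n):
                E[t] += nm[k, t] * q
        for t in range(n):
            C[t] = C[t] * loop + E[t]
            s[t] = C[t] + N[t] + B[t]
        for k in range(M):
            for t in range(n):
                s[t] += nm[k, t] + ni[k, t] + nd_[k, t]
        for t in range(n):
            log_acc[t] += math.log(s[t])
            s[t] = 1.0 / s[t]
            C[t] *= s[t]
            N[t] *= s[t]
            B[t] *= s[t]
        for k in range(M):
            for t in range(n):
                m[k, t] = nm[k, t] * s[t]
                ii[k, t] = ni[k, t] * s[t]
                d[k, t] = nd_[k, t] * s[t]
    out = np.empty(n)
    for t in range(n):
        out[t] = (math.log(C[t] * move) + log_acc[t] - ln_null) / LN2
    return out


def forward_scores(sp, X: np.ndarray) -> np.ndarray:
    """Uni-hit local Forward bit score per target in the batch."""
    X = np.ascontiguousarray(X, dtype=np.uint8)
    if X.shape[0] >= 8:
        XT = np.ascontiguousarray(X.T)
        return _forward_scores_batch(*lin_pack(sp), XT)
    return _forward_scores(*lin_pack(sp), X)


def forward_score_single(sp, x: np.ndarray) -> float:
    return float(forward_scores(sp, x[None, :])[0])


# ------------------------------------------------------- background sampling

@njit(cache=True)
def _markov_states(start_cum, trans_cum, u):
    L = u.shape[0]
    S = start_cum.shape[0]
    states = np.empty(L, dtype=np.uint8)
    s = 0
    for j in range(S):
        if u[0] <= start_cum[j]:
            s = j
            break
    states[0] = s
    for i in range(1, L):
        row = trans_cum[s]
        ui = u[i]
        s = S - 1
        for j in range(S):
            if ui <= row[j]:
                s = j
                break
        states[i] = s
    return states


def markov_states(start: np.ndarray, trans: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Sample a Markov state path given pre-drawn uniforms ``u``."""
    return _markov_states(
        np.cumsum(start).astype(np.float64),
        np.cumsum(trans, axis=1).astype(np.float64),
        np.ascontiguousarray(u, dtype=np.float64),
    )
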