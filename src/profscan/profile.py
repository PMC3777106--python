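"""Profile HMM construction and local-search configuration.

A :class:`ProfileHMM` has M match states.  Node ``k`` (0-based internally)
carries match emissions ``e_Mk(a)`` over A,C,G,T, insert emissions
``e_Ik(a)`` (fixed to the background ``null1``, so insert log-odds are
zero), and a 7-transition row ``(MM, MI, MD, IM, II, DM, DD)`` describing
transitions from node k to node k+1.

Construction from an alignment follows the classical recipe: choose
match columns by a gap-fraction rule, weight sequences (Henikoff
position-based), count weighted residues and state-path transitions, and
smooth with Laplace plus-one pseudocounts.  Dirichlet-mixture priors and
entropy weighting are deliberately not implemented; the DNA alphabet is
small enough that plus-one smoothing is serviceable, and the choice is
isolated here.

:func:`configure_local` converts a ProfileHMM into a
:class:`SearchProfile`: a uni-hit local-alignment form in which an
alignment may begin at any match state (uniform-fragment entry
``entry_k = 2(M-k+1)/(M(M+1))``, 1-based k) and end at any match state
(exit probability ``q_k = 1/(M-k+1)``, forcing exit at the last node).
Multiple hits on a target arise from multiple windows in the pipeline,
not from a J state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seqio
from .seqio import MultipleAlignment, SequenceRecord

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
# fractional-count vectors for every IUPAC code (uniform over compatible bases)
_CODE_FRAC = {
    code: np.array([1.0 if b in bases else 0.0 for b in BASES]) / len(bases)
    for code, bases in seqio.IUPAC_CODES.items()
}

# transition row layout
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

UNIFORM_NULL = np.full(4, 0.25)

# weak transition prior, biased toward match continuation like standard
# profile builders: a flat prior over (MM, MI, MD) would put ~17% mass on
# opening a gap at every column of a small alignment, wrecking alignment
# scores; observed counts still dominate as alignments grow
TRANS_PRIOR = np.array([0.95, 0.025, 0.025,   # MM MI MD
                        0.80, 0.20,           # IM II
                        0.75, 0.25])          # DM DD


@dataclass
class ProfileHMM:
    """Position-specific match/insert emission and transition probabilities."""

    name: str
    match_emit: np.ndarray      # (M, 4)
    insert_emit: np.ndarray     # (M, 4)
    transitions: np.ndarray     # (M, 7): MM MI MD IM II DM DD, node k -> k+1
    null1: np.ndarray           # (4,)
    consensus: str

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        self.insert_emit = np.asarray(self.insert_emit, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.null1 = np.asarray(self.null1, dtype=float)
        M = self.match_emit.shape[0]
        if M < 1:
            raise ValueError("profile must have at least one match state")
        if len(self.consensus) != M:
            raise ValueError("consensus length must equal model length")
        self.validate()

    @property
    def M(self) -> int:
        return self.match_emit.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        for nm, arr in (("match_emit", self.match_emit), ("insert_emit", self.insert_emit)):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=tol):
                raise ValueError(f"{nm} rows must sum to 1")
        t = self.transitions
        for nm, cols in (("M", [T_MM, T_MI, T_MD]), ("I", [T_IM, T_II]), ("D", [T_DM, T_DD])):
            if not np.allclose(t[:, cols].sum(axis=1), 1.0, atol=tol):
                raise ValueError(f"from-{nm} transition group must sum to 1")
        if not math.isclose(float(self.null1.sum()), 1.0, abs_tol=tol):
            raise ValueError("null1 must sum to 1")


def assign_match_columns(msa: MultipleAlignment, gap_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask: column is a match column iff its non-gap fraction
    is >= ``gap_threshold`` (unweighted; ties resolve to match)."""
    if not 0 < gap_threshold <= 1:
        raise ValueError("gap_threshold must be in (0, 1]")
    n = msa.n_rows
    mask = np.array(
        [sum(c != "-" for c in msa.column(j)) / n >= gap_threshold
         for j in range(msa.n_columns)],
        dtype=bool,
    )
    if not mask.any():
        raise ValueError("no consensus columns: every column fails the match rule")
    return mask


def sequence_weights(msa: MultipleAlignment) -> np.ndarray:
    """Henikoff position-based weights, normalized to sum to n_rows.

    In each column, a residue shared by n sequences among r distinct
    residues contributes 1/(r*n) to each carrier; gap rows contribute
    nothing in that column.  Rows that would receive zero weight (e.g.
    all-gap rows) are floored at a small positive value before
    normalization so all weights stay > 0.
    """
    n = msa.n_rows
    raw = np.zeros(n)
    for j in range(msa.n_columns):
        col = msa.column(j)
        counts: dict[str, int] = {}
        for c in col:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, c in enumerate(col):
            if c != "-":
                raw[i] += 1.0 / (r * counts[c])
    raw = np.maximum(raw, 1e-6)
    return raw * (n / raw.sum())


def _column_counts(msa: MultipleAlignment, j: int, weights: np.ndarray) -> np.ndarray:
    """Weighted residue counts in column j; degenerate codes fractional."""
    counts = np.zeros(4)
    for i, c in enumerate(msa.column(j)):
        if c != "-":
            counts += weights[i] * _CODE_FRAC[c]
    return counts


def consensus_from_msa(
    msa: MultipleAlignment, mask: np.ndarray, weights: np.ndarray | None = None
) -> SequenceRecord:
    """Weighted plurality residue per match column; ties break alphabetically."""
    if weights is None:
        weights = np.ones(msa.n_rows)
    out = []
    for j in np.flatnonzero(mask):
        counts = _column_counts(msa, int(j), weights)
        out.append(BASES[int(np.argmax(counts))])  # argmax takes first = alphabetical
    return SequenceRecord(id="consensus", residues="".join(out))


def build_profile(
    msa: MultipleAlignment,
    mask: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    pseudocount: float = 1.0,
    null1: np.ndarray | None = None,
    name: str = "profile",
) -> ProfileHMM:
    """Build a ProfileHMM from an alignment.

    Match emissions are Laplace-smoothed weighted counts per match
    column (plus-one over the 4-letter alphabet, scaled by
    ``pseudocount``).  Insert emissions are fixed to null1.  Transitions
    come from the weighted observed state paths (M/D at match columns, I
    at insert columns) plus a weak match-biased prior (``TRANS_PRIOR``
    scaled by ``pseudocount``).
    """
    if mask is None:
        mask = assign_match_columns(msa)
    if weights is None:
        weights = sequence_weights(msa)
    if null1 is None:
        null1 = UNIFORM_NULL
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != msa.n_columns:
        raise ValueError("mask length must equal alignment column count")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    match_cols = np.flatnonzero(mask)
    M = len(match_cols)
    if M == 0:
        raise ValueError("mask selects no match columns")

    emit = np.zeros((M, 4))
    for k, j in enumerate(match_cols):
        emit[k] = _column_counts(msa, int(j), weights)
    emit += pseudocount
    emit /= emit.sum(axis=1, keepdims=True)

    # state path per row: at each match column M (residue) or D (gap);
    # insert-column residues between match columns k and k+1 are I_k.
    tcounts = np.zeros((M, 7))
    for i, (_, aligned) in enumerate(msa.rows):
        w = weights[i]
        prev_state: str | None = None   # 'M' | 'I' | 'D', at node prev_k
        prev_k = -1
        for j in range(msa.n_columns):
            c = aligned[j]
            if mask[j]:
                k = int(np.searchsorted(match_cols, j))
                state = "M" if c != "-" else "D"
                if prev_state is not None and prev_k >= 0:
                    col = {"MM": T_MM, "MD": T_MD, "IM": T_IM,
                           "DM": T_DM, "DD": T_DD}.get(prev_state + state)
                    if col is not None:
                        tcounts[prev_k, col] += w
                prev_state, prev_k = state, k
            else:
                if c != "-":
                    if prev_state == "M" and prev_k >= 0:
                        tcounts[prev_k, T_MI] += w
                    elif prev_state == "I" and prev_k >= 0:
                        tcounts[prev_k, T_II] += w
                    # inserts before the first match column are ignored
                    # (local alignment has no node to hang them on)
                    if prev_k >= 0:
                        prev_state = "I"

    tcounts += pseudocount * TRANS_PRIOR
    trans = np.zeros((M, 7))
    for cols in ([T_MM, T_MI, T_MD], [T_IM, T_II], [T_DM, T_DD]):
        grp = tcounts[:, cols]
        trans[:, cols] = grp / grp.sum(axis=1, keepdims=True)

    cons = consensus_from_msa(msa, mask, weights)
    return ProfileHMM(
        name=name,
        match_emit=emit,
        insert_emit=np.tile(null1, (M, 1)),
        transitions=trans,
        null1=null1.copy(),
        consensus=cons.residues,
    )


def profile_from_single_sequence(
    seq: SequenceRecord,
    match_prob: float = 0.85,
    gap_open: float = 0.02,
    gap_extend: float = 0.4,
    null1: np.ndarray | None = None,
) -> ProfileHMM:
    """One match state per query residue; position-independent gap costs.

    The query residue gets emission probability ``match_prob``; the
    remaining mass is split over the other bases.  Degenerate query
    residues spread ``match_prob`` over their compatible bases.  With the
    defaults the match/mismatch log-odds are about +1.8/-2.3 bits,
    comparable to sensitive blastn-style scoring.
    """
    if len(seq) < 1:
        raise ValueError("query sequence must be non-empty")
    if not 0 < match_prob < 1:
        raise ValueError("match_prob must be in (0,1)")
    if null1 is None:
        null1 = UNIFORM_NULL
    M = len(seq)
    emit = np.zeros((M, 4))
    cons = []
    for k, c in enumerate(seq.residues):
        frac = _CODE_FRAC[c]
        hit = frac > 0
        emit[k][hit] = match_prob * frac[hit] / frac[hit].sum()
        n_other = int((~hit).sum())
        if n_other:
            emit[k][~hit] = (1.0 - match_prob) / n_other
        else:
            emit[k] = emit[k] / emit[k].sum()
        cons.append(BASES[int(np.argmax(emit[k]))])
    trans = np.tile(
        [1.0 - 2 * gap_open, gap_open, gap_open,       # MM MI MD
         1.0 - gap_extend, gap_extend,                 # IM II
         1.0 - gap_extend, gap_extend],                # DM DD
        (M, 1),
    )
    return ProfileHMM(
        name=seq.id,
        match_emit=emit,
        insert_emit=np.tile(null1, (M, 1)),
        transitions=trans,
        null1=np.asarray(null1, dtype=float).copy(),
        consensus="".join(cons),
    )


def fragment_entry(M: int) -> np.ndarray:
    """Uniform-fragment entry distribution: entry_k = 2(M-k+1)/(M(M+1))."""
    k = np.arange(1, M + 1)
    return 2.0 * (M - k + 1) / (M * (M + 1))


@dataclass
class SearchProfile:
    """Local-alignment, log-odds-configured form of a ProfileHMM.

    ``entry``/``exit_q`` define the uni-hit local topology; ``match_lod``
    is the match emission log-odds table in bits.  ``_msc16`` extends the
    match log-odds (in nats) to all 15 IUPAC masks: a degenerate target
    code scores the background-weighted average odds of its compatible
    bases, ln(sum e) - ln(sum f).  ``calibration`` holds fitted null
    score statistics (see :mod:`profscan.stats`); it is required for
    E-values and pipeline thresholds.
    """

    hmm: ProfileHMM
    entry: np.ndarray           # (M,) probabilities, sums to 1
    exit_q: np.ndarray          # (M,) M_k -> E probability; exit_q[M-1] = 1
    match_lod: np.ndarray       # (M, 4) bits
    calibration: "object | None" = None
    mode: str = "local-unihit"
    # probability of entering the core model from B (vs the empty B->E path)
    p_core: float = 0.5
    _msc16: np.ndarray = field(default=None, repr=False)

    @property
    def M(self) -> int:
        return self.hmm.M

    @property
    def name(self) -> str:
        return self.hmm.name


def configure_local(hmm: ProfileHMM, calibration=None) -> SearchProfile:
    """Configure a ProfileHMM for uni-hit local search."""
    M = hmm.M
    entry = fragment_entry(M)
    k = np.arange(M)
    exit_q = 1.0 / (M - k)          # 1/(M-k+1) with 1-based k; q_M = 1
    with np.errstate(divide="ignore"):
        match_lod = np.log2(hmm.match_emit / hmm.null1)
    # degenerate-extended match scores, nats; mask index 0 unused
    msc16 = np.full((M, 16), -np.inf)
    for m in range(1, 16):
        sel = np.array([(m >> i) & 1 for i in range(4)], dtype=bool)
        e = hmm.match_emit[:, sel].sum(axis=1)
        f = hmm.null1[sel].sum()
        with np.errstate(divide="ignore"):
            msc16[:, m] = np.log(e) - np.log(f)
    return SearchProfile(
        hmm=hmm, entry=entry, exit_q=exit_q,
        match_lod=match_lod, calibration=calibration, _msc16=msc16,
    )


# ---------------------------------------------------------------- profile I/O

_MAGIC = "PROFSCAN-HMM"
_VERSION = "1"


def write_profile(hmm: ProfileHMM, path: str | Path, calibration=None) -> None:
    """Write the plain-text profile format (optionally with calibration).

    Layout: header lines (magic/version/alphabet, NAME, LENG, NULL,
    CONS, optional CALIB), then one NODE line per match state with 4
    match emissions, 4 insert emissions and 7 transitions, then END.
    """
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC} {_VERSION} DNA\n")
        fh.write(f"NAME {hmm.name}\n")
        fh.write(f"LENG {hmm.M}\n")
        fh.write("NULL " + " ".join(f"{v:.6e}" for v in hmm.null1) + "\n")
        fh.write(f"CONS {hmm.consensus}\n")
        if calibration is not None:
            c = calibration
            fh.write(
                "CALIB "
                f"{c.ssv_mu:.6e} {c.ssv_lambda:.6e} "
                f"{c.vit_mu:.6e} {c.vit_lambda:.6e} "
                f"{c.fwd_tau:.6e} {c.fwd_lambda:.6e} {c.fwd_tailmass:.6e} "
                f"{c.calib_L} {c.calib_N} {c.seed}\n"
            )
            if c.fwd_qgrid is not None:
                fh.write("CALIBQ " + " ".join(f"{v:.6e}" for v in c.fwd_qgrid) + "\n")
        for k in range(hmm.M):
            vals = np.concatenate(
                [hmm.match_emit[k], hmm.insert_emit[k], hmm.transitions[k]]
            )
            fh.write(f"NODE {k + 1} " + " ".join(f"{v:.6e}" for v in vals) + "\n")
        fh.write("END\n")


def read_profile(path: str | Path):
    """Read a profile text file -> (ProfileHMM, CalibrationParams | None)."""
    from .stats import CalibrationParams

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(_MAGIC):
        raise seqio.ParseError(f"{path}: not a {_MAGIC} file")
    head = lines[0].split()
    if len(head) != 3 or head[1] != _VERSION:
        raise seqio.ParseError(f"{path}: unsupported profile version: {lines[0]!r}")
    if head[2] != "DNA":
        raise seqio.ParseError(f"{path}: alphabet {head[2]!r} not supported (expected DNA)")

    meta: dict[str, str] = {}
    calib = None
    nodes: dict[int, np.ndarray] = {}
    ended = False
    for ln in lines[1:]:
        tag, _, rest = ln.partition(" ")
        if tag == "END":
            ended = True
        elif tag == "CALIB":
            v = rest.split()
            calib = CalibrationParams(
                ssv_mu=float(v[0]), ssv_lambda=float(v[1]),
                vit_mu=float(v[2]), vit_lambda=float(v[3]),
                fwd_tau=float(v[4]), fwd_lambda=float(v[5]), fwd_tailmass=float(v[6]),
                calib_L=int(v[7]), calib_N=int(v[8]), seed=int(v[9]),
            )
        elif tag == "CALIBQ":
            if calib is None:
                raise seqio.ParseError(f"{path}: CALIBQ before CALIB line")
            calib.fwd_qgrid = np.array([float(x) for x in rest.split()])
        elif tag == "NODE":
            v = rest.split()
            k = int(v[0])
            vals = np.array([float(x) for x in v[1:]])
            if vals.shape[0] != 15:
                raise seqio.ParseError(f"{path}: NODE {k}: expected 15 values, got {vals.shape[0]}")
            nodes[k] = vals
        else:
            meta[tag] = rest
    if "LENG" not in meta or "NAME" not in meta:
        raise seqio.ParseError(f"{path}: missing NAME/LENG header")
    M = int(meta["LENG"])
    for k in range(1, M + 1):
        if k not in nodes:
            raise seqio.ParseError(f"{path}: truncated profile: missing NODE {k} of {M}")
    if not ended:
        raise seqio.ParseError(f"{path}: truncated profile: missing END")
    tbl = np.stack([nodes[k] for k in range(1, M + 1)])
    # renormalize away round-tripping error so validation stays strict
    me = tbl[:, 0:4]; ie = tbl[:, 4:8]; tr = tbl[:, 8:15].copy()
    me = me / me.sum(axis=1, keepdims=True)
    ie = ie / ie.sum(axis=1, keepdims=True)
    for cols in ([0, 1, 2], [3, 4], [5, 6]):
        tr[:, cols] /= tr[:, cols].sum(axis=1, keepdims=True)
    null1 = np.array([float(x) for x in meta["NULL"].split()])
    null1 = null1 / null1.sum()
    hmm = ProfileHMM(
        name=meta["NAME"], match_emit=me, insert_emit=ie, transitions=tr,
        null1=null1, consensus=meta["CONS"],
    )
    return hmm, calib
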