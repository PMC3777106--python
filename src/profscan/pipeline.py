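"""The staged acceleration pipeline over long targets.

Search proceeds per query x target x strand:

1. **SSV seeding** — the ungapped diagonal filter scans the full strand
   (in 256 kb chunks with 2M overlap, so seeds at chunk joins are never
   lost) at the score threshold implied by the ``p_ssv`` P-value cutoff.
2. **Windows** — each seed is padded by ``pad_factor * M`` on both sides
   and overlapping/adjacent windows are merged, so every window is
   scored at most once (one aligned segment per window).
3. **Viterbi filter** — windows whose gapped Viterbi P-value exceeds
   ``p_vit`` are rejected.
4. **Forward/Backward** — survivors are rescored by Forward; the
   alignment-specific composition (null2) bias is subtracted, and
   windows whose corrected P-value exceeds ``p_fwd`` are rejected.
5. **Hit construction** — posterior decoding yields the envelope (the
   smallest interval containing every position with aligned-state
   posterior >= 0.1) and the per-column confidence line; the alignment
   itself is the Viterbi traceback.

Setting every threshold to 1 disables filtering: the target is covered
with overlapping fixed-size windows and every window is Forward-scored
(the ``--max`` mode of the CLI).

Coordinates are 0-based half-open on the plus strand internally; report
formatting is 1-based inclusive, with minus-strand hits printed with
``from > to``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, dp, stats
from .dp import DiagonalHit
from .profile import SearchProfile
from .seqio import COMP_MASK, MASK_TO_CODE, SequenceRecord

CHUNK = 262_144

# confidence characters for posterior probabilities
def _pp_char(p: float) -> str:
    if p >= 0.95:
        return "*"
    return str(min(9, int(p * 10.0)))


@dataclass
class PipelineThresholds:
    """Stage P-value cutoffs and the report E-value threshold."""

    p_ssv: float = 0.02
    p_vit: float = 1e-3
    p_fwd: float = 1e-5
    report_evalue: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.p_fwd <= self.p_vit <= self.p_ssv <= 1):
            raise ValueError("need 0 < p_fwd <= p_vit <= p_ssv <= 1")

    @classmethod
    def open(cls, report_evalue: float = 10.0) -> "PipelineThresholds":
        """All filters disabled (every window endures full Forward)."""
        return cls(p_ssv=1.0, p_vit=1.0, p_fwd=1.0, report_evalue=report_evalue)

    @property
    def filters_off(self) -> bool:
        return self.p_ssv >= 1.0


@dataclass
class Window:
    """A candidate region, in scan-strand coordinates."""

    target_id: str
    strand: str
    start: int
    end: int
    seeds: list = field(default_factory=list)


@dataclass
class Rejection:
    """Marker for a window filtered out at a named stage."""

    stage: str
    score: float
    pvalue: float


@dataclass
class Hit:
    """One local match on a target, with confidence-annotated alignment.

    ``env_*``/``ali_*`` are 0-based half-open plus-strand coordinates
    (``ali`` nested in ``env``); ``hmm_*`` are 1-based model nodes.
    ``score`` is the bias-corrected Forward bit score.
    """

    query_name: str
    target_id: str
    strand: str
    env_start: int
    env_end: int
    ali_start: int
    ali_end: int
    hmm_start: int
    hmm_end: int
    score: float
    raw_score: float
    bias: float
    pvalue: float
    evalue: float
    alignment: tuple[str, str, str]  # model line, target line, confidence line

    def _fmt(self, start: int, end: int) -> tuple[int, int]:
        if self.strand == "+":
            return start + 1, end
        return end, start + 1          # minus strand: from > to

    @property
    def ali_coords(self) -> tuple[int, int]:
        """1-based inclusive alignment coordinates (from > to on '-')."""
        return self._fmt(self.ali_start, self.ali_end)

    @property
    def env_coords(self) -> tuple[int, int]:
        return self._fmt(self.env_start, self.env_end)

    def tbl_row(self) -> str:
        af, at = self.ali_coords
        ef, et = self.env_coords
        return "\t".join([
            self.target_id, self.query_name,
            str(self.hmm_start), str(self.hmm_end),
            str(af), str(at), str(ef), str(et), self.strand,
            f"{self.score:.1f}", f"{self.bias:.1f}", f"{self.evalue:.2g}",
        ])

    def format_alignment(self, width: int = 60) -> str:
        mline, tline, pline = self.alignment
        af, at = self.ali_coords
        out = [f"  {self.query_name} -> {self.target_id}/{af}-{at} ({self.strand})  "
               f"score {self.score:.1f} bits  E {self.evalue:.2g}"]
        for i in range(0, len(mline), width):
            out.append(f"  model  {mline[i:i + width]}")
            out.append(f"  target {tline[i:i + width]}")
            out.append(f"  conf   {pline[i:i + width]}")
            out.append("")
        return "\n".join(out)


TBL_HEADER = "\t".join([
    "target", "query", "hmm_from", "hmm_to", "ali_from", "ali_to",
    "env_from", "env_to", "strand", "score", "bias", "evalue",
])


def windows_from_seeds(
    seeds: list[DiagonalHit], M: int, target_len: int, pad_factor: float = 2.0
) -> list[tuple[int, int]]:
    """Pad each seed by pad_factor*M and merge overlapping/adjacent windows."""
    if not seeds:
        return []
    pad = int(round(pad_factor * M))
    ivs = sorted(
        (max(0, s.target_start - pad), min(target_len, s.target_end + pad))
        for s in seeds
    )
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def cover_windows(target_len: int, M: int, length: int = 10_000) -> list[tuple[int, int]]:
    """Overlapping fixed windows covering the whole target (filters-off
    mode).  The window length defaults to the calibration target length
    so per-window score statistics match the calibration; windows share
    a length where possible (the final window is shifted left rather
    than shortened) so they can be scored in batch, and the 2M overlap
    keeps any single alignment intact in some window."""
    W = max(8 * M, length)
    if target_len <= W:
        return [(0, target_len)]
    step = W - 2 * M
    out = []
    s = 0
    while s + W < target_len:
        out.append((s, s + W))
        s += step
    out.append((target_len - W, target_len))
    return out


def null2_bias(post: dp.Posterior, window_codes: np.ndarray, null1: np.ndarray,
               match_emit: np.ndarray) -> float:
    """Composition-bias score (bits) from the alignment-specific null.

    null2 is the posterior-usage-weighted average of the emitting
    states' distributions; the bias is the (non-negative) total log-odds
    of the aligned residues under null2 vs null1.
    """
    w_match = post.match.sum(axis=0)            # (M,)
    w_ins = float(post.insert.sum())
    tot = float(w_match.sum()) + w_ins
    if tot <= 0:
        return 0.0
    null2 = (w_match @ match_emit + w_ins * null1) / tot
    # extend to 4-bit degenerate masks
    n2_16 = np.zeros(16)
    n1_16 = np.zeros(16)
    for m in range(1, 16):
        sel = [(m >> i) & 1 == 1 for i in range(4)]
        n2_16[m] = null2[sel].sum() if any(sel) else 0.0
        n1_16[m] = np.asarray(null1)[sel].sum()
    aligned = post.aligned >= 0.1
    if not aligned.any():
        return 0.0
    xs = window_codes[aligned]
    bias = float(np.sum(np.log2(n2_16[xs] / n1_16[xs])))
    return max(0.0, bias)


def _alignment_strings(sp: SearchProfile, codes: np.ndarray, path: list,
                       post: dp.Posterior) -> tuple[str, str, str]:
    cons = sp.hmm.consensus
    mline, tline, pline = [], [], []
    for el in path:
        if el[0] == "M":
            _, k, i = el
            mline.append(cons[k - 1])
            tline.append(MASK_TO_CODE[int(codes[i - 1])])
            pline.append(_pp_char(float(post.match[i - 1, k - 1])))
        elif el[0] == "I":
            _, k, i = el
            mline.append(".")
            tline.append(MASK_TO_CODE[int(codes[i - 1])].lower())
            pline.append(_pp_char(float(post.insert[i - 1, k - 1])))
        elif el[0] == "D":
            _, k, i = el
            mline.append(cons[k - 1])
            tline.append("-")
            pline.append(".")
    return "".join(mline), "".join(tline), "".join(pline)


def score_window(
    sp: SearchProfile,
    window_codes: np.ndarray,
    thresholds: PipelineThresholds,
    calibration: stats.CalibrationParams | None = None,
    searched_residues: int | None = None,
):
    """Run one window through Viterbi filter -> Forward/Backward -> Hit.

    Returns a :class:`Hit` with window-local coordinates (caller maps to
    target coordinates), or a :class:`Rejection` naming the stage.
    """
    calibration = calibration or sp.calibration
    if calibration is None:
        raise ValueError(
            "profile is not calibrated; run stats.calibrate() or the "
            "'profscan calibrate' command first"
        )
    if searched_residues is None:
        searched_residues = len(window_codes)

    vit_bits = _kernels.viterbi_score_single(sp, window_codes)
    p_vit = stats.gumbel_sf(vit_bits, calibration.vit_mu, calibration.vit_lambda)
    if p_vit > thresholds.p_vit:
        return Rejection("vit", vit_bits, p_vit)

    fwd_bits = _kernels.forward_score_single(sp, window_codes)
    # bias >= 0 can only worsen the corrected P-value: pre-reject cheaply
    p_fwd_raw = min(1.0, stats.score_to_pvalue(fwd_bits, "fwd", calibration))
    if p_fwd_raw > thresholds.p_fwd:
        return Rejection("fwd", fwd_bits, p_fwd_raw)
    # a cheap E-value bound before committing to Backward + posteriors
    _, ev_bound = stats.score_to_evalue(fwd_bits, "fwd", calibration, searched_residues)
    if ev_bound > thresholds.report_evalue:
        return Rejection("report", fwd_bits, p_fwd_raw)

    fm = dp.forward_matrix(sp, window_codes)
    bm = dp.backward_matrix(sp, window_codes)
    post = dp.posterior_decode(sp, window_codes, fm, bm)
    bias = null2_bias(post, window_codes, sp.hmm.null1, sp.hmm.match_emit)
    score = fwd_bits - bias
    pvalue, evalue = stats.score_to_evalue(score, "fwd", calibration, searched_residues)
    if pvalue > thresholds.p_fwd:
        return Rejection("fwd", score, pvalue)
    if evalue > thresholds.report_evalue:
        return Rejection("report", score, pvalue)

    _, path = dp.viterbi(sp, window_codes)
    core = [el for el in path if el[0] in "MID"]
    m_emits = [el for el in core if el[0] == "M"]
    if not m_emits:
        return Rejection("empty", score, pvalue)
    ali_start = m_emits[0][2] - 1
    ali_end = m_emits[-1][2]
    hmm_start = m_emits[0][1]
    hmm_end = m_emits[-1][1]
    aligned_idx = np.flatnonzero(post.aligned >= 0.1)
    if aligned_idx.size:
        env_start = min(int(aligned_idx[0]), ali_start)
        env_end = max(int(aligned_idx[-1]) + 1, ali_end)
    else:
        env_start, env_end = ali_start, ali_end
    alignment = _alignment_strings(sp, window_codes, core, post)
    return Hit(
        query_name=sp.name, target_id="", strand="+",
        env_start=env_start, env_end=env_end,
        ali_start=ali_start, ali_end=ali_end,
        hmm_start=hmm_start, hmm_end=hmm_end,
        score=score, raw_score=fwd_bits, bias=bias,
        pvalue=pvalue, evalue=evalue, alignment=alignment,
    )


def _merge_overlapping(hits: list[Hit]) -> list[Hit]:
    """Among hits overlapping on the same target and strand, keep the one
    with the best E-value per overlap component."""
    out: list[Hit] = []
    bykey: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        bykey.setdefault((h.target_id, h.strand), []).append(h)
    for group in bykey.values():
        group.sort(key=lambda h: h.env_start)
        comp: list[Hit] = []
        comp_end = -1
        for h in group:
            if comp and h.env_start < comp_end:
                comp.append(h)
                comp_end = max(comp_end, h.env_end)
            else:
                if comp:
                    out.append(min(comp, key=lambda c: (c.evalue, -c.score)))
                comp = [h]
                comp_end = h.env_end
        if comp:
            out.append(min(comp, key=lambda c: (c.evalue, -c.score)))
    return out


def search_one(
    sp: SearchProfile,
    targets: list[SequenceRecord],
    thresholds: PipelineThresholds | None = None,
    pad_factor: float = 2.0,
) -> list[Hit]:
    """Search one calibrated profile against targets, both strands."""
    if thresholds is None:
        thresholds = PipelineThresholds()
    calib = sp.calibration
    if calib is None:
        raise ValueError("profile is not calibrated")
    M = sp.M
    searched = sum(len(t) for t in targets) * 2
    if searched == 0:
        return []
    if not thresholds.filters_off:
        t_ssv = stats.gumbel_isf(
            min(thresholds.p_ssv, 1.0 - 1e-12), calib.ssv_mu, calib.ssv_lambda
        )
    hits: list[Hit] = []
    for rec in targets:
        codes_plus = rec.encoded()
        L = len(codes_plus)
        if L == 0:
            continue
        for strand in "+-":
            codes = codes_plus if strand == "+" else COMP_MASK[codes_plus][::-1]
            if thresholds.filters_off:
                wins = cover_windows(L, M, calib.calib_L)
                if len(wins) > 4:
                    # batch Forward pre-screen: bias and merging can only
                    # worsen a window's E-value, so windows whose raw
                    # Forward E-value already exceeds the report threshold
                    # cannot yield a reportable hit
                    W = wins[0][1] - wins[0][0]
                    batch = np.stack([codes[a:b] for a, b in wins if b - a == W])
                    fwd = _kernels.forward_scores(sp, batch)
                    keep = []
                    bi = 0
                    for a, b in wins:
                        if b - a == W:
                            _, ev = stats.score_to_evalue(
                                float(fwd[bi]), "fwd", calib, searched)
                            bi += 1
                            if ev <= thresholds.report_evalue:
                                keep.append((a, b))
                        else:
                            keep.append((a, b))
                    wins = keep
            else:
                seeds: list[DiagonalHit] = []
                step = max(CHUNK - 2 * M, CHUNK // 2)
                for c0 in range(0, L, step):
                    c1 = min(L, c0 + CHUNK)
                    for s in dp.ssv_scan(sp, codes[c0:c1], t_ssv, fast=True):
                        seeds.append(DiagonalHit(
                            target_start=s.target_start + c0,
                            target_end=s.target_end + c0,
                            model_start=s.model_start, score=s.score,
                        ))
                    if c1 >= L:
                        break
                wins = windows_from_seeds(seeds, M, L, pad_factor)
            for w0, w1 in wins:
                res = score_window(sp, codes[w0:w1], thresholds, calib, searched)
                if isinstance(res, Rejection):
                    continue
                h = res
                # window-local -> scan coords -> plus-strand coords
                for attr in ("env_start", "env_end", "ali_start", "ali_end"):
                    setattr(h, attr, getattr(h, attr) + w0)
                if strand == "-":
                    h.env_start, h.env_end = L - h.env_end, L - h.env_start
                    h.ali_start, h.ali_end = L - h.ali_end, L - h.ali_start
                h.target_id = rec.id
                h.strand = strand
                hits.append(h)
    hits = _merge_overlapping(hits)
    hits = [h for h in hits if h.evalue <= thresholds.report_evalue]
    hits.sort(key=_rank_key)
    return hits


def _rank_key(h: Hit):
    return (h.evalue, -h.score, h.target_id, h.strand, h.env_start)


def search(
    queries: list[SearchProfile],
    targets: list[SequenceRecord],
    thresholds: PipelineThresholds | None = None,
    seed: int = 0,
) -> list[Hit]:
    """Search every query against every target (both strands); ranked hits.

    The pipeline is deterministic given its inputs; ``seed`` is accepted
    for interface stability but no stage draws random numbers at search
    time (all randomness lives in calibration, which is stored on the
    profile).
    """
    hits: list[Hit] = []
    for sp in queries:
        hits.extend(search_one(sp, targets, thresholds))
    hits.sort(key=lambda h: (h.evalue, -h.score, h.query_name, h.target_id, h.strand, h.env_start))
    return hits
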