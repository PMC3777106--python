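"""Score-distribution calibration and E-values.

Null score statistics are estimated by simulation: the profile is run
against i.i.d. background targets and the per-target optimal-alignment
scores are fitted.  SSV and Viterbi best scores follow an extreme-value
(Gumbel) law.  Forward scores, being a log-sum over alignments, have no
closed-form null: their high tail is modeled as exponential (slope one
per bit by default), anchored at the empirical (1 - tailmass) quantile,
while below the anchor the calibration sample's own quantile grid is
interpolated.  The hybrid is needed because the Forward null bulk is
strongly compressed and non-exponential: extrapolating the tail law
below its anchor misstates weak-hit P-values by an order of magnitude,
which would break the self-consistency of E-values near 1.

P-values are per calibration-length target; E-values rescale linearly
in the number of residues searched, E = P * searched / calib_L.  No
finite-length edge correction is applied (adequate when target windows
are much longer than the model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .seqio import SequenceRecord, MASK_TO_CODE

_BASE_MASKS = np.array([1, 2, 4, 8], dtype=np.uint8)  # A C G T

DEFAULT_CALIB_N = 200
DEFAULT_CALIB_L = 10_000
DEFAULT_CALIB_SEED = 42
DEFAULT_TAILMASS = 0.04

#: quantile levels of the Forward-null bulk grid (0 .. 1 - tailmass)
FWD_QGRID_LEVELS = np.linspace(0.0, 1.0 - DEFAULT_TAILMASS, 49)


@dataclass
class CalibrationParams:
    """Fitted null-score statistics for the three pipeline stages (bits)."""

    ssv_mu: float
    ssv_lambda: float
    vit_mu: float
    vit_lambda: float
    fwd_tau: float
    fwd_lambda: float
    fwd_tailmass: float
    calib_L: int
    calib_N: int
    seed: int
    fwd_qgrid: np.ndarray | None = None   # scores at FWD_QGRID_LEVELS
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.ssv_lambda <= 0 or self.vit_lambda <= 0 or self.fwd_lambda <= 0:
            raise ValueError("calibration lambdas must be positive")
        if not 0 < self.fwd_tailmass < 1:
            raise ValueError("fwd_tailmass must be in (0,1)")


def _sample_codes(null1: np.ndarray, n: int, L: int, rng: np.random.Generator) -> np.ndarray:
    return _BASE_MASKS[rng.choice(4, size=(n, L), p=np.asarray(null1, dtype=float))]


def sample_null_targets(null1, n: int, L: int, seed: int) -> list[SequenceRecord]:
    """n i.i.d. background targets of length L, deterministic per seed."""
    if n < 1 or L < 1:
        raise ValueError("n and L must be >= 1")
    rng = np.random.default_rng(seed)
    codes = _sample_codes(null1, n, L, rng)
    lut = np.zeros(16, dtype="U1")
    for m, c in MASK_TO_CODE.items():
        lut[m] = c
    return [
        SequenceRecord(id=f"null{i}", residues="".join(lut[codes[i]]))
        for i in range(n)
    ]


def fit_gumbel(scores) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda).

    Survival: P(S >= x) = 1 - exp(-exp(-lambda (x - mu))).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 100:
        raise ValueError("need at least 100 scores for a stable Gumbel fit")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate (all-equal) scores")
    mu, beta = sps.gumbel_r.fit(scores)
    return float(mu), float(1.0 / beta)


def fit_exp_tail(scores, tailmass: float = DEFAULT_TAILMASS) -> float:
    """Anchor of the base-2 exponential tail: the (1-tailmass) quantile.

    Tail model: P(S >= x) = tailmass * 2^-(x - tau) for x >= tau.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 100:
        raise ValueError("need at least 100 scores to fit a tail")
    if not 0 < tailmass < 1:
        raise ValueError("tailmass must be in (0,1)")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate (all-equal) scores")
    return float(np.quantile(scores, 1.0 - tailmass))


def gumbel_sf(x: float, mu: float, lam: float) -> float:
    """P(S >= x) under Gumbel(mu, lambda), numerically stable far out."""
    y = lam * (x - mu)
    if y > 30:  # 1 - exp(-e^-y) ~ e^-y
        return math.exp(-y)
    return -math.expm1(-math.exp(-y))


def gumbel_isf(p: float, mu: float, lam: float) -> float:
    """Score threshold with survival probability p."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0,1)")
    return mu - math.log(-math.log1p(-p)) / lam


def exp_tail_sf(x: float, tau: float, lam: float, tailmass: float) -> float:
    """Tail survival, extrapolated below tau (may exceed 1; cap by caller)."""
    return tailmass * 2.0 ** (-lam * (x - tau))


def calibrate(
    sp,
    null1=None,
    n: int = DEFAULT_CALIB_N,
    L: int = DEFAULT_CALIB_L,
    seed: int = DEFAULT_CALIB_SEED,
    tailmass: float = DEFAULT_TAILMASS,
) -> CalibrationParams:
    """Simulate null targets and fit all three stage distributions.

    Records, per simulated target: the best SSV diagonal-segment score,
    the best (full-target) Viterbi score, and the Forward score; fits
    Gumbels to the first two and the exponential tail to the third.
    The params are attached to ``sp.calibration`` as a side effect.
    """
    from . import _kernels

    if null1 is None:
        null1 = sp.hmm.null1
    warning = None
    if n < 100:
        warning = f"calibration with n={n} < 100 targets is unreliable"
    rng = np.random.default_rng(seed)
    X = _sample_codes(null1, n, L, rng)
    ssv = _kernels.ssv_best_scores(sp, X)
    vit = _kernels.viterbi_scores(sp, X)
    fwd = _kernels.forward_scores(sp, X)
    ssv_mu, ssv_lam = _fit_gumbel_any(ssv)
    vit_mu, vit_lam = _fit_gumbel_any(vit)
    tau = float(np.quantile(fwd, 1.0 - tailmass))
    levels = np.linspace(0.0, 1.0 - tailmass, len(FWD_QGRID_LEVELS))
    qgrid = np.maximum.accumulate(np.quantile(fwd, levels))
    params = CalibrationParams(
        ssv_mu=ssv_mu, ssv_lambda=ssv_lam,
        vit_mu=vit_mu, vit_lambda=vit_lam,
        fwd_tau=tau, fwd_lambda=1.0, fwd_tailmass=tailmass,
        calib_L=L, calib_N=n, seed=seed, fwd_qgrid=qgrid, warning=warning,
    )
    sp.calibration = params
    return params


def _fit_gumbel_any(scores: np.ndarray) -> tuple[float, float]:
    # fit_gumbel's >=100 guard is relaxed here: calibrate() already
    # warns about small n, and tiny calibrations are useful in tests
    if np.ptp(scores) == 0:
        raise ValueError("degenerate (all-equal) calibration scores")
    mu, beta = sps.gumbel_r.fit(scores)
    return float(mu), float(1.0 / beta)


def score_to_pvalue(score: float, stage: str, params: CalibrationParams) -> float:
    """Per-calibration-length-target P-value.

    For the Forward stage, scores at or above the tail anchor use the
    exponential tail law; scores below it interpolate the calibration
    sample's quantile grid (falling back to pure tail extrapolation if
    the profile was calibrated without a grid)."""
    if stage == "ssv":
        return gumbel_sf(score, params.ssv_mu, params.ssv_lambda)
    if stage == "vit":
        return gumbel_sf(score, params.vit_mu, params.vit_lambda)
    if stage == "fwd":
        if score >= params.fwd_tau or params.fwd_qgrid is None:
            return exp_tail_sf(score, params.fwd_tau, params.fwd_lambda,
                               params.fwd_tailmass)
        g = params.fwd_qgrid
        if score <= g[0]:
            return 1.0
        levels = np.linspace(0.0, 1.0 - params.fwd_tailmass, len(g))
        return float(1.0 - np.interp(score, g, levels))
    raise ValueError(f"unknown pipeline stage {stage!r}")


def score_to_evalue(
    score: float, stage: str, params: CalibrationParams, searched_residues: int
) -> tuple[float, float]:
    """(pvalue, evalue) for a score at a given search size.

    The P-value is per calib_L-residue target (capped at 1); the E-value
    rescales the uncapped exceedance rate linearly to the number of
    residues searched, so it is always >= the P-value for searches at
    least calib_L long.
    """
    p_raw = score_to_pvalue(score, stage, params)
    pvalue = min(1.0, p_raw)
    evalue = p_raw * (searched_residues / params.calib_L)
    return pvalue, evalue


def ks_uniform_pvalue(pvalues) -> float:
    """One-sample KS test of P-values against Uniform(0,1)."""
    return float(sps.kstest(np.asarray(pvalues, dtype=float), "uniform").pvalue)
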