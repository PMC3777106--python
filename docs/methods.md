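# Methods

`profscan` is a profile hidden Markov model (profile HMM) search engine
for DNA/DNA homology: it builds a probabilistic model of a sequence
family from a nucleotide alignment, scans both strands of long targets
through a staged filter pipeline, and reports local hits ranked by
E-value with per-column posterior confidence. This note records the
model, the numerical choices, and what the synthetic benchmark does and
does not establish.

## The probabilistic model

A profile of length M has match states M_1..M_M with position-specific
emission distributions over A,C,G,T, insert states I_k emitting the
background distribution null1, and delete states D_k. Node k carries a
seven-transition row (M→M, M→I, M→D, I→M, I→I, D→M, D→D) from node k to
k+1.

**Construction.** Match columns are alignment columns whose unweighted
non-gap fraction is ≥ 0.5 (ties count as match). Sequences are weighted
by the Henikoff position-based scheme, normalized to the number of
rows. Match emissions are weighted counts smoothed with Laplace
plus-one pseudocounts over the four-letter alphabet; degenerate IUPAC
residues contribute fractional counts split over their compatible
bases. Insert emissions are pinned to null1, which makes insert
emission log-odds exactly zero. Transitions are weighted state-path
counts smoothed with a *match-biased* prior (0.95/0.025/0.025 for
M→{M,I,D}; 0.80/0.20 for I→{M,I}; 0.75/0.25 for D→{M,D}), scaled by the
same pseudocount strength. A flat transition prior is indefensible at
small family sizes: with three sequences it would set t(M→M) ≈ 0.66,
charging every aligned column −0.6 bits and pushing real alignments
below the null floor; the biased prior matches the practice of
production profile builders while still letting observed counts
dominate as families grow. Dirichlet mixture priors and entropy
weighting are deliberately out of scope.

**Local, uni-hit configuration.** An alignment may begin at any match
state with the uniform-fragment entry probability
entry_k = 2(M−k+1)/(M(M+1)) and end at any match state with exit
probability q_k = 1/(M−k+1) (forced exit at the last node; the last
delete state exits freely). The search model wraps the core in
flanking states N and C that emit background residues, plus a begin
state B that can also go straight to the end state E — the "no
alignment" path, so the Forward score is a proper odds ratio over *all*
explanations of the target, with a floor of about −(log2 L + 1) bits at
the empty alignment. There is no multi-hit J state: multiple hits on a
target arise from multiple windows in the pipeline. One asymmetry is
deliberate: **Viterbi maximizes only over paths through the core**
(≥ 1 match emission). If the empty path competed in Viterbi, every null
target would score the identical empty-path constant and the
extreme-value calibration below would be degenerate.

**Length model.** The flank self-loop probability is set to L/(L+1),
exactly the null model's extension probability, so flank-emitted
residues are score-neutral and a profile whose emissions equal null1
can never accumulate positive score from length modeling alone. Scores
are reported in bits (log2 odds); recursions run in natural-log space
with an explicit −inf sentinel (reference implementations) or in scaled
linear space (compiled batch kernels), the two agreeing to < 1e-6 bits
in tests.

## The pipeline

Per query × target × strand (minus strand via reverse complement, with
coordinates mapped back to the plus strand):

1. **SSV** ("single segment ungapped Viterbi"): for every diagonal, the
   maximal-scoring contiguous run of match log-odds cells, with no
   transition or entry/exit terms. Targets are scanned in 256 kb chunks
   with 2M overlap (no seed can be lost at a join; verified by test).
   Seeds must clear the score at the p_ssv = 0.02 tail of the SSV null
   Gumbel.
2. **Windows**: seeds padded by 2M each side, overlapping/adjacent
   windows merged — so each candidate region is scored once and at most
   one hit is reported per window.
3. **Viterbi filter**: windows with gapped-Viterbi P-value above
   p_vit = 1e-3 are dropped.
4. **Forward/Backward**: survivors are rescored by Forward; the
   composition bias (below) is subtracted; windows with corrected
   P-value above p_fwd = 1e-5 are dropped.
5. **Hit construction**: posterior decoding gives the envelope (the
   smallest interval holding every position with aligned-state
   posterior ≥ 0.1, always extended to contain the Viterbi alignment)
   and the 0–9/`*` confidence line; the displayed alignment is the
   Viterbi traceback.

Setting every threshold to 1 (`--max`) disables filtering: the target
is covered with overlapping windows of the calibration length and every
window is Forward-scored. Window length matters here: per-window score
statistics match the calibration targets only when the windows have
comparable length, and with calibration-length windows the expected
number of reported null hits at E ≤ e is ≈ e.

**Composition bias (null2).** The alignment-specific null emission is
the posterior-usage-weighted mixture of the emitting states'
distributions; the bias is the non-negative total log-odds of the
aligned residues (positions with aligned posterior ≥ 0.1) under null2
versus null1, subtracted from the Forward score. With insert emissions
pinned to null1, only match-state usage can create bias.

## Score statistics and E-values

Calibration simulates n i.i.d. null1 targets of length L (defaults
n = 200, L = 10^4, seed 42) and records per-target best SSV score, best
Viterbi score, and the Forward score. SSV and Viterbi get maximum-
likelihood Gumbel fits. The Forward null needs more care: its upper
tail is modeled as base-2 exponential with slope fixed at 1/bit,
anchored at the empirical (1 − 0.04) quantile τ, but the bulk below τ
is kept *empirically*, as a 49-point quantile grid interpolated at
query time. The measured Forward null bulk is strongly compressed and
non-exponential (interquartile range ~0.15 bits against a tail that
decays over bits); extrapolating the tail law below its anchor
overstates the rarity of ordinary scores roughly ten-fold, which would
wreck the calibration of weak E-values. The grid is serialized with the
profile (CALIBQ line), so every written profile is self-contained.

P-values are per calibration-length target; E = P·(residues searched /
calib_L), with both strands counted. The rescaling is linear, with no
finite-length edge correction — adequate when windows are much longer
than the model, and a documented limitation otherwise. Filter
thresholds are P-value cutoffs on these same fitted distributions.

Self-consistency, verified in the acceptance tests: over seeded null
searches of calibration-length targets with filters open, the mean
number of hits at E ≤ 1 sits in the 3σ Poisson band [0.4, 1.6], and
held-out null Forward P-values pass a Kolmogorov–Smirnov uniformity
check at α = 0.01.

## The synthetic benchmark

The benchmark reproduces the structure of identity-split embedded-decoy
evaluations used for remote DNA/RNA homology search: families are split
so that no query-group sequence is > 60% identical to any test-group
sequence; test sequences are embedded at random positions and strands
in decoy sequence sampled from a 15-state background HMM trained by
Baum–Welch; hits from all families are pooled, ranked by E-value and
swept into a sensitivity versus false-positives-per-Mb-per-search
curve. A positive is an embedded instance with > 50% of its length
covered by a same-family hit; a false positive is a hit with > 50% of
its span in decoy; hits mostly covering an instance of a *different*
family are ignored. Three modes are compared: one profile per family,
one consensus-sequence query per family, and family-pairwise (fpw) —
every query-group member searched separately with overlapping hits
adjudicated by best E-value. For fpw the per-search normalization
counts each member search.

**The family simulator.** Families evolve an ancestral sequence
(length log-uniform on [80, 400]; real family lengths are
right-skewed) along a random coalescent topology, with per-edge
substitution probability 0.35 modulated by gamma-distributed per-site
rates (shape 0.5) and ~1% indels per site per lineage; insertions are
placed on terminal branches. Site-rate heterogeneity is essential, not
cosmetic: real families have conserved cores, and those conserved
blocks are precisely what an ungapped seed filter keys on — with
uniform rates nothing clears the seed stage and no method detects
anything. The defaults put cross-group identity mostly in the 40–60%
band (the remote-homology regime the 60% split presumes), with ≥ 2/3 of
simulated families splittable; they were fixed from these
generator-level measurements. Families default to 6 sequences (~3
query + ~3 test after the split).

**A caveat on the baselines.** Under this generator the expected
qualitative result splits: profile search dominates both
single-sequence baselines by a wide margin on every seed tested, but
the consensus baseline edges out family-pairwise search more often
than not, whereas on real-family benchmarks fpw is usually the
stronger single-sequence method. The mechanism is understood: with
symmetric divergence and family-wide shared site rates, the
majority-rule consensus is an excellent ancestor estimate — right at
exactly the intermediate-conservation sites that carry score — and
max-over-members cannot beat that denoising (the best member is
*closer by overall identity* to most test instances, and the effect
persists at larger family sizes, so it is not a sampling artifact).
Real families break this symmetry through subfamily-specific
conservation and biased member sampling, which the simulator does not
model; the fpw-versus-consensus margin should therefore not be read as
transferable.

What the simulator does **not** emulate: real transposable-element
length and copy-number distributions, nested or fragmented insertions,
genomic isochore/composition structure (the trained background is
nearly homogeneous because its training corpus is simulated), soft-
masked repeats, and sequencing artifacts. Passing benchmarks here shows
the engine implements the method correctly and that the expected
qualitative ordering (profile ≥ fpw ≥ consensus) emerges under
controlled remote homology — not that any particular sensitivity number
transfers to a real genome.

**Scale.** The benchmark defaults to 20 families in 2 Mb of decoy
(roughly a fifth of the classic protocol's decoy size), with per-query
calibration at n = 100, L = 2000 inside the benchmark harness; the
linear length rescaling of P-values makes the shorter calibration
statistically equivalent for ranking. These sizes keep a full
five-seed, three-mode sweep around ten minutes on one CPU.

## Numerical and engineering notes

- Degenerate IUPAC target residues score as the background-weighted
  average over compatible bases, ln(Σe) − ln(Σf), computed from a
  16-slot bitmask-indexed table; `N` scores exactly 0.
- DP equality tolerances: 1e-9 bits against the enumeration oracle
  (Forward/Viterbi/SSV), 1e-6 for Forward-vs-Backward and posteriors
  (double-precision accumulation over window-scale lengths).
- The brute-force oracle enumerates every legal state path (guarded to
  M ≤ 6, L ≤ 8) and is the reference for Forward sums, Viterbi maxima
  and posterior state frequencies.
- Compiled kernels (numba): diagonal SSV with a 4-way interleaved
  Kadane recurrence (the scalar recurrence is latency-bound), plus
  Viterbi/Forward batch kernels laid out transposed so the inner loop
  runs over independent calibration targets. All kernels are asserted
  equal to the numpy log-space reference implementations.
- The pipeline's seeding scan runs in single precision (float32 scores;
  threshold comparisons only); all reported scores come from the
  double-precision Forward/Backward stage.
- Ties: consensus residues break alphabetically; equal-scoring hits
  rank by (E-value, −score, target, strand, start), making tabular
  output byte-deterministic.
- Degenerate inputs: empty targets return the empty-alignment score;
  an all-gap alignment column set raises a "no consensus columns"
  error; profiles must be calibrated before search (explicit error
  otherwise).

## Known limitations

- Uni-hit per window: two instances closer than ~2M merge into one
  window and only the better-scoring one is reported.
- The Viterbi filter's Gumbel is calibrated on full-length calibration
  targets but applied to shorter windows; this is slightly
  conservative for true hits near the threshold.
- E-value accuracy far in the tail (E ≪ 1e-6) rests on the fixed
  1 bit⁻¹ tail slope; the measured tail near the anchor decays faster
  (~2 bit⁻¹), so deep-tail E-values are conservative.
- No soft-masking semantics: lowercase input is uppercased.
- No Dirichlet-mixture priors or entropy weighting; profiles from very
  deep alignments may be under-smoothed relative to hmmbuild-style
  construction.
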