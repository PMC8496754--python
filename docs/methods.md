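# Methods

## Problem

A steady-state visual evoked potential (SSVEP) speller presents `N` stimuli
flickering at distinct frequencies; attending to one imprints its frequency
and harmonics on occipital EEG. Classification must pick the attended target
from a short multichannel window, balancing accuracy against selection time.
Conventional pipelines commit to one frequency-recognition method, one
electrode montage and one window length, all of which are usually tuned
offline per user. This package implements an unsupervised alternative: many
(method, electrode-subset) classifications vote, and the analysis window
grows until the vote is decisive.

## Vote features

For an electrode pool `E` with `Ne` elements and a scorer `Φ`, the exact
feature for target `i` is the fraction of the `2^Ne − 1` non-empty subsets
of `E` whose argmax classification is `i`:

    ψ_i(Φ, E) = |E_i^Φ| / (2^Ne − 1),        Σ_i ψ_i = 1.

`enumerate_votes_exact` computes this for pools of ≤ 12 electrodes and is
the oracle against which the estimator is tested. For the default
21-electrode occipital/parietal pool enumerating the power set is
infeasible, so `R` subsets are drawn uniformly from the non-empty power set
(each electrode included independently with probability 1/2, empty draws
redrawn; draws with replacement). Subset cardinality is then
Binomial(21, 1/2): mean 10.5, variance 5.25 — a distributional fact the
tests check on the sampler. With `K` scorers voting over the *same* subset
sample, the combined per-target feature is

    ψ_i = ‖(share_i^1, …, share_i^K)‖₂ / K  ≤ 1/√K,

reaching the bound exactly at unanimity. Because the Euclidean version is
bounded by `1/√K` rather than 1, an `l1` variant (the mean share, range
[0, 1]) is exposed as a config option; the Euclidean form is the default.
Note the consequence, verified in tests: with `K = 3` a threshold of 0.5 is
only cleared near unanimity (`1/√3 ≈ 0.577`), and thresholds above `1/√K`
are unreachable, in which case the classifier always runs to the maximum
window.

## Dynamic window length

Windows start at stimulation onset (no response-latency offset is applied)
and extend from 0.7 s to 2.1 s in 0.1 s steps — 15 lengths; seconds convert
to samples as `round(L·fs)`, so every step is exactly 25 samples at 250 Hz.
Thresholds `τ[j]` descend equidistantly from `τ_max` (shortest window) to
`τ_min` (longest); `τ_min = τ_max = 0.5` is the no-tuning majority setting.
At each length the vote matrix is re-tallied from zero over the same subset
sample, and the classifier stops when `max_i ψ_i > τ[j]` (strictly greater;
equality extends the window). If the longest window still fails, the leading
target is returned anyway (`stopped_by = "max_window"`). Argmax ties break
to the lowest target index. Identical seeds give bit-identical vote counts.

Resetting the vote matrix at each extension (rather than accumulating
counts across extensions and renormalizing) keeps rows summing to `R` and
ψ inside its stated bounds; accumulation would mix normalized and raw
counts across passes.

## Scorers

All four scorers consume a `channels × samples` window and one target's
harmonic reference matrix (phase-free sin/cos pairs, harmonics `1…Nh`);
references are rebuilt per window length.

* **CCA** — largest canonical correlation between channel combinations and
  reference combinations. Defaults: `Nh = 3`, no band-pass.
* **FBCCA** — `Σ_{i=1..7} (i^−1.25 + 0.25)·ρ_i²` with `ρ_i` the CCA score
  on the `[8i, 88]` Hz band-passed window; `Nh = 5`. Only the EEG is
  sub-band filtered; references are unchanged.
* **MSI** — S-estimator: `S = 1 + Σ λ̄_k log λ̄_k / log P` over the
  normalized eigenvalues of the whitened joint correlation matrix of
  `[window; reference]` (`P` = joint dimension). `S = 1` for perfect
  synchronization, `S → 0` for independence. Defaults: `Nh = 3`, band-pass
  [0.5, 50] Hz (upper corner at 50 Hz keeps the third harmonic of 15.8 Hz).
  The delay-embedding parameter of some formulations is not used; the
  no-delay joint-correlation form is implemented.
* **MEC** — minimum energy combination. The reference subspace is projected
  out of the (mean-removed, unfiltered) channels; the residual energy matrix
  is eigen-decomposed and the smallest-eigenvalue combinations holding at
  most 10% of residual energy are kept (at least one), weighted `1/√λ`.
  The test statistic averages, over kept virtual channels and harmonics,
  signal power at the harmonic over an AR noise floor fit to the residual
  virtual channels by Burg recursion (order 15). A numerically zero residual
  (noiseless data) maps to a documented cap of `1e9`.

Numerical choices: zero-phase forward–backward Butterworth order 4 for all
band-passes (corner frequencies are the configuration; family/order is this
package's choice); ridge `ε = 1e−8·trace/dim` on every covariance or
correlation block before Cholesky whitening; windows are mean-removed per
channel. Per-subset scoring factors all per-window quantities (reference
bases, Gram matrices, their projections) out of the inner loop, so a subset
costs a few small Cholesky/eigen solves; the Burg recursion is batched
across all virtual channels of all targets. `statsmodels`' Burg estimator
serves as an independent oracle in the tests, never as the implementation.

The stimulus phases carried by the grid are used only by the synthetic
generator: all four scorers are phase-invariant by construction, so
references are phase-free.

## Evaluation

Accuracy counts every trial, including max-window fallbacks. ITR follows
the Wolpaw formula with `0 log 0 = 0`; selection time `T` is the mean
stopping window plus the 0.5 s pre-stimulation interval. When a participant
breakdown is supplied, per-participant ITRs (each from that participant's
accuracy and mean window) are averaged, and the pooled ITR is reported
alongside — the two differ in general because ITR is nonlinear in accuracy.
Fixed-window single-method baselines (`baseline_fixed_window`) use the
conventional posterior electrode sets per method (MEC: P3, Pz, P4-adjacent
six; MSI: eight; FBCCA: nine including POz) and enable ensemble-vs-baseline
comparisons on identical epochs.

## Synthetic sessions

The generator emulates the structure of 40-target benchmark recordings:
frequencies 8.0–15.8 Hz in 0.2 Hz steps, phases cycling 0, π/2, π, 3π/2,
250 Hz sampling, 64-channel montage, a 0.5 s noise-only pre-stimulation
interval, and `N × blocks` trials with every target appearing once per
block. From onset, channel `c` carries
`g_c · Σ_h A_h sin(2π h f t + h φ)` with gains peaked over O (1.0), CB
(0.85), PO (0.7) and P (0.45) sites and harmonic amplitudes (1.0, 0.5,
0.25) over three harmonics. Noise is per-channel 1/f ("pink") plus a
spatially common-mode pink component (half the pink power) and, in the
default `mixed` model, a 20% white component; the common-mode term makes
some channel subsets genuinely better than others, which the voting scheme
requires to be non-trivial. The requested SNR (dB) is realized exactly as
signal power over noise power on the occipital channels during stimulation;
`estimate_snr_db` verifies delivery by harmonic-subspace projection
(±1 dB in tests). Default trial length is 3.0 s (0.5 s pre-stimulus +
2.5 s), enough for the full window schedule.

What the generator does **not** contain — and therefore what passing tests
do not show about real EEG: no alpha rhythm or other narrowband background
activity, no artifacts, no head-model mixing, no inter-subject variability,
and harmonic structure stops at three harmonics. One concrete consequence,
measured here: the multi-sub-band advantage of FBCCA over a single
full-range sub-band does not materialize on this generator (sub-bands above
~48 Hz carry no signal, and there is no alpha-band contamination to filter
away), so FBCCA's seven-band score trails its own one-band reduction at
every SNR probed. On real recordings the ordering is the reverse; tests
therefore assert the ranking-equivalence of one-band FBCCA with CCA and
planted-target recovery rather than a synthetic head-to-head.

## Problem sizes and defaults used in checks

The end-to-end recovery check runs the three-method ensemble (MEC, MSI,
FBCCA) with `R = 50` on an 80-trial (+10 dB, 2-block) session under the
majority schedule; sampling-density robustness compares `R = 512` against
`R = 50` with CCA-only voting on 50 fixed-seed trials at −12 dB (the claim
concerns vote-sampling density, not the scorer mix); the exact-vs-sampled
comparison uses a 4-electrode pool where full enumeration is feasible.
Subset-sampling statistics use 10⁵ draws.

## Known limitations

* `R = 512` with `K = 3` is computationally heavy in pure Python/NumPy;
  the defaults are exact but the robustness result above justifies `R = 50`
  for interactive use.
* The MEC noise floor assumes the AR spectrum evaluated at the harmonic is
  a good local noise estimate; very short windows (< 0.7 s) make the Burg
  fit unstable and are outside the schedule by construction.
* The benchmark loader maps unlabeled 64-channel containers onto the
  standard extended 10-10 montage ordering; containers with other channel
  counts must embed labels (the fixture writer always does).
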