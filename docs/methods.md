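# Methods

## Model

`narxid` identifies multiple-input single-output NARX systems. For output
molecule *p* with input set M_p,

    y_k = Σ_{i=1..m_y} a_i y_{k−i}
        + Σ_{q ∈ M_p} Σ_{j=1..m_u} b_j^q f(u^q_{k−j}; n_q, K_q),
    f(u; n, K) = u^n / (u^n + K^n),

on a uniform time grid of step `dt` minutes, with all series min–max
normalized to [0, 1] per molecule (pooled across stimulation conditions so
relative amplitudes between conditions — which the gain analysis needs —
are preserved). The Hill stage carries the dose–response sensitivity
(graded at n ≈ 1, switch-like at large n; K is the EC50 on the normalized
scale); the linear ARX stage carries the dynamics (gain and time constant).
Simulations set the output to 0 before time 0. The model assumes no
synergy between inputs (transformed inputs enter additively) and a
time-invariant system across the experiment.

## Unequally spaced data as a missing-data problem

Measurements arrive as long-format records, one time list per (molecule,
condition). On the common grid (step = GCD of observed times by default),
each series is a masked array: observed entries are equality constraints,
everything else is missing. Missing entries are initialized by carrying the
previous observation forward (entries before the first observation take its
value: the pre-stimulus baseline is the first measurement). No other
interpolation is ever used — recovery is driven by the model structure, not
by smoothness assumptions.

## Signal recovery (IPMS)

If the data obey the ARX law noiselessly, the vertically condition-stacked,
horizontally concatenated Hankel-like matrix [Y U₁ … U_L] of width c has
rank m_y + L·c. Recovery completes the matrix at minimal rank subject to
the observed entries, via an iterative-partial-matrix-shrinkage scheme: for
a rank cap r = 1, 2, …, alternate (1) SVD, (2) truncation to the r leading
singular values, (3) re-imposition of the Hankel structure by averaging all
cells that hold the same grid value, (4) exact re-imposition of observed
entries, until the partial nuclear norm (the tail singular-value sum)
stalls. Each stage restarts from the carried-forward initialization; a
too-small cap otherwise drags the free entries into a spurious fixed point
that poisons later stages.

A stage is accepted when either

* the tail collapses below 1e−6 of the total nuclear norm — an exact
  structured completion exists at rank r (noiseless data); or
* `recovery_noise` > 0 and the rank-r truncation reproduces the observed
  entries to RMS ≤ `recovery_noise` — the completion explains the data to
  within the assumed measurement noise.

`recovery_noise` is the package's one data-quality parameter: the expected
observation noise SD on the normalized scale (rule of thumb: noise SD ÷
dynamic range; 0 demands exactness). The accepted cap doubles as the rank
estimate, from which the output lag order is m_y = clip(rank − L·c, 1,
`m_max`); with real transient inputs the inputs themselves are nearly
low-rank, so the accepted rank reflects signal complexity rather than the
idealized m_y + L·c law, and the clip keeps the lag order in the
biologically sensible 1–`m_max` range (default `m_max` = 3).

Two pieces of domain knowledge are built into the iteration: transformed
input blocks are box-projected to [0, 1] (a Hill output cannot leave that
range — without this the completion invents excursions > 1 at unobserved
transient peaks), and ARX coefficients are read from the *denoised*
low-rank matrix (the truncation before the final data re-imposition);
regressing on series with noisy observations re-imposed visibly attenuates
the autoregressive coefficients and biases the gain.

Known limitation: a missing input sample later than the last output
observation is structurally unconstrained (no equation pins it), and
clustered missing runs can make the completion non-unique. Sampling designs
should observe the endpoints and avoid long gaps in both tiers at once.

## Parameter estimation

Identification runs `restarts` independent restarts. Each restart:

1. draws initial Hill parameters (n = 1, K^n ~ U(0, 1]) per input,
   transforms the observed inputs, and recovers all series by IPMS;
2. reads the ARX coefficients and lag order off the recovered matrix;
3. refines (n, K): the recovered transformed inputs are mapped back through
   the inverse Hill function, `inner_combos` candidate pairs are drawn
   (n ~ U(1, 100], K^n ~ U[0.001, 1]), each candidate is scored by the
   free-running simulation RSS at the observed output points with its own
   least-squares ARX refit, and the best candidate is polished by a local
   Nelder–Mead descent in (n, log K^n) within the sampling box; the winner
   re-recovers the data and the coefficients are re-extracted. This step
   can repeat (`iv_cycles`, default 2) so the scoring uses a recovery
   produced under an increasingly apt transform; the full-scale preset
   keeps a single cycle and relies on restart volume instead;
4. polishes (a, b) by a Gauss–Newton pass on the free-run residual (the
   quantity AIC actually scores), accepted only if it improves the residual
   and keeps every pole's time constant within the record length;
5. computes AIC = n·ln(RSS/n) + 2·k on the observed training points only
   (k = m_y + L·m_u + 2L; recovered points are never scored).

The restart with minimal AIC wins, with a plausibility preference applied
first: restarts whose AR poles alternate in sign or decay slower than the
record, or whose transformed inputs barely vary over the data (an
unexcited channel with unidentifiable gain), lose to plausible ones
regardless of AIC and are used only if nothing better exists. These gates
address aliasing and excitation — classic identifiability failures that
sparse sampling invites — not goodness of fit.

Everything is a pure function of (data, config, master seed): per-restart
random streams are derived from the seed and a position-based path, so
results are independent of execution order.

## Input-set selection

For each candidate subset and each held-out stimulation condition, the
model is trained on the remaining conditions; the held-out condition's
*inputs* are then recovered with the training rows frozen while its output
stays entirely unobserved in the matrix (its observations are reserved for
scoring), the trained model simulates the held-out output, and the residual
sum of squares at the observed output points accumulates into RSS_LOO.
All non-empty subsets are enumerated (the motivating study's pools give
452 combinations over ten outputs). Selection applies the
one-standard-error rule: the smallest subset (ties lexicographic) whose
RSS_LOO is within one standard error of the minimum, the SE being
estimated from the minimizer's fold spread. Plain argmin systematically
rewards supersets whose extra channels absorb recovery error without
predictive substance; the outright minimizer is reported alongside. The
chosen subset is refit on all conditions to yield the final model.

## Gain and time constant

Per input channel, G(z) = (Σ_j b_j z^−j) / (1 − Σ_i a_i z^−i). The
steady-state gain is |G(1)| = |Σb| / |1 − Σa|. Frequency curves are scanned
over ω ∈ [1e−6, 1e2] rad/min (2000 log-spaced points, bisection-refined to
relative 1e−6); the cutoff is the first ω where the gain falls to
`cutoff_fraction` of the steady-state gain, and τ = 1/(2π f_cutoff).
`cutoff_fraction` defaults to 1/√2 (the −3 dB point); the alternative
reading 1/2 is config-selectable, as the source text of the motivating
study is ambiguous between the two. Two frequency conventions are
provided: `"substitution"` (default) plugs z → iω directly into G — the
form used to produce the study's printed time constants — and
`"discrete"` uses the standard z → exp(iω·dt). Note that under the
substitution convention the ω → 0 limit of |G(iω)| is *not* the
steady-state gain (ω → 0 sends z → 0, not 1); the low-frequency/DC
consistency property holds only under the discrete convention, which is
why the curves and the printed gain column are computed by different
formulas. Channels whose gain never crosses the threshold in the scanned
band report τ as undefined; Σa = 1 flags an integrator with infinite gain.

## Cascaded simulation

Identified models compose by topological order: each model's inputs are
root series, upstream outputs, or user-supplied overrides (measured or
recovered series substituted for simulated intermediates — used to
localize which stage of a cascade fails to predict a perturbation).
`ablate` zeroes named root inputs before simulation, the in-silico
analogue of a pathway inhibitor: descendants reachable only through the
ablated root go exactly to zero.

## Synthetic studies

The generator emulates the motivating experiments: transient root inputs
t·e^{1−t/τ} (peak 1 at t = τ, τ ~ U[10, 30] min, signaling-like) and
sustained inputs 1 − e^{−t/τ} (τ ~ U[30, 90] min); three stimulation
conditions with comparable amplitudes (scalings 1.0 / 0.85 / 0.7) but
distinct kinetics (waveform-τ multipliers 1.0 / 1.8 / 0.6, overridable per
root) — mirroring stimuli that act through different pathways and evoke
different temporal patterns rather than scaled copies; stable first-order
(optionally second-order) ARX stages with poles in [0.5, 0.9] per step and
steady-state gains in [0.5, 2]; Hill parameters n ~ U[1.5, 8],
K ~ U[0.2, 0.8]; additive Gaussian observation noise (σ = 0.01 default)
floored at 0. The study-like sampling design observes fast species every
5 min through the first hour then sparsely to 720 min, and slow species at
60–120 min intervals.

What the generator does not emulate: replicate-to-replicate biological
variability (noise is i.i.d. Gaussian on a normalized scale),
non-stationarity of the system over the experiment, synergy between
inputs, and measurement-specific distortions (antibody saturation, PCR
efficiency). Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to violations
of them.

## Benchmark problem sizes and known limits

The benchmark suite (`narxid.benchmarks`, driven by `scripts/acceptance.py`
and the acceptance tests) uses scaled problems chosen to exercise the full
pipeline on one CPU: a 0–480 min grid at 20-min steps (N = 25), three
conditions, inputs observed densely through the transient and outputs
every 60 min, 20 restarts with 200 draws × 2 refinement cycles for gain
recovery (30 systems, enough to estimate the median of a long-tailed error
distribution stably), and 20 restarts with 50 draws × 2 cycles for the 20
two-candidate selection replicates. The full-scale configuration (500
restarts × 200 draws, single cycle) is the `full` preset.

Known estimation limits, visible in the benchmarks: systems whose true
K^n falls below the search floor of 0.001 (strongly switch-like with small
EC50) cannot be represented exactly by any searched candidate; the
steady-state gain extrapolates beyond the largest transformed-input value
the data reach, so Hill mis-estimation trades off against gain; and with
sparse output sampling the within-interval dynamics are aliased — the
plausibility gates above are what keep these cases from dominating.
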