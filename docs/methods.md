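# Methods

## The model

All analyses in this package are built on the recurrence plot. Given a
sequence of phase-space states V_1 … V_n, the plot marks the pairs of time
indices whose states lie within a threshold distance of each other:

    RP_ij = Θ(T − ‖V_i − V_j‖),

with Θ the Heaviside step (Θ(0) = 1, so a distance exactly equal to T
counts as recurrent) and ‖·‖ the Euclidean norm throughout. The state
sequence can come from four places, giving the four plot kinds:

- **auto**: a single trajectory, classically reconstructed from one
  observable x by time-delay embedding, V_i = (x_i, x_{i+τ}, …,
  x_{i+(D−1)τ}) — there are n − (D−1)τ such vectors;
- **cross**: two separately embedded trajectories, one indexing rows and
  one columns (generally rectangular, no line of identity);
- **joint**: the elementwise product of several individual auto plots —
  only coincident recurrences survive;
- **multidim**: a single phase space whose coordinates are N
  simultaneously measured channels, W_i = (y_{1,i}, …, y_{N,i}),
  optionally with each channel additionally delay-embedded m times for a
  total dimension D = N·m. "Embedded once" means one delayed copy per
  channel in addition to the original, i.e. m = 2 (three channels
  embedded once give D = 3·2 = 6). With N = 1 the multidimensional
  analysis reduces bit-exactly to classical single-channel RQA.

A plot is quantified through its diagonal line structure. Lines are
maximal runs of recurrent cells along diagonals; runs touching the matrix
border count (no edge correction). The four measures are

    RR  = recurrent cells / counted cells,
    DET = recurrent cells on lines of length ≥ ℓ_min / recurrent cells,
    ADL = mean line length,
    LDL = longest line length,

with ℓ_min = 2 by default (the classical convention; any smaller value
makes "diagonally adjacent" meaningless). Vertical-line measures
(laminarity, trapping time) and line-length entropy are deliberately out
of scope.

## Parameters that matter

- **Threshold T and its mode.** `absolute` applies T directly to the
  distances; `meanfrac` (the default) resolves T as a fraction of the
  mean off-diagonal distance of the plot's own distance matrix, which
  makes analyses of phase spaces with different scales or
  dimensionalities comparable. Both conventions are current in the
  field's published software, and reference analyses often mix them —
  the Lorenz benchmark bundled here uses absolute 0.1 for the
  single-channel plots and meanfrac 0.08 for the multidimensional plot,
  the combination under which the benchmark's recurrence rates and the
  multidimensional-to-joint RR ratio (~6) are reproduced together.
- **Theiler window w.** Cells with |i − j| < w are excluded from the cell
  counts and the line scan: w = 1 (default for auto/multidim/joint plots)
  masks exactly the line of identity, w = 0 (cross plots) masks nothing.
  RR's denominator also excludes masked cells, keeping RR comparable
  across window choices.
- **Embedding (m, τ) / (D, τ).** No automatic delay or dimension
  selection is provided (false-nearest-neighbour and mutual-information
  estimators are out of scope); the benchmarks fix D = 3, τ = 4 (Lorenz),
  D = 2, τ = 1 (van der Pol) and m = 2, τ = 6 (group signals).
- **z-scoring** is applied per channel, before embedding, with the
  sample standard deviation (n − 1 denominator); differences against the
  population convention are O(1/n) and below every test tolerance.

## Simulators and what they emulate

**Lorenz.** σ = 10, ρ = 28, β = 8/3, integrated with an adaptive
Runge-Kutta scheme at rtol = atol = 1e−9 and resampled on the grid
t = k·Δt, k = 0 … ⌊t_max/Δt⌋ − 1 (Δt = 0.0162, t_max = 20 → 1234
samples). The initial state defaults to (10, 10, 10), near the attractor,
so the analysed window is dominated by on-attractor dynamics; both the
initial state and an optional transient-discard length are parameters.
Note on solver independence: because the system is chaotic (largest
Lyapunov exponent ≈ 0.9), trajectories at t = 20 amplify any local
tolerance by ~e^18, so no tolerance makes the full window
solver-independent to 1e−6; that contract holds on short horizons
(t ≲ 3), and the recurrence measures at the benchmark settings are
insensitive to tolerance halving. Line-length statistics (ADL, LDL) are
the most trajectory-sensitive outputs: across plausible initial states
LDL varies by a factor of several while RR and DET barely move.

**Coupled van der Pol pair.** μ = 100 (strongly stiff relaxation
oscillators, period ≈ 1.61μ), asymmetric coupling ε₂ = 5ε₁, reduced to
four first-order states and integrated with LSODA; default window
t ∈ [0, 4000] sampled at Δt = 2 (n = 2000, ~25 periods), initial state
(2, 0, −2, 0). With these conditions the multidimensional RR correlates
with ε₁ at ~0.997 over a 10-point log-spaced sweep of [0.005, 0.05],
while the cross-recurrence RR is nearly flat — the signature that the
multidimensional plot sees the joint system where the cross plot sees
two individually periodic trajectories.

**Group signals.** Each member's channel is a unit-variance AR(1) drift
(autocorrelation time 50 samples — slow and drifting, the qualitative
character of tonic skin conductance) plus white measurement noise. The
member drifts are mixed through the symmetric PSD square root of the
requested coupling matrix, so the latent correlation matrix equals the
coupling matrix exactly (eigenvalue clipping handles the singular
all-ones case). What this fixture does **not** emulate: phasic
skin-conductance responses, nonstationary baselines, event-locked
structure, or any physiological nonlinearity. Passing tests therefore
show that the analysis pipeline recovers designed covariance structure,
not that it recovers real electrodermal dynamics.

**Team studies.** `gen_team_study` draws independent teams whose
outcome is tied either to the whole-team coupling ("group" design;
individual marginals identical across teams, so only multi-member
analyses carry outcome information) or to the members' drift timescale
("individual" design; the information already lives in single channels).
These designs are what give the multi-level regression something to
localize; 25 teams of 3 members × 300 samples keep a full sweep at a few
seconds per seed.

## Group-level scheme

Level k runs the multidimensional analysis on every k-member subset of a
team's channels and averages the four measures arithmetically (including
LDL) across the C(N, k) subsets; the averaging is invariant to channel
order. Per-team measures at a level are regressed on the outcome by OLS
with intercept, and the significance threshold on R² is obtained by
inverting the F statistic: R²* = pF*/(pF* + df_resid) at the α critical
value F*. For the reference design (4 predictors, 95 residual df,
α = 0.05) this gives R²* = 0.0941; the commonly quoted 0.096 for that
design does not match the standard F inversion (0.096 corresponds to
α ≈ 0.047) and the package reports the F-derived value. The threshold's
calibration is verified by Monte-Carlo null simulation.

## Dimensionality baseline correction

For independent unit-variance coordinates E‖Δ‖² = 2D exactly, so the RMS
inter-point distance is √(2D) and distances across dimensionalities are
related by L_D = √(L²_{D+n} − 2n). The law is implemented on RMS
distances, for which it is exact; the plain mean distance differs by a
D-dependent factor (≈18% for uniform variates at D = 1, <3% for D ≥ 3).
It holds equally when the added dimensions are separately measured
variables or time-delayed surrogates of one variable. Two correction
routes are provided: rescaling a threshold by √(D_to/D_from), and fixing
the recurrence rate via the empirical quantile of the off-diagonal
distance distribution (exact and deterministic, in place of an iterative
bisection). Limitations: √D rescaling preserves the distance *scale*, so
it approximately preserves RR only for thresholds comparable to the mean
distance; in the sparse-recurrence regime the D-dependence of the
distance distribution's lower tail dominates and no scalar rescaling can
preserve RR. The law also assumes independent dimensions — correlated
channels (the interesting case in practice) lower the effective
dimensionality and the correction is then conservative.

## Numerical choices

- Distances via `scipy.spatial.distance.cdist`; dense boolean matrices
  (an n = 5000 plot is 25 MB; above that, export via the sparse
  coordinate format).
- Recurrence at exact distance equality is included (Θ(0) = 1).
- Degenerate inputs: constant channels cannot be z-scored (error naming
  the channel); an all-zero distance matrix has no scale for `meanfrac`
  (error); plots with no recurrences or no lines report DET = ADL =
  LDL = 0 with a `no_lines` flag rather than NaN.
- Mean squared distances for large point sets are accumulated in row
  chunks (no n² matrix is materialized).
- RP export uses 1-based indices, upper triangle only for symmetric
  kinds, with a JSON sidecar carrying kind/threshold/window/shape so the
  round trip is lossless.
- All simulators are bit-reproducible given identical parameters and
  seed; the only randomness is NumPy's `default_rng` seeded explicitly.

## Problem sizes used in the test and validation suite

Lorenz benchmark n = 1234 (as specified by its window and sampling);
van der Pol sweep 10 couplings × n = 2000; scaling law n = 10⁴ per
dimension D = 1…10; null regression calibration 2000 Monte-Carlo fits of
a 100 × 4 design; team studies 20 seeds × 25 teams × 300 samples. These
sizes were chosen so the full suite completes in a couple of minutes
while keeping Monte-Carlo error well inside each test's assertion band.
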