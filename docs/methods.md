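# Methods

## The measurement

Each parcel's resting-state BOLD signal x_p(t) (time × parcels, repetition
time TR in seconds) is decomposed into intrinsic mode functions (IMFs) by
empirical mode decomposition (EMD), so no frequency band has to be prescribed
a priori: mode 0 is the fastest intrinsic oscillation (for slow BOLD
fluctuations, typically ~0.04–0.07 Hz) and mode 1 the next slower one
(~0.01–0.04 Hz). The instantaneous phase θ_p(t) of the selected mode comes
from the analytic signal (Hilbert transform). For a functional network *n*
the Kuramoto order parameter

    φ_n(t) = | ⟨ e^{iθ_p(t)} ⟩_{p∈n} |

is the instantaneous level of phase alignment; **sync** is its time mean and
**metastability** its standard deviation over time. An all-parcel "Global"
network is always appended to the labeled networks. The
**sync-metastability feature vector** concatenates all networks' sync values
followed by all metastability values in a fixed network order (14 networks →
28 dimensions). Static functional connectivity (FC), the classical
comparator, is the Fisher-z-transformed Pearson correlation matrix between
parcel time series, vectorized as the upper triangle.

## Trimming protocol

The first 60 s of each session are discarded before sifting (scan-start
transients), and 5 samples are trimmed from **each end of the phase series,
after the transform** (EMD/Hilbert end effects). A 10-min session at
TR 1.16 s (517 samples) therefore retains 517 − 51 − 10 = 456 samples
≈ 8.8 min. The static-FC comparator uses the raw series restricted to the
identical retained window, so both metric families see the same data.

## EMD sifting rules (frozen)

Sifting isolates one IMF by repeatedly subtracting the mean of the
cubic-spline envelopes through the local maxima and minima:

- stopping rule per mode: Cauchy-style criterion
  Σ(h_prev − h)² / Σ h_prev² < 0.2, capped at 100 sifts;
- envelope end effect: up to 2 extrema are mirror-reflected past each end
  before spline fitting;
- recursion stops when the residual has fewer than 4 extrema or when
  `max_imfs` (default 4; only modes 0 and 1 are consumed) is reached;
- a signal with fewer than 4 extrema is returned whole as the residual and
  flagged degenerate;
- completeness Σ IMFs + residual = input holds to round-off by construction
  and is asserted to 1e−8 relative in the tests.

Instantaneous frequency is the centered-difference derivative of the
unwrapped phase over 2π·TR (one-sided at the ends). Because no EMD
implementation ships with the supported numerical stack, the sifter is part
of this package; its behavior is pinned by closed-form tone and two-tone
oracles (tone frequency recovered to <1%, two tones separated into modes 0
and 1 within 15%).

## Split-half reliability engine

Sessions are split into two disjoint halves A and B; uniqueness of the
unordered partition is enforced across iterations. The baseline vector is
computed from the concatenated phase time courses of all of A's sessions.
For each duration level k = 1 … |B|, k sessions are drawn **fresh** from B
(without replacement, independently per duration within an iteration — the
protocol's "select one complete session; for two increments, select two"
reading), the test vector is computed from their concatenation, and
similarity to baseline is recorded: Pearson correlation for vector metrics
(FC, sync, metastability, combined), and the normalized absolute error
1 − |test − baseline| / baseline for single-network scalars (correlation is
undefined for scalars; negative values are possible and not clipped). Per
duration, the mean, population SD, and a normal-approximation 95% CI of the
mean (mean ± 1.96·SD/√n_iter) are reported.

Because φ_n(t) is instantaneous, concatenation needs no cross-session phase
continuity, and pooled means/SDs follow exactly from per-session moment
sums (Σφ, Σφ², n); pooled FC likewise from per-session column sums and
cross-product matrices. The tests assert this cached pooling equals direct
computation on explicit concatenations to 1e−9 or better. Departure from
baseline for state-change designs is 1 − Pearson r between a session's
feature vector and a reference session's (0 identical, 1 uncorrelated,
2 anti-correlated). Long sessions can be cut into equal contiguous
sub-sessions (e.g., 30 min → 3 × 10 min) before splitting.

No multiple-comparison correction is applied across networks: the profiles
characterize data-quantity requirements per network, not hypothesis tests
between networks.

## Surrogate null

Phase-randomized surrogates keep each parcel's full amplitude spectrum
(hence its autocorrelation) while drawing uniform random Fourier phases
**independently per parcel** — deliberately the coupling-destroying variant,
not the shared-phase-vector variant that preserves cross-correlations. DC
and (for even lengths) the Nyquist bin are untouched so the inverse
transform is exactly real. Per session, `n_surrogates` realizations are
defined and `pick` of them (default 1) are selected at random and pushed
through the full phase→metric pipeline, giving one matched null sample per
session. Comparison statistics: classic pooled-variance two-sample t
(df = n₁+n₂−2; Welch available by flag), Mann–Whitney U, and Cohen's d with
pooled sample-variance SD. Metastability uses population SD (ddof 0, the
Kuramoto-literature convention); Cohen's d uses sample variances (ddof 1,
the standard definition).

## Synthetic cohorts: what they emulate, and what they don't

The generator produces multi-session cohorts of community-coupled Kuramoto
phase oscillators:

    dθ_p = ω_p dt + (K_n/|n|) Σ_{q∈n} sin(θ_q − θ_p) dt + σ_φ dW_p,

observed as cos(θ_p(t)) plus additive Gaussian noise. Natural frequencies
ω_p are drawn once per configuration (2π × uniform over 0.01–0.07 Hz by
default) — a "subject" keeps its intrinsic dynamics across sessions — while
each session restarts from fresh random phases, like independent scan runs.
A linear-null generator (independent band-limited Gaussian processes per
parcel, one child seed per parcel) provides coupling-free data with the
same spectral occupancy.

Numerical choices:

- **Integration step.** Euler–Maruyama at tr/10, refined to dt ≤ 0.2/K_max
  under strong coupling: explicit Euler requires K·dt ≪ 1, and at K = 50 a
  tr/10 step turns the locked state into numerical jitter.
- **Observation noise color.** Noise is low-passed at 0.1 Hz by default
  (white available via `noise_cutoff_hz=None`). Parcel-averaged,
  preprocessed BOLD carries negligible power above ~0.1 Hz; white noise at
  TR sampling is unrealistic *and* triggers EMD's well-known intermittency
  artifact, splitting one oscillation across two modes.
- **Moderate coupling K_mid = 0.1.** For ω ~ U(2π·0.03, 2π·0.07) the
  mean-field critical coupling is K_c = 4γ/π ≈ 0.16 (γ = half-width); just
  below K_c the network is partially synchronized and order-parameter
  fluctuations — metastability — are maximal. K = 0 and K = 50 bracket this
  with independence and rigid locking.
- **Phase noise** σ_φ = 0.05 rad·s^(−1/2): enough Brownian jitter that
  sessions of one subject differ beyond their initial conditions, small
  enough not to wash out the coupling structure.

Not modeled, deliberately: hemodynamic response convolution, scanner noise
models, motion, and population (between-subject) variability. Passing tests
on these cohorts therefore show that the *pipeline* recovers known phase
structure, trims correctly, and orders metric reliabilities as claimed;
they do not certify effect sizes on real BOLD data, whose noise and
nonstationarity are richer.

## Problem sizes

Validation runs use desk-scale cohorts chosen to keep every experiment in
minutes while leaving Monte-Carlo margins interpretable: a 24-session ×
5-min stationary cohort (20 parcels, 2 networks, 100 split-half iterations)
for reliability; a 20-session strongly coupled cohort (12 parcels, K = 10)
plus 20 replicates of 8-session uncoupled cohorts for the surrogate
analysis; 20 seed replicates per coupling level for the recovery sweep. The
full-scale protocol (84 sessions × 10 min, 1,000 iterations, 333 parcels)
is a configuration change, not a code change.

## Known limitations

- EMD mode selection can fail on signals whose fastest component is not
  oscillatory (degenerate inputs raise rather than guess).
- The sifting stop rule and envelope boundary treatment are one reasonable
  freezing of EMD's free parameters; other implementations will differ in
  detail on identical data.
- The normal-approximation CI understates uncertainty below ~30 iterations;
  with a single iteration the CI is degenerate and flagged.
- Fisher z is clipped at |r| = 1 − 1e−15; inert for real data, it makes
  duplicated-signal edge cases finite.
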