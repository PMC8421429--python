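# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hopfbrain`, in the spirit of a model-documentation page: it
states how each quantity is defined and computed, not empirical results
(those are produced by the tests, the `analysis/` scripts and
`scripts/acceptance.py` at run time).

## Phase dynamics

**Band-pass.** Signals are demeaned per region and filtered with a
second-order Butterworth band-pass applied forward and backward
(`scipy.signal.filtfilt`; effective fourth order, zero phase). Zero-phase
filtering matters here because the instantaneous phases *are* the
downstream signal; a causal filter would shift them. Default band
0.04–0.07 Hz, where resting-state BOLD oscillatory power concentrates.
Series shorter than the filter settling length raise `ShortSeriesError`.

**Phases.** The analytic signal z(t) = s(t) + iH[s(t)] gives
ϕ(t) = arg z(t), wrapped to (−π, π]. All-zero rows have no phase and raise
`UndefinedPhaseError` rather than propagating NaNs. Because Hilbert and
filter transients contaminate the edges, `extract_phases` trims a fixed
margin (default 10 samples per end) before any phase statistic; the margin
is a free choice, documented here, and is not critical at 300 volumes.

**Phase interactions.** P_jk(t) = cos(ϕ_j − ϕ_k); since cosine is even
this equals cos(|ϕ_j − ϕ_k|). Computed as the sum of outer products of
cos ϕ and sin ϕ, which is exactly symmetric in floating point; the
diagonal is set to exactly 1 and entries are clipped to [−1, 1]. The
global synchrony r(t) is the mean of the strict upper triangle, and the
fluctuation statistic m is the *population* (ddof = 0) standard deviation
of r over the retained samples — the convention is arbitrary but fixed and
documented. A fast path computes r(t) through |Σ_j e^{iϕ_j}|² without
materializing the T×N×N tensor; the two routes agree to 1e−10 and are
cross-checked in the tests.

**Surrogates.** Phase-randomized surrogates keep each row's Fourier
amplitude spectrum and replace phases with i.i.d. uniform draws on the
half-spectrum, mirrored conjugate-symmetrically; the DC and (even-length)
Nyquist bins keep their sign. This guarantees a real-valued surrogate with
the amplitude spectrum preserved to numerical precision (checked at 1e−10
relative). The time-averaged ⟨P⟩ is bias-corrected by subtracting the
surrogate-ensemble mean of ⟨P⟩ computed through the identical analysis
chain. Surrogate seeds are `seed + i`, so an ensemble of one with a known
seed is exactly reproducible.

## Measures

**Integration** scans binarization thresholds 0 → 1 in steps of 0.01
(strict `entry > threshold`), takes the largest connected component's
relative size at each threshold (scipy's union-find), and averages over
the grid. 1 means the graph never fragments; 1/N means it always does.
The bias-corrected ⟨P⟩ is the default input.

**Segregation** binarizes pairs whose raw ⟨P⟩ exceeds the per-pair
(1 − α) quantile of the surrogate null (α = 0.01, which requires ≥ 100
surrogates to resolve), then maximizes Newman modularity with seeded
Louvain, best of 10 restarts (`networkx.community.louvain_communities`).
An edgeless binarized graph returns Q = 0 with a warning. Louvain is
validated against exhaustive partition enumeration on graphs of ≤ 10
nodes in the tests.

**FCD** averages P(t) over sliding windows of 30 TRs shifted by 1 TR
(normalizing by the window length), vectorizes strict upper triangles, and
fills an M×M cosine-similarity matrix. `mean_fcd` averages the strict
upper triangle; by default all window pairs are included, and an
`exclude_overlap` flag drops pairs sharing samples. The overlap
contribution is not recurrence — band-passed signals are autocorrelated
over ~10 samples, so overlapping windows of white noise already show
similarity ≈ 0.13 while the overlap-free mean is ≈ 0 — but the inclusive
default is kept because the windowing convention of the reference analyses
includes all pairs; both numbers are available.

**Pearson FC** is the Fisher-z transformed correlation matrix with the
diagonal masked; |r| is clipped at 1 − 1e−7 (z ≈ 8.1) so duplicated rows
stay finite, and zero-variance rows are flagged and returned as NaN.

## The simulator

The coupled Stuart–Landau SDE is integrated with a stochastic Heun scheme:
a predictor–corrector drift step plus additive complex Gaussian increments
of standard deviation β√dt per component (independent real and imaginary
parts), with β = 0.02 and dt = 0.1 s by default. Heun was chosen over
plain Euler–Maruyama because Euler's first-order treatment of the rotation
inflates the noise-free limit-cycle radius to r² ≈ a + dt·ω²/2 — a 2.7 %
amplitude error at a = 0.09, ω = 2π·0.05 — while the second-order drift
makes the √a amplitude exact to well under 1 % at the same step size
(verified against the closed form and by step-halving in the tests). A
60 s transient is discarded; the state is then sampled every tr/dt steps
(no averaging), and tr must be an integer multiple of dt. Trajectories
exceeding |z| = 10³ raise `InstabilityError` naming the step size.
Identical (spec, duration, tr, seed) give bit-identical output.

*Effective mode* re-parameterizes the same dynamics by
a_eff_j = a_j − gS_j with pure input coupling gΣC_jk z_k; the two forms
follow the identical computation path, so matched parameters give
bit-identical trajectories (asserted in the tests).

**Spectral estimators.** Power spectra are Welch periodograms with segment
length min(128, T/4). The power proportion p_j integrates the PSD over
0.04–0.07 Hz relative to 0.04–min(0.25, Nyquist) Hz on a fine grid
interpolated between the exact band edges (the same grid density for both
bands), which removes the dependence on how Welch bins straddle the edges:
white noise gives the flat-spectrum value 0.03/0.21 ≈ 0.143. Band-limiting
the signal before the PSD would attenuate the band edges (the numerator
band sits against the filter's lower cutoff) and bias p downward, so the
raw-PSD band integral is used instead. Intrinsic frequencies are per-node
Welch peak locations within the band, averaged across subjects, with a
band-centre fallback (and warning) for flat spectra.

## Fitting

**Global coupling.** For each g on a sorted grid (default 0–3, step 0.1; a
coarser 0.25 grid is used in the recovery experiments), the model is
simulated `trials` times with deterministic sub-seeds
(`numpy.random.SeedSequence(seed, spawn_key=(grid index, trial))`), each
run's FCD upper-triangle distribution is compared to the empirical one
with the two-sample KS statistic, and the per-g mean and standard error
are recorded. g_opt is the grid argmin; `numpy.nanargmin` ties break to
the smallest g, and grid points whose simulations fail are excluded with a
warning. Single 10-minute FCD distributions are noisy, so recovery is
accurate to about one grid step at 0.25 resolution.

**Local parameters.** Parallel gradient updates
a_j ← a_j + η(p_emp_j − p_sim_j) with η = 0.1, stopping when
max_j |p_emp_j − p_sim_j| < 0.01 or after `max_iter` iterations (the
mismatch typically plateaus at a stochastic floor above the tolerance at
desk scale; the result is returned with `converged=False` and the full
trace). Each iteration simulates with a fresh deterministic sub-seed to
avoid overfitting one noise path. The same estimator settings are forced
for p_emp and p_sim. The effective fit starts from the homogeneous line
a_eff = −gS unless the caller supplies its own starting point.

**Strength residuals.** Ordinary least squares of a_eff on node strength;
the reported summary is the median of the absolute residuals. In the
homogeneous model a_eff is exactly linear in strength, so this median
quantifies dynamically generated (rather than structurally imposed)
heterogeneity.

**Shuffle control.** Permuting a fitted a vector across nodes preserves
its value distribution but destroys its alignment with the network. The
effect on fit quality is only expected when the arrangement is structured
(e.g. strongly negative a on hubs); an i.i.d. random arrangement is
exchangeable, so shuffling it changes nothing on average — the control
experiment in the tests therefore uses a strength-aligned ground truth.

## Stability

At the silent fixed point z = 0 the cubic term has no linear contribution
and the conjugate sector decouples, so the linearization is the N×N
complex Jacobian A = diag(a − gS + iω) + gC (diag(a_eff + iω) + gC in
effective mode). Eigenvalues are sorted ascending by real part;
eigenvectors are unit-norm with the largest-magnitude component rotated
real-positive for reproducible reporting. Useful exact facts, all asserted
in the tests: the real row sums of A equal a (the strength term cancels
against the coupling row), Gershgorin discs centred at a_j − gS_j with
radius gS_j bound max Re λ ≤ max a_j, the g = 0 spectrum is {a_j + iω_j},
and ω = 0 with symmetric C gives a real spectrum.

## Structural graph analysis

Node strength is the row sum of the weight matrix; hubs are nodes with
strength strictly above a threshold. The conventional threshold 4.5 is
meaningful on the fibre-count-normalized scale of empirical connectomes;
synthetic desk-scale matrices use a threshold on their own strength scale
(the analyses here place it midway between the designated core and the
strongest peripheral node). The weighted k-density ρ(S′) scans S′ from 0
to S_max in steps of 0.2 by default, averaging off-diagonal weights among
nodes with S > S′; strengths are computed once on the full matrix (no
iterative re-pruning). At S′ = 0 all nodes are included, so ρ(0) is the
global mean off-diagonal weight; the curve is marked undefined (cutoff)
once fewer than two nodes survive. By default zero-weight pairs are
included in the average (a weighted density); a flag restricts the average
to existing links. Raw tractography-like matrices are prepared by
averaging with their transpose, zeroing the diagonal, dividing by total
weight, and optionally rescaling the maximum to exactly 0.2 (the model
scale that prevents full synchronization).

## Synthetic data

The core–periphery generator draws links independently with probability
min(1, density·f^h) and log-normal weights (σ = 0.75) boosted by f^h,
where f is the hub factor and h ∈ {0, 1, 2} the number of designated-hub
endpoints (nodes 0..n_hubs−1). Boosting degree and weight together makes
the hubs' strength advantage a sum over many links rather than a few lucky
draws, so with f ≥ 2 the designated hubs essentially always dominate and
the core forms a rich-club; f = 1 removes the structure. The desk-scale
study conditions used throughout (N = 40, 6 hubs, f = 3, density 0.08)
were chosen once so that (i) the strength distribution is long-tailed with
a clear rich-club, mimicking healthy tractography connectomes, and (ii)
the mean-FCD-vs-g curve rises smoothly across g ∈ [0, 3] without
saturating, keeping the coupling identifiable; denser or more uniform
matrices synchronize fully by g ≈ 1 and destroy identifiability. Lesions
are modelled as multiplicative attenuation of all hub-incident links,
keeping N fixed so groups share a parcellation.

Ground-truth BOLD comes from the simulator itself with ω drawn uniformly
in the band and a either homogeneous or uniform on an interval. What
passing tests on these data do show: the estimators recover the parameters
of the generating model under realistic noise, durations and network
scales, and the group-level contrasts move in the direction the model
predicts. What they do not show: robustness to haemodynamic convolution,
measurement noise spectra, head-motion artefacts, parcellation error or
inter-subject anatomical variability — none of which the generator
emulates.

## Problem sizes and defaults

Tests and analyses run at N = 40 (10 for unit fixtures) with 300 volumes
at TR = 2 s, the recording geometry of the emulated datasets; 214-region
runs are supported by the same code paths. The pipeline defaults freeze
the analysis constants: band 0.04–0.07 Hz, wide band 0.04–0.25 Hz, window
30 TRs, step 1 TR, β = 0.02, η = 0.1, α = 0.01, hub threshold 4.5, g grid
0–3. Recovery experiments use 5 simulation trials per grid point on a
0.25-step grid and 40–60 gradient iterations, sizes at which the recovery
targets are met with margin while a full suite completes in a few minutes.

## Known limitations

- BOLD is Real(z) with no haemodynamic (Balloon–Windkessel) convolution.
- Group outputs are descriptive means ± SE; no inferential statistics.
- The gradient fit matches band-power proportions, not the full spectrum;
  nodes whose p_emp is insensitive to a (deep in the damped regime) are
  weakly identified, which bounds the achievable rank correlation.
- The KS fit compares FCD value distributions, not their temporal order.
- k-density cutoffs and hub thresholds depend on the weight normalization;
  comparisons are only meaningful within one normalization.
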