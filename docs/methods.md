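# Methods

## Model

A receptor is an aggregated continuous-time Markov chain: states carry a
conductance class (open or shut), transitions carry first-order rate
constants, and agonist-binding transitions scale linearly with agonist
concentration. All builtin schemes are trees (no cycles), so detailed
balance holds for any rate values; the `detailed_balance_report` utility
verifies this and would report cycle products for user-defined cyclic
schemes. Two equivalent binding sites are modelled with the standard
stoichiometric factors — 2·k_on for the first binding and 2·k_off for
unbinding from the doubly bound state — configurable per edge, since
published scheme drawings rarely print them.

Two drawing ambiguities in the source schemes are resolved as star
topologies by default and are configurable: the second open state A2O′
attaches to the flipped state A2F (alternative: to A2O), and the second
desensitized state A2D′ attaches to A2F (alternative: to A2D).

Rates are stored in s⁻¹ (binding in M⁻¹s⁻¹) and concentrations in molar;
durations at the analysis API are milliseconds, converted internally. The
builtin schemes ship with placeholder rate values of realistic order
(`PLACEHOLDER_RATES`) so they are runnable out of the box; these are not
experimentally fitted values, and every fitting test generates its own
ground truth.

## Macroscopic simulation and descriptors

Concentration-jump responses propagate the state distribution through
each protocol segment with the matrix exponential of that segment's
generator; the simulated current is total open-state occupancy, and the
initial condition is the stationary distribution at the first segment's
concentration (restricted to the closed communicating class when binding
edges vanish at zero agonist). Optional solution-exchange smoothing
models the concentration as relaxing exponentially toward each segment's
target (150–300 μs is typical for excised patches, slower for lifted
cells); it is off by default so unit tests see ideal jumps.

Descriptors follow bench conventions. The peak is the global maximum
inside the application window; the desensitization fit
A_fast·e^(−t/τ_fast) + A_slow·e^(−t/τ_slow) + C starts at the first
sample after the peak on the peak-normalized trace, and percentages are
the fitted amplitudes renormalized to sum to one. FR10/FR300/FR500 are
read from the normalized **raw** trace at fixed times after the peak —
not from the fitted curve — because they are defined as fractions of
amplitude remaining in the data; on noiseless input the two agree to
within the fit residual. The onset is summarized by the 10–90% rise time
from interpolated level crossings. Deactivation after washout is fitted
with one or two exponentials, the pair accepted when an F-test on the
residual sums of squares rejects the single exponential at α = 0.05, and
summarized by the amplitude-weighted τ_mean. A trace whose post-peak
segment is constant short-circuits to %C = 1 (no desensitization); a
degenerate biexponential fit falls back to a single exponential and
records the fallback in the descriptor's `note`.

Dose–response relationships use the bracketed protocol: each test
amplitude is divided by the mean of the saturating responses recorded
before and after it, which cancels linear rundown; per-concentration
relative responses are averaged across cells and fitted with the Hill
equation (least squares on log-EC50 to keep the parameter positive).

## Waveform rate fitting

The objective is the sum of squared residuals between the data and the
simulated open-probability trace over a restricted window from the start
of agonist application, with the amplitude scale profiled analytically at
every evaluation (simulated shape matched to data up to a non-negative
multiplicative factor — the number of channels is never known). Rates are
log-parameterized and minimized by Nelder–Mead with one restart from the
optimum (a fresh simplex polishes ill-conditioned directions), wrapped in
a seeded multistart whose first start is the supplied rate set and whose
remaining starts perturb each free rate log-uniformly (×0.5–2 by
default). The full per-start record (initial guesses, fitted rates,
objectives, convergence flags) is attached to every result so
non-reproducible fits are visible rather than silently averaged away.

A structural caveat, documented here because it shapes what fitting can
deliver: at saturating agonist with binding rates fixed and amplitude
profiled, a ~30 ms response exposes roughly five observables (three
relaxation rates and two relative amplitudes) against six free rates of
the one-desensitized-state scheme. The fit therefore has an exactly
degenerate direction; noiseless self-fits starting at the truth recover
it precisely, but under measurement noise individual rate estimates
wander along the degenerate manifold even though the fitted curve
reproduces the data. The package's tests assert exactly this split:
rate-level recovery on noiseless data, curve-level (predictive) recovery
on noisy data. Window comparison (`compare_windows`) flags rates whose
estimates shift by more than 50% between windows, the signature of model
components (e.g. a slow desensitized state) that only long windows
constrain.

## Single-channel analysis

Dwell sequences are sampled exactly (exponential holding times,
categorical jumps), with same-class sojourns merged into aggregated
dwells. Dead-time imposition uses the retrospective convention: an
unresolved dwell (< t_d) is absorbed into the preceding resolved dwell,
re-merging same-class neighbours; leading unresolved dwells are absorbed
forward into the first resolved one. Only this one convention is
implemented — comparisons across resolutions need consistency, not a
menu. The operation conserves total record duration exactly and is
idempotent at fixed t_d.

Mixture fitting maximizes the likelihood of a k-component exponential
mixture left-truncated at the dead time. By memorylessness each truncated
component is again exponential in t − t_d, so EM runs on the shifted
data (deterministic quantile initialization plus seeded random restarts)
and the full-distribution areas are recovered as w_i ∝ w_i′·e^(t_d/τ_i).
k is selected by BIC up to k_max (default 5) unless pinned by the caller
— the conventional choices (four shut and two open components for
WT-like records, three shut for the strongly affected mutants) are
available as an override. Components are reported sorted by τ.

The critical time between adjacent shut components solves
%P_i·e^(−t/τ_i) = %P_j·(1 − e^(−t/τ_j)) — equal expected numbers of
misclassified events — by bracketed root finding on (τ_i, τ_j); the
conventional pair is the 3rd/4th components of four-component fits and
2nd/3rd of three-component fits. Bursts are delimited by shut dwells
longer than t_crit; a burst runs from its first to its last opening
(edge shut dwells count as inter-burst time, so bursts plus inter-burst
shut time tile the record exactly), its length includes intra-burst
shuttings, and single-opening bursts are retained. Mode analysis fits a
one-dimensional Gaussian mixture to per-cluster P_open values (BIC over
k ≤ 3 by default), calls the largest-share mode predominant, and breaks
exact ties toward the higher P_open, recording the tie in the log. A
spread below 0.02 across clusters short-circuits to a single mode.
Cascaded analogue/digital filters compose as fc = (fa⁻² + fd⁻²)^(−1/2)
with sampling at fs = 10·fc.

## Dwell-sequence likelihood and the two-stage fit

The likelihood of an alternating dwell sequence is
φ·Π_k[e^(Q_AA·t_k)·Q_AB]·1, with the final dwell of each cluster
contributing survival only and φ the stationary occupancy conditional on
the entering class (the more refined burst-entry vectors used by
missed-event ML software are intentionally out of scope). Within-class
propagators are expanded spectrally once per rate set; the sequential
product is evaluated either by a scaled scan (short clusters) or by a
scaled binary-tree reduction (long clusters) — the two agree to ~1e-12
and the tree is an order of magnitude faster at 10⁴ dwells. Degenerate
eigenvector bases (condition number > 1e10) fall back to per-dwell
matrix exponentials. A rate set that annihilates the data returns a
large negative floor rather than −inf so optimizers keep moving.

This is the **ideal-resolution** likelihood: the recording dead time is
not folded into the dwell densities (no exact missed-event correction).
Fidelity at finite resolution is instead checked by simulation: the
fitted model generates records at the experimental dead time and at zero
dead time, mixtures are fitted to each, and the resulting component
tables are compared side by side with the observed ones. Left truncation
is honoured where it is exact — in the mixture fits.

The two-stage procedure targets records whose fastest shut component
carries a small fraction of events: stage 1 removes shut dwells longer
than t_crit (attributable to desensitization), splits the record into
burst clusters, and fits the desensitization-free four-state scheme to
the burst-internal dwells, pinning δ2 and γ2; stage 2 fixes those two
rates and fits the full scheme to the complete record. Stage-1
non-convergence aborts with the per-start diagnostic; stage-2 failures
preserve the stage-1 result. In this implementation the single-step fit
turned out to converge reproducibly even in the rare-fast-component
regime (the exact likelihood plus log-parameterized multistart is robust
where older missed-event ML software was not), so the two-stage
procedure's value here is confirmatory: its δ2/γ2 estimates agree with
the single-step fit and recover the generating values within 15% in the
designed regime. The open-state permutation symmetry of two-open-state
schemes (relabelling A2O ↔ A2O′ with their rates leaves the likelihood
invariant) means fitted branch rates are identified only up to that
swap; recovery tests compare against both labellings.

`predicted_mean_open` encodes the topology-discrimination observable:
the reciprocal total exit rate of the open state — 1/α2 for the
bifurcating scheme, 1/(α2 + d2) for the linear scheme — extended to
multiple open states as an equilibrium-weighted mean sojourn with a
warning.

## Synthetic data

Macroscopic fixtures are composed from the descriptor equations directly
(exponential onset matched to the target rise time, the biexponential
decay from the peak, a single-exponential deactivation tail at τ_mean),
**not** from scheme simulation, so descriptor-extraction tests are
independent of any rate choices; the peak is placed where the onset
reaches 99.99% of its asymptote. Published amplitude percentages that sum
to 0.99 after rounding are renormalized to 1. Noise is additive Gaussian
with SD = peak/SNR and SNR defaults to 15, the recording acceptance
threshold reused as the generator's realism convention. The default
pulse is 510 ms so that a full 500 ms of decay exists after the peak.
Deactivation uses a single exponential because the profiles record only
τ_mean, not the component split.

Dose–response generation emits the saturating/test/saturating sweep
triplet per concentration with a per-sweep rundown factor, so the
bracket-correction path is exercised end to end. Single-channel records
are clusters separated by 1 s shut gaps (far above any t_crit, making
cluster segmentation unambiguous); each cluster draws an activity mode —
its own rate set — from the mode shares, and ground-truth labels remain
in the metadata. What the generators do **not** emulate: raw current
waveforms (idealization is out of scope), filter-shaped noise,
multichannel stacking, and slow drift; passing round-trip tests
therefore demonstrates correctness of the analysis chain on idealized
inputs, not robustness to idealization artifacts.

## Numerical choices and problem sizes

Matrix exponentials per protocol segment are computed once per dt and
iterated; probability conservation is maintained to ~1e-12 over
thousands of steps. EM convergence tolerance is 1e-9 relative
log-likelihood; mixture τ values are floored at 1e-8 ms. Root finding
uses machine-tight brackets on (τ_i, τ_j). Optimizer log-rates are
clipped to [1e-6, 1e12] s⁻¹ to keep exploratory simplex steps from
disconnecting the chain. Nelder–Mead runs with fatol 1e-10 and one
restart; multistart defaults are 8 starts for waveform fitting and 4 for
dwell ML.

Test and acceptance problem sizes are chosen to keep the full suite in a
few CPU-minutes while leaving Monte-Carlo bands meaningful: Gillespie
ensembles of 3000–4000 trajectories with 3-SE bands, 10⁴ dwells for
recovery experiments (8000 for the two-stage regime), 2–3 optimizer
starts in tests (the first start being the supplied rate set), and
replicate counts of 3–12 where scatter is the quantity of interest.
Larger sizes change nothing qualitatively; the 3-SE criteria scale
automatically.

## Known limitations

- No exact missed-event (dead-time-corrected) likelihood; validation is
  simulation-based. Estimates from heavily truncated records inherit the
  corresponding bias, as the bracketed/unbracketed comparison tables make
  visible.
- Macroscopic rate fitting at saturating agonist is over-parameterized by
  one degree of freedom (see above); treat single-trace rate estimates as
  curve-consistent, not individually identified.
- One dead-time convention (absorb into the preceding resolved dwell);
  per-class dead times are supported by imposing per class, but a single
  t_d is the default.
- Burst-entry initial vectors are stationary-conditional, not
  first-latency corrected.
- No multi-agonist schemes, voltage-dependent rates, or joint fitting
  across concentrations.
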