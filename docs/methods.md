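# Methods

`bvrlf` simulates populations of human ventricular epicardial myocytes with
stochastic ion-channel gating under phasic sympathetic forcing, quantifies
beat-to-beat variability of repolarization (BVR) and low-frequency (LF)
oscillations of action-potential duration (APD), and attributes both — and
pro-arrhythmic outcomes — to ionic conductances.  This note records the
model, its assumptions, the tunable constants and the design choices that
were genuinely open.

## Cell model

The electrophysiological substrate is the O'Hara–Rudy (ORd) dynamic human
ventricular epicardial cell model, implemented verbatim from the published
formulation (41 state variables; constants tabulated in
`bvrlf.constants`, version `ord-epi-1.0`).  A virtual cell is defined by
eight dimensionless factors θ = (θ_Ks, θ_Kr, θ_to, θ_CaL, θ_K1, θ_Na,
θ_NaCa, θ_NaK) scaling the corresponding maximal conductances /
permeabilities; θ = 1 reproduces the nominal model exactly.

Integration is fixed-step forward Euler at dt = 0.02 ms, with
Rush–Larsen exponential updates for all Hodgkin–Huxley gates.  The same
stepping kernel serves deterministic and stochastic runs so their
trajectories are directly comparable.  The stimulus is a rectangular
−80 µA/µF pulse of 0.5 ms at each pacing instant, gated by integer step
index so that restarting from a serialized state reproduces the trajectory
bit-exactly.  Pacing to steady state stops at 1000 beats or when APD90
drifts by less than 0.1 ms over 50 consecutive beats, whichever comes
first.

## Stochastic gating

Gating noise enters the Hodgkin–Huxley gates of I_Ks, I_Kr, I_to and
I_CaL as a channel-number-limited SDE: for a gate x,

    dx = (x∞ − x)/τ_x dt + sqrt((x∞ + (1 − 2 x∞) x) / (τ_x N)) dw,

advanced by Euler–Maruyama on the same dt grid, with the radicand clipped
at zero and the gate clamped to [0, 1].  The Ca²⁺-dependent non-gating
variables of I_CaL (the fraction in Ca-dependent mode) remain
deterministic.  Channel counts scale with the cell's conductance factor,
N_j = round(θ_j · N_j,nominal), floored at one channel.

Nominal channel counts are configuration values.  They were set per
current from whole-cell conductance divided by a typical single-channel
conductance (order of magnitude only), then scaled once by a single global
constant (0.25, giving N_Ks = 750, N_Kr = 1250, N_to = 2000,
N_CaL = 3750) so that the nominal cell's baseline short-term variability
falls inside the experimentally plausible 1–5 ms band (measured:
≈ 2 ms).  The tuning constant is fixed in `bvrlf.constants` and is never
adjusted per experiment.

Each (cell, realization, segment) triple gets an independent 31-bit seed
derived through `numpy.random.SeedSequence`, so realizations are
reproducible and statistically independent without a shared stream.

## Sympathetic forcing

Sympathetic drive has two phasic effectors at 0.1 Hz, in phase with each
other:

* **β-adrenergic stimulation** — a square-wave isoproterenol (ISO) dose:
  on-dose for the first half of each 10 s period, 0 µM for the second.
  On-dose is 0.01 µM at baseline and 1 µM under sympathetic provocation
  (SP).
* **Mechanical stretch** — a raised-cosine stretch ratio
  λ(t) = 1 + (A/2)(1 − cos(2π·0.1·t − φ)), with A = 1% (baseline) or 10%
  (SP) and φ chosen so λ peaks at the midpoint of the ISO-on half-period.

### Phosphorylation surrogate

Full β-adrenergic signaling cascades resolve cAMP/PKA dynamics that this
package does not need; here PKA phosphorylation is a first-order kinetic
surrogate acting on the same five substrates.  Each substrate's
phosphorylated fraction f relaxes toward a saturating Hill function of the
ISO dose (EC₅₀ = 0.1 µM, coefficient 1; f∞(0) = 0) with separate
phosphorylation and dephosphorylation time constants:

| substrate | τ_phos (s) | τ_dephos (s) | effect at f = 1 |
|---|---|---|---|
| I_CaL | 3 | 4 | permeability ×1.8, activation shifted −4 mV |
| I_Ks | 30 | 40 | conductance ×3.0, activation τ ×0.6 |
| PLM/NKA | 30 | 40 | NKA Na⁺ half-saturation ×0.7 |
| RyR | 3 | 4 | SR release gain ×1.4 |
| troponin | 10 | 10 | Ca²⁺ affinity K_d ×1.3 |

Effects interpolate linearly between identity (f = 0) and the endpoint
(f = 1).  The deliberately slower I_Ks kinetics relative to I_CaL are the
mechanism that converts the 0.1 Hz dose pattern into APD oscillations
rather than a quasi-static shift.  Endpoint magnitudes were fixed once so
that the nominal deterministic cell's APD oscillation under SP is of
order a few to ten milliseconds (measured ≈ 15 ms peak-to-trough at the
oscillation maximum, ≈ 2 ms at baseline forcing) while long-APD cells in
the calibrated range remain repolarization-competent under provocation;
they are flagged as surrogate constants in the configuration.

### Stretch-activated channels

Stretch feeds back electrically through two SAC components:

* non-specific cationic: I_SAC,ns = G_ns · g(λ) · (V − E_ns),
  E_ns = −10 mV, G_ns = 0.006 nS/pF (0.01 nS/pF under severe disease);
* K⁺-selective: I_SAC,K = G_K · g(λ) · r(V) · (V − E_K), with
  G_K = G_ns/2 and a sigmoidal outward rectification r(V).

g(λ) = (λ − 1)/(λ_ref − 1) clipped to [0, 1] with λ_ref = 1.10, so the
SACs saturate at the SP stretch maximum.  λ < 1 is treated as slack.
E_ns, G_K and r(V) are surrogate constants (the detailed SAC kinetics are
not constrained by the data the model is calibrated to).  Half of
I_SAC,ns is booked to Na⁺ and half to K⁺ in the ionic balances; I_SAC,K
to K⁺.

### Disease conditions

Ca²⁺ overload and reduced repolarization reserve are composed
multiplicatively with θ and phosphorylation effects:

| level | [Ca]o | I_Kr block | I_Ks block | G_SAC,ns |
|---|---|---|---|---|
| physiological | ×1.0 | 0% | 0% | 0.006 |
| mild | ×1.5 | 7.5% | 20% | 0.006 |
| moderate | ×2.5 | 22.5% | 60% | 0.006 |
| severe | ×4.0 | 30% | 80% | 0.010 |

## Population construction and calibration

Candidate cells are sampled by Latin Hypercube over θ ∈ [0, 2]⁸ (±100%
around nominal).  Each candidate is paced deterministically to steady
state at 1 Hz and kept only if: APD90 ∈ [178.1, 442.7] ms, APD50 ∈
[106.6, 349.4] ms, resting potential ∈ [−94.4, −78.5] mV, peak
potential ≥ 7.3 mV; and its APD90 change under 90% I_Ks block ∈
[−54.4, 62]%, under 70% I_Kr block ∈ [34.25, 91.94]%, and under 50% I_K1
block ∈ [−5.26, 14.86]% (blocks re-equilibrated for 200 beats from the
baseline steady state).  Cells showing pro-arrhythmic events at baseline
are excluded regardless of biomarkers; the baseline event check runs on a
deterministic continuation (the stochastic-vs-deterministic choice for
this screen is not pinned down by the calibration data; deterministic is
cheaper and reproducible).  The large negative lower bound on the I_Ks
block response is applied as printed even though it is physiologically
loose.  All verdicts are deterministic functions of θ.

## Protocols and event taxonomy

The standard protocol paces a cell at 1 Hz for 320 baseline beats
followed by 320 SP beats (stochastic gating on, forcing as above, state
carried over; each realization preceded by a deterministic equilibration
under the disease modifiers).  Metrics use the last 120 beats of each
segment, averaged over realizations (default 5).

APD90/APD50 are measured per beat from the stimulus instant to the
interpolated downward crossing of V_rest + (1 − p)(V_peak − V_rest),
where V_rest and V_peak are that beat's own diastolic minimum and peak;
beats that never recross the APD90 threshold are flagged invalid (never
silently dropped).  The stimulus, rather than dV/dt_max, anchors
depolarization because it is stable under gating noise.

Pro-arrhythmic events are detected on the voltage trace with declared
thresholds: an EAD is a local minimum above −40 mV after the plateau peak
followed by a ≥2 mV depolarization (the plateau peak is located after a
50 ms post-stimulus guard so the epicardial spike-notch-dome transient is
not miscounted); an EAD burst is ≥3 EADs in one beat; a spontaneous beat
is an upstroke through −40 mV steeper than 10 V/s and more than 10 ms
from any stimulus.  Detection is invariant to halving the sampling step.

## Variability and spectral measures

On the last L = 120 beats: m_SD is the sample standard deviation of
APD90 (denominator L − 1); m_STV is the mean perpendicular
Poincaré-plot distance |ΔAPD|/√2 averaged over the L − L_win + 1 sliding
windows of L_win = 30 beats; m_NSD = m_SD²/APD̄² and m_NSTV =
m_STV²/APD̄².  The √2 in the STV denominator is the geometric
(perpendicular-distance) reading of the definition; a configuration
switch selects the literal factor 2 instead.  Triangulation is
T1 = APD90 − APD50.

For LF power the series is linearly detrended and an autoregressive model
fitted by Yule–Walker (biased autocovariances; the returned innovation
variance makes the AR spectrum integrate exactly to the sample variance).
The order is chosen in [L/3, L/2] = [40, 60] to minimize the Gaussian AIC
(L·ln σ̂² + 2·order) among orders whose residuals pass a Ljung–Box
whiteness test (20 lags, α = 0.05; if none passes, the global AIC minimum
is used and flagged).  The one-sided PSD is evaluated on a 0.0005 Hz grid
and integrated by trapezoid: m_PLF over [0.04, 0.15] Hz, normalized by
[0.04, 0.5] Hz for m_NPLF.  The whiteness test and AIC variant are
declared choices; the high-frequency band is deliberately not analyzed.

## Relevance analysis (ARD)

A Gaussian-process regression with linear covariance
c(x, x′) = Σᵢ σ²_d,i xᵢx′ᵢ plus noise σ²_r links the eight conductance
factors to each standardized measure.  Hyperparameters are fitted by
type-II maximum likelihood — the negative log marginal likelihood
½ log det C_ext + ½ yᵀC_ext⁻¹y + (N/2) log 2π minimized by L-BFGS on
log-scale hyperparameters with analytic gradients, restarting from
jittered initializations on non-convergence — on each of ten
cross-validation folds.  Per-feature variances are averaged over folds
and normalized to sum to one; signs come from reading the fit as linear
regression: s_i = sign(((C_ext⁻¹X)ᵀy)_i).  Features are used raw
(θ ∈ [0, 2]); a configuration switch enables centering.  Leave-one-factor-
out ablation refits with each feature removed in turn to expose
co-dependencies.  With a one-dimensional outcome the GP predictive mean
coincides with per-feature-penalized ridge regression; the test suite
pins this equivalence.

## Arrhythmia analysis (CCA)

A binary vector z marks cells with any pro-arrhythmic event following SP.
With a one-dimensional second view, the canonical pair maximizing
corr(X w_x, z w_z) is the least-squares direction of z on column-centered
X; the canonical correlation is the multiple correlation coefficient.
The weight sign is fixed so corr(X w_x, z) ≥ 0; collinear feature blocks
are ridge-stabilized with a logged ε.  Only the single canonical pair is
computed.

## Synthetic generators

`bvrlf.synthetic_data` emulates the statistical structure of the study's
inputs without simulation: beat series with a linear trend, a 0.1 Hz
sinusoid and white or AR(2)-colored noise (the stand-in for human
activation-recovery-interval recordings, which are not redistributable);
cohorts X ~ LHS[0, 2]⁸ with known linear measure weights and logistic
event labels (default N = 200, larger than a realistic calibrated
population, to give recovery tests headroom); and voltage-trace fixtures
with known event counts.  Every generator is a pure function of its spec
and seed.  What these generators do **not** emulate: respiratory/
high-frequency components, interindividual APD means correlated with
conductances, and the nonlinear θ→measure map of the real model — so
passing recovery tests validates the statistical machinery, not the
electrophysiology.

## Problem sizes in the test suite

The packaged test suite runs reduced scales chosen to exercise every
stage end-to-end: a 60-candidate Latin Hypercube draw filtered to 12
accepted cells (300-beat steady-state pacing, 80-beat block
re-equilibration), 130 beats per protocol condition (last 120 analyzed)
with one stochastic realization per cell, and a severe-disease SP segment
per cell for the arrhythmia fraction.  The full study conditions (500
candidates, 1000-beat calibration pacing, 320-beat segments, five
realizations) are the package defaults used by the pipeline CLI.

## Known limitations

* The phosphorylation surrogate collapses receptor/cyclase/PKA dynamics
  into per-substrate first-order kinetics; absolute endpoint magnitudes
  are plausible but not fitted to signaling data.
* Because the surrogate multiplies I_CaL permeability, the absolute size
  of the β-adrenergic Ca-current swing grows with θ_CaL; in populations
  this tends to make higher θ_CaL associate with larger APD oscillations,
  whereas signaling-cascade models can invert that association through
  AP-triangulation effects.  Conclusions about the *direction* of the
  I_CaL contribution to variability measures are therefore
  surrogate-dependent.
* SAC formulation (rectification, reversal, K⁺ share) is a declared
  surrogate; only its qualitative mechano-electric feedback is relied on.
* I_SAC is only partially ion-resolved (half Na⁺ / half K⁺ for the
  non-specific component).
* Event-detection thresholds are declared constants, not fitted to an
  annotated event corpus.
* Single cells only; no electrotonic coupling, no tissue propagation.
* Channel numbers are order-of-magnitude estimates tuned once through a
  single global constant; per-current absolute counts are uncertain.
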