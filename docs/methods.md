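# Methods

## The kinetic scheme

Release sites exist in empty (ES), loosely docked (LS) and tightly
docked (TS) states; only TS vesicles fuse.  Between APs the expected
occupancies follow the linear system

    dES/dt = −k1(Ca)·ES + b1·LS            (+ ers_decay·ERS)
    dLS/dt =  k1(Ca)·ES − (b1 + k2(Ca))·LS + b2·TS   (+ tsl_decay·TSL)
    dTS/dt =  k2(Ca)·LS − b2·TS

with optional labile states TSL (fuses like TS, relaxes to LS) and
ERS (relaxes to ES), disabled by default.  At each AP, `p_fusion_now ·
(TS + TSL)` vesicles fuse and their sites return to ES (or ERS when
the labile extension is on); immediately afterwards a fixed fraction
`ap_conversion` of LS tightens to TS, representing the brief local
calcium transient of the AP.  Because tightening is applied after
release, vesicles that were loosely docked before stimulation cannot
fuse at the first stimulus — the delayed-onset property the tensor
factorization exploits.

Global calcium is `ca_rest` plus linearly summating per-AP
exponential transients (`ca_increment_per_ap`, `tau_global`).  The
forward rates are linear in supra-resting calcium, `k_i = k_i_rest +
sigma_i · ΔCa(µM)`, capped at `rate_cap`; `p_fusion_now = p_fusion_0 ·
(1 + facilitation_gain · ΔCa(µM))`, capped at `p_fusion_max`, is
evaluated just before each AP, so a resting synapse's first response
is exactly `p_fusion_0 · TS_rest`.  Linearity is the minimal choice
for an unspecified "calcium sensitivity"; saturating forms can be
swapped behind the same interface.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `N_total` | 3600 | release sites (≈500 AZs × 7.2 nanoclusters) |
| `k1_rest` / `b1` | 0.36 / 0.5 s⁻¹ | ES↔LS at rest (LS/ES = 0.72) |
| `k2_rest` / `b2` | 0.7 / 1.8 s⁻¹ | LS↔TS at rest → `f_TS` = 0.28 |
| `sigma1` | 1.5 s⁻¹/µM | Ca sensitivity of ES→LS (recruitment) |
| `sigma2` | 3.0 s⁻¹/µM | Ca sensitivity of LS→TS (tightening) |
| `p_fusion_0` | 0.34 | TS fusion probability per AP at rest |
| `ap_conversion` | 0.10 | LS→TS fraction per AP (local Ca) |
| `facilitation_gain` | 8 µM⁻¹ | p_fusion facilitation per residual Ca |
| `p_fusion_max` | 0.6 | facilitation cap |
| `ca_rest` | 50 nM | resting global Ca |
| `ca_increment_per_ap` | 30 nM | residual-Ca build-up per AP |
| `tau_global` | 0.15 s | residual-Ca decay |

The rate constants governing the resting equilibria, `p_fusion` and
`f_TS` for both presets are fixed by the quantities the analyses
estimate (`f_TS = k2_rest/(k2_rest + b2)`, with the mutant-like
preset obtained by multiplying `k2_rest` by 2.15 → `f_TS` ≈ 0.455 and
reducing `sigma1` to 15%).  The remaining dynamic parameters
(`sigma1`, `sigma2`, `ap_conversion`, `facilitation_gain`, calcium
transient) are not identified by any single printed quantity; they
were calibrated once so the presets jointly reproduce the qualitative
phenotype the model must show — wild-type-like facilitation (333-Hz
PPR > 1) versus mutant-like depression (PPR < 1), lower mutant
steady-state release at ≥100 Hz, a fast recovery component present
only with large `sigma1`, and depletion-dominated cumulative-release
curves whose back-extrapolation bias shrinks with stimulation
frequency — and are not tuned further.

### Numerics

Fixed-step RK4 (default dt = 0.1 ms, hard limit 0.5 ms) integrates
the occupancies between APs; halving dt changes every per-AP release
by < 0.1% at defaults (`check_accuracy=True` asserts this).  Once the
residual calcium has decayed to a negligible level the remaining
quiet stretch is advanced in a single exact matrix-exponential step,
so long recovery intervals cost nothing.  Site conservation holds to
1e−9 relative at every reported time point.  The stochastic mode uses
integer site counts, binomial release and tau-leaping transitions
with exact per-step exponential jump probabilities; its expectation
matches the mean-field trajectory (unbiased for a linear scheme).

## Nonnegative tensor factorization

The cohort tensor `V[s, f, j]` (quantal content of synapse `s`,
frequency `f`, stimulus `j`) is modeled as `Σ_c L[s, c] · W[c, f, j]`
with nonnegative loadings (pool sizes) and shared signatures
(fraction of the pool released per stimulus).  Alternating NNLS on
the observed (masked) entries gives exact block minimizers, so the
objective is nonincreasing.  Three conventions resolve the remaining
ambiguities:

1. **Scale** — each component is rescaled so its most depleting
   frequency releases the whole pool (`max_f Σ_j W[c,f,j] = 1`).
2. **Delayed onset** — only the TS component may release at stimulus
   1 (loosely docked or newly recruited vesicles need at least one
   inter-stimulus interval to tighten).  This labels the components
   structurally.
3. **Irreducibility (de-mixing)** — a nonnegative factorization can
   still carry component `c` a multiple of component `d`'s signature
   with the loadings compensating.  Sweeping ordered pairs, the
   largest multiple keeping `W_c` nonnegative is transferred out;
   this preserves the fit exactly and terminates at the extreme
   factorization in which each signature has zeros where the others
   are positive.  On noisy fits the entries never reach zero, so the
   rule grants head-room of `demix_z` (default 0.5) standard errors
   of the signature estimate, derived from the fit RMSE.  The exact
   (zero head-room) rule is also applied inside the ALS loop, which
   removes the otherwise very slowly converging flat direction.

An optional small ridge penalty on the signature updates
(`ridge`, default 0; 1e−3 recommended for noisy cohorts) biases the
noise-flattened mixing direction toward the irreducible end; it
slightly breaks the exact monotonicity guarantee, which is therefore
only asserted at `ridge=0`.  The default component count is 2
(TS, LS); with 3 components the third ("recruitment") signature is
constrained nondecreasing in the stimulus index via a nonnegative-
increment parameterization, absorbing steady-state replenishment —
the configuration used for cohort analyses here, where trains show
prominent activity-dependent recruitment.  `p_fusion` is the slope of
the regression of `m₁` on `M_TS` through the origin, implementing the
constraint of a common initial fusion probability within a cohort.

## Pool estimators

`frp_prime` fits an ordinary least-squares line to the cumulative
quantal release over the late (default last 10) stimuli and reads it
out at stimulus 0; under complete pool depletion and constant-rate
replenishment the intercept is the initial pool.  Replenishment per
stimulus falls as `1/f_stim`, so `1/FRP′` is regressed on `1/f_stim`
and inverted at the intercept (`correct_pool_across_frequencies`);
`release_fraction` treats `F′ = m₁/FRP′` the same way.  The
back-extrapolation intercept is taken at j = 0 (cumulative-at-zero
equals the pool under the idealization).  Geometric fits use bounded
nonlinear least squares in the linear domain (p ∈ [0, 1], stimuli
1–15 by default), so noisy zero or negative points need no exclusion.
The balanced bootstrap permutes B concatenated copies of the sample
into B resamples, so every observation appears exactly B times in
aggregate; confidence intervals are percentile-based.

Validation of the pool estimators uses the simulator with `sigma1 =
0` (recruitment held at its resting rate): the estimator assumes
constant replenishment, and that is the regime in which its accuracy
can be stated.  Under the full presets, calcium-accelerated
recruitment ramps up during the train and the back-extrapolation
intercept acquires a bias that the 1/f correction cannot remove —
a genuine property of the method, reported as such rather than
calibrated away.

## Plasticity metrics

Recovery curves use the fraction `(m_test − m_ss)/(m₁ − m_ss)` on the
interval grid 0.125–16 s.  Exponential fits bound the total recovered
amplitude at 1.05; the bi-exponential model is parameterized as
(total amplitude, weight, τ_fast, τ_slow) with a deterministic
multistart, and in `model="auto"` replaces the mono fit only when the
F-ratio `((RSS₁ − RSS₂)/2)/(RSS₂/(n−4))` exceeds 6.  PTP fold is the
maximum baseline-normalized amplitude within 60 s after the tetanus
(an explicit fold-at-first-point readout is also returned), and t₀.₅
is found by linear interpolation of (value − 1) after the peak;
measuring potentiation above baseline rather than the raw value makes
"half-maximum potentiation" well defined.  Cooperativity predictions
are the pure power law `(Ca_post/Ca_pre)^slope`.

## Nanocluster statistics

DBSCAN follows the published algorithm — core points have ≥
`min_pts` neighbors (self included) within `eps`; clusters are
density-connected sets of core points — with a deterministic,
input-order-independent border rule: border points join the lowest
cluster id among their core neighbors, ids being assigned by
ascending smallest member index.  Defaults `eps = 50 nm`, `min_pts =
5` resolve ~48-nm-r_g clusters at ~20 nm localization error; both are
explicit parameters.  `r_g` is the RMS distance of the localizations
from their center of mass (the verbal definition; the compact printed
formula omitting the centering is not used).  Nearest-neighbor and
distance-to-center distances are 3D Euclidean via a k-d tree, exactly
equal to brute force.  Hotspot enrichment z-normalizes ROI pixels by
the background mean/SD; z50 is the median and z90 the k-th largest
z-value with `k = floor(0.1·n)` — the smallest threshold whose
exceedance area fraction is ≤ 10%, which honors the area-fraction
definition exactly on discrete data (a linear-interpolation quantile
would not).

## Synthetic data: what it emulates, and what not

`gen_train_cohort` draws per-synapse FRP log-uniformly over the
preset's ≈7-fold range, jitters the initial TS fraction (≤1.4-fold)
and the empty-site reservoir (≤1.3-fold), and simulates stochastic
trains with shared kinetics, averaging 10 sweeps per train (as train
analyses operate on averaged mean traces).  Heterogeneous initial
composition with shared kinetics is exactly the regime the NTF
assumes; it is implemented by drawing the pre-stimulus state directly
rather than by per-synapse rate constants, a deliberate idealization
— real synapses realize different equilibria through different rates,
which would make the shared-signature model only approximate.
Amplitude noise beyond binomial release statistics is optional
multiplicative Gaussian (CV 5%).  mEPSC streams are inhomogeneous
Poisson by thinning.  Nanocluster clouds are isotropic Gaussians with
per-axis SD `r_g/√3` (localization error adds in quadrature),
release-site clusters displaced 100–300 nm laterally from scaffold
clusters, with uniform clutter; cluster placement enforces minimum
separations so density-based clustering is well posed.  Hotspot ROIs
sit at 2 background SDs with a 10% bright subset at `contrast` SDs
and small intra-ROI noise, so the measured z90 tracks the bright
level.

Passing recovery tests on these cohorts shows the estimators are
correct under the statistical structure they assume (quantal
binomial noise, log-spread pools, common within-genotype kinetics).
It does not establish robustness to features real recordings add —
series-resistance artifacts, receptor saturation/desensitization,
rundown, non-Poisson mini bursts, or anisotropic localization errors
— all deliberately out of scope.

## Problem sizes

Cohort analyses use 20 synapses × 5 frequencies × 40 stimuli with 10
averaged sweeps; estimator validation uses 20 pool draws and 500
geometric-fit replicates; bootstrap coverage uses 200 outer
replicates of B = 1000.  These sizes put Monte-Carlo error well below
the tolerances asserted while keeping the full suite and the
acceptance script to a few minutes on one CPU.

## Known limitations

- The calcium dependences are linear with hard caps; no attempt is
  made to model local-domain saturation beyond the per-AP conversion
  fraction.
- Labile-state kinetics (TSL/ERS) are first-order relaxations with
  nominal defaults; they are off unless enabled.
- The NTF de-mixing head-room `demix_z` trades a small downward bias
  for robustness to noise; at very low signal-to-noise the component
  split degrades gracefully but is not guaranteed.
- Pool back-extrapolation under calcium-accelerated recruitment is
  biased (see above); the package reports the estimator as defined
  rather than attempting a model-based correction.
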