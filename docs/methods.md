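# Methods

## Problem and model

In drug-resistant focal epilepsy, stereo-EEG (SEEG) records tens to
hundreds of depth-electrode contacts during several seizures of the same
patient. The working hypothesis behind this package is that a patient's
ictal dynamics are built from a small number of *functional subgraphs* —
weighted sets of contact-pair connections that switch on together during
reproducible phases of the seizure — and that these subgraphs are shared
across that patient's seizures even when seizure durations differ.

The pipeline has two stages.

**Stage 1 — dynamic functional connectivity.** Each recording is
re-referenced to a bipolar montage along each electrode rod, high-pass
filtered, and reduced to instantaneous phases by the Hilbert transform.
For every pair of bipolar channels the phase-locking value

    PLV = | (1/N) Σ_n exp(i (φ_a[n] − φ_b[n])) |

is computed in sliding windows (4 s long, stepping by 1 s). Stacking the
L = n(n−1)/2 edge values over the T(s) windows of seizure s gives a
matrix X{s} ∈ [0,1]^(L×T(s)); the patient's dataset is the list
{X{1}, …, X{S}}.

**Stage 2 — joint constrained factorization.** The matrices are jointly
decomposed as X{s} ≈ F V{s}ᵀ, with one non-negative, sparse subgraph
matrix F (L×K) shared by all seizures and non-negative activation
profiles V{s} (T(s)×K) per seizure. The fitted objective is

    min Σ_s ζ_s ‖X{s} − F V{s}ᵀ‖_F² + (λ/S) Σ_{l,k} |F_lk|
    s.t. F ≥ 0, V{s} ≥ 0,
         C(V_:k{s}; γ_s, η_s) ≤ 1 for all k, s,

where the activation budget

    C(v; γ, η) = γ Σ_t |v_t| + η Σ_t |v_{t+1} − v_t| + Σ_t v_t²

combines sparsity (γ), temporal compactness via total variation (η), and
a quadratic term that pins the scale of each activation column: since
‖v‖² ≤ 1, all magnitude lives in F and the scaling indeterminacy of the
factorization is resolved without extra normalization steps.

## Optimization

The problem is non-convex; we use block-coordinate descent with random
restarts (default 20) and keep the restart with the smallest final
objective (ties resolve to the lowest restart index; all randomness
derives from one integer seed, so fits are bit-reproducible).

* **F block.** With all V{s} fixed the problem separates over the rows
  of F into non-negative lasso problems sharing the K×K normal matrix
  A = Σ_s ζ_s V{s}ᵀV{s}. Cyclic coordinate descent with
  soft-thresholding at λ/(2S) and clipping at zero solves them; the
  thresholding produces exact zeros, which is what makes edge density a
  meaningful function of λ.
* **V block.** Each activation column solves
  min_v a‖v‖² − 2 bᵀv subject to v ≥ 0, C(v) ≤ 1, a scalar-quadratic
  objective under the fused-lasso budget. We solve the penalized form:
  for a multiplier μ the minimizer is the proximal operator of
  μγ‖·‖₁ + μη TV(·) (exact 1-D total-variation prox by the direct
  taut-string algorithm, then soft-threshold, then non-negative clip —
  the composition is exact for this penalty), evaluated at b/(a+μ); μ is
  bisected until C(v) lands in [1−10⁻³, 1], or μ=0 if the unconstrained
  minimizer is already feasible. A safeguard keeps the previous column
  whenever the bisection tolerance would degrade its data fit, which
  guarantees a monotonically non-increasing objective trace.

Iterations stop when the relative objective change drops below
`rel_tol` (default 1e−5) or after `max_iter` (default 500) alternations.
Initialization is i.i.d. uniform(0,1) for F and for V columns, the
latter rescaled onto the budget boundary (the rescaling solves the
scalar quadratic aα² + bα = 1 exactly).

Degenerate cases: an all-zero subgraph column forces its activation
columns to zero (recorded in `zeroed_components`); a zero-energy seizure
is rejected when computing ζ; objective blow-up to non-finite values
aborts with a diagnostic rather than returning garbage.

## Per-seizure weights and duration adaptation

Seizures contribute on very different scales (durations 18–337 s are
typical clinically), so the data terms are balanced by
ζ_s = 1/‖X{s}‖_F², making each seizure's term a *relative* residual.
The activation budget weights adapt to duration as
γ_s = γ √(T_ref/T(s)), η_s = η √(T_ref/T(s)) with T_ref the median
duration: the ℓ1 and TV terms grow like √T for a fixed-energy profile,
so this keeps the effective tightness of the budget comparable across
seizures. Both rules are this package's own concrete choices; any
monotone variant would be defensible, and both are isolated behind
`compute_zeta` and `adapt_fused_params`.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| window length / step | 4 s / 1 s | PLV estimation windows |
| high-pass cutoff | 20 Hz (−3 dB) | isolates high-frequency ictal activity |
| η | 0.2 | temporal compactness of activations |
| λ = γ | tuned | sparsity of F and of activations, coupled by default |
| target edge density | 20 % | λ is bisected until this fraction of edges survives |
| K sweep | 3–10 | candidate subgraph counts |
| subgraph threshold | 0.2 | per-component relative edge-weight cutoff |
| restarts | 20 | random initializations per fit |

λ is tuned by bisection on [0, λ_max], where
λ_max = 2S·max_l Σ_s ζ_s‖x_l{s}‖₂ is an instance-specific gradient
bound that provably empties F (every feasible activation column has
‖v‖₂ ≤ 1), so the bracket always contains the target density. The
achieved density is monotone non-increasing in λ because the
soft-threshold level scales with λ.

K is chosen at the elbow of the relative-error curve: the K whose
point lies farthest from the chord joining the curve's endpoints after
min-max normalization of both axes. The rule is parameter-free,
invariant to affine rescaling of the error axis, and resolves ties to
the smaller K; perfectly linear or increasing curves return the
smallest K with a warning. It is a reproducible stand-in for the visual
inspection an analyst would do, and the error curve is always exported
so the choice can be overridden.

After fitting, each subgraph column is normalized to maximum 1 and
edges below 0.2 are dropped. Components whose mean pre-ictal activation
is at least half their mean ictal activation *in every seizure* are
flagged as non-specific (background networks rather than
seizure-related ones); the 50 % ratio is this package's operational
cutoff for a triage that is qualitative in clinical practice.

## Signal processing choices

* High-pass filter: 4th-order Butterworth applied forward–backward
  (zero phase). Because filtering twice squares the magnitude response,
  the design cutoff is pre-warped by (√2−1)^{1/8} ≈ 0.896 so the −3 dB
  point of the *combined* response lands exactly at the requested
  cutoff; this is verified against the designed frequency response in
  the tests.
* Windows are anchored at the signal start and advance by the step;
  the last partial window is discarded, giving
  T = ⌊(N − W)/Δ⌋ + 1 windows.
* PLV uses the raw phase difference per window, no tapering.
* Bipolar channels are "contact k minus contact k+1" within a rod,
  labeled `A1-A2`; contacts without an adjacent neighbor are dropped
  and logged. The 0.15 Hz acquisition high-pass and 50 Hz notch of
  clinical recorders are treated as properties of the input data and
  not reapplied.

## Synthetic data: what it emulates and what it does not

The FC-level generator plants the model's own structure: a shared
sparse F (each component occupying a chosen fraction of edges, weights
uniform in [0.3, 1]) and per-seizure boxcar activations at random
positions (amplitude uniform in [0.5, 1]), plus additive Gaussian noise
clipped to [0,1]. F is globally rescaled so noiseless products stay
within [0,1]; with zero noise the planted factorization is therefore
exact, which the tests exploit. Supports are recorded per (seizure,
component).

The signal-level generator produces unit-amplitude cosines at a 25 Hz
carrier whose phases follow Wiener processes: independent per channel
(diffusion 6 rad/√s, chosen so phases decorrelate well within one 4 s
window and baseline PLV stays near the chance floor), or shared within
a scheduled group plus per-channel jitter of scale 1/√coupling_strength.
Phases are continuous across coupling boundaries.

Neither generator models seizure physiology: there are no neural-mass
dynamics, no spectral evolution, no artifacts, line noise, or electrode
dropout, and FC noise is i.i.d. rather than temporally correlated.
Passing the planted benchmarks therefore demonstrates that the
estimator recovers the model's own structure under bounded noise — a
correctness statement about the algorithm, not a validation on clinical
SEEG.

## Evaluation conventions

Recovered components are matched to planted ones by optimal one-to-one
assignment (Hungarian algorithm) maximizing summed subgraph cosine
similarity; cosine similarity is the natural score because the
factorization is defined up to positive per-component rescaling split
between F and V. Activation supports are compared at half the column
maximum (the full-width-at-half-maximum convention; the Eq.-budget
spreads ‖v‖² ≤ 1 over the active windows, so thresholds relative to the
maximum are the scale-free choice). In the signal-level benchmark,
windows that only partially overlap a coupling interval are genuinely
ambiguous — the pair is coupled for part of the window — so support
Jaccard is computed over unambiguous windows only (fully inside versus
fully outside the interval).

## Problem sizes used in tests and the acceptance script

The reference planted family uses 20 nodes (190 edges), K = 4,
three seizures of 60/80/100 windows, noise σ = 0.05 (recovery) or 0.01
(model-order selection), with 20 restarts for recovery fits and 5 for
the K sweep (on this family all restarts reach the same objective, so
the sweep spends its budget on the 8 candidate orders instead). The
signal-level benchmark uses 8 channels at 256 Hz, two seizures of
60/75 s, and two 3-channel groups coupled for 20–25 s each. These sizes
keep a full run in the low minutes on one core while leaving the
estimation problems non-trivial (L ≫ K, overlapping supports,
noise well above the solver tolerances).

## Known limitations

* The optimization is non-convex; restarts mitigate but do not remove
  dependence on initialization. Restart seeds make any run exactly
  reproducible.
* The fused-lasso budget rounds the corners of genuinely rectangular
  activations (TV shrinkage), which slightly inflates the apparent
  benefit of adding components beyond the true order; the elbow rule
  compensates in the benchmarks but K remains a judgment call on real
  data.
* ζ_s and the γ_s/η_s duration adaptation are pragmatic normalizations,
  not estimated quantities.
* PLV is symmetric and bivariate: directionality and genuinely
  multivariate coupling are out of scope, as are per-band decompositions
  (one broad band > 20 Hz is used).
* The EDF writer targets the plain 16-bit EDF subset (integer sampling
  rates, one-second records) — sufficient for synthetic round trips,
  not a general-purpose exporter.
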