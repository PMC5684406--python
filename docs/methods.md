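# Methods

## Model and assumptions

The package propagates the single-excitation amplitude of an effective
two-level system — the weak-excitation reduction of a two-chromophore
Frenkel dimer — coupled to a bosonic (phonon) bath at two spatial points of
a feedback loop.  Working assumptions, inherited from the model class:

* **Single excitation, pure state.**  Total excitation number is conserved
  and the joint state stays in the zero/one-excitation sector, so the full
  dynamics reduces to linear equations for complex site amplitudes c_n(t).
  Populations are |c_n|², coherence is |c₁* c₂|.  There is no thermal
  occupation: the bath starts in vacuum (zero-temperature model).
* **Rotating wave approximation.**  Counter-rotating system–bath terms are
  dropped; the site transition frequency Ω₀ is absorbed by the rotating
  frame and only a detuning δ₀ (default 0) survives.
* **Discrete delay.**  The two-point coupling gives mode couplings
  κ_ξ = √(2γ₀/M)·cos(ξ̄(ω_ξτ/2 + φ₀)) and, in the continuum limit, the
  spectral density J(ω) = (γ₀/π)(1 + cos(ωτ + φ)) with φ = 2φ₀ (ω > 0).
  Its two-sided transform is the three-delta kernel
  γ₀(e^{iφ}δ(s−τ) + 2δ(s) + e^{−iφ}δ(s+τ)), s = t − t′.  The acausal
  (s = −τ) delta never enters the memory integral over [0, t]; the s = 0
  delta sits on the integration endpoint and carries half weight, which is
  the only convention that reduces the 2γ₀δ term to the plain γ₀c(t)
  damping of the scalar delay equation.  The source of truth for the
  dynamics is the equation of motion with delayed coefficient γ₀e^{−iφ};
  the printed kernel decomposition attaches e^{+iφ} to the retarded delta,
  and `kernel_weights` exposes a `conjugated` flag so both sign conventions
  are available and testable.  For φ ∈ {0, π} — every regime with a special
  physical role (constructive/destructive interference) — the two
  conventions coincide.

## Parameters

| parameter | meaning | unit | default/typical |
|---|---|---|---|
| γ₀ | system–bath coupling rate | fs⁻¹ (or cm⁻¹ at the interface) | 530 cm⁻¹ ≈ 0.0998 fs⁻¹ in the reference regime |
| τ | feedback round-trip delay | fs | 0.01–150 fs explored |
| φ | feedback phase (= 2φ₀) | rad | π (destructive) in the trapping regime |
| δ₀ | detuning from the rotating frame | fs⁻¹ | 0 |

Wavenumber input uses the angular convention 2πc·x (c = 2.99792458e-5
cm/fs), because γ₀ multiplies amplitudes directly as a rate; the plain-c
convention is selectable everywhere (`convention="plain"`,
`--gamma0-unit`).  The factor lives in one constant in `units.py`.

## Numerical methods

**Delay solver (`solve_scalar`, `solve_dimer_cross_delay`).**  Classical
RK4 with the method of steps.  The step is snapped so that it divides τ
exactly: solutions of this DDE have derivative discontinuities propagating
from t = τ to every multiple of τ, and placing them on grid nodes is what
preserves fourth order (measured error ratio ≈ 16 per step halving).
Delayed values at half-step stage times land exactly on segment midpoints
of the stored past and are recovered by cubic Hermite interpolation from
stored values and one-sided derivatives (the left derivative at the first
breakpoint excludes the delayed term).  Before t = τ the delayed term is
identically zero and the solution is advanced by the exact exponential.
A requested step above τ/2 is refused; `tol` (default 1e-9) further
subdivides the step so the RK4 local-error bound (L·h)⁵/120 with
L = |a| + |b| stays below it.  The default output step is
min(τ/200, 0.5 fs); sweeps floor it at τ/10 for sub-femtosecond delays,
where the feedback term is a small perturbation and τ/10 fully resolves it.

**Piecewise-analytic oracle.**  On [nτ, (n+1)τ) the solution is
Σ_{k≤n} (−b)^k (t−kτ)^k e^{−a(t−kτ)}/k! with a = iδ₀+γ₀, b = γ₀e^{−iφ}.
Each summand carries its own damped exponential, so every term is O(1)
and the form is stable at arbitrary γ₀τ (the naive "e^{−at} × polynomial"
grouping needs ~50 decimal digits at γ₀τ = 10).

**Characteristic roots.**  s_k = −iδ₀ − γ₀ + W_k(−γ₀τe^{−iφ}e^{(iδ₀+γ₀)τ})/τ
per Lambert-W branch, then 3 Newton polish iterations on the
characteristic function; residuals are stored per root and duplicates
(branch-point coincidences) removed at 1e-12.  At φ = π, δ₀ = 0 the
principal branch gives s = 0 exactly — the trapped mode whose residue
1/(1+γ₀τ) is the steady-state amplitude.

**Volterra engine (`solve_volterra`).**  Trapezoidal quadrature over the
full stored history (no truncation window; desk-scale runs are ≤ ~2·10⁵
steps) with an Euler predictor and two trapezoidal corrector passes
(second order; measured ratio ≈ 4).  Kernels factorize as
e^{i(Ω_j t − Ω_l t′)} g(t−t′); the phases are folded into the stored
history so the memory term stays a lag convolution.  Kernel samples below
1e-13 of the peak are skipped in the history dot products — exact to that
level for the localized kernels used here, and what makes fine-width runs
affordable.  Delta kernels of zero width bypass quadrature entirely and
are handed to the exact delay solver.  A kernel feature (regularization
width, or π/ω_max for sampled densities) resolved by fewer than ten steps
is refused with a diagnostic.

**Regularization extrapolation.**  For the DDE cross-check the three
deltas become normalized Gaussians of width w.  Two error mechanisms
dominate: the lag-0 Gaussian loses ≈ 0.8γ₀w of integrated weight at the
t′ = 0 boundary (linear in w), and the smoothing of the θ(t−τ) onset is
symmetric (quadratic in w).  `regularized_feedback_solution` therefore
runs w, w/2, w/4 (each with dt = w/10) and applies two-stage Richardson
extrapolation with assumed orders (w¹, w²).  At base width τ/256 the
extrapolated solution agrees with the DDE to ≈ 2.7e-5 over [0, 5τ] at
γ₀τ = 1.

## Design choices that were genuinely open

* **Dimer mode.**  How donor/acceptor components relate to the scalar
  total amplitude is not fixed by the model; the package implements a
  cross-delay reading — local decay per site, delayed feedback exchanging
  the sites — whose symmetric/antisymmetric combinations obey the scalar
  equation with phases φ and φ+π.  That internal consistency is the mode's
  defining check, it is tagged as an interpretation in trajectory
  metadata, and the scalar equation remains the default mode.
* **No pre-history API.**  The Heaviside factor nullifies the delayed term
  before τ, so solvers take only c(0); accepting history functions would
  suggest generality the model does not have.
* **Beating detection** uses strict local maxima with a 1e-12 tie
  tolerance (plateaus count once), period = mean maxima spacing, envelope
  rate = least-squares slope of log(maxima), and an amplitude floor of
  1e-4 for the oscillation count.  A series with fewer than two maxima
  (or fewer than three extrema) returns an explicit no-beating marker
  rather than raising.
* **Sweeps** emit long-format tables (one row per cell per time point) as
  the canonical output because they survive per-cell failures; cells fail
  independently and are recorded, never fatal.  The grid is capped at 10⁶
  cells.

## Problem sizes

Default verification runs use: 2000 fs horizons at τ = 50–150 fs
(8k–16k steps); 20 random parameter draws with γ₀τ ∈ [0.1, 10] over
[0, 10τ] for the oracle comparison; Volterra cross-validation at γ₀τ = 1
over [0, 5τ] with base width τ/256 (finest run 25.6k steps); and
small-delay scans at τ = 0.01 fs over 1000 fs at dt = τ/10 (10⁶ steps).
These sizes keep every check at seconds on one core while leaving all
tolerances dominated by method error, not run length.

## Limitations

* Zero temperature and pure single-excitation states only: no thermal
  occupation, dephasing baths, or density-matrix (mixed-state)
  propagation.
* One discrete delay per system; no distributed or state-dependent delays
  and no stiff/implicit DDE machinery (the explicit method of steps with
  aligned breakpoints covers the parameter ranges of interest).
* The analytic-delta Volterra path requires the rotating frame (all site
  rates zero) and a single shared lag; general multi-lag networks go
  through the regularized quadrature path.
* The steady-state formula is established for δ₀ = 0 only and the solver
  refuses to extrapolate it to detuned systems.
* In the slow-root regime (γ₀τ ≳ 5 away from φ = π) the dominant
  characteristic root is only weakly damped (e.g. Re s·τ ≈ −0.107 at
  φ = 0, γ₀τ = 5), so "decay to zero" takes many tens of delay periods;
  finite-horizon checks must budget for it (see the characteristic-root
  analysis, which the package exposes precisely so such horizons can be
  chosen rationally).
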