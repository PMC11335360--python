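# Methods

This note documents the mathematical conventions, numerical choices, and
known limitations of `svdecon`.

## Core matrix and metadata separation

Observations (absorption spectra or 3-D density maps) are serialized into
the columns of one M × N matrix A; only measured values enter A. All
experimental conditions (time, temperature, pH, …) live in a metadata table
keyed to the columns and never enter the factorization — a property the test
suite enforces by checking that jointly permuting columns and metadata rows
leaves the singular values unchanged.

Maps are serialized voxel-by-voxel under an explicit order tag,
`first_axis_fastest` (Fortran ravel) or `last_axis_fastest` (C ravel). The
tag travels with every archive and artifact header because a silent
convention mismatch between serialization and deserialization would scramble
every component map while leaving all scalar statistics (singular values,
residuals) unchanged — the hardest class of bug to notice. Masked
serialization keeps only selected voxels, in the same documented order.

Difference series subtract a chosen reference column, optionally with a
per-column least-squares scale k = (aⱼ·ref)/(ref·ref) that minimizes the
residual after subtraction.

## SVD and rank

`decompose` computes the thin SVD A = U W Vᵀ (tall matrices only; the
transpose is never applied implicitly). The sign ambiguity of each singular
pair is fixed deterministically: the largest-magnitude element of each left
singular vector is made positive, flipping U and V jointly. This makes
exported component spectra/maps byte-reproducible across runs and platforms.

Rank screening offers a largest-adjacent-gap criterion and a relative
threshold. Scree inspection is inherently judgement-laden, so every caller
can override the screened rank; the pipeline then warns when the first
*discarded* singular value exceeds 3× the deep-tail noise plateau (median of
the lower half of the spectrum), which indicates the cut removed genuine
signal.

Reconstitution from a component subset K is Σ_{k∈K} w_k v_kj U_k. Retaining
the top n components is the least-squares optimal rank-n approximation
(Eckart–Young; the truncation residual equals sqrt(Σ tail w²), verified to
1e−10 in the tests). Excluding an identified systematic-error component
removes it from every reconstituted observation.

## The rotation theorem

Applying one planar rotation to a component pair and the *same* rotation to
their coefficient rows,

    R_h = U_h cosθ − U_k sinθ,  R_k = U_h sinθ + U_k cosθ
    f_h = c_h cosθ − c_k sinθ,  f_k = c_h sinθ + c_k cosθ,

leaves every reconstituted observation unchanged (the dot product is
rotation invariant). Composed pairwise steps give an arbitrary rotation of
the significant subspace; steps do not commute, so `RotationPlan` preserves
order and is replayable from JSON. Every rotation the pipeline performs is
guarded by an invariance report (maximum reconstruction deviation, required
< 1e−10).

Rotated singular values are s_k = sqrt(Σ_j f_kj²) — the square root is
required for the rotated right vectors t_k = f_k/s_k to have unit norm.
Note one deliberate deviation from an idealized invariant: after a genuine
rotation of a pair with unequal singular values, the rows of T remain
unit-norm but are *not* mutually orthogonal, because the coefficient rows
rotate with their weights (f = G·diag(w)·Vᵀ, and G·diag(w²)·Gᵀ is not
diagonal). Full orthonormality of T holds exactly at the identity rotation
(T = Vᵀ), and the columns of R stay orthonormal under every rotation.

### Verticalization

For a linear coefficient trajectory in the (c_h, c_k) plane, the angle that
makes it vertical is solved in closed form as the principal-axis angle of
the centered scatter, θ = ½·atan2(2s_xy, s_yy − s_xx), picking the
variance-minimizing branch and reporting θ in (−90°, 90°]. Isotropic or
degenerate scatter raises `AmbiguousRotationError` instead of returning an
arbitrary angle.

### Model-guided rotation

`optimize_to_model` scans, for each search dimension paired with the target,
the rotation angle on a coarse grid (2° default) with the identity evaluated
first, refines the best angle by bounded scalar minimization, and keeps the
identity when no angle genuinely improves the kinetic-model residual of the
target coefficient row. The procedure is deterministic and seed-free. The
objective (which residual, which dimensions) is a documented choice of this
implementation, not a published protocol.

## Kinetic fitting

All fits are deterministic variable-projection fits: nonlinear parameters
(time constants, angular frequency) are scanned on fixed multi-start grids
and refined locally; amplitudes and baselines enter linearly and are solved
exactly by least squares at every candidate. No randomized starts are used,
so a rerun reproduces a fit bit-for-bit.

* **Single exponential** f(t) = b + a(1 − e^(−t/τ)): τ profiled on a
  40-point log grid spanning [min Δt/10, 10·span], refined by bounded
  minimization on log τ. Constant input is flagged
  `tau_unidentifiable_constant_input` instead of fitted.
* **Biexponential**: all ordered τ pairs from a 20-point grid, then
  Nelder–Mead on (log τ₁, log τ₂); τ₁ < τ₂ is enforced to break label
  symmetry, and τ₂/τ₁ < 3 raises an identifiability flag.
  `fit_biexp_joint` shares the two time constants across many rows (global
  analysis) with per-row linear amplitudes — much better determined time
  constants than any single-trace fit.
* **Damped sinusoid** [a·cos(ωt − α) + ct + b]·e^(−(t/τ)^ε): rows share
  (ω, τ, ε); per-row amplitude/phase/drift/baseline are linear via the
  (cos ωt, sin ωt, t, 1)·envelope basis. ω is scanned from one cycle per
  four spans to the sampling Nyquist limit. The damping is the *stretched*
  exponential exp(−(t/τ)^ε); ε = 1 recovers plain exponential damping and
  can be fixed. Windows shorter than one fitted period are flagged
  frequency-unidentifiable.

Asymptotic standard errors come from a numerical Jacobian at the solution.

### Physical conversions

Period(ps) = 10¹²/(c·ν̃), frequency(THz) = c·ν̃/10¹², acoustic wavelength
λ(Å) = v/(c·ν̃) (2λ for a standing wave), with c = 2.998·10¹⁰ cm/s and ν̃ in
cm⁻¹; relative molecular sizes from cube-root mass ratios.

## Pure states

After verticalization the reaction trajectory lies along one dimension k and
the fitted rise form parametrizes progress: the zero-progress endpoint is
f_k = 0 and the completed-reaction endpoint is the t → ∞ plateau
f_k = a + b. With a = 0 there is no reaction and both endpoints coincide at
b. Endpoint coordinates combined with the rotated components reconstruct the
unmixed spectra/maps; any observed value maps to a composition fraction
(f − f_start)/(f_end − f_start), reported unclamped with a range flag.

The f_k = 0 convention assumes the start-state spectrum is orthogonal to the
reaction difference direction — then one rotated component is exactly the
pure start state and f_k is directly proportional to the reacted fraction.
The two-state generator constructs exactly this geometry (it orthogonalizes
the difference direction against the start spectrum), which is the geometry
the deconvolution targets. For arbitrary data the zero-progress point is
still well defined via the fitted model, but the pre-reaction spectrum is
pure only under this orthogonality.

## Synthetic regimes

All generators are seeded, return full ground truth, and add white Gaussian
noise scaled to the peak of the clean signal.

* **two_state**: 45 spectra over 180 min; mixture (1 − p)A + pB with
  p(t) = s₀ + (1 − s₀)(1 − e^(−t/τ)), τ = 58 min, s₀ = 1/3; Gaussian band
  spectra peaking at 707 nm (A) and 748 nm (B). Noise-free rank exactly 2.
* **multiphase**: 200 difference spectra over 20 s on a 350–700 nm grid;
  three signed spectral components driven through a 3 × 3 coupling matrix by
  phase I (τ₁ = 0.4 s), phase II (τ₂ = 9 s), and a zero-mean smoothed
  random-walk fluctuation whose spectrum is confined below 450 nm.
  Noise-free rank exactly 3.
* **oscillatory_maps**: 40 maps on an 8³ grid over 1.1 ps; QR-orthonormalized
  random blob components; static step-rise courses plus a quadrature pair
  cos(ωt)/sin(ωt) sharing the damped envelope, ω the rad/ps equivalent of
  61 cm⁻¹ (11.49 rad/ps), τ = 0.9 ps. The 2-D projection of the pair is an
  inward spiral.
* **inject_artifact** adds a rank-1 systematic term to any series so
  exclusion tests can verify its removal.

## File formats

Spectra: CSV, wavelength column first, `%.17g` precision and round-trip
float parsing so CSV round trips are exact. Metadata: CSV with an
`# ordering_axis=` header line. Maps: CCP4 mode-2 (float32) via gemmi, P1,
orthorhombic cell = shape × spacing, one file per observation plus an
optional 0/1 mask map. Core matrices and bases: single HDF5 archives
carrying the matrix/basis, addressing (wavelengths or grid + mask + order
tag), metadata (exact-JSON encoded), rotation history, and the
sign-convention tag.

## Limitations

* The gap-based rank screen keys on the largest adjacent singular-value
  ratio and picks rank 1 when w₁ dwarfs everything (e.g. difference-free
  multiphase data at realistic noise); it is a default, not an oracle —
  override the rank when the scree plot says otherwise (the pipeline warns
  when an override discards signal-sized components).
* `optimize_to_model` minimizes a non-convex objective by grid + local
  refinement; it can settle in a different valid local minimum than the one
  intended when several subspace directions fit the model family comparably
  well. Verticalization, when applicable, is closed-form and has no such
  ambiguity.
* Pure-state extrapolation requires single-exponential trajectory kinetics;
  multiphasic trajectories must first be rotated so each phase occupies its
  own dimension.
* Problem sizes: everything here is dense-LAPACK based and aimed at desk
  scale (M up to ~10⁵ serialized voxels, N up to ~10³ observations);
  out-of-core or randomized SVD is out of scope.
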