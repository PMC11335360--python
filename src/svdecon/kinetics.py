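"""Kinetic models for metadata-dependent coefficient rows.

A deconvoluted coefficient row f_k(t) should follow the kinetics of a single
chemical process: a single exponential for one first-order step, a
two-exponential form for a biphasic reaction, or a rapidly damped sinusoid
for low-frequency structural oscillations.  All fits are deterministic:
nonlinear parameters (time constants, angular frequency) are scanned on
fixed multi-start grids and refined locally, while amplitudes and baselines
— which enter linearly — are profiled out by exact linear least squares at
every candidate (variable projection).

The module also provides the physical conversions used when interpreting
oscillatory components: wavenumber to period/frequency, acoustic wavelength
at a given wave velocity, and relative molecular size from cube-root mass
ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "SingleExpModel",
    "BiExpModel",
    "DampedSinusoidModel",
    "FitResult",
    "fit_single_exp",
    "fit_biexp",
    "fit_biexp_joint",
    "fit_damped_sinusoid_joint",
    "wavenumber_to_period",
    "wavenumber_to_thz",
    "acoustic_wavelength",
    "size_ratio_from_masses",
    "SPEED_OF_LIGHT_CM_S",
]

#: Speed of light in cm/s (wavenumbers are reciprocal centimeters).
SPEED_OF_LIGHT_CM_S = 2.998e10


@dataclass
class SingleExpModel:
    """f(t) = b + a·[1 − exp(−t/τ)] (rise form).

    The decay form b' + a'·exp(−t/τ) is the same model under
    (a', b') = (−a, a + b); :meth:`decay_params` converts.
    """

    b: float
    a: float
    tau: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.b + self.a * (1.0 - np.exp(-t / self.tau))

    def decay_params(self) -> tuple[float, float]:
        """(amplitude, baseline) of the equivalent decay form b' + a'·e^{−t/τ}."""
        return -self.a, self.a + self.b

    @property
    def plateau(self) -> float:
        """t → ∞ limit, a + b."""
        return self.a + self.b


@dataclass
class BiExpModel:
    """f(t) = b + a₁·[1 − exp(−t/τ₁)] + a₂·[1 − exp(−t/τ₂)], with τ₁ < τ₂."""

    b: float
    a1: float
    tau1: float
    a2: float
    tau2: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.b
                + self.a1 * (1.0 - np.exp(-t / self.tau1))
                + self.a2 * (1.0 - np.exp(-t / self.tau2)))

    @property
    def well_separated(self) -> bool:
        """Time constants differing by < 3× are practically unidentifiable."""
        return self.tau2 / self.tau1 >= 3.0


@dataclass
class DampedSinusoidModel:
    """f(t) = [a·cos(ωt − α) + c·t + b] · exp(−(t/τ)^ε).

    ω is the shared angular frequency (rad per time unit), α the phase, c a
    linear drift, b a baseline, τ the damping time, and ε a stretching
    exponent (ε = 1 recovers plain exponential damping).
    """

    a: float
    omega: float
    alpha: float
    c: float
    b: float
    tau: float
    epsilon: float = 1.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        env = np.exp(-np.power(np.maximum(t, 0.0) / self.tau, self.epsilon))
        return (self.a * np.cos(self.omega * t - self.alpha) + self.c * t + self.b) * env


@dataclass
class FitResult:
    """A fitted model with residuals, uncertainties, and reproducibility info."""

    model: object
    rss: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: list = field(default_factory=list)
    starts: dict = field(default_factory=dict)

    @property
    def params(self) -> dict:
        return {k: v for k, v in vars(self.model).items() if isinstance(v, (int, float))}


def _check_time(t: np.ndarray, f: np.ndarray, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if t.size != f.size:
        raise ValueError("time and coefficient vectors must have equal length")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    return t, f


def _tau_grid(t: np.ndarray, n: int = 40) -> np.ndarray:
    dt = float(np.min(np.diff(t)))
    span = float(t[-1] - t[0])
    return np.geomspace(max(dt / 10.0, 1e-12), span * 10.0, n)


def _stderr(residual_fn, p: np.ndarray, rss: float, npts: int, names: list[str]) -> dict:
    """Asymptotic standard errors from a numerical Jacobian at the solution."""
    nfree = p.size
    if npts <= nfree or rss < 0:
        return {}
    eps = 1e-6
    r0 = residual_fn(p)
    jac = np.empty((r0.size, nfree))
    for i in range(nfree):
        dp = np.zeros(nfree)
        dp[i] = eps * max(1.0, abs(p[i]))
        jac[:, i] = (residual_fn(p + dp) - r0) / dp[i]
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / (npts - nfree)
    except np.linalg.LinAlgError:
        return {}
    d = np.diag(cov)
    return {name: float(np.sqrt(v)) if v > 0 else float("nan") for name, v in zip(names, d)}


def fit_single_exp(t, f, init: float | None = None) -> FitResult:
    """Least-squares fit of b + a·[1 − exp(−t/τ)].

    The time constant is profiled on a fixed log-spaced grid (optionally
    seeded with ``init``) and refined by bounded scalar minimization; the
    amplitude and baseline are solved exactly by linear least squares at each
    candidate τ.  A constant input leaves τ unidentifiable and is flagged.
    """
    t, f = _check_time(t, f, 4)
    flags: list[str] = []
    if np.ptp(f) == 0.0 or np.allclose(f, f.mean(), atol=1e-14 * max(1.0, abs(f.mean()))):
        model = SingleExpModel(b=float(f.mean()), a=0.0, tau=float("nan"))
        flags.append("tau_unidentifiable_constant_input")
        return FitResult(model, rss=float(np.sum((f - f.mean()) ** 2)), flags=flags)

    def solve_linear(tau: float) -> tuple[float, float, float]:
        # f ≈ p + q·exp(−t/τ); rise form has a = −q, b = p + q.
        basis = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
        coef, res, *_ = np.linalg.lstsq(basis, f, rcond=None)
        rss = float(np.sum((basis @ coef - f) ** 2))
        return float(coef[0]), float(coef[1]), rss

    grid = _tau_grid(t)
    if init is not None and init > 0:
        grid = np.sort(np.append(grid, float(init)))
    rsses = [solve_linear(tau)[2] for tau in grid]
    i = int(np.argmin(rsses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(lambda lt: solve_linear(math.exp(lt))[2],
                          bounds=(math.log(lo), math.log(hi)), method="bounded",
                          options={"xatol": 1e-12})
    tau = float(math.exp(res.x))
    if res.fun > rsses[i]:
        tau = float(grid[i])
    p, q, rss = solve_linear(tau)
    model = SingleExpModel(b=p + q, a=-q, tau=tau)
    if abs(model.a) < 1e-12 * max(1.0, abs(model.b)):
        flags.append("tau_unidentifiable_zero_amplitude")

    def residual(pv: np.ndarray) -> np.ndarray:
        return SingleExpModel(pv[0], pv[1], pv[2])(t) - f

    stderr = _stderr(residual, np.array([model.b, model.a, model.tau]), rss, t.size,
                     ["b", "a", "tau"])
    return FitResult(model, rss=rss, stderr=stderr, converged=bool(res.success),
                     flags=flags, starts={"tau_grid": [float(g) for g in grid]})


def fit_biexp(t, f, init: tuple[float, float] | None = None) -> FitResult:
    """Least-squares fit of b + a₁[1 − e^{−t/τ₁}] + a₂[1 − e^{−t/τ₂}].

    Multi-start over all ordered pairs from a log-spaced τ grid with exact
    linear solves for (b, a₁, a₂), followed by simplex refinement of
    (log τ₁, log τ₂).  Label symmetry is broken by enforcing τ₁ < τ₂;
    near-equal time constants raise an identifiability warning flag.
    """
    t, f = _check_time(t, f, 6)
    flags: list[str] = []

    def solve_linear(tau1: float, tau2: float):
        basis = np.column_stack([np.ones_like(t), np.exp(-t / tau1), np.exp(-t / tau2)])
        coef, *_ = np.linalg.lstsq(basis, f, rcond=None)
        rss = float(np.sum((basis @ coef - f) ** 2))
        return coef, rss

    grid = _tau_grid(t, n=20)
    if init is not None:
        grid = np.sort(np.append(grid, [x for x in init if x > 0]))
    best = None
    for i1, tau1 in enumerate(grid):
        for tau2 in grid[i1 + 1:]:
            _, rss = solve_linear(tau1, tau2)
            if best is None or rss < best[2]:
                best = (tau1, tau2, rss)
    tau1, tau2, _ = best

    def objective(lp: np.ndarray) -> float:
        return solve_linear(math.exp(lp[0]), math.exp(lp[1]))[1]

    res = minimize(objective, np.log([tau1, tau2]), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-30, "maxiter": 2000})
    tau1, tau2 = sorted(math.exp(x) for x in res.x)
    coef, rss = solve_linear(tau1, tau2)
    # f = p + q1 e1 + q2 e2  ->  rise form b = p + q1 + q2, a_i = −q_i.
    p, q1, q2 = (float(x) for x in coef)
    model = BiExpModel(b=p + q1 + q2, a1=-q1, tau1=tau1, a2=-q2, tau2=tau2)
    if not model.well_separated:
        flags.append("time_constants_poorly_separated")
    if abs(model.a2) < 1e-10 * max(1.0, abs(model.a1)):
        flags.append("second_phase_amplitude_negligible")

    def residual(pv: np.ndarray) -> np.ndarray:
        return BiExpModel(pv[0], pv[1], pv[2], pv[3], pv[4])(t) - f

    stderr = _stderr(residual, np.array([model.b, model.a1, model.tau1, model.a2, model.tau2]),
                     rss, t.size, ["b", "a1", "tau1", "a2", "tau2"])
    return FitResult(model, rss=rss, stderr=stderr, converged=bool(res.success),
                     flags=flags, starts={"tau_grid": [float(g) for g in grid]})


def fit_biexp_joint(t, rows: np.ndarray, init: tuple[float, float] | None = None) -> list[FitResult]:
    """Jointly fit rows with biexponentials sharing (τ₁, τ₂) — global analysis.

    Each row keeps its own baseline and phase amplitudes (linear, solved
    exactly per candidate pair); the shared time constants are scanned on the
    same multi-start grid as :func:`fit_biexp` and refined by simplex.
    Sharing the nonlinear parameters across many observation channels makes
    the time constants far better determined than any single-trace fit.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    t = np.asarray(t, dtype=float)
    for row in rows:
        _check_time(t, row, 6)

    def solve_linear(tau1: float, tau2: float):
        basis = np.column_stack([np.ones_like(t), np.exp(-t / tau1), np.exp(-t / tau2)])
        coef, *_ = np.linalg.lstsq(basis, rows.T, rcond=None)  # 3 x n_rows
        rss = float(np.sum((basis @ coef - rows.T) ** 2))
        return coef, rss

    grid = _tau_grid(t, n=20)
    if init is not None:
        grid = np.sort(np.append(grid, [x for x in init if x > 0]))
    best = None
    for i1, tau1 in enumerate(grid):
        for tau2 in grid[i1 + 1:]:
            _, rss = solve_linear(tau1, tau2)
            if best is None or rss < best[2]:
                best = (tau1, tau2, rss)
    tau1, tau2, _ = best

    res = minimize(lambda lp: solve_linear(math.exp(lp[0]), math.exp(lp[1]))[1],
                   np.log([tau1, tau2]), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-30, "maxiter": 2000})
    tau1, tau2 = sorted(math.exp(x) for x in res.x)
    coef, _total = solve_linear(tau1, tau2)
    flags = [] if tau2 / tau1 >= 3.0 else ["time_constants_poorly_separated"]
    results = []
    for j, row in enumerate(rows):
        p, q1, q2 = (float(x) for x in coef[:, j])
        model = BiExpModel(b=p + q1 + q2, a1=-q1, tau1=tau1, a2=-q2, tau2=tau2)
        rss = float(np.sum((model(t) - row) ** 2))
        results.append(FitResult(model, rss=rss, converged=bool(res.success),
                                 flags=list(flags),
                                 starts={"tau_grid": [float(g) for g in grid]}))
    return results


def fit_damped_sinusoid_joint(
    t,
    rows: np.ndarray,
    fix_epsilon: float | None = None,
    omega_init: float | None = None,
) -> list[FitResult]:
    """Jointly fit coefficient rows with damped sinusoids sharing (ω, τ, ε).

    Each row gets its own amplitude, phase, drift, and baseline — all linear
    given the shared nonlinear parameters, hence solved exactly per candidate.
    ω is scanned on a fixed grid spanning the resolvable band (from one cycle
    over four spans up to the Nyquist limit of the sampling), then (ω, log τ,
    log ε) are refined by simplex.  Rows shorter than one fitted period are
    flagged frequency-unidentifiable.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    t = np.asarray(t, dtype=float)
    for row in rows:
        _check_time(t, row, 8)
    flags: list[str] = []
    span = float(t[-1] - t[0])
    dt = float(np.min(np.diff(t)))

    if np.all(np.abs(rows) < 1e-300) or np.all(np.ptp(rows, axis=1) == 0.0):
        flags.append("zero_amplitude_rows")
        models = [DampedSinusoidModel(0.0, float("nan"), 0.0, 0.0, float(r.mean()),
                                      float("nan")) for r in rows]
        return [FitResult(m, rss=float(np.sum((r - r.mean()) ** 2)), flags=list(flags))
                for m, r in zip(models, rows)]

    def solve_linear(omega: float, tau: float, eps: float):
        env = np.exp(-np.power(np.maximum(t, 0.0) / tau, eps))
        basis = np.column_stack([np.cos(omega * t), np.sin(omega * t), t, np.ones_like(t)])
        basis *= env[:, None]
        coefs, rss_total = [], 0.0
        for row in rows:
            coef, *_ = np.linalg.lstsq(basis, row, rcond=None)
            rss_total += float(np.sum((basis @ coef - row) ** 2))
            coefs.append(coef)
        return coefs, rss_total

    eps0 = 1.0 if fix_epsilon is None else float(fix_epsilon)
    omega_grid = np.geomspace(2 * math.pi / (4 * span), math.pi / dt, 80)
    if omega_init is not None and omega_init > 0:
        omega_grid = np.sort(np.append(omega_grid, float(omega_init)))
    tau_grid = np.geomspace(span / 20.0, span * 4.0, 12)
    best = None
    for om in omega_grid:
        for tau in tau_grid:
            _, rss = solve_linear(om, tau, eps0)
            if best is None or rss < best[2]:
                best = (om, tau, rss)
    om0, tau0, _ = best

    if fix_epsilon is None:
        x0 = np.array([om0, math.log(tau0), 0.0])

        def objective(x):
            if x[0] <= 0:
                return 1e300
            return solve_linear(x[0], math.exp(x[1]), math.exp(x[2]))[1]
    else:
        x0 = np.array([om0, math.log(tau0)])

        def objective(x):
            if x[0] <= 0:
                return 1e300
            return solve_linear(x[0], math.exp(x[1]), eps0)[1]

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-30, "maxiter": 4000})
    omega = float(res.x[0])
    tau = float(math.exp(res.x[1]))
    eps = eps0 if fix_epsilon is not None else float(math.exp(res.x[2]))
    coefs, rss_total = solve_linear(omega, tau, eps)
    if span * omega < 2 * math.pi:
        flags.append("frequency_unidentifiable_less_than_one_period")

    results = []
    for coef, row in zip(coefs, rows):
        A, B, c, b = (float(x) for x in coef)
        a = math.hypot(A, B)
        alpha = math.atan2(B, A)
        model = DampedSinusoidModel(a=a, omega=omega, alpha=alpha, c=c, b=b,
                                    tau=tau, epsilon=eps)
        rss = float(np.sum((model(t) - row) ** 2))
        results.append(FitResult(model, rss=rss, converged=bool(res.success),
                                 flags=list(flags),
                                 starts={"omega_grid_size": int(omega_grid.size)}))
    return results


# ---------------------------------------------------------------------------
# Physical conversions for oscillation analysis


def wavenumber_to_period(wavenumber_cm: float) -> float:
    """Oscillation period in picoseconds for a wavenumber in cm⁻¹."""
    if wavenumber_cm <= 0:
        raise ValueError("wavenumber must be positive")
    return 1.0 / (SPEED_OF_LIGHT_CM_S * wavenumber_cm) * 1e12


def wavenumber_to_thz(wavenumber_cm: float) -> float:
    """Frequency in THz for a wavenumber in cm⁻¹."""
    if wavenumber_cm <= 0:
        raise ValueError("wavenumber must be positive")
    return SPEED_OF_LIGHT_CM_S * wavenumber_cm / 1e12


def acoustic_wavelength(velocity_km_s: float, wavenumber_cm: float,
                        standing_wave: bool = False) -> float:
    """Wavelength in Å of a mechanical wave of given velocity and wavenumber.

    λ = v / (c·ν̃).  With ``standing_wave=True`` returns 2λ, the cavity
    thickness a standing wave of this frequency corresponds to.
    """
    if velocity_km_s <= 0 or wavenumber_cm <= 0:
        raise ValueError("velocity and wavenumber must be positive")
    v_cm_s = velocity_km_s * 1e5
    lam_cm = v_cm_s / (SPEED_OF_LIGHT_CM_S * wavenumber_cm)
    lam_angstrom = lam_cm * 1e8
    return 2.0 * lam_angstrom if standing_wave else lam_angstrom


def size_ratio_from_masses(masses_kda, reference_index: int = 0) -> np.ndarray:
    """Relative linear sizes of near-globular proteins from cube-root mass ratios."""
    masses = np.asarray(masses_kda, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    ref = masses[reference_index]
    return np.cbrt(masses / ref)
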