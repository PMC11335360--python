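"""Rotations in the significant SVD subspace.

The rotation theorem: applying one and the same planar rotation to a pair of
basis components (U_h, U_k) and to their coefficient rows (c_h, c_k) leaves
every reconstituted observation unchanged,

    c_h U_h + c_k U_k = f_h R_h + f_k R_k,

because the dot product of two vectors is invariant when both rotate by the
same angle.  Composing such pairwise steps gives an arbitrary rotation of the
n-dimensional subspace, which re-expresses the factorization A = U W Vᵀ as an
alternative solution A = R S Tᵀ without introducing or destroying any signal.
A well-chosen rotation isolates one physical process (a single-exponential
time course, a pure-state spectrum, a systematic-error component) into a
single dimension — the deconvolution step that plain SVD cannot perform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .core_data import MetadataTable, RowAddressing
from .svd_engine import CoefficientSet, SingularTriplets

__all__ = [
    "RotationStep",
    "RotationPlan",
    "RotatedBasis",
    "as_rotated",
    "rotate_pair",
    "apply_plan",
    "verticalize",
    "optimize_to_model",
    "invariance_report",
    "AmbiguousRotationError",
]


class AmbiguousRotationError(ValueError):
    """The scatter has no preferred direction; the rotation angle is undefined."""


@dataclass(frozen=True)
class RotationStep:
    """One planar rotation: dimension pair (h < k, 1-based) and angle in degrees.

    The angle is counterclockwise positive in the (h, k) plane.
    """

    h: int
    k: int
    theta_deg: float

    def __post_init__(self) -> None:
        if self.h == self.k:
            raise ValueError("rotation plane needs two distinct dimensions")
        if self.h > self.k:
            raise ValueError("dimension pair must satisfy h < k")
        if self.h < 1:
            raise ValueError("dimensions are 1-based")
        if not math.isfinite(self.theta_deg):
            raise ValueError("rotation angle must be finite")


@dataclass
class RotationPlan:
    """An ordered, replayable sequence of pairwise rotation steps.

    Pairwise rotations do not commute, so the order is significant and is
    preserved by (de)serialization.
    """

    steps: list[RotationStep] = field(default_factory=list)
    n_dims: int | None = None

    def __post_init__(self) -> None:
        if self.n_dims is not None:
            for s in self.steps:
                if s.k > self.n_dims:
                    raise ValueError(f"step {s} exceeds subspace dimension {self.n_dims}")

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def inverse(self) -> "RotationPlan":
        return RotationPlan(
            [RotationStep(s.h, s.k, -s.theta_deg) for s in reversed(self.steps)],
            self.n_dims,
        )

    def to_json(self) -> str:
        return json.dumps(
            {"n_dims": self.n_dims,
             "steps": [{"h": s.h, "k": s.k, "theta_deg": s.theta_deg} for s in self.steps]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RotationPlan":
        d = json.loads(text)
        return cls([RotationStep(s["h"], s["k"], s["theta_deg"]) for s in d["steps"]],
                   d.get("n_dims"))


@dataclass
class RotatedBasis:
    """Alternative factorization R S Tᵀ of the significant subspace.

    ``r`` holds the rotated components in columns (M × n) and ``f`` the
    coefficient rows f_kj (n × N).  The rotated singular values are
    s_k = sqrt(Σ_j f_kj²) and the rotated right vectors are the unit-norm rows
    t_k = f_k / s_k.  After rotation the singular values are generally no
    longer in descending order; components keep their original indices.
    """

    r: np.ndarray
    f: np.ndarray
    addressing: RowAddressing
    metadata: MetadataTable
    history: RotationPlan = field(default_factory=RotationPlan)

    @property
    def n_dims(self) -> int:
        return self.f.shape[0]

    @property
    def s(self) -> np.ndarray:
        return np.linalg.norm(self.f, axis=1)

    @property
    def t(self) -> np.ndarray:
        s = self.s
        safe = np.where(s > 0, s, 1.0)
        return self.f / safe[:, None]

    @property
    def coefficients(self) -> CoefficientSet:
        return CoefficientSet(self.f, self.metadata)

    def reconstruction(self) -> np.ndarray:
        """Subspace reconstitution Σ_k f_kj R_k for every observation."""
        return self.r @ self.f

    def copy(self) -> "RotatedBasis":
        return RotatedBasis(self.r.copy(), self.f.copy(), self.addressing,
                            self.metadata, RotationPlan(list(self.history.steps), self.n_dims))


def as_rotated(basis: SingularTriplets | RotatedBasis, n: int | None = None) -> RotatedBasis:
    """View the top-n singular triplets as an (un-rotated) RotatedBasis."""
    if isinstance(basis, RotatedBasis):
        return basis.copy()
    n = basis.rank if n is None else int(n)
    if not 1 <= n <= basis.n_components:
        raise ValueError(f"subspace dimension must be in [1, {basis.n_components}]")
    f = basis.w[:n, None] * basis.v[:, :n].T
    return RotatedBasis(basis.u[:, :n].copy(), f, basis.addressing, basis.metadata,
                        RotationPlan([], n))


def rotate_pair(
    basis: SingularTriplets | RotatedBasis,
    h: int,
    k: int,
    theta_deg: float,
) -> RotatedBasis:
    """Rotate dimensions (h, k) by θ, applied to components and coefficients.

    R_h = U_h cosθ − U_k sinθ, R_k = U_h sinθ + U_k cosθ, and the coefficient
    rows transform identically, so every reconstituted observation is
    unchanged.  Dimensions outside the pair are untouched.
    """
    step = RotationStep(min(h, k), max(h, k), float(theta_deg))
    if (h, k) != (step.h, step.k):
        raise ValueError("dimension pair must satisfy h < k")
    out = as_rotated(basis)
    if step.k > out.n_dims:
        raise IndexError(f"dimension {step.k} exceeds subspace dimension {out.n_dims}")
    th = math.radians(step.theta_deg)
    c, s = math.cos(th), math.sin(th)
    i, j = step.h - 1, step.k - 1
    rh, rk = out.r[:, i].copy(), out.r[:, j].copy()
    out.r[:, i] = rh * c - rk * s
    out.r[:, j] = rh * s + rk * c
    fh, fk = out.f[i].copy(), out.f[j].copy()
    out.f[i] = fh * c - fk * s
    out.f[j] = fh * s + fk * c
    out.history.steps.append(step)
    out.history.n_dims = out.n_dims
    return out


def apply_plan(
    basis: SingularTriplets | RotatedBasis,
    plan: RotationPlan,
) -> RotatedBasis:
    """Apply the steps of a rotation plan in order."""
    out = as_rotated(basis)
    for step in plan:
        out = rotate_pair(out, step.h, step.k, step.theta_deg)
    return out


def verticalize(coeffs: CoefficientSet | RotatedBasis, h: int, k: int) -> float:
    """Angle θ (degrees) that makes the (c_h, c_k) trajectory vertical.

    Solved in closed form as the principal-axis angle of the centered 2-D
    scatter: the returned θ minimizes the variance of the rotated f_h over
    observations, so an exactly collinear trajectory ends up along dimension k
    alone with f_h constant.  θ is reported in (−90°, 90°].
    """
    cs = coeffs.coefficients if isinstance(coeffs, RotatedBasis) else coeffs
    if max(h, k) > cs.n_dims or min(h, k) < 1 or h == k:
        raise ValueError("invalid dimension pair")
    x = cs.c[h - 1]
    y = cs.c[k - 1]
    if x.size < 3:
        raise ValueError("need at least 3 observations to determine an angle")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    total = sxx + syy
    if total == 0.0:
        raise AmbiguousRotationError("all points coincide; no preferred direction")
    aniso = math.hypot(syy - sxx, 2.0 * sxy) / total
    if aniso < 1e-9:
        raise AmbiguousRotationError(
            f"scatter is isotropic (anisotropy {aniso:.2e}); rotation angle is undefined"
        )
    # Var(f_h) = sxx cos²θ − sxy sin2θ + syy sin²θ is stationary at
    # tan(2θ) = 2 sxy / (syy − sxx); of the two stationary angles 90° apart,
    # pick the variance minimum and map into (−90°, 90°].
    theta = 0.5 * math.atan2(2.0 * sxy, syy - sxx)

    def var_fh(t: float) -> float:
        return sxx * math.cos(t) ** 2 - sxy * math.sin(2 * t) + syy * math.sin(t) ** 2

    if var_fh(theta) > var_fh(theta + math.pi / 2):
        theta += math.pi / 2
    deg = math.degrees(theta)
    while deg <= -90.0:
        deg += 180.0
    while deg > 90.0:
        deg -= 180.0
    return deg


def invariance_report(
    before: SingularTriplets | RotatedBasis,
    after: SingularTriplets | RotatedBasis,
) -> float:
    """Maximum absolute deviation between subspace reconstitutions.

    The rotation theorem guarantees this is ≈ 0 (< 1e−10) for any genuine
    rotation plan; a larger value signals an inconsistent transformation
    (e.g., components and coefficients rotated by different angles).
    """
    b = as_rotated(before)
    a = as_rotated(after)
    if b.n_dims != a.n_dims:
        raise ValueError("bases span different subspace dimensions")
    return float(np.max(np.abs(b.reconstruction() - a.reconstruction())))


def _model_rss(model: str, t: np.ndarray, f: np.ndarray) -> float:
    from . import kinetics

    if model == "single_exp":
        return kinetics.fit_single_exp(t, f).rss
    if model == "biexp":
        return kinetics.fit_biexp(t, f).rss
    raise ValueError(f"unsupported model family {model!r}")


def optimize_to_model(
    basis: SingularTriplets | RotatedBasis,
    target_dim: int,
    model: str = "single_exp",
    metadata_axis: str | None = None,
    search_dims: "list[int] | None" = None,
    coarse_step_deg: float = 2.0,
) -> tuple[RotationPlan, "object"]:
    """Find pairwise rotations that make f_{target} follow a kinetic model.

    For each dimension in ``search_dims`` (in the given order) the angle of
    the planar rotation pairing it with ``target_dim`` is scanned on a coarse
    grid (default 2° over (−90°, 90°]) and then refined locally, minimizing
    the residual sum of squares of the requested model family fitted to the
    target coefficient row against the metadata axis.  Deterministic and
    seed-free; returns the composed plan and the final fit.  If no angle
    improves on the starting objective for a pair, that pair contributes an
    identity step (θ = 0).
    """
    from . import kinetics
    from scipy.optimize import minimize_scalar

    work = as_rotated(basis)
    n = work.n_dims
    if not 1 <= target_dim <= n:
        raise ValueError("target dimension outside the subspace")
    if search_dims is None:
        search_dims = [d for d in range(1, n + 1) if d != target_dim]
    if any(d == target_dim or not 1 <= d <= n for d in search_dims):
        raise ValueError("search dims must be within the subspace and differ from the target")
    t = work.metadata.axis_values(metadata_axis)

    plan = RotationPlan([], n)
    for d in search_dims:
        h, k = (d, target_dim) if d < target_dim else (target_dim, d)

        def objective(theta: float) -> float:
            trial = rotate_pair(work, h, k, theta)
            return _model_rss(model, t, trial.f[target_dim - 1])

        grid = np.arange(-90.0 + coarse_step_deg, 90.0 + 1e-9, coarse_step_deg)
        grid = np.concatenate(([0.0], grid))  # evaluate identity first
        vals = [objective(g) for g in grid]
        best = int(np.argmin(vals))
        res = minimize_scalar(
            objective,
            bounds=(grid[best] - coarse_step_deg, grid[best] + coarse_step_deg),
            method="bounded",
            options={"xatol": 1e-6},
        )
        theta_best, val_best = float(res.x), float(res.fun)
        if vals[best] < val_best:  # keep grid point if refinement regressed
            theta_best, val_best = float(grid[best]), float(vals[best])
        if val_best >= vals[0] - 1e-15:  # no genuine improvement over identity
            theta_best = 0.0
        step = RotationStep(h, k, theta_best)
        work = rotate_pair(work, h, k, theta_best)
        plan.steps.append(step)

    if model == "single_exp":
        fit = kinetics.fit_single_exp(t, work.f[target_dim - 1])
    else:
        fit = kinetics.fit_biexp(t, work.f[target_dim - 1])
    return plan, fit
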