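"""Pure-state extrapolation along the invariant reaction trajectory.

After a rotation has isolated one process into a single subspace dimension,
the observed coefficient points trace a straight segment of the reaction
trajectory.  The fitted kinetic model extends that segment to its limits:
the zero-progress point (t → 0 pre-reaction limit of the rise form, f_k = 0)
and the completed-reaction point (t → ∞, f_k = a + b).  Those extrapolated
coordinates, combined linearly with the rotated components, reconstruct the
spectra or maps of the unmixed species, and any observed point maps to a
composition fraction between the two endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import FitResult, SingleExpModel
from .rotation import RotatedBasis

__all__ = [
    "TrajectoryModel",
    "PureState",
    "extrapolate_endpoints",
    "reconstruct_state",
    "composition_fraction",
]


@dataclass
class TrajectoryModel:
    """A fitted linear reaction trajectory in the rotated subspace.

    ``varying_dim`` is the 1-based dimension carrying the kinetics;
    ``constant_values`` hold the remaining (fitted-constant) coordinates; the
    start/end points are the model's zero-progress and completion limits.
    """

    varying_dim: int
    fit: FitResult
    constant_values: np.ndarray  # full n-vector; entry at varying_dim is ignored
    start_point: np.ndarray
    end_point: np.ndarray

    @property
    def n_dims(self) -> int:
        return self.constant_values.size

    def point_at(self, f_value: float) -> np.ndarray:
        """Subspace coordinates for a given value of the varying coefficient."""
        p = self.constant_values.copy()
        p[self.varying_dim - 1] = f_value
        return p


@dataclass
class PureState:
    """An extrapolated unmixed species: subspace coordinates + reconstruction."""

    coordinates: np.ndarray
    reconstruction: np.ndarray
    label: str = ""
    provenance: dict = field(default_factory=dict)


def extrapolate_endpoints(
    fit: FitResult,
    varying_dim: int,
    constant_values,
) -> TrajectoryModel:
    """Build the trajectory from a single-exponential fit of one dimension.

    The start endpoint corresponds to zero reaction progress — the rise form
    extrapolated to f_k = 0, which may lie before the first recorded
    observation when the experiment began with a partially converted sample.
    The end endpoint is the t → ∞ plateau f_k = a + b.  All other dimensions
    are carried through at their constant values.  A zero-amplitude model
    (a = 0) describes no reaction at all: the trajectory degenerates and both
    endpoints coincide at the constant value b.
    """
    model = fit.model
    if not isinstance(model, SingleExpModel):
        raise TypeError("endpoint extrapolation requires a single-exponential trajectory fit")
    if any("unidentifiable" in fl for fl in fit.flags):
        raise ValueError("cannot extrapolate an unidentifiable fit: " + ", ".join(fit.flags))
    constant_values = np.asarray(constant_values, dtype=float).copy()
    if not 1 <= varying_dim <= constant_values.size:
        raise ValueError("varying dimension outside the coordinate vector")
    start = constant_values.copy()
    start[varying_dim - 1] = 0.0 if model.a != 0.0 else model.plateau
    end = constant_values.copy()
    end[varying_dim - 1] = model.plateau
    return TrajectoryModel(varying_dim, fit, constant_values, start, end)


def reconstruct_state(
    basis: RotatedBasis,
    point,
    label: str = "",
) -> PureState:
    """Reconstruct the spectrum/map at a subspace coordinate: Σ_k point_k R_k."""
    point = np.asarray(point, dtype=float)
    if point.ndim != 1 or point.size > basis.n_dims:
        raise ValueError(f"point must be a vector of dimension <= {basis.n_dims}")
    recon = basis.r[:, : point.size] @ point
    return PureState(
        coordinates=point.copy(),
        reconstruction=recon,
        label=label,
        provenance={"rotation_steps": len(basis.history), "n_dims": basis.n_dims},
    )


def composition_fraction(
    value,
    trajectory: TrajectoryModel,
) -> tuple[float, bool]:
    """Fractional reaction progress of a point between the two endpoints.

    ``value`` is either the varying coefficient alone or a full coordinate
    vector (the varying dimension is extracted).  Returns (fraction,
    within_range); 0 at the start endpoint, 1 at the end endpoint.  Fractions
    outside [0, 1] mark over-extrapolated points and are reported unclamped
    with ``within_range=False``.
    """
    k = trajectory.varying_dim - 1
    f0 = trajectory.start_point[k]
    f1 = trajectory.end_point[k]
    if f0 == f1:
        raise ValueError("coincident endpoints: zero-length trajectory")
    v = np.asarray(value, dtype=float)
    fval = float(v[k]) if v.ndim == 1 else float(v)
    frac = (fval - f0) / (f1 - f0)
    return frac, bool(0.0 <= frac <= 1.0)
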