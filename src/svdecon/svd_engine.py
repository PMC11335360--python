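"""Singular value decomposition of the core matrix and low-rank reconstitution.

Factorizes A = U W Vᵀ, screens the number of significant singular triplets,
reconstitutes observations from any chosen subset of components (allowing the
exclusion of identified systematic-error components), and exposes the scaled
coefficients c_kj = w_k v_kj whose per-observation points trace the reaction
trajectory in the significant Euclidean subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CoreMatrix, MetadataTable, RowAddressing

__all__ = [
    "SingularTriplets",
    "CoefficientSet",
    "decompose",
    "screen_rank",
    "reconstitute",
    "coefficients",
]

SIGN_CONVENTION = "largest-magnitude element of each left singular vector positive"

ORTHO_TOL = 1e-10


@dataclass
class SingularTriplets:
    """Thin SVD of the core matrix: U (M×N), w (N, descending), V (N×N).

    ``rank`` is the retained effective rank n; the sign convention used to fix
    the inherent ± ambiguity of each singular pair is recorded alongside.
    """

    u: np.ndarray
    w: np.ndarray
    v: np.ndarray  # columns are right singular vectors
    rank: int
    addressing: RowAddressing
    metadata: MetadataTable
    sign_convention: str = SIGN_CONVENTION

    @property
    def n_components(self) -> int:
        return self.w.size

    @property
    def vt(self) -> np.ndarray:
        return self.v.T

    def reconstruct(self) -> np.ndarray:
        """Full product U·diag(w)·Vᵀ (machine-precision copy of A)."""
        return (self.u * self.w) @ self.v.T


@dataclass
class CoefficientSet:
    """Coefficient rows c_k = w_k · Vᵀ_k for the top-n triplets.

    ``points`` stacks the per-observation coordinate vectors
    P_j = (c_1j, …, c_nj); any two dimensions give an orthographic projection
    of the trajectory through the conformational subspace.
    """

    c: np.ndarray  # n x N
    metadata: MetadataTable

    @property
    def n_dims(self) -> int:
        return self.c.shape[0]

    @property
    def points(self) -> np.ndarray:
        """N × n array of subspace coordinates, one row per observation."""
        return self.c.T

    def projection(self, h: int, k: int) -> np.ndarray:
        """N × 2 orthographic projection onto dimensions h, k (1-based)."""
        return self.c[[h - 1, k - 1], :].T


def decompose(matrix: CoreMatrix | np.ndarray) -> SingularTriplets:
    """Compute the thin SVD of the core matrix with a deterministic sign fix.

    The matrix must be tall (M ≥ N) and finite.  Each left singular vector is
    flipped, together with its right partner, so that its largest-magnitude
    element is positive, making exported component maps/spectra reproducible.
    """
    if isinstance(matrix, CoreMatrix):
        a = matrix.matrix
        addressing, metadata = matrix.addressing, matrix.metadata
    else:
        a = np.asarray(matrix, dtype=float)
        addressing = RowAddressing()
        metadata = MetadataTable(pd.DataFrame(index=range(a.shape[1])))
    if not np.all(np.isfinite(a)):
        raise ValueError("core matrix contains non-finite entries")
    m, n = a.shape
    if m < n:
        raise ValueError(
            f"matrix must be tall (M >= N); got {m} x {n} — transpose is not applied implicitly"
        )
    if n < 2:
        raise ValueError("need at least two observations")
    u, w, vt = np.linalg.svd(a, full_matrices=False)
    v = vt.T
    # Deterministic sign convention applied jointly to each (U_k, V_k) pair.
    for k in range(n):
        i = int(np.argmax(np.abs(u[:, k])))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    return SingularTriplets(u, w, v, rank=n, addressing=addressing, metadata=metadata)


def screen_rank(
    w: np.ndarray | SingularTriplets,
    method: str = "gap",
    parameter: float = 0.01,
) -> int:
    """Estimate the effective rank n from the singular-value spectrum.

    ``gap`` returns the index before the largest adjacent ratio w_k/w_{k+1};
    ``threshold`` counts values at least ``parameter`` × w₁.  Rank selection by
    scree-plot inspection is inherently judgement-laden, so callers may always
    override the result.
    """
    if isinstance(w, SingularTriplets):
        w = w.w
    w = np.asarray(w, dtype=float)
    if np.any(np.diff(w) > 0):
        raise ValueError("singular values must be in descending order")
    if not np.any(w > 0):
        raise ValueError("all singular values are zero")
    if method == "threshold":
        return int(np.count_nonzero(w >= parameter * w[0]))
    if method != "gap":
        raise ValueError("method must be 'gap' or 'threshold'")
    if w.size == 1:
        return 1
    with np.errstate(divide="ignore"):
        ratios = np.where(w[1:] > 0, w[:-1] / np.maximum(w[1:], 1e-300), np.inf)
    # A zero tail makes the ratio infinite at the first zero: rank stops there.
    return int(np.argmax(ratios)) + 1


def reconstitute(
    triplets: SingularTriplets,
    components: "list[int] | range | None" = None,
    column: int | None = None,
) -> np.ndarray:
    """Low-rank approximation Σ_{k∈K} w_k v_kj U_k (1-based component indices).

    With ``components=None`` the top-``rank`` components are used.  Selecting
    all N components reproduces the original matrix to machine precision;
    omitting an identified systematic-error component removes it from every
    reconstituted observation.  Returns the full M × N matrix, or one column.
    """
    n_total = triplets.n_components
    if components is None:
        components = range(1, triplets.rank + 1)
    idx = np.asarray(sorted(set(int(k) for k in components))) - 1
    if idx.size == 0:
        raise ValueError("component set K must be non-empty")
    if idx.min() < 0 or idx.max() >= n_total:
        raise IndexError("component index out of range (1-based)")
    u = triplets.u[:, idx]
    wv = triplets.w[idx, None] * triplets.v[:, idx].T  # |K| x N
    if column is not None:
        return u @ wv[:, column]
    return u @ wv


def coefficients(triplets: SingularTriplets, n: int | None = None) -> CoefficientSet:
    """Coefficient rows c_kj = w_k v_kj for the top-n singular triplets."""
    n = triplets.rank if n is None else int(n)
    if not 1 <= n <= triplets.n_components:
        raise ValueError(f"n must be in [1, {triplets.n_components}]")
    c = triplets.w[:n, None] * triplets.v[:, :n].T
    return CoefficientSet(c, triplets.metadata)
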