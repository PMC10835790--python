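"""Blood rheology: Carreau–Yasuda viscosity and the shear-rate scalar.

Blood is shear-thinning: apparent viscosity falls from a zero-shear plateau
``mu_0`` to an infinite-shear plateau ``mu_inf`` as the shear rate grows.
The Carreau–Yasuda law interpolates between the plateaus,

    mu(γ̇) = mu_inf + (mu_0 − mu_inf) · (1 + (λ·γ̇)^a)^((n−1)/a),

with power index ``n``, transition sharpness ``a`` and time constant ``λ``.
The shear rate itself is the scalar γ̇ = sqrt(2 D:D) built from the rate of
deformation tensor D = (∇u + ∇uᵀ)/2 — the standard invariant used to feed a
generalized-Newtonian law, and an index of mechanical platelet activation.

This module provides the constitutive law, the stress τ = mu(γ̇)·γ̇, and the
γ̇ operator both pointwise (on a 3×3 velocity-gradient tensor) and on
rectilinear gridded velocity fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConstitutiveModelError, DomainError, GridTooSmallError

__all__ = [
    "RheologyParams",
    "BLOOD",
    "carreau_yasuda_viscosity",
    "shear_stress",
    "shear_rate_scalar",
    "shear_rate_field",
    "VelocityGrid",
    "ScalarField",
    "read_velocity_csv",
    "write_scalar_csv",
]


@dataclass(frozen=True)
class RheologyParams:
    """Carreau–Yasuda constants.

    Parameters
    ----------
    mu_inf : float
        Infinite-shear viscosity, Pa·s.
    mu_0 : float
        Zero-shear viscosity, Pa·s.  ``mu_0 >= mu_inf``.
    n : float
        Power index, dimensionless, in (0, 1].
    a : float
        Transition parameter, dimensionless, > 0.
    lam : float
        Time constant λ, s, > 0.

    On construction the stress law τ(γ̇) = mu(γ̇)·γ̇ is scanned on a dense
    logarithmic grid over [0, 1e6] 1/s; parameter sets for which τ is not
    strictly increasing are rejected (the profile solver would be ill-posed).
    """

    mu_inf: float
    mu_0: float
    n: float
    a: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.mu_0 >= self.mu_inf > 0):
            raise DomainError(
                f"require mu_0 >= mu_inf > 0, got mu_0={self.mu_0}, mu_inf={self.mu_inf}"
            )
        if not (self.a > 0 and self.lam > 0 and 0 < self.n <= 1):
            raise DomainError(
                f"require a > 0, lam > 0, 0 < n <= 1; got a={self.a}, lam={self.lam}, n={self.n}"
            )
        g = np.logspace(-6, 6, 2001)
        tau = shear_stress(g, self, _validate=False)
        if np.any(np.diff(tau) <= 0):
            raise ConstitutiveModelError(
                "shear stress is not strictly increasing on [0, 1e6] 1/s"
            )

    @property
    def is_newtonian(self) -> bool:
        """True when the two plateaus coincide (constant viscosity)."""
        return self.mu_0 == self.mu_inf

    @classmethod
    def newtonian(cls, mu: float) -> "RheologyParams":
        """Degenerate constant-viscosity parameter set (mu_0 = mu_inf = mu)."""
        return cls(mu_inf=mu, mu_0=mu, n=1.0, a=1.0, lam=1.0)


def carreau_yasuda_viscosity(gamma_dot, params: RheologyParams):
    """Apparent viscosity mu(γ̇) in Pa·s.

    Monotone non-increasing in γ̇, bounded by [mu_inf, mu_0]; well defined at
    γ̇ = 0 where it equals mu_0.  Accepts scalars or arrays; γ̇ must be >= 0.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0) or not np.all(np.isfinite(g)):
        raise DomainError("shear rate must be finite and >= 0")
    mu = params.mu_inf + (params.mu_0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    return mu if mu.ndim else float(mu)


def shear_stress(gamma_dot, params: RheologyParams, *, _validate: bool = True):
    """Shear stress τ = mu(γ̇)·γ̇ in Pa (scalar or array)."""
    if _validate:
        g = np.asarray(gamma_dot, dtype=float)
        if np.any(g < 0) or not np.all(np.isfinite(g)):
            raise DomainError("shear rate must be finite and >= 0")
    g = np.asarray(gamma_dot, dtype=float)
    mu = params.mu_inf + (params.mu_0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    tau = mu * g
    return tau if tau.ndim else float(tau)


#: Whole-blood Carreau–Yasuda constants used throughout the venous model.
BLOOD = RheologyParams(mu_inf=0.0035, mu_0=0.16, n=0.2128, a=0.64, lam=8.2)


def shear_rate_scalar(velocity_gradient) -> float:
    """Shear-rate invariant γ̇ = sqrt(2 D:D) of a 3×3 velocity gradient (1/s).

    ``velocity_gradient[i, j]`` holds ∂u_i/∂x_j.  The antisymmetric (rigid
    rotation) part of the gradient does not contribute: D is the symmetric
    part, and the double contraction D:D sums the squares of its entries.
    """
    grad = np.asarray(velocity_gradient, dtype=float)
    if grad.shape != (3, 3):
        raise DomainError(f"expected a 3x3 tensor, got shape {grad.shape}")
    if not np.all(np.isfinite(grad)):
        raise DomainError("velocity gradient entries must be finite")
    d = 0.5 * (grad + grad.T)
    return float(np.sqrt(2.0 * np.sum(d * d)))


@dataclass
class VelocityGrid:
    """Velocity components (u, v, w) in mm/s on a rectilinear 3D grid.

    ``spacing`` is the grid step per axis in mm (3-sequence or scalar).
    """

    spacing: tuple
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
        if not (self.u.shape == self.v.shape == self.w.shape):
            raise DomainError("u, v, w must share one shape")
        if any(s <= 0 for s in self.spacing):
            raise DomainError("grid spacing must be > 0")


@dataclass
class ScalarField:
    """Shear rate γ̇ per grid node (1/s), non-negative by construction."""

    spacing: tuple
    values: np.ndarray = field(repr=False)


def shear_rate_field(grid: VelocityGrid) -> ScalarField:
    """Evaluate γ̇ = sqrt(2 D:D) node-by-node on a gridded velocity field.

    Gradients use second-order central differences in the interior and
    first-order one-sided differences on the boundary; each axis needs at
    least 3 nodes.
    """
    if any(s < 3 for s in grid.u.shape):
        raise GridTooSmallError(
            f"need >= 3 nodes per axis for gradients, got shape {grid.u.shape}"
        )
    comps = (grid.u, grid.v, grid.w)
    # grads[i][j] = d(comp_i)/d(axis_j)
    grads = [np.gradient(c, *grid.spacing, edge_order=1) for c in comps]
    dd = np.zeros_like(grid.u)
    for i in range(3):
        for j in range(3):
            dij = 0.5 * (grads[i][j] + grads[j][i])
            dd += dij * dij
    return ScalarField(spacing=grid.spacing, values=np.sqrt(2.0 * dd))


def read_velocity_csv(path, shape, spacing) -> VelocityGrid:
    """Read a velocity grid from CSV columns (x, y, z, u, v, w).

    Rows must enumerate the grid in C order for the given ``shape``; the
    coordinate columns are present for human readability and are not
    re-gridded.
    """
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.shape[0] != int(np.prod(shape)):
        raise DomainError(
            f"CSV has {data.shape[0]} rows, expected {int(np.prod(shape))} for shape {shape}"
        )
    u, v, w = (data[:, 3 + k].reshape(shape) for k in range(3))
    return VelocityGrid(spacing=spacing, u=u, v=v, w=w)


def write_scalar_csv(path, fld: ScalarField) -> None:
    """Write a scalar field to CSV columns (i, j, k, value)."""
    idx = np.indices(fld.values.shape).reshape(3, -1).T
    out = np.column_stack([idx, fld.values.ravel()])
    np.savetxt(path, out, delimiter=",", header="i,j,k,shear_rate_1_s", comments="")
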