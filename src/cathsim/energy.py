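"""Quadratic-form representation of the total potential energy.

Every term of the total potential

    Pi = U_e + U_p - W

is expressed as a quadratic polynomial E(t) = 1/2 t^T H t + g^T t + c over the
stacked free tangents t = (t_1^T, ..., t_{N-1}^T)^T:

* U_e — Kirchhoff bending energy of the centerline.  With piecewise-linear
  tangent interpolation, t'(s) = (t_i - t_{i-1}) / h_i on element i, so the
  discretized energy is the closed form

      U_e = alpha * sum_i ||t_i - t_{i-1}||^2 / h_i .

* U_p — vessel-wall penalty.  Each active node-triangle contact j contributes
  Hooke-law energy 1/2 kappa g(x_j)^2 where g(x) = n·x + d is the (inward-
  positive) plane distance; substituting the affine position map x = B t + c
  makes this quadratic in t.

* W — work of external nodal forces, W = sum_i f_i · (x_i - x_i0), with x_i0
  the node's position at the last equilibrium; linear in t.

Minimizing Pi (the standard total-potential convention) gives physically
correct response to applied forces; the sign convention on W is selectable
because kinematically driven simulations carry no external forces at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catheter import CatheterState
from .errors import ValidationError

STANDARD = "standard"
WORK_ADDED = "work_added"  # the work term enters the potential with a plus sign


@dataclass
class QuadraticForm:
    """E(t) = 1/2 t^T H t + g^T t + c over the stacked free tangents."""

    H: np.ndarray
    g: np.ndarray
    c: float = 0.0

    def __post_init__(self):
        self.H = np.asarray(self.H, float)
        self.g = np.asarray(self.g, float).reshape(-1)
        if self.H.shape != (len(self.g), len(self.g)):
            raise ValidationError("H and g dimensions do not conform")
        self.H = 0.5 * (self.H + self.H.T)  # symmetrize at construction
        self.c = float(self.c)

    @classmethod
    def zero(cls, dim: int) -> "QuadraticForm":
        return cls(np.zeros((dim, dim)), np.zeros(dim), 0.0)

    @property
    def dim(self) -> int:
        return len(self.g)

    def __add__(self, other: "QuadraticForm") -> "QuadraticForm":
        if self.dim != other.dim:
            raise ValidationError("cannot add forms of different dimension")
        return QuadraticForm(self.H + other.H, self.g + other.g, self.c + other.c)

    def evaluate(self, t) -> float:
        t = np.asarray(t, float).reshape(-1)
        if len(t) != self.dim:
            raise ValidationError("argument dimension does not match form")
        return float(0.5 * t @ self.H @ t + self.g @ t + self.c)

    def gradient(self, t) -> np.ndarray:
        t = np.asarray(t, float).reshape(-1)
        return self.H @ t + self.g


@dataclass(frozen=True)
class MaterialParams:
    """Bending constant alpha and vessel-wall stiffness kappa.

    alpha scales the bending energy (energy·mm); kappa is the Hooke modulus of
    the wall (energy/mm^2).  Units are working units: only the ratio
    alpha : kappa : force magnitude shapes the equilibrium.
    """

    alpha: float = 1.0
    kappa: float = 100.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValidationError("alpha must be > 0")
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")


@dataclass
class ExternalLoad:
    """Nodal forces and the reference (last-equilibrium) positions.

    ``forces`` maps node index (>= 1) to a 3-vector; ``reference_positions``
    is the (N, 3) array of positions at the previous equilibrium, so the work
    of each force is f_i · (x_i - x_i0).
    """

    forces: dict = field(default_factory=dict)
    reference_positions: np.ndarray | None = None

    def validate_for(self, state: CatheterState) -> None:
        for i in self.forces:
            if not 1 <= i < state.n_nodes:
                raise ValidationError(f"force on invalid node index {i} (N={state.n_nodes})")


def elastic_quadratic(state: CatheterState, params: MaterialParams) -> QuadraticForm:
    """Bending energy U_e = alpha sum_i ||t_i - t_{i-1}||^2 / h_i as a quadratic form.

    The fixed boundary tangent t_0 folds into the linear and constant parts.
    The Hessian restricted to the free tangents is positive definite (the
    energy is a sum of squares and vanishes only when all tangents equal t_0).
    """
    h = state.element_lengths
    m = len(h)
    a = params.alpha
    H = np.zeros((3 * m, 3 * m))
    g = np.zeros(3 * m)
    I3 = np.eye(3)
    for i in range(m):  # element i joins t_i and t_{i+1}; unknown k lives at block k-1
        w = 2.0 * a / h[i]
        if i == 0:
            # ||t_1 - t_0||^2 / h_1: quadratic in t_1 plus linear/constant in t_0
            H[0:3, 0:3] += w * I3
            g[0:3] += -w * state.base_tangent
        else:
            sl = slice(3 * i, 3 * i + 3)
            sp = slice(3 * (i - 1), 3 * i)
            H[sl, sl] += w * I3
            H[sp.start:sp.stop, sp.start:sp.stop] += w * I3
            H[sl, sp] += -w * I3
            H[sp, sl] += -w * I3
    c = a / h[0] * float(state.base_tangent @ state.base_tangent)
    return QuadraticForm(H, g, c)


def contact_quadratic(state: CatheterState, contacts, params: MaterialParams,
                      B: np.ndarray, c: np.ndarray) -> QuadraticForm:
    """Wall-penalty energy U_p = sum_j 1/2 kappa (n_j · x_j + d_j)^2 in tangent space.

    For a contact on node m, x_m is the m-th block row of B t + c, so each term
    is 1/2 kappa (a^T t + b)^2 with a = B_m^T n and b = n · c_m + d — a rank-one
    positive-semidefinite contribution.  Contacts on the pinned base node are
    rejected (x_0 is not a degree of freedom).
    """
    dim = B.shape[0]
    H = np.zeros((dim, dim))
    g = np.zeros(dim)
    const = 0.0
    kappa = params.kappa
    for ct in contacts:
        if ct.node < 1:
            raise ValidationError("contact on the boundary-fixed base node x_0")
        row = slice(3 * (ct.node - 1), 3 * ct.node)
        a = B[row].T @ ct.normal
        b = float(ct.normal @ c[row] + ct.offset)
        H += kappa * np.outer(a, a)
        g += kappa * b * a
        const += 0.5 * kappa * b * b
    return QuadraticForm(H, g, const)


def external_work_quadratic(state: CatheterState, load: ExternalLoad,
                            B: np.ndarray, c: np.ndarray,
                            convention: str = STANDARD) -> QuadraticForm:
    """Contribution of external nodal forces to the total potential.

    Under the ``standard`` convention this is -W = -sum_i f_i · (x_i - x_i0)
    (forces lower the potential along their direction of motion); under
    ``work_added`` the sign is +W.  Linear in t (H = 0).
    """
    if convention not in (STANDARD, WORK_ADDED):
        raise ValidationError(f"unknown sign convention {convention!r}")
    sign = -1.0 if convention == STANDARD else 1.0
    load.validate_for(state)
    dim = B.shape[0]
    g = np.zeros(dim)
    const = 0.0
    ref = load.reference_positions
    for i, f in sorted(load.forces.items()):
        f = np.asarray(f, float).reshape(3)
        row = slice(3 * (i - 1), 3 * i)
        x0 = np.zeros(3) if ref is None else np.asarray(ref, float).reshape(-1, 3)[i]
        g += sign * (B[row].T @ f)
        const += sign * float(f @ (c[row] - x0))
    return QuadraticForm(np.zeros((dim, dim)), g, const)


def total_potential(forms, t) -> float:
    """Evaluate the summed potential of a list of conformable quadratic forms."""
    forms = list(forms)
    if not forms:
        return 0.0
    dims = {f.dim for f in forms}
    if len(dims) != 1:
        raise ValidationError("forms have mismatched dimensions")
    return float(sum(f.evaluate(t) for f in forms))
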