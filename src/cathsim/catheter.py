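"""Discrete catheter centerline in tangent space.

The catheter is a polyline of N nodes joined by N-1 elements.  The solver's
unknowns are the nodal tangent vectors t_1 … t_{N-1}; the base tangent t_0 is
a fixed boundary condition imposed by the introducer sheath, and the base
position x_0 is pinned at the insertion site.  Node positions are recovered by
integrating the piecewise-linear tangent field, which for linear interpolation
is exactly the trapezoid rule:

    x_i = x_{i-1} + (h_i / 2) (t_{i-1} + t_i)

All element lengths equal the segment length l except possibly the *base*
element (the one adjacent to the sheath), which absorbs partial push/pull
steps h < l.  New nodes enter, and leave, at the base with tangent t_0.

Tangents are **not** constrained to unit norm — the equilibrium is found by an
unconstrained quadratic minimization, and renormalizing would change the
minimizer.  The drift max_i |‖t_i‖ - 1| is reported as a per-step diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import StateError, ValidationError

_TOL = 1e-12


@dataclass(frozen=True)
class CatheterState:
    """Catheter configuration: base pose, free tangents, element lengths.

    ``tangents[i-1]`` is t_i for node i (i = 1 … N-1); ``element_lengths[i-1]``
    is the length h_i of the element joining node i-1 to node i, so
    ``element_lengths[0]`` is the base element.
    """

    base_position: np.ndarray
    base_tangent: np.ndarray
    tangents: np.ndarray  # (N-1, 3)
    element_lengths: np.ndarray  # (N-1,)

    def __post_init__(self):
        object.__setattr__(self, "base_position", np.asarray(self.base_position, float).reshape(3))
        object.__setattr__(self, "base_tangent", np.asarray(self.base_tangent, float).reshape(3))
        object.__setattr__(self, "tangents", np.asarray(self.tangents, float).reshape(-1, 3))
        object.__setattr__(self, "element_lengths", np.asarray(self.element_lengths, float).reshape(-1))
        if abs(np.linalg.norm(self.base_tangent) - 1.0) > _TOL:
            raise ValidationError("base tangent must be a unit vector")
        if len(self.tangents) != len(self.element_lengths) or len(self.tangents) < 1:
            raise ValidationError("need one tangent and one length per element, N >= 2")
        if np.any(self.element_lengths <= 0):
            raise ValidationError("element lengths must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.tangents) + 1

    @property
    def total_length(self) -> float:
        return float(self.element_lengths.sum())

    @property
    def all_tangents(self) -> np.ndarray:
        """(N, 3) array t_0 … t_{N-1}."""
        return np.vstack([self.base_tangent[None, :], self.tangents])

    def with_tangents(self, tangents: np.ndarray) -> "CatheterState":
        return replace(self, tangents=np.asarray(tangents, float).reshape(-1, 3))

    def tangent_norm_drift(self) -> float:
        """max_i |‖t_i‖ - 1| over the free tangents (unit-length diagnostic)."""
        return float(np.max(np.abs(np.linalg.norm(self.tangents, axis=1) - 1.0)))


@dataclass(frozen=True)
class InsertionState:
    """Bookkeeping of total inserted arc length and partial base-element advance."""

    inserted_length: float
    segment_length: float

    @property
    def residual(self) -> float:
        """Accumulated partial advance in [0, l): base element length mod l."""
        r = self.inserted_length % self.segment_length
        return 0.0 if abs(r) < 1e-9 or abs(r - self.segment_length) < 1e-9 else r


def init_catheter(base_position, base_tangent, initial_length: float, segment_length: float
                  ) -> tuple[CatheterState, InsertionState]:
    """Straight catheter along the sheath direction, discretized at segment length l.

    Uses ceil(initial_length / l) elements; if ``initial_length`` is not an
    integer multiple of l, the base element carries the remainder.
    """
    if segment_length <= 0:
        raise ValidationError("segment length must be > 0")
    if initial_length < segment_length:
        raise ValidationError("initial length must be >= one segment length")
    l = segment_length
    n_elem = max(1, math.ceil(initial_length / l - 1e-9))
    base_elem = initial_length - (n_elem - 1) * l
    lengths = np.full(n_elem, l)
    lengths[0] = base_elem
    t0 = np.asarray(base_tangent, float)
    state = CatheterState(base_position, t0, np.tile(t0, (n_elem, 1)), lengths)
    return state, InsertionState(inserted_length=float(initial_length), segment_length=l)


def reconstruct_positions(state: CatheterState) -> np.ndarray:
    """Node positions by trapezoid integration of the piecewise-linear tangents.

    Exact for linearly interpolated tangents; returns an (N, 3) array with
    x_0 = base_position.
    """
    t = state.all_tangents
    h = state.element_lengths
    steps = 0.5 * h[:, None] * (t[:-1] + t[1:])
    return state.base_position + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def assemble_B(state: CatheterState) -> tuple[np.ndarray, np.ndarray]:
    """Affine map from stacked free tangents to stacked positions x_1 … x_{N-1}.

    Returns (B, c) with ``stack(x_1..x_{N-1}) = B @ stack(t_1..t_{N-1}) + c``.
    B is block-lower-triangular with diagonal blocks (h_i/2) I_3, hence
    nonsingular; c absorbs the base position and the fixed t_0 contribution.
    """
    h = state.element_lengths
    m = len(h)
    # scalar block weights: (h_j + h_{j+1})/2 below the diagonal, h_i/2 on it
    below = np.zeros(m)
    below[:-1] = 0.5 * (h[:-1] + h[1:])
    W = np.tril(np.broadcast_to(below, (m, m)), -1) + np.diag(0.5 * h)
    B = np.kron(W, np.eye(3))
    c = np.tile(state.base_position + 0.5 * h[0] * state.base_tangent, m)
    return B, c


def advance(state: CatheterState, ins: InsertionState, step: float
            ) -> tuple[CatheterState, InsertionState]:
    """Push the catheter in by ``step`` mm.

    The base element grows by ``step``; whenever it would exceed l, a new node
    with tangent t_0 is inserted at the base and the base element wraps by l.
    Total arc length increases by exactly ``step``; all interior tangents are
    preserved.
    """
    if step <= 0:
        raise ValidationError("advance step must be > 0")
    l = ins.segment_length
    lengths = state.element_lengths.copy()
    tangents = state.tangents
    lengths[0] += step
    while lengths[0] > l * (1 + 1e-12):
        tangents = np.vstack([state.base_tangent[None, :], tangents])
        lengths = np.concatenate([[lengths[0] - l, l], lengths[1:]])
        lengths[0] = max(lengths[0], _TOL)
    new_state = replace(state, tangents=tangents, element_lengths=lengths)
    return new_state, replace(ins, inserted_length=ins.inserted_length + step)


def retract(state: CatheterState, ins: InsertionState, step: float
            ) -> tuple[CatheterState, InsertionState]:
    """Pull the catheter out by ``step`` mm (mirror of :func:`advance`).

    Nodes are removed at the base when the base element would shrink to zero.
    The catheter may not be withdrawn past a single element.
    """
    if step <= 0:
        raise ValidationError("retract step must be > 0")
    if step >= ins.inserted_length - ins.segment_length:
        raise StateError("cannot withdraw the catheter past one element")
    lengths = state.element_lengths.copy()
    tangents = state.tangents
    lengths[0] -= step
    while lengths[0] <= _TOL:
        if len(lengths) < 2:
            raise StateError("cannot withdraw the catheter past one element")
        lengths = np.concatenate([[lengths[1] + lengths[0]], lengths[2:]])
        tangents = tangents[1:]
    new_state = replace(state, tangents=tangents, element_lengths=lengths)
    return new_state, replace(ins, inserted_length=ins.inserted_length - step)
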