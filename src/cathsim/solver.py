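"""Quasi-static equilibrium solver: active-set contact loop around a linear solve.

Each user input (push/pull) takes the catheter from one energy-minimizing
equilibrium to the next.  Stationarity of the quadratic total potential
Pi(t) = 1/2 t^T A t - b^T t + const gives the linear system

    A t = b,    A = sum_k H_k (symmetric positive definite),  b = -sum_k g_k

solved in tangent space by dense Cholesky factorization; positions are then
reconstructed through the affine map x = B t + c.  (Solving A t = b and
mapping through B is algebraically identical to the composed position-space
system A B^{-1} x = b, since B is nonsingular; the tangent-space route avoids
forming B^{-1}.)

Because the penalty terms depend on positions that the solve itself changes,
a single solve cannot be self-consistent: the solver iterates
detect-contacts -> assemble -> solve -> reconstruct until the re-detected
contact set matches the one the solve assumed and per-contact penetrations
have stopped changing, or an iteration cap is reached.  This active-set loop
is a reconstruction of the method's overall algorithm from its energy terms;
non-convergence is reported in the result, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .catheter import CatheterState, InsertionState, advance, assemble_B, reconstruct_positions, retract
from .collision import ContactSet, detect_contacts, max_penetration
from .energy import (
    STANDARD,
    ExternalLoad,
    MaterialParams,
    QuadraticForm,
    contact_quadratic,
    elastic_quadratic,
    external_work_quadratic,
)
from .errors import SetupError, SingularSystemError, ValidationError
from .trace import SimulationTrace, StepRecord
from .vessel import VesselMesh


@dataclass(frozen=True)
class SolverConfig:
    """Active-set loop controls and energy sign convention."""

    max_outer_iterations: int = 50
    active_set_tolerance: float = 1e-6  # mm, per-contact penetration change
    # mm; spatial scale below which the active-set iterate is accepted as
    # stationary even while the contact set keeps relabeling.  Against a
    # faceted wall the one-sided penalty is nonsmooth across facet creases,
    # so the equilibrium cannot be localized below the crease scale; 1e-3 mm
    # is far below both the facet size and the method's accuracy.
    stagnation_tolerance: float = 1e-3
    linear_solver: str = "direct"
    sign_convention: str = STANDARD
    # mm; contact-detection envelope.  A strictly-penetration-only active set
    # (margin 0) cannot settle on incipient contacts — the equilibrium sits at
    # |g| ~ 0, exactly on the active/inactive boundary, so the set flips
    # between solves.  A micron-scale envelope keeps such contacts active;
    # the extra |g|^2 penalty inside the band is O(kappa * margin^2).
    contact_margin: float = 1e-3

    def __post_init__(self):
        if self.max_outer_iterations < 1:
            raise ValidationError("max_outer_iterations must be >= 1")
        if self.active_set_tolerance <= 0 or self.stagnation_tolerance <= 0:
            raise ValidationError("solver tolerances must be > 0")
        if self.linear_solver != "direct":
            raise ValidationError("only the direct linear solver is available")


@dataclass
class EquilibriumResult:
    """Converged (or capped) equilibrium with solver diagnostics."""

    state: CatheterState
    contacts: ContactSet
    potential: float
    gradient_residual: float
    outer_iterations: int
    converged: bool
    tangent_norm_drift: float
    elastic_energy: float = 0.0
    contact_energy: float = 0.0
    external_work: float = 0.0
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]


def assemble_system(forms) -> tuple[np.ndarray, np.ndarray]:
    """Stationarity system of the summed forms: A = sum H_k, b = -sum g_k."""
    forms = list(forms)
    if not forms:
        raise ValidationError("need at least one quadratic form")
    dims = {f.dim for f in forms}
    if len(dims) != 1:
        raise ValidationError("forms have mismatched dimensions")
    dim = dims.pop()
    A = np.zeros((dim, dim))
    b = np.zeros(dim)
    for f in forms:
        A += f.H
        b -= f.g
    return 0.5 * (A + A.T), b


def solve_linear(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve the SPD stationarity system by Cholesky factorization.

    Raises :class:`SingularSystemError` (naming the near-null direction) if A
    is not positive definite — e.g. a zero bending constant with no contacts.
    """
    try:
        cho = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        w, V = np.linalg.eigh(A)
        raise SingularSystemError(
            f"stationarity matrix is not positive definite (lambda_min={w[0]:.3e})",
            null_direction=V[:, 0],
        ) from exc
    t = scipy.linalg.cho_solve(cho, b, check_finite=False)
    # one step of iterative refinement keeps the residual at working precision
    r = b - A @ t
    t = t + scipy.linalg.cho_solve(cho, r, check_finite=False)
    return t


def _contacts_settled(new: ContactSet, ref, tol: float, unpacked: bool = False,
                      ref_pen=None) -> bool:
    """True when ``new`` matches the reference contacts with penetration drift < tol."""
    if unpacked:
        ref_pairs, ref_pens = ref, ref_pen
    else:
        ref_pairs, ref_pens = ref.pairs(), ref.penetrations()
    if new.pairs() != ref_pairs:
        return False
    if len(new) == 0:
        return True
    return float(np.abs(new.penetrations() - ref_pens).max()) < tol


def _refresh_penetrations(contacts: ContactSet, positions: np.ndarray) -> ContactSet:
    """Recompute each contact's penetration at the given node positions."""
    from dataclasses import replace as _replace

    out = []
    for ct in contacts:
        s = float(ct.normal @ positions[ct.node] + ct.offset)
        out.append(_replace(ct, penetration=max(0.0, -s)))
    return ContactSet(out)


def _build_forms(state: CatheterState, contacts: ContactSet, params: MaterialParams,
                 load: ExternalLoad | None, B: np.ndarray, c: np.ndarray,
                 convention: str) -> list[QuadraticForm]:
    forms = [elastic_quadratic(state, params)]
    if contacts:
        forms.append(contact_quadratic(state, contacts, params, B, c))
    if load is not None and load.forces:
        forms.append(external_work_quadratic(state, load, B, c, convention))
    return forms


def solve_equilibrium(state: CatheterState, mesh: VesselMesh, params: MaterialParams,
                      load: ExternalLoad | None = None,
                      cfg: SolverConfig | None = None) -> EquilibriumResult:
    """Find the minimal-total-potential configuration for the current insertion.

    Iterates collision detection and the linear stationarity solve until the
    active contact set is self-consistent (re-detection reproduces the set the
    solve assumed and no contact's penetration changed by more than the
    tolerance).  Always returns a result; ``converged`` is False at the
    iteration cap.
    """
    cfg = cfg or SolverConfig()
    if max_penetration(mesh, state.base_position[None, :]) > 1e-6:
        raise SetupError("catheter base position lies outside the vessel")
    B, c = assemble_B(state)

    # smooth (contact-independent) part of the potential; constant across the loop
    smooth_forms = _build_forms(state, ContactSet(), params, load, B, c, cfg.sign_convention)

    def one_sided_potential(t_vec: np.ndarray) -> tuple[float, ContactSet]:
        """Merit potential of the active-set map: smooth terms plus the Hooke
        penalty of every contact detected within the margin (its full plane
        distance, so the merit is consistent with the assembled forms)."""
        pos = reconstruct_positions(state.with_tangents(t_vec.reshape(-1, 3)))
        cset = detect_contacts(mesh, pos, cfg.contact_margin)
        pi = float(sum(f.evaluate(t_vec) for f in smooth_forms))
        for ct in cset:
            g = float(ct.normal @ pos[ct.node] + ct.offset)
            pi += 0.5 * params.kappa * g * g
        return pi, cset

    positions = reconstruct_positions(state)
    contacts = detect_contacts(mesh, positions, cfg.contact_margin)
    converged = False
    forms: list[QuadraticForm] = []
    A = b = t = None
    t_prev = state.tangents.ravel().copy()
    pi_prev, _ = one_sided_potential(t_prev)
    pos_prev = positions
    iterations = 0
    finalize_set: ContactSet | None = None
    stagnant = 0
    history: list[tuple] = [(contacts.pairs(), contacts.penetrations())]
    for iterations in range(1, cfg.max_outer_iterations + 1):
        forms = _build_forms(state, contacts, params, load, B, c, cfg.sign_convention)
        A, b = assemble_system(forms)
        t = solve_linear(A, b)
        # the solve is a (generalized) Newton step on the one-sided potential;
        # backtracking keeps the loop descending instead of oscillating
        # between distant active sets
        theta = 1.0
        t_try = t
        pi_try, new_contacts = one_sided_potential(t_try)
        while pi_try > pi_prev + 1e-12 * (1.0 + abs(pi_prev)) and theta > 2**-12:
            theta *= 0.5
            t_try = t_prev + theta * (t - t_prev)
            pi_try, new_contacts = one_sided_potential(t_try)
        if pi_try > pi_prev + 1e-12 * (1.0 + abs(pi_prev)):
            # no descent in this direction even at the smallest step: the
            # iterate is pinned on a facet crease of the one-sided potential
            stagnant = 2
            t = t_prev
            pi_try = pi_prev
        else:
            t = t_try
        state = state.with_tangents(t.reshape(-1, 3))
        positions = reconstruct_positions(state)
        if stagnant < 2:
            if theta == 1.0 and _contacts_settled(new_contacts, contacts, cfg.active_set_tolerance):
                contacts = new_contacts
                converged = True
                break
            if theta == 1.0 and iterations >= 2 and _contacts_settled(
                    new_contacts, history[-2][0], cfg.active_set_tolerance,
                    unpacked=True, ref_pen=history[-2][1]):
                # period-2 relabeling between geometrically equivalent contacts
                # (a node projecting onto a shared edge of near-coplanar
                # triangles): the configuration is a fixed point up to the label
                finalize_set = new_contacts
                break
            dpos = float(np.abs(positions - pos_prev).max())
            dpen = abs(new_contacts.max_penetration() - contacts.max_penetration())
            stagnant = stagnant + 1 if max(dpos, dpen) < cfg.stagnation_tolerance else 0
        if stagnant >= 2:
            # pinned against a facet crease, where the penalty is nonsmooth
            # and no single-facet active set is self-consistent: accept once
            # the configuration stops moving on the crease scale, gluing in
            # every wall plane within that distance so the finalizing solve
            # cannot drop the load-bearing contacts
            finalize_set = detect_contacts(
                mesh, positions, max(cfg.contact_margin, cfg.stagnation_tolerance))
            break
        history.append((new_contacts.pairs(), new_contacts.penetrations()))
        contacts = new_contacts
        t_prev, pi_prev, pos_prev = t, pi_try, positions
    if finalize_set is not None:
        # Exact solve against the accepted set so the reported residual and
        # active set describe the returned state.  Wall planes the iterate
        # hovers within the stagnation tolerance of are glued in, and the set
        # grows monotonically until it supports the equilibrium: an incipient
        # contact (equilibrium penetration below the detection threshold) can
        # never be held by strict penetration-only detection.  An energy guard
        # keeps the finalize from jumping away from the accepted iterate.
        glue_margin = max(cfg.contact_margin, cfg.stagnation_tolerance)
        aug = {(ct.node, ct.triangle): ct for ct in finalize_set}
        t_f = t
        pi_f = pi_try
        for _ in range(10):
            forms_f = _build_forms(state, ContactSet(aug.values()), params, load, B, c,
                                   cfg.sign_convention)
            A_f, b_f = assemble_system(forms_f)
            t_f = solve_linear(A_f, b_f)
            pi_f, _ = one_sided_potential(t_f)
            pos_f = reconstruct_positions(state.with_tangents(t_f.reshape(-1, 3)))
            bearing = detect_contacts(mesh, pos_f, glue_margin)
            missing = [ct for ct in bearing if (ct.node, ct.triangle) not in aug]
            if not missing:
                break
            for ct in missing:
                aug[(ct.node, ct.triangle)] = ct
        # energy resolution implied by the spatial tolerance: each glued
        # contact may legitimately move by ~tol onto its plane
        slack = 0.5 * params.kappa * cfg.stagnation_tolerance**2 * max(1, len(aug))
        if pi_f <= pi_try + slack + 1e-9 * (1.0 + abs(pi_try)):
            t = t_f
            state = state.with_tangents(t.reshape(-1, 3))
            positions = reconstruct_positions(state)
            contacts = _refresh_penetrations(ContactSet(aug.values()), positions)
            converged = True
        else:  # keep the damped iterate; report honestly as non-converged
            contacts = detect_contacts(mesh, positions, cfg.contact_margin)
    assert t is not None
    # rebuild forms for the final active set so diagnostics match the returned state
    forms = _build_forms(state, contacts, params, load, B, c, cfg.sign_convention)
    A, b = assemble_system(forms)
    residual = float(np.linalg.norm(A @ t - b))
    u_e = forms[0].evaluate(t)
    u_p = contact_quadratic(state, contacts, params, B, c).evaluate(t) if contacts else 0.0
    work = 0.0
    if load is not None and load.forces:
        # work done by the forces (positive along their direction), regardless of convention
        w_form = external_work_quadratic(state, load, B, c, STANDARD)
        work = -w_form.evaluate(t)
    potential = float(sum(f.evaluate(t) for f in forms))
    return EquilibriumResult(
        state=state,
        contacts=contacts,
        potential=potential,
        gradient_residual=residual,
        outer_iterations=iterations,
        converged=converged,
        tangent_norm_drift=state.tangent_norm_drift(),
        elastic_energy=u_e,
        contact_energy=u_p,
        external_work=work,
        positions=positions,
    )


def _remap_load(load: ExternalLoad | None, old_positions: np.ndarray,
                n_new: int) -> ExternalLoad | None:
    """Shift a node-indexed load when nodes enter/leave at the base.

    Material points keep their distance from the tip, so node i in the new
    discretization corresponds to node i - (n_new - n_old) in the old one;
    newly entered nodes take their current position as reference.
    """
    if load is None or not load.forces:
        return load
    n_old = len(old_positions)
    shift = n_new - n_old
    forces = {}
    for i, f in load.forces.items():
        j = i + shift
        if 1 <= j < n_new:
            forces[j] = f
    ref = np.zeros((n_new, 3))
    for j in range(n_new):
        i = j - shift
        ref[j] = old_positions[i] if 0 <= i < n_old else np.nan
    return ExternalLoad(forces=forces, reference_positions=ref)


def simulate_sequence(initial: CatheterState, mesh: VesselMesh, params: MaterialParams,
                      inputs, cfg: SolverConfig | None = None,
                      load: ExternalLoad | None = None,
                      insertion: InsertionState | None = None) -> SimulationTrace:
    """Drive the catheter through a scripted sequence of signed push/pull steps.

    Positive steps push (advance), negative pull (retract); each step's
    magnitude may not exceed the segment length.  After every input the new
    equilibrium is solved; each step's external-work reference positions are
    the previous equilibrium.  Non-convergent steps are recorded, not fatal.
    """
    cfg = cfg or SolverConfig()
    if insertion is None:
        l = float(initial.element_lengths.max())
        insertion = InsertionState(inserted_length=initial.total_length, segment_length=l)
    l = insertion.segment_length
    for s in inputs:
        if abs(s) > l * (1 + 1e-9):
            raise ValidationError(f"input step {s} exceeds the segment length {l}")
        if s == 0:
            raise ValidationError("input steps must be nonzero")
    trace = SimulationTrace()
    result = solve_equilibrium(initial, mesh, params, load, cfg)
    trace.append(StepRecord.from_result(0, 0.0, result, insertion.inserted_length))
    state = result.state
    cur_load = load
    for k, s in enumerate(inputs, start=1):
        prev_positions = reconstruct_positions(state)
        if s > 0:
            state, insertion = advance(state, insertion, float(s))
        else:
            state, insertion = retract(state, insertion, float(-s))
        cur_load = _remap_load(cur_load, prev_positions, state.n_nodes)
        if cur_load is not None and cur_load.reference_positions is not None:
            # new base nodes reference their freshly reconstructed position
            ref = cur_load.reference_positions
            fresh = reconstruct_positions(state)
            nan = np.isnan(ref[:, 0])
            ref[nan] = fresh[nan]
        result = solve_equilibrium(state, mesh, params, cur_load, cfg)
        state = result.state
        trace.append(StepRecord.from_result(k, float(s), result, insertion.inserted_length))
    return trace
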