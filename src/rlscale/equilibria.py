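"""Closed-form steady-state solvers for the named receptor architectures.

All solvers assume fast binding-unbinding dynamics relative to downstream
processes, a well-mixed medium, and an unlimited ligand pool (the free ligand
concentration is not depleted by receptor binding).  Finite ligand pools and
receptor turnover live in :mod:`rlscale.extensions`.

Mass-conservation stoichiometry per architecture:

=========  ==========================================
AL         A + F = A0
ALA        A + P + 2F = A0
LAAL       A + P + 2F = A0
ALB        A + P + F = A0  and  B + F = B0
=========  ==========================================

The internal ``*_full_complex`` helpers are vectorized over receptor totals
(NumPy broadcasting); the public ``solve_*`` functions wrap them into scalar
:class:`~rlscale.params.EquilibriumState` objects with residual bookkeeping.
"""

from __future__ import annotations

import numpy as np

from .params import (
    EquilibriumState,
    LigandParams,
    ModelKind,
    ParameterDomainError,
    ReceptorConfig,
)

__all__ = [
    "solve_al",
    "solve_ala",
    "solve_laal",
    "solve_alb_seq",
    "solve",
    "response",
    "al_full_complex",
    "ala_species",
    "laal_species",
    "alb_seq_full_complex",
    "full_complex",
]


def _positive_quadratic_root(a, b, c):
    """Positive root of ``a x^2 + b x + c = 0`` with ``a >= 0``, ``b > 0``,
    ``c <= 0``, computed with the cancellation-stable formula.

    For ``a = 0`` degenerates smoothly to ``-c / b``.  Low-affinity regimes
    make ``b**2`` dominate ``4ac`` by many orders of magnitude, so the naive
    ``(-b + sqrt(...)) / 2a`` form would cancel catastrophically.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    disc = np.sqrt(b * b - 4.0 * a * c)
    # root = 2c / (-b - disc) == (-b + disc) / (2a), stable when b > 0
    denom = b + disc
    with np.errstate(invalid="ignore", divide="ignore"):
        root = np.where(denom > 0, -2.0 * c / np.where(denom > 0, denom, 1.0), 0.0)
    return root


# ---------------------------------------------------------------------------
# vectorized species helpers


def al_full_complex(ligand: LigandParams, a_total):
    """AL complex amount ``F = A0 * K_P C / (1 + K_P C)`` (vectorized)."""
    a_total = np.asarray(a_total, dtype=float)
    kc = ligand.partial_affinity * ligand.concentration
    return a_total * kc / (1.0 + kc)


def ala_species(ligand: LigandParams, a_total):
    """Free A, partial P and full F for the ALA model (vectorized).

    Equilibrium relations ``P = K_P C A`` and ``F = K_F A P`` combined with
    ``A + P + 2F = A0`` give the quadratic
    ``2 K_F K_P C A^2 + (1 + K_P C) A - A0 = 0``.
    """
    a_total = np.asarray(a_total, dtype=float)
    kc = ligand.partial_affinity * ligand.concentration
    quad = 2.0 * ligand.full_affinity * kc
    free_a = _positive_quadratic_root(quad, 1.0 + kc, -a_total)
    partial = kc * free_a
    full = ligand.full_affinity * free_a * partial
    return free_a, partial, full


def laal_species(ligand: LigandParams, a_total):
    """Free A, partial P and full F for the LAAL model (vectorized).

    Each partial complex carries its own ligand; two partials pair into F:
    ``P = K_P C A``, ``F = K_F P^2``, conservation ``A + P + 2F = A0``.
    """
    a_total = np.asarray(a_total, dtype=float)
    kc = ligand.partial_affinity * ligand.concentration
    quad = 2.0 * ligand.full_affinity * kc * kc
    free_a = _positive_quadratic_root(quad, 1.0 + kc, -a_total)
    partial = kc * free_a
    full = ligand.full_affinity * partial * partial
    return free_a, partial, full


def alb_seq_full_complex(ligand: LigandParams, a_total, b_total):
    """Full-complex amount for the sequential heterodimeric model (vectorized).

    Substituting ``P = K_P C A`` and ``F = K_F P B`` into the conservation
    laws ``A (1 + K_P C) + F = A0`` and ``B + F = B0`` yields

        k F^2 - (1 + k (A0 + B0)) F + k A0 B0 = 0,
        k = K_F K_P C / (1 + K_P C),

    whose smaller root is the physical one (it alone satisfies
    ``F <= min(A0, B0)``).
    """
    a_total = np.asarray(a_total, dtype=float)
    b_total = np.asarray(b_total, dtype=float)
    kc = ligand.partial_affinity * ligand.concentration
    k = ligand.full_affinity * kc / (1.0 + kc)
    if k == 0:
        return np.zeros(np.broadcast(a_total, b_total).shape)
    b = 1.0 + k * (a_total + b_total)
    disc = np.sqrt(b * b - 4.0 * k * k * a_total * b_total)
    # smaller root, stable form (b > 0 always)
    full = 2.0 * k * a_total * b_total / (b + disc)
    return full


def full_complex(model: ModelKind, ligand: LigandParams, a_total, b_total=None):
    """Vectorized full-complex amount for any closed-form architecture."""
    if model is ModelKind.AL:
        return al_full_complex(ligand, a_total)
    if model is ModelKind.ALA:
        return ala_species(ligand, a_total)[2]
    if model is ModelKind.LAAL:
        return laal_species(ligand, a_total)[2]
    if model is ModelKind.ALB_SEQ:
        if b_total is None:
            raise ParameterDomainError("ALB_SEQ requires b_total")
        return alb_seq_full_complex(ligand, a_total, b_total)
    raise ParameterDomainError(
        f"no closed-form solver for {model}; use rlscale.network"
    )


# ---------------------------------------------------------------------------
# scalar state-building solvers


def solve_al(ligand: LigandParams, receptors: ReceptorConfig) -> EquilibriumState:
    """Monomeric-receptor equilibrium: Michaelis-Menten occupancy."""
    a0 = receptors.a_total
    full = float(al_full_complex(ligand, a0))
    free_a = a0 - full
    state = EquilibriumState(
        model=ModelKind.AL,
        species={"A": free_a, "F": full},
        residuals={"A_total": free_a + full - a0},
    )
    return state


def solve_ala(ligand: LigandParams, receptors: ReceptorConfig) -> EquilibriumState:
    """Homodimeric (single-ligand) equilibrium."""
    a0 = receptors.a_total
    free_a, partial, full = (float(x) for x in ala_species(ligand, a0))
    return EquilibriumState(
        model=ModelKind.ALA,
        species={"A": free_a, "P": partial, "F": full},
        residuals={"A_total": free_a + partial + 2.0 * full - a0},
    )


def solve_laal(ligand: LigandParams, receptors: ReceptorConfig) -> EquilibriumState:
    """Homodimeric (two-ligand) equilibrium."""
    a0 = receptors.a_total
    free_a, partial, full = (float(x) for x in laal_species(ligand, a0))
    return EquilibriumState(
        model=ModelKind.LAAL,
        species={"A": free_a, "P": partial, "F": full},
        residuals={"A_total": free_a + partial + 2.0 * full - a0},
    )


def solve_alb_seq(ligand: LigandParams, receptors: ReceptorConfig) -> EquilibriumState:
    """Sequential heterodimeric equilibrium (ligand binds A, then B joins)."""
    a0 = receptors.a_total
    b0 = receptors.require_b()
    full = float(alb_seq_full_complex(ligand, a0, b0))
    kc = ligand.partial_affinity * ligand.concentration
    free_a = (a0 - full) / (1.0 + kc)
    partial = kc * free_a
    free_b = b0 - full
    if full < -1e-12 or free_b < -1e-12 or free_a < -1e-12:
        raise RuntimeError("ALB_SEQ root selection produced an infeasible state")
    return EquilibriumState(
        model=ModelKind.ALB_SEQ,
        species={"A": free_a, "B": free_b, "P": partial, "F": full},
        residuals={
            "A_total": free_a + partial + full - a0,
            "B_total": free_b + full - b0,
        },
    )


_SOLVERS = {
    ModelKind.AL: solve_al,
    ModelKind.ALA: solve_ala,
    ModelKind.LAAL: solve_laal,
    ModelKind.ALB_SEQ: solve_alb_seq,
}


def solve(model: ModelKind, ligand: LigandParams, receptors: ReceptorConfig) -> EquilibriumState:
    """Dispatch to the closed-form solver for ``model``.

    ``ALB_NONSEQ`` has no closed form here; build it with
    :func:`rlscale.network.build_alb_nonseq_network` and solve numerically.
    """
    try:
        solver = _SOLVERS[ModelKind(model)]
    except KeyError:
        raise ParameterDomainError(
            f"no closed-form solver for {model}; use rlscale.network"
        ) from None
    return solver(ligand, receptors)


def response(state, ligand: LigandParams, exponent: float = 1.0):
    """Downstream response ``E = e * F**n``.

    ``state`` may be an :class:`EquilibriumState` or a raw full-complex
    amount (scalar or array).  The default linear case ``n = 1`` is the
    main-text model; ``n != 1`` models cooperative downstream steps.
    """
    if exponent <= 0:
        raise ParameterDomainError(f"response exponent must be > 0, got {exponent}")
    full = state.full_complex if isinstance(state, EquilibriumState) else np.asarray(state)
    return ligand.activity_rate * full**exponent
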