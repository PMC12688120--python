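"""Robustness extensions of the core equilibrium models.

Three relaxations of the baseline assumptions are implemented:

* **Receptor turnover** — receptors are produced at a constant rate and
  degraded with first-order kinetics, with ligand-bound complexes optionally
  removed faster than free receptors.  The receptor total becomes emergent,
  and scaling is computed against the production rate (the cell-intrinsic
  quantity replacing A0).
* **Finite ligand pool** — the ligand is a conserved per-cell species
  instead of a fixed ambient concentration; the unlimited-pool solution is
  recovered as the pool grows.
* **Nonlinear downstream response** — ``E = e * F**n`` for cooperative
  downstream steps; the scaling is exactly ``n`` times the linear-response
  value and remains independent of the ligand's activity rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import equilibria, scaling as scaling_mod
from .network import Reaction, ReactionNetwork, solve_equilibrium
from .params import (
    EquilibriumState,
    LigandParams,
    ModelKind,
    ParameterDomainError,
    ReceptorConfig,
)

__all__ = [
    "TurnoverParams",
    "LigandPool",
    "solve_with_turnover",
    "turnover_scaling",
    "solve_finite_ligand",
    "finite_ligand_full_complex",
    "scaling_with_nonlinearity",
]


@dataclass(frozen=True)
class TurnoverParams:
    """Receptor production/degradation rates.

    ``degradation_partial_as_complex`` selects whether partial complexes are
    removed at the complex rate (default, ligand binding marks the receptor
    for internalisation) or at the free-receptor rate.
    """

    production_rate: float
    degradation_free: float
    degradation_complex: float
    degradation_partial_as_complex: bool = True

    def __post_init__(self) -> None:
        if self.production_rate < 0:
            raise ParameterDomainError("production_rate must be >= 0")
        if self.degradation_free <= 0:
            raise ParameterDomainError("degradation_free must be > 0")
        if self.degradation_complex <= 0:
            raise ParameterDomainError("degradation_complex must be > 0")


@dataclass(frozen=True)
class LigandPool:
    """Finite, conserved per-cell ligand amount (ACU)."""

    total_ligand: float

    def __post_init__(self) -> None:
        if self.total_ligand < 0:
            raise ParameterDomainError("total_ligand must be >= 0")


# ---------------------------------------------------------------------------
# ligand-dependent receptor turnover


def _turnover_balance(model: ModelKind, ligand: LigandParams, t: TurnoverParams, free_a: float) -> float:
    """Net subunit flux (production minus degradation) at free amount A.

    Binding equilibrates fast relative to turnover, so P and F track A via
    the equilibrium relations while the slow balance sets the emergent total.
    """
    kc = ligand.partial_affinity * ligand.concentration
    d_p = t.degradation_complex if t.degradation_partial_as_complex else t.degradation_free
    if model is ModelKind.AL:
        full = kc * free_a
        out = t.degradation_free * free_a + t.degradation_complex * full
    elif model is ModelKind.ALA:
        partial = kc * free_a
        full = ligand.full_affinity * free_a * partial
        out = t.degradation_free * free_a + d_p * partial + 2.0 * t.degradation_complex * full
    elif model is ModelKind.LAAL:
        partial = kc * free_a
        full = ligand.full_affinity * partial * partial
        out = t.degradation_free * free_a + d_p * partial + 2.0 * t.degradation_complex * full
    else:
        raise ParameterDomainError(
            f"turnover extension supports single-subunit models, not {model}"
        )
    return t.production_rate - out


def solve_with_turnover(
    model: ModelKind, ligand: LigandParams, turnover: TurnoverParams
) -> EquilibriumState:
    """Steady state of production-binding-degradation dynamics.

    The receptor total is emergent: production balances the degradation of
    free and bound forms.  With a uniform degradation rate this reduces
    exactly to the fixed-total model with ``A0 = production / degradation``.
    """
    model = ModelKind(model)
    if turnover.production_rate == 0:
        zero = {ModelKind.AL: {"A": 0.0, "F": 0.0}}.get(
            model, {"A": 0.0, "P": 0.0, "F": 0.0}
        )
        return EquilibriumState(model=model, species=zero, residuals={"flux": 0.0})

    # the balance is strictly decreasing in A: bracket then root-solve
    hi = turnover.production_rate / turnover.degradation_free
    free_a = brentq(
        lambda a: _turnover_balance(model, ligand, turnover, a),
        0.0,
        hi * (1.0 + 1e-12),
        xtol=1e-300,
        rtol=8.9e-16,
        maxiter=300,
    )
    kc = ligand.partial_affinity * ligand.concentration
    if model is ModelKind.AL:
        species = {"A": free_a, "F": kc * free_a}
    elif model is ModelKind.ALA:
        partial = kc * free_a
        species = {"A": free_a, "P": partial, "F": ligand.full_affinity * free_a * partial}
    else:
        partial = kc * free_a
        species = {"A": free_a, "P": partial, "F": ligand.full_affinity * partial * partial}
    return EquilibriumState(
        model=model,
        species=species,
        residuals={"flux": _turnover_balance(model, ligand, turnover, free_a)},
    )


def turnover_scaling(
    model: ModelKind, ligand: LigandParams, turnover: TurnoverParams, h: float = 1e-4
) -> float:
    """Scaling of the response against the production rate, the
    cell-intrinsic quantity that replaces the fixed receptor total."""

    def full_at(m):
        t = TurnoverParams(
            production_rate=turnover.production_rate * m,
            degradation_free=turnover.degradation_free,
            degradation_complex=turnover.degradation_complex,
            degradation_partial_as_complex=turnover.degradation_partial_as_complex,
        )
        return solve_with_turnover(model, ligand, t).full_complex

    return float(scaling_mod.numeric_scaling(full_at, h=h))


# ---------------------------------------------------------------------------
# finite (depletable) ligand pool


def _finite_ligand_network(
    model: ModelKind, ligand: LigandParams, receptors: ReceptorConfig, pool: LigandPool
) -> ReactionNetwork:
    kp, kf = ligand.partial_affinity, ligand.full_affinity
    a0 = receptors.a_total
    if model is ModelKind.AL:
        return ReactionNetwork(
            reactions=[Reaction(("A", "L"), "F", kp)],
            conservation=[
                ({"A": 1.0, "F": 1.0}, a0),
                ({"L": 1.0, "F": 1.0}, pool.total_ligand),
            ],
        )
    if model is ModelKind.ALA:
        return ReactionNetwork(
            reactions=[
                Reaction(("A", "L"), "P", kp),
                Reaction(("A", "P"), "F", kf),
            ],
            conservation=[
                ({"A": 1.0, "P": 1.0, "F": 2.0}, a0),
                ({"L": 1.0, "P": 1.0, "F": 1.0}, pool.total_ligand),
            ],
        )
    if model is ModelKind.LAAL:
        return ReactionNetwork(
            reactions=[
                Reaction(("A", "L"), "P", kp),
                Reaction(("P", "P"), "F", kf),
            ],
            conservation=[
                ({"A": 1.0, "P": 1.0, "F": 2.0}, a0),
                ({"L": 1.0, "P": 1.0, "F": 2.0}, pool.total_ligand),
            ],
        )
    if model is ModelKind.ALB_SEQ:
        b0 = receptors.require_b()
        return ReactionNetwork(
            reactions=[
                Reaction(("A", "L"), "P", kp),
                Reaction(("P", "B"), "F", kf),
            ],
            conservation=[
                ({"A": 1.0, "P": 1.0, "F": 1.0}, a0),
                ({"B": 1.0, "F": 1.0}, b0),
                ({"L": 1.0, "P": 1.0, "F": 1.0}, pool.total_ligand),
            ],
        )
    raise ParameterDomainError(f"finite-ligand extension does not support {model}")


def solve_finite_ligand(
    model: ModelKind, ligand: LigandParams, receptors: ReceptorConfig, pool: LigandPool
) -> EquilibriumState:
    """Equilibrium with the ligand as a conserved per-cell species.

    The ligand's ``concentration`` field is ignored; the pool total takes
    its place.  As ``total_ligand -> infinity`` (at fixed receptor totals)
    the constant-ligand solution is recovered.
    """
    model = ModelKind(model)
    net = _finite_ligand_network(model, ligand, receptors, pool)
    state = solve_equilibrium(net, model=model)
    return state


def finite_ligand_full_complex(
    model: ModelKind, ligand: LigandParams, a_total: float, pool: LigandPool,
    b_total=None,
) -> float:
    receptors = ReceptorConfig(a_total=a_total, b_total=b_total)
    return solve_finite_ligand(model, ligand, receptors, pool).full_complex


def finite_ligand_scaling(
    model: ModelKind,
    ligand: LigandParams,
    receptors: ReceptorConfig,
    pool: LigandPool,
    h: float = 1e-4,
) -> float:
    """Numeric scaling d ln F / d ln A0 under ligand depletion."""

    def full_at(m):
        r = ReceptorConfig(a_total=receptors.a_total * m, b_total=receptors.b_total)
        return solve_finite_ligand(model, ligand, r, pool).full_complex

    return float(scaling_mod.numeric_scaling(full_at, h=h))


# ---------------------------------------------------------------------------
# nonlinear downstream response


def scaling_with_nonlinearity(
    model: ModelKind,
    ligand: LigandParams,
    receptors: ReceptorConfig,
    exponent: float,
    subunit: str = "A",
):
    """Scaling of ``E = e * F**n``: the chain rule gives ``S(n) = n * S(1)``
    for every architecture, so nonlinearity rescales the attainable range
    but leaves its ligand-parameter (and activity-rate) independence intact.
    """
    return scaling_mod.local_scaling(
        model, ligand, receptors, subunit=subunit, exponent=exponent
    )
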