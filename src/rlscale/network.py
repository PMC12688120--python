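"""General coupled-binding equilibrium solver for mass-action networks.

A :class:`ReactionNetwork` is a set of association reactions
``r1 + r2 + ... -> product`` with association constants ``K`` (so that at
equilibrium ``product = K * prod(reactants)``), a set of species held
constant (e.g. ligands under the unlimited-pool assumption), and linear
conservation laws over the free species.

Every species amount is a monomial in the *base* species (free species that
are never a product of any reaction), which reduces the equilibrium problem
to solving the conservation laws for the base amounts.  We do this with a
damped Newton iteration on the log base amounts — positivity is then
automatic — with an analytic Jacobian, falling back to bisection for
one-dimensional problems.

This module is the independent oracle for the closed-form solvers in
:mod:`rlscale.equilibria` and the only solver for competition (activator +
inhibitor) and non-sequential heterodimer networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .params import EquilibriumState, LigandParams, ModelKind, ReceptorConfig

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "NetworkValidationError",
    "EquilibriumSolverError",
    "solve_equilibrium",
    "build_model_network",
    "build_competition_network",
    "build_alb_nonseq_network",
    "AlbNonSeqAffinities",
]

DETAILED_BALANCE_RTOL = 1e-6
RESIDUAL_RTOL = 1e-10
MAX_ITER = 200


class NetworkValidationError(ValueError):
    """The network specification is inconsistent (stoichiometry, cycles...)."""


class EquilibriumSolverError(RuntimeError):
    """Newton iteration failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (final relative residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class Reaction:
    """One association reaction: ``reactants -> product`` with
    ``product = K * prod(reactant amounts)`` at equilibrium.

    Multiplicity is expressed by repeating a reactant name.
    """

    reactants: Tuple[str, ...]
    product: str
    K: float

    def __post_init__(self) -> None:
        if len(self.reactants) < 1:
            raise NetworkValidationError("reaction needs at least one reactant")
        if self.K <= 0:
            raise NetworkValidationError(f"association constant must be > 0, got {self.K}")
        if self.product in self.reactants:
            raise NetworkValidationError("product cannot appear among its own reactants")


@dataclass
class ReactionNetwork:
    """Species, reactions and conservation laws of one binding network.

    Parameters
    ----------
    constants : dict
        Species held at fixed amounts (name -> amount), e.g. free ligand.
    reactions : list of Reaction
    conservation : list of (coeffs, total)
        Each law is ``sum_s coeffs[s] * amount[s] = total`` over free
        species.
    """

    constants: Dict[str, float] = field(default_factory=dict)
    reactions: List[Reaction] = field(default_factory=list)
    conservation: List[Tuple[Dict[str, float], float]] = field(default_factory=list)

    # -- derived structure ---------------------------------------------------

    def species_names(self) -> List[str]:
        names: List[str] = list(self.constants)
        for rxn in self.reactions:
            for s in (*rxn.reactants, rxn.product):
                if s not in names:
                    names.append(s)
        for coeffs, _ in self.conservation:
            for s in coeffs:
                if s not in names:
                    names.append(s)
        return names

    def base_species(self) -> List[str]:
        products = {r.product for r in self.reactions}
        return [
            s
            for s in self.species_names()
            if s not in products and s not in self.constants
        ]

    def monomials(self) -> Dict[str, Tuple[float, Dict[str, float]]]:
        """Express every species as ``coef * prod(base**exp)``.

        Constants fold into the coefficient.  A product reachable by several
        reaction routes (a thermodynamic cycle) must yield the same monomial;
        coefficients agreeing to ``DETAILED_BALANCE_RTOL`` are accepted and
        the first route is used, otherwise validation fails.
        """
        mono: Dict[str, Tuple[float, Dict[str, float]]] = {}
        for s in self.base_species():
            mono[s] = (1.0, {s: 1.0})
        for s, v in self.constants.items():
            mono[s] = (float(v), {})

        pending = list(self.reactions)
        progress = True
        while pending and progress:
            progress = False
            remaining = []
            for rxn in pending:
                if all(r in mono for r in rxn.reactants):
                    coef = rxn.K
                    exps: Dict[str, float] = {}
                    for r in rxn.reactants:
                        c, e = mono[r]
                        coef *= c
                        for k, v in e.items():
                            exps[k] = exps.get(k, 0.0) + v
                    if rxn.product in mono:
                        c0, e0 = mono[rxn.product]
                        if e0 != exps:
                            raise NetworkValidationError(
                                f"species {rxn.product!r} has inconsistent "
                                "composition along different reaction routes"
                            )
                        scale = max(abs(c0), abs(coef), 1e-300)
                        if abs(c0 - coef) > DETAILED_BALANCE_RTOL * scale:
                            raise NetworkValidationError(
                                f"detailed balance violated for {rxn.product!r}: "
                                f"route constants {c0:g} vs {coef:g}"
                            )
                    else:
                        mono[rxn.product] = (coef, exps)
                    progress = True
                else:
                    remaining.append(rxn)
            pending = remaining
        if pending:
            raise NetworkValidationError(
                "reactions reference species that are never defined: "
                + ", ".join(r.product for r in pending)
            )
        return mono

    def validate(self) -> None:
        mono = self.monomials()
        free = [s for s in mono if s not in self.constants]
        covered = set()
        for coeffs, total in self.conservation:
            if total < 0:
                raise NetworkValidationError("conservation total must be >= 0")
            for s, c in coeffs.items():
                if s in self.constants:
                    raise NetworkValidationError(
                        f"constant species {s!r} cannot appear in a conservation law"
                    )
                if s not in mono:
                    raise NetworkValidationError(f"unknown species {s!r} in conservation law")
                if c != 0:
                    covered.add(s)
        missing = set(free) - covered
        if missing:
            raise NetworkValidationError(
                "free species missing from every conservation law: "
                + ", ".join(sorted(missing))
            )
        nbase = len(self.base_species())
        nlaws = len(self.conservation)
        if nbase != nlaws:
            raise NetworkValidationError(
                f"{nbase} base species but {nlaws} conservation laws"
            )

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "constants": self.constants,
                "reactions": [
                    {"reactants": list(r.reactants), "product": r.product, "K": r.K}
                    for r in self.reactions
                ],
                "conservation": [
                    {"coeffs": coeffs, "total": total}
                    for coeffs, total in self.conservation
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        doc = json.loads(text)
        return cls(
            constants=dict(doc.get("constants", {})),
            reactions=[
                Reaction(tuple(r["reactants"]), r["product"], float(r["K"]))
                for r in doc.get("reactions", [])
            ],
            conservation=[
                (dict(law["coeffs"]), float(law["total"]))
                for law in doc.get("conservation", [])
            ],
        )


# ---------------------------------------------------------------------------
# solver


def _amounts_from_log_base(
    log_base: np.ndarray,
    base: Sequence[str],
    mono: Dict[str, Tuple[float, Dict[str, float]]],
    free: Sequence[str],
) -> Dict[str, float]:
    idx = {s: i for i, s in enumerate(base)}
    out: Dict[str, float] = {}
    for s in free:
        coef, exps = mono[s]
        logx = np.log(coef) if coef > 0 else -np.inf
        for b, e in exps.items():
            logx += e * log_base[idx[b]]
        out[s] = float(np.exp(logx))
    return out


def solve_equilibrium(network: ReactionNetwork, model: ModelKind | None = None) -> EquilibriumState:
    """Solve a validated network to relative residual ``1e-10``.

    Damped Newton on log base amounts; the step is halved until the residual
    norm decreases.  One-dimensional problems that fail Newton are retried
    with bracketed bisection (``scipy.optimize.brentq``) on the log amount.
    """
    network.validate()
    mono = network.monomials()
    base = network.base_species()
    free = [s for s in mono if s not in network.constants]
    laws = network.conservation
    totals = np.array([t for _, t in laws])
    scale = np.maximum(np.abs(totals), 1e-300)

    # degenerate laws (total 0) force all their species to zero
    zero_species = set()
    for coeffs, total in laws:
        if total == 0:
            zero_species.update(s for s, c in coeffs.items() if c > 0)
    active_base = [b for b in base if b not in zero_species]
    if not active_base:
        amounts = {s: 0.0 for s in free}
        return _finalize(network, amounts, model)

    def residual(log_base_full: np.ndarray) -> np.ndarray:
        amounts = _amounts_from_log_base(log_base_full, base, mono, free)
        res = np.empty(len(laws))
        for i, (coeffs, total) in enumerate(laws):
            res[i] = sum(c * amounts[s] for s, c in coeffs.items()) - total
        return res

    def jacobian(log_base_full: np.ndarray) -> np.ndarray:
        amounts = _amounts_from_log_base(log_base_full, base, mono, free)
        jac = np.zeros((len(laws), len(base)))
        bidx = {s: i for i, s in enumerate(base)}
        for i, (coeffs, _) in enumerate(laws):
            for s, c in coeffs.items():
                coef, exps = mono[s]
                x = amounts[s]
                for b, e in exps.items():
                    jac[i, bidx[b]] += c * x * e
        return jac

    # initial guess: each base species at half the tightest total that binds it
    log0 = np.empty(len(base))
    for j, b in enumerate(base):
        caps = [
            total / coeffs[b]
            for coeffs, total in laws
            if coeffs.get(b, 0) > 0 and total > 0
        ]
        log0[j] = np.log(0.5 * min(caps)) if caps else 0.0
    for j, b in enumerate(base):
        if b in zero_species:
            log0[j] = -np.inf

    act = [j for j, b in enumerate(base) if b not in zero_species]
    act_laws = [i for i, (_, t) in enumerate(laws) if t > 0]

    log_base = log0.copy()
    res = residual(log_base)
    norm = float(np.max(np.abs(res[act_laws]) / scale[act_laws])) if act_laws else 0.0
    it = 0
    while norm > RESIDUAL_RTOL and it < MAX_ITER:
        jac = jacobian(log_base)[np.ix_(act_laws, act)]
        try:
            step = np.linalg.solve(jac, -res[act_laws])
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -20.0, 20.0)
        lam = 1.0
        improved = False
        for _ in range(60):
            trial = log_base.copy()
            trial[act] += lam * step
            tres = residual(trial)
            tnorm = float(np.max(np.abs(tres[act_laws]) / scale[act_laws]))
            if tnorm < norm:
                log_base, res, norm = trial, tres, tnorm
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
        it += 1

    if norm > RESIDUAL_RTOL and len(act) == 1:
        log_base, norm = _bisect_1d(log_base, act[0], residual, act_laws[0], scale[act_laws[0]])

    if norm > RESIDUAL_RTOL:
        raise EquilibriumSolverError("equilibrium solver did not converge", norm)

    amounts = _amounts_from_log_base(log_base, base, mono, free)
    return _finalize(network, amounts, model)


def _bisect_1d(log_base, j, residual, law_idx, scale):
    """Bracketed root solve on one log amount; monotone by mass action."""
    from scipy.optimize import brentq

    def f(y):
        v = log_base.copy()
        v[j] = y
        return residual(v)[law_idx]

    lo, hi = -60.0, log_base[j] + 1.0
    while f(hi) < 0 and hi < 700:
        hi += 10.0
    root = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=300)
    out = log_base.copy()
    out[j] = root
    return out, abs(f(root)) / scale


def _finalize(network, amounts, model) -> EquilibriumState:
    residuals = {}
    for i, (coeffs, total) in enumerate(network.conservation):
        name = "+".join(sorted(coeffs)) or f"law{i}"
        residuals[f"law:{name}"] = (
            sum(c * amounts[s] for s, c in coeffs.items()) - total
        )
    species = dict(amounts)
    for s, v in network.constants.items():
        species.setdefault(s, float(v))
    return EquilibriumState(model=model, species=species, residuals=residuals)


# ---------------------------------------------------------------------------
# network builders for the named architectures


def build_model_network(
    model: ModelKind, ligand: LigandParams, receptors: ReceptorConfig
) -> ReactionNetwork:
    """Reaction network equivalent to one closed-form architecture."""
    model = ModelKind(model)
    C = ligand.concentration
    kp, kf = ligand.partial_affinity, ligand.full_affinity
    a0 = receptors.a_total
    if model is ModelKind.AL:
        return ReactionNetwork(
            constants={"L": C},
            reactions=[Reaction(("A", "L"), "F", kp)],
            conservation=[({"A": 1.0, "F": 1.0}, a0)],
        )
    if model is ModelKind.ALA:
        return ReactionNetwork(
            constants={"L": C},
            reactions=[
                Reaction(("A", "L"), "P", kp),
                Reaction(("A", "P"), "F", kf),
            ],
            conservation=[({"A": 1.0, "P": 1.0, "F": 2.0}, a0)],
        )
    if model is ModelKind.LAAL:
        return ReactionNetwork(
            constants={"L": C},
            reactions=[
                Reaction(("A", "L"), "P", kp),
                Reaction(("P", "P"), "F", kf),
            ],
            conservation=[({"A": 1.0, "P": 1.0, "F": 2.0}, a0)],
        )
    if model is ModelKind.ALB_SEQ:
        b0 = receptors.require_b()
        return ReactionNetwork(
            constants={"L": C},
            reactions=[
                Reaction(("A", "L"), "P", kp),
                Reaction(("P", "B"), "F", kf),
            ],
            conservation=[
                ({"A": 1.0, "P": 1.0, "F": 1.0}, a0),
                ({"B": 1.0, "F": 1.0}, b0),
            ],
        )
    raise NetworkValidationError(f"use build_alb_nonseq_network for {model}")


def build_competition_network(
    activator: LigandParams, inhibitor: LigandParams, receptors: ReceptorConfig
) -> ReactionNetwork:
    """Two ALA-architecture ligands competing for the same subunit pool A.

    The inhibitor is typically a zero-activity ligand (``activity_rate=0``):
    it sequesters receptor subunits in complexes that produce no response.
    Species are suffixed ``_L`` (activator) and ``_I`` (inhibitor).
    """
    return ReactionNetwork(
        constants={"L": activator.concentration, "I": inhibitor.concentration},
        reactions=[
            Reaction(("A", "L"), "P_L", activator.partial_affinity),
            Reaction(("A", "P_L"), "F_L", activator.full_affinity),
            Reaction(("A", "I"), "P_I", inhibitor.partial_affinity),
            Reaction(("A", "P_I"), "F_I", inhibitor.full_affinity),
        ],
        conservation=[
            ({"A": 1.0, "P_L": 1.0, "F_L": 2.0, "P_I": 1.0, "F_I": 2.0}, receptors.a_total)
        ],
    )


@dataclass(frozen=True)
class AlbNonSeqAffinities:
    """Association constants of the B-first route in the non-sequential
    heterodimer: the ligand binds B with ``partial_affinity_b`` to form P_B,
    which binds A with ``full_affinity_b`` to complete F.

    Detailed balance around the cycle requires
    ``K_P * K_F == partial_affinity_b * full_affinity_b``.
    """

    partial_affinity_b: float
    full_affinity_b: float


def build_alb_nonseq_network(
    ligand: LigandParams,
    extra: AlbNonSeqAffinities,
    receptors: ReceptorConfig,
) -> ReactionNetwork:
    """Heterodimer where the ligand may bind A first (P_A) or B first (P_B);
    both partial complexes recruit the remaining subunit to form the same F.
    """
    b0 = receptors.require_b()
    return ReactionNetwork(
        constants={"L": ligand.concentration},
        reactions=[
            Reaction(("A", "L"), "P_A", ligand.partial_affinity),
            Reaction(("P_A", "B"), "F", ligand.full_affinity),
            Reaction(("B", "L"), "P_B", extra.partial_affinity_b),
            Reaction(("P_B", "A"), "F", extra.full_affinity_b),
        ],
        conservation=[
            ({"A": 1.0, "P_A": 1.0, "F": 1.0}, receptors.a_total),
            ({"B": 1.0, "P_B": 1.0, "F": 1.0}, b0),
        ],
    )
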