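"""Domain types shared across the equilibrium, scaling and population modules.

Units are arbitrary throughout: ligand concentrations are in arbitrary
concentration units (ACU) and receptor amounts in arbitrary receptor units
(ARU).  Affinities are *association* constants, so that at equilibrium the
partial complex obeys ``P = K_P * C * A`` and the full complex is formed from
the partial complex with association constant ``K_F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ModelKind(str, Enum):
    """Receptor architecture.

    AL
        Monomeric receptor: one ligand binds one receptor subunit to form the
        active complex (Michaelis-Menten response).
    ALA
        Homodimeric receptor, single ligand: the ligand binds a subunit A to
        form a partial complex P, which recruits a second A to form the full
        trimeric complex F.
    LAAL
        Homodimeric receptor, two ligands: each subunit binds its own ligand
        to form a partial complex; two partial complexes pair into F.
    ALB_SEQ
        Heterodimeric receptor, sequential assembly: the ligand binds A first
        (forming P), and P then recruits the second subunit B.
    ALB_NONSEQ
        Heterodimeric receptor where the ligand may bind either subunit
        first; both routes converge on the same full complex and must satisfy
        detailed balance.
    """

    AL = "AL"
    ALA = "ALA"
    LAAL = "LAAL"
    ALB_SEQ = "ALB_SEQ"
    ALB_NONSEQ = "ALB_NONSEQ"

    @property
    def heterodimeric(self) -> bool:
        return self in (ModelKind.ALB_SEQ, ModelKind.ALB_NONSEQ)

    @property
    def subunits_in_full_complex(self) -> int:
        """Number of A subunits consumed by one full complex."""
        return 1 if self in (ModelKind.AL, ModelKind.ALB_SEQ, ModelKind.ALB_NONSEQ) else 2


class ParameterDomainError(ValueError):
    """Raised when a biochemical parameter lies outside its physical domain."""


@dataclass(frozen=True)
class LigandParams:
    """Biochemical identity of one ligand.

    Parameters
    ----------
    concentration : float
        Extracellular ligand concentration C (ACU); non-negative.  Under the
        default unlimited-pool assumption this stays constant while binding.
    partial_affinity : float
        Association constant K_P (1/ACU) of the first binding step, so that
        P = K_P * C * A at equilibrium.  Strictly positive.
    full_affinity : float
        Association constant K_F (1/ARU) of the step that completes the full
        complex.  Strictly positive.  (Ignored by the AL model.)
    activity_rate : float
        Response produced per full complex, e (response units per ARU);
        non-negative.
    name : str, optional
        Identifier used in tables and reports.
    """

    concentration: float
    partial_affinity: float
    full_affinity: float = 1.0
    activity_rate: float = 1.0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ParameterDomainError(
                f"ligand concentration must be >= 0, got {self.concentration}"
            )
        if self.partial_affinity <= 0:
            raise ParameterDomainError(
                f"partial_affinity must be > 0, got {self.partial_affinity}"
            )
        if self.full_affinity <= 0:
            raise ParameterDomainError(
                f"full_affinity must be > 0, got {self.full_affinity}"
            )
        if self.activity_rate < 0:
            raise ParameterDomainError(
                f"activity_rate must be >= 0, got {self.activity_rate}"
            )

    def with_(self, **changes) -> "LigandParams":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class ReceptorConfig:
    """Per-cell receptor subunit totals.

    ``b_total`` is only meaningful for heterodimeric (ALB) models and is
    ignored elsewhere.
    """

    a_total: float
    b_total: Optional[float] = None

    def __post_init__(self) -> None:
        if self.a_total < 0:
            raise ParameterDomainError(f"a_total must be >= 0, got {self.a_total}")
        if self.b_total is not None and self.b_total < 0:
            raise ParameterDomainError(f"b_total must be >= 0, got {self.b_total}")

    def require_b(self) -> float:
        if self.b_total is None:
            raise ParameterDomainError("heterodimeric models require b_total")
        return self.b_total


@dataclass
class EquilibriumState:
    """Steady-state amounts of every molecular species plus residuals.

    ``species`` maps species names (``A``, ``B``, ``P``, ``P_A``, ``P_B``,
    ``F`` ...) to non-negative amounts; ``residuals`` maps conservation-law
    names to the signed defect ``sum(coeff * amount) - total``.
    """

    model: ModelKind
    species: dict = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)

    @property
    def full_complex(self) -> float:
        return self.species["F"]

    def max_relative_residual(self, scale: float) -> float:
        if not self.residuals:
            return 0.0
        denom = max(abs(scale), 1e-300)
        return max(abs(r) for r in self.residuals.values()) / denom
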