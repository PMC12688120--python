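"""Local scaling of the response with respect to receptor totals.

The local scaling ``S = d ln E / d ln A0`` is the power-law exponent of the
response with respect to receptor abundance at one operating point: a cell
whose receptor level is a fraction ``delta`` above the population mean
responds a fraction ``S * delta`` above the mean response, so ``S`` governs
how receptor-level variability propagates into response variability.

The numeric central-difference log-derivative is the ground-truth method
here; the closed-form expressions (:func:`scaling_from_bound_fraction_ala`,
:func:`scaling_alb_closed`) are accelerators validated against it in the
test suite.  Since ``E = e * F**n``, the activity rate ``e`` cancels exactly
in the log-difference and the derivative is computed on ``ln F`` alone —
scaling is therefore independent of ``e`` by construction, mirroring the
model's analytic structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import equilibria
from .params import LigandParams, ModelKind, ParameterDomainError, ReceptorConfig

__all__ = [
    "ScalingResult",
    "UndefinedScalingError",
    "local_scaling",
    "numeric_scaling",
    "scaling_from_bound_fraction_ala",
    "scaling_alb_closed",
    "scan_scaling",
    "bound_fraction",
]

#: relative step of the central difference in log space; truncation error
#: O(h^2) ~ 1e-8 is far below every tolerance used downstream.
DEFAULT_STEP = 1e-4


class UndefinedScalingError(ValueError):
    """The response is zero at the evaluation point (e.g. C = 0)."""


@dataclass(frozen=True)
class ScalingResult:
    """Scaling value(s) at one operating point.

    ``s`` is the scaling for the perturbed total(s): for single-subunit
    models the only scaling; for heterodimers the scaling of the requested
    subunit (or the joint scaling when both totals are perturbed together).
    ``s_a``/``s_b`` are filled for heterodimeric models.
    """

    model: ModelKind
    s: float
    bound_fraction: float
    s_a: Optional[float] = None
    s_b: Optional[float] = None
    ligand: Optional[LigandParams] = None
    receptors: Optional[ReceptorConfig] = None


def numeric_scaling(full_at_scale: Callable, h: float = DEFAULT_STEP):
    """Central-difference log-derivative through a complex-amount callback.

    ``full_at_scale(m)`` must return the full-complex amount (scalar or
    array) when the perturbed receptor total(s) are multiplied by ``m``.
    """
    up = np.asarray(full_at_scale(np.exp(h)), dtype=float)
    dn = np.asarray(full_at_scale(np.exp(-h)), dtype=float)
    if np.any(up <= 0) or np.any(dn <= 0):
        raise UndefinedScalingError(
            "response is zero at the evaluation point; scaling undefined"
        )
    return (np.log(up) - np.log(dn)) / (2.0 * h)


def bound_fraction(
    model: ModelKind, full: float, receptors: ReceptorConfig
) -> float:
    """Fraction of receptor subunits sequestered in full complexes.

    ``2F/A0`` for the homodimers (each F holds two A subunits), ``F/A0`` for
    the monomer, and ``F/min(A0, B0)`` — relative to the less abundant
    subunit — for heterodimers.
    """
    model = ModelKind(model)
    if model.heterodimeric:
        denom = min(receptors.a_total, receptors.require_b())
    else:
        denom = receptors.a_total
    if denom == 0:
        return 0.0
    return model.subunits_in_full_complex * full / denom if not model.heterodimeric else full / denom


def local_scaling(
    model: ModelKind,
    ligand: LigandParams,
    receptors: ReceptorConfig,
    subunit: str = "A",
    exponent: float = 1.0,
    h: float = DEFAULT_STEP,
) -> ScalingResult:
    """Local scaling of ``E = e * F**n`` with respect to receptor totals.

    Parameters
    ----------
    subunit : {"A", "B", "both"}
        Which total to perturb.  ``"B"`` and ``"both"`` require a
        heterodimeric model; ``"both"`` perturbs A0 and B0 jointly (its value
        equals ``S_A + S_B`` up to the finite-difference error).
    exponent : float
        Downstream response exponent ``n``; the scaling is ``n`` times the
        ``n = 1`` value and never depends on the activity rate.
    """
    model = ModelKind(model)
    if exponent <= 0:
        raise ParameterDomainError(f"exponent must be > 0, got {exponent}")
    if subunit not in ("A", "B", "both"):
        raise ValueError(f"subunit must be 'A', 'B' or 'both', got {subunit!r}")
    if subunit in ("B",) and not model.heterodimeric:
        raise ParameterDomainError(f"{model.value} has no B subunit")

    a0 = receptors.a_total
    b0 = receptors.b_total if model.heterodimeric else None

    def full_at(m, which):
        aa = a0 * m if which in ("A", "both") else a0
        bb = None
        if model.heterodimeric:
            bb = b0 * m if which in ("B", "both") else b0
        return equilibria.full_complex(model, ligand, aa, bb)

    s = float(numeric_scaling(lambda m: full_at(m, subunit), h=h)) * exponent

    s_a = s_b = None
    if model.heterodimeric:
        s_a = s if subunit == "A" else float(
            numeric_scaling(lambda m: full_at(m, "A"), h=h)
        ) * exponent
        s_b = s if subunit == "B" else float(
            numeric_scaling(lambda m: full_at(m, "B"), h=h)
        ) * exponent

    full = float(equilibria.full_complex(model, ligand, a0, b0))
    return ScalingResult(
        model=model,
        s=s,
        s_a=s_a,
        s_b=s_b,
        bound_fraction=bound_fraction(model, full, receptors),
        ligand=ligand,
        receptors=receptors,
    )


# ---------------------------------------------------------------------------
# closed forms (validated against the numeric derivative in the test suite)


def scaling_from_bound_fraction_ala(f: float) -> float:
    """ALA scaling as a function of the bound fraction ``f = 2F/A0``.

    ``S = 2 / (1 + f)``: the scaling interpolates from 2 (quadratic regime,
    vanishing occupancy) down to 1 (linear regime, full occupancy) and
    depends on the ligand only through the occupancy it achieves.
    """
    if not 0.0 <= f <= 1.0:
        raise ParameterDomainError(f"bound fraction must lie in [0, 1], got {f}")
    return 2.0 / (1.0 + f)


def scaling_alb_closed(receptors: ReceptorConfig, full: float) -> tuple:
    """Per-subunit scalings of the sequential heterodimer from ``F`` alone.

    ``S_A = A0 / ((A0 - F) * B0 / (B0 - F) + F)`` and the A<->B mirror image
    for ``S_B``.  Both reduce to 1 as ``F -> 0`` and the abundant subunit's
    scaling falls to 0 as the scarce subunit saturates (``F -> min(A0, B0)``).
    """
    a0, b0 = receptors.a_total, receptors.require_b()
    if full >= min(a0, b0):
        raise ParameterDomainError(
            f"F = {full} must be below min(A0, B0) = {min(a0, b0)}"
        )
    if full < 0:
        raise ParameterDomainError(f"F must be >= 0, got {full}")
    s_a = a0 / ((a0 - full) * b0 / (b0 - full) + full)
    s_b = b0 / ((b0 - full) * a0 / (a0 - full) + full)
    return s_a, s_b


# ---------------------------------------------------------------------------
# parameter scans


def _default_grid() -> np.ndarray:
    return np.logspace(-4, 4, 41)


def scan_scaling(
    model: ModelKind,
    kp_c: Optional[Sequence[float]] = None,
    kf_a0: Optional[Sequence[float]] = None,
    ratios: Optional[Iterable[float]] = None,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Scaling over a log grid of the dimensionless groups.

    The grid is realised with ``C = 1`` and a reference total of 1 for the
    perturbed pool (``A0 = 1`` for single-subunit models; ``B0 = 1`` and
    ``A0 = ratio`` for heterodimers), so ``K_P = K_P*C`` and
    ``K_F = K_F*A0`` numerically.  One row per grid point; solver failures
    are recorded as missing values rather than aborting the scan.

    Returns a tidy frame with columns ``model, kp_c, kf_a0, a0_over_b0, S,
    S_A, S_B, bound_fraction``.
    """
    model = ModelKind(model)
    kp_c = _default_grid() if kp_c is None else np.asarray(kp_c, dtype=float)
    kf_a0 = _default_grid() if kf_a0 is None else np.asarray(kf_a0, dtype=float)
    if model.heterodimeric:
        ratios = [1.0] if ratios is None else list(ratios)
    else:
        ratios = [np.nan]

    rows = []
    for ratio in ratios:
        if model.heterodimeric:
            b0 = 1.0
            a0 = ratio * b0
            receptors = ReceptorConfig(a_total=a0, b_total=b0)
        else:
            a0 = 1.0
            receptors = ReceptorConfig(a_total=a0)
        for kp in np.atleast_1d(kp_c):
            for kf in np.atleast_1d(kf_a0):
                ligand = LigandParams(
                    concentration=1.0,
                    partial_affinity=float(kp),
                    full_affinity=float(kf) / a0 if model.heterodimeric else float(kf),
                )
                try:
                    if model.heterodimeric:
                        res = local_scaling(
                            model, ligand, receptors, subunit="A", exponent=exponent
                        )
                        s_a, s_b = res.s_a, res.s_b
                        s = s_a + s_b
                    else:
                        res = local_scaling(
                            model, ligand, receptors, subunit="A", exponent=exponent
                        )
                        s, s_a, s_b = res.s, np.nan, np.nan
                    bf = res.bound_fraction
                except (UndefinedScalingError, RuntimeError):
                    s = s_a = s_b = bf = np.nan
                rows.append(
                    {
                        "model": model.value,
                        "kp_c": float(kp),
                        "kf_a0": float(kf),
                        "a0_over_b0": ratio,
                        "S": s,
                        "S_A": s_a,
                        "S_B": s_b,
                        "bound_fraction": bf,
                    }
                )
    return pd.DataFrame(rows)
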