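"""Heterogeneous cell-population simulations.

Cells differ only in their receptor totals, drawn from a gamma distribution
parameterised by mean and standard deviation (moment matching: shape =
(mean/sd)^2, scale = sd^2/mean).  All cells see the same ligand concentration
(well-mixed medium), and the response heterogeneity is summarised by the
coefficient of variation CV = SD/mean.

To compare ligands on an equal footing the activity rate of each ligand is
matched so the population mean response is a common target (the response is
proportional to ``e``, so matching is exact); differences in CV then isolate
how the ligand's binding parameters reshape the response distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import equilibria, scaling
from .params import LigandParams, ModelKind, ParameterDomainError, ReceptorConfig

__all__ = [
    "PopulationSpec",
    "PopulationResponse",
    "sample_receptors",
    "simulate_population",
    "match_mean_activity",
    "compare_ligands",
    "heterodimer_population_experiment",
    "competition_full_complex",
    "simulate_competition_population",
    "constant_complex_inhibitor_path",
    "default_al_panel",
    "default_ala_panel",
    "default_alb_panel",
    "default_heterodimer_populations",
]

#: population size used in the reference experiments.
DEFAULT_N_CELLS = 100_000


def default_al_panel() -> List[LigandParams]:
    """Five monomeric-model ligands at C = 1 with affinities log-spaced over
    [1e-2, 1e2]: they differ widely in occupancy yet induce identical CV."""
    return [
        LigandParams(concentration=1.0, partial_affinity=k, name=f"K={k:g}")
        for k in np.logspace(-2, 2, 5)
    ]


def default_ala_panel() -> List[LigandParams]:
    """Five homodimer ligands at the partial-binding EC50 (K_P C = 1) whose
    pairing affinities K_F A0 log-span [1e-2, 1e2], covering the quadratic
    (low occupancy, S near 2) through linear (high occupancy, S near 1)
    regimes."""
    return [
        LigandParams(concentration=1.0, partial_affinity=1.0, full_affinity=k,
                     name=f"KF={k:g}")
        for k in np.logspace(-2, 2, 5)
    ]


def default_alb_panel() -> List[LigandParams]:
    """Three heterodimer ligands spanning sub-saturated, intermediate and
    saturated binding."""
    return [
        LigandParams(1.0, 0.01, 0.01, name="weak"),
        LigandParams(1.0, 1.0, 1.0, name="intermediate"),
        LigandParams(1.0, 1e4, 1e4, name="saturating"),
    ]


def default_heterodimer_populations(
    n_cells: int = DEFAULT_N_CELLS, seed: int = 0
) -> List["PopulationSpec"]:
    """Four receptor-population archetypes for the heterodimer experiment.

    Ordered by increasing capacity for ligand-dependent heterogeneity:
    balanced subunits; imbalanced with a tight abundant subunit; imbalanced
    with a variable abundant subunit; and the extreme case (100-fold
    imbalance, abundant subunit CV 1, limiting subunit CV 0.05) where the
    ligand-to-ligand CV spread exceeds an order of magnitude.
    """
    return [
        PopulationSpec(n_cells=n_cells, mean_a=1.0, sd_a=0.5, mean_b=1.0, sd_b=0.5, seed=seed),
        PopulationSpec(n_cells=n_cells, mean_a=1.0, sd_a=0.5, mean_b=10.0, sd_b=1.0, seed=seed),
        PopulationSpec(n_cells=n_cells, mean_a=1.0, sd_a=0.1, mean_b=10.0, sd_b=10.0, seed=seed),
        PopulationSpec(n_cells=n_cells, mean_a=1.0, sd_a=0.05, mean_b=100.0, sd_b=100.0, seed=seed),
    ]


@dataclass(frozen=True)
class PopulationSpec:
    """Gamma-distributed receptor totals for a population of cells.

    ``mean_b``/``sd_b`` describe the second subunit of heterodimeric models
    and are ignored otherwise.  ``correlation`` (Gaussian-copula rank
    correlation between the A and B draws) defaults to 0: subunit levels are
    drawn independently.
    """

    n_cells: int = DEFAULT_N_CELLS
    mean_a: float = 1.0
    sd_a: float = 0.5
    mean_b: Optional[float] = None
    sd_b: Optional[float] = None
    seed: int = 0
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterDomainError("n_cells must be >= 1")
        if self.mean_a <= 0 or self.sd_a < 0:
            raise ParameterDomainError("mean_a must be > 0 and sd_a >= 0")
        if (self.mean_b is None) != (self.sd_b is None):
            raise ParameterDomainError("mean_b and sd_b must be given together")
        if self.mean_b is not None and (self.mean_b <= 0 or self.sd_b < 0):
            raise ParameterDomainError("mean_b must be > 0 and sd_b >= 0")
        if not -1.0 < self.correlation < 1.0:
            raise ParameterDomainError("correlation must lie in (-1, 1)")


@dataclass
class PopulationResponse:
    """Per-cell responses with summary statistics.

    ``cv`` is NaN when the mean response is zero (all-zero responses carry
    no heterogeneity information).
    """

    responses: np.ndarray
    mean: float
    sd: float
    cv: float
    ligand: Optional[str] = None
    spec: Optional[PopulationSpec] = None

    @classmethod
    def from_responses(cls, responses, ligand=None, spec=None) -> "PopulationResponse":
        responses = np.asarray(responses, dtype=float)
        mean = float(responses.mean())
        sd = float(responses.std(ddof=0))
        cv = sd / mean if mean > 0 else float("nan")
        return cls(responses=responses, mean=mean, sd=sd, cv=cv, ligand=ligand, spec=spec)


def _gamma_draw(rng: np.random.Generator, n: int, mean: float, sd: float,
                normal: Optional[np.ndarray] = None) -> np.ndarray:
    from scipy import stats

    if sd == 0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    if normal is None:
        return rng.gamma(shape, scale, size=n)
    # Gaussian copula: transform correlated standard normals through the
    # gamma quantile function.
    u = stats.norm.cdf(normal)
    return stats.gamma.ppf(u, a=shape, scale=scale)


def sample_receptors(spec: PopulationSpec) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Draw per-cell receptor totals ``(A0, B0)``; ``B0`` is None when the
    spec describes a single subunit.  Reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.mean_b is None:
        return _gamma_draw(rng, spec.n_cells, spec.mean_a, spec.sd_a), None
    if spec.correlation != 0.0:
        cov = np.array([[1.0, spec.correlation], [spec.correlation, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=spec.n_cells)
        a = _gamma_draw(rng, spec.n_cells, spec.mean_a, spec.sd_a, normal=z[:, 0])
        b = _gamma_draw(rng, spec.n_cells, spec.mean_b, spec.sd_b, normal=z[:, 1])
    else:
        a = _gamma_draw(rng, spec.n_cells, spec.mean_a, spec.sd_a)
        b = _gamma_draw(rng, spec.n_cells, spec.mean_b, spec.sd_b)
    return a, b


def simulate_population(
    model: ModelKind,
    ligand: LigandParams,
    spec: PopulationSpec,
    exponent: float = 1.0,
    receptors: Optional[Tuple[np.ndarray, Optional[np.ndarray]]] = None,
) -> PopulationResponse:
    """Per-cell equilibrium response across a receptor-variable population.

    ``receptors`` allows reusing one sampled population across ligands (the
    paired design used whenever ligands are compared).
    """
    model = ModelKind(model)
    a0, b0 = sample_receptors(spec) if receptors is None else receptors
    if model.heterodimeric and b0 is None:
        raise ParameterDomainError("heterodimeric model needs mean_b/sd_b in the spec")
    full = equilibria.full_complex(model, ligand, a0, b0 if model.heterodimeric else None)
    resp = equilibria.response(full, ligand, exponent=exponent)
    return PopulationResponse.from_responses(resp, ligand=ligand.name, spec=spec)


def match_mean_activity(
    model: ModelKind,
    ligand: LigandParams,
    spec: PopulationSpec,
    target_mean: float = 1.0,
    exponent: float = 1.0,
    receptors: Optional[Tuple[np.ndarray, Optional[np.ndarray]]] = None,
) -> LigandParams:
    """Return the ligand with its activity rate set so the population mean
    response equals ``target_mean`` (exact, since ``E`` is proportional to
    ``e``)."""
    if target_mean <= 0:
        raise ParameterDomainError("target_mean must be > 0")
    model = ModelKind(model)
    a0, b0 = sample_receptors(spec) if receptors is None else receptors
    full = equilibria.full_complex(model, ligand, a0, b0 if model.heterodimeric else None)
    mean_fn = float(np.mean(np.asarray(full, dtype=float) ** exponent))
    if mean_fn <= 0:
        raise ParameterDomainError(
            f"ligand {ligand.name or ''} forms no complexes; mean response unmatchable"
        )
    return ligand.with_(activity_rate=target_mean / mean_fn)


def compare_ligands(
    model: ModelKind,
    ligands: Sequence[LigandParams],
    spec: PopulationSpec,
    target_mean: float = 1.0,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Mean-matched CV comparison across a ligand panel.

    All ligands are evaluated on the *same* receptor sample (paired design)
    so CV differences reflect ligand identity, not sampling noise.  The
    returned frame has one row per ligand with the matched activity rate,
    response mean/SD/CV and the scaling at the mean cell; the max/min CV
    ratio is stored in ``frame.attrs['cv_ratio']``.
    """
    if len(ligands) < 1:
        raise ValueError("need at least one ligand")
    model = ModelKind(model)
    sample = sample_receptors(spec)
    mean_receptors = ReceptorConfig(
        a_total=spec.mean_a,
        b_total=spec.mean_b if model.heterodimeric else None,
    )
    rows = []
    for i, lig in enumerate(ligands):
        lig = lig if lig.name else lig.with_(name=f"ligand_{i + 1}")
        matched = match_mean_activity(
            model, lig, spec, target_mean, exponent=exponent, receptors=sample
        )
        resp = simulate_population(model, matched, spec, exponent=exponent, receptors=sample)
        s_at_mean = scaling.local_scaling(
            model, matched, mean_receptors, subunit="both" if model.heterodimeric else "A",
            exponent=exponent,
        ).s
        rows.append(
            {
                "ligand": matched.name,
                "activity_rate": matched.activity_rate,
                "mean": resp.mean,
                "sd": resp.sd,
                "cv": resp.cv,
                "scaling_at_mean": s_at_mean,
            }
        )
    frame = pd.DataFrame(rows)
    cvs = frame["cv"].to_numpy()
    frame.attrs["cv_ratio"] = float(np.nanmax(cvs) / np.nanmin(cvs))
    return frame


def heterodimer_population_experiment(
    populations: Sequence[PopulationSpec],
    ligands: Sequence[LigandParams],
    target_mean: float = 1.0,
) -> pd.DataFrame:
    """CV per (population, ligand) for heterodimeric receptor populations.

    Each population supplies its own gamma specs for the A and B subunits;
    each ligand's activity rate is re-matched per population.  The largest
    ligand-to-ligand CV spread arises when the subunit means are imbalanced
    and the abundant subunit is the more variable one.
    """
    rows = []
    for p, spec in enumerate(populations):
        if spec.mean_b is None:
            raise ParameterDomainError("heterodimer experiment needs two-subunit specs")
        frame = compare_ligands(ModelKind.ALB_SEQ, ligands, spec, target_mean)
        for _, r in frame.iterrows():
            rows.append(
                {
                    "population": p,
                    "mean_a": spec.mean_a,
                    "sd_a": spec.sd_a,
                    "mean_b": spec.mean_b,
                    "sd_b": spec.sd_b,
                    "ligand": r["ligand"],
                    "mean": r["mean"],
                    "sd": r["sd"],
                    "cv": r["cv"],
                }
            )
    out = pd.DataFrame(rows)
    ratios = {
        p: float(g["cv"].max() / g["cv"].min()) for p, g in out.groupby("population")
    }
    out.attrs["cv_ratio_per_population"] = ratios
    return out


# ---------------------------------------------------------------------------
# competition (activator + zero-activity inhibitor), vectorized


def competition_full_complex(
    activator: LigandParams, inhibitor: LigandParams, a_total
):
    """Activator full-complex amount when two ALA-type ligands compete for
    one subunit pool (vectorized over ``a_total``).

    With ``k_X = K_P^X C_X``, the shared-subunit conservation law
    ``A (1 + k_L + k_I) + 2 A^2 (K_F^L k_L + K_F^I k_I) = A0`` is quadratic
    in the free subunit A; cross-checked against the general network solver
    in the test suite.
    """
    a_total = np.asarray(a_total, dtype=float)
    k_l = activator.partial_affinity * activator.concentration
    k_i = inhibitor.partial_affinity * inhibitor.concentration
    lin = 1.0 + k_l + k_i
    quad = 2.0 * (activator.full_affinity * k_l + inhibitor.full_affinity * k_i)
    free_a = equilibria._positive_quadratic_root(quad, lin, -a_total)
    return activator.full_affinity * k_l * free_a**2


def simulate_competition_population(
    activator: LigandParams,
    inhibitor: LigandParams,
    spec: PopulationSpec,
    receptors: Optional[np.ndarray] = None,
) -> PopulationResponse:
    """Population response to an activator in the presence of a competitive
    (typically zero-activity) inhibitor."""
    a0 = sample_receptors(spec)[0] if receptors is None else receptors
    full = competition_full_complex(activator, inhibitor, a0)
    resp = equilibria.response(full, activator)
    return PopulationResponse.from_responses(resp, ligand=activator.name, spec=spec)


def constant_complex_inhibitor_path(
    activator: LigandParams,
    inhibitor: LigandParams,
    spec: PopulationSpec,
    inhibitor_concentrations: Iterable[float],
    a_reference: float = 1.0,
) -> pd.DataFrame:
    """CVs along a path in the (C_L, C_I) plane that holds the activator
    complex amount fixed at the reference cell.

    For each inhibitor concentration, the activator concentration is
    adjusted (1-D root solve) so that ``F_L`` at ``A0 = a_reference`` equals
    its inhibitor-free value; the population CV of the response is then
    computed on a shared receptor sample.  Raising the inhibitor along this
    path lowers the scaling and hence the CV.
    """
    from scipy.optimize import brentq

    target_f = float(competition_full_complex(activator, inhibitor.with_(concentration=0.0), a_reference))
    sample = sample_receptors(spec)[0]
    rows = []
    for c_i in inhibitor_concentrations:
        inh = inhibitor.with_(concentration=float(c_i))

        def f_gap(log_c):
            act = activator.with_(concentration=float(np.exp(log_c)))
            return float(competition_full_complex(act, inh, a_reference)) - target_f

        # more inhibitor needs more activator to restore F_L; step the upper
        # bracket outward until the gap changes sign (the dose-response is
        # non-monotone at saturating C_L, so stop at the first sign change)
        lo = np.log(activator.concentration) - 1e-9
        hi = np.log(activator.concentration)
        g = f_gap(hi)
        while g < 0 and hi < 60:
            lo, hi = hi, hi + 0.5
            g = f_gap(hi)
        if g < 0:
            raise ParameterDomainError(
                f"cannot restore the complex amount at inhibitor concentration {c_i}"
            )
        c_l = float(np.exp(brentq(f_gap, lo, hi, xtol=1e-13)))
        act = activator.with_(concentration=c_l)
        resp = simulate_competition_population(act, inh, spec, receptors=sample)
        rows.append(
            {
                "inhibitor_concentration": float(c_i),
                "activator_concentration": c_l,
                "full_complex_at_reference": target_f,
                "cv": resp.cv,
                "mean": resp.mean,
            }
        )
    return pd.DataFrame(rows)
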