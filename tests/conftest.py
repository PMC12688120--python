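import numpy as np
import pytest

from rlscale.params import LigandParams, ModelKind, ReceptorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def log_uniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def random_ligand(rng, lo=1e-2, hi=1e2) -> LigandParams:
    """Ligand with log-uniform concentration and affinities, so the
    dimensionless groups K_P*C and K_F*A0 span [lo^2, hi^2]."""
    return LigandParams(
        concentration=float(log_uniform(rng, lo, hi)),
        partial_affinity=float(log_uniform(rng, lo, hi)),
        full_affinity=float(log_uniform(rng, lo, hi)),
    )


def random_receptors(rng, model: ModelKind, lo=1e-2, hi=1e2) -> ReceptorConfig:
    a0 = float(log_uniform(rng, lo, hi))
    if ModelKind(model).heterodimeric:
        return ReceptorConfig(a_total=a0, b_total=float(log_uniform(rng, lo, hi)))
    return ReceptorConfig(a_total=a0)
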