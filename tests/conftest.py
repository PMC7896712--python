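import numpy as np
import pytest

from idbench import evaluate
from idbench.markers_io import MarkerPanel
from idbench.simcore import (PopulationState, SimulationConfig,
                             default_scenario)


def make_population(haplotypes, positions=None, is_qtl=None, s=None, a=None,
                    h=None, generation=0):
    """Hand-built population from a (2N, S) 0/1 matrix."""
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    S = haplotypes.shape[1]
    if positions is None:
        positions = np.arange(S, dtype=np.int64) * 1000
    is_qtl = (np.zeros(S, dtype=bool) if is_qtl is None
              else np.asarray(is_qtl, dtype=bool))
    zeros = np.zeros(S)
    return PopulationState(
        haplotypes=haplotypes,
        positions=np.asarray(positions, dtype=np.int64),
        is_qtl=is_qtl,
        s=zeros.copy() if s is None else np.asarray(s, dtype=float),
        a=zeros.copy() if a is None else np.asarray(a, dtype=float),
        h=np.full(S, 0.2) if h is None else np.asarray(h, dtype=float),
        origin_gen=np.zeros(S, dtype=np.int32),
        generation=generation,
    )


def make_panel(genotypes, positions=None, derived_is_minor=None):
    """Hand-built marker panel from a dosage matrix (minor-allele coded)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    S = genotypes.shape[1]
    if positions is None:
        positions = np.arange(S, dtype=np.int64) * 1000
    p = genotypes.mean(axis=0) / 2.0
    if derived_is_minor is not None:
        derived_is_minor = np.asarray(derived_is_minor, dtype=bool)
    return MarkerPanel(genotypes=genotypes,
                       positions=np.asarray(positions, dtype=np.int64),
                       p=p, derived_is_minor=derived_is_minor)


def random_panel(rng, n_ind=12, n_snp=20):
    """Random complete panel with segregating, minor-coded columns."""
    while True:
        g = rng.integers(0, 3, size=(n_ind, n_snp)).astype(np.int8)
        freq = g.mean(axis=0) / 2.0
        g = np.where(freq <= 0.5, g, 2 - g).astype(np.int8)
        freq = g.mean(axis=0) / 2.0
        if ((freq > 0) & (freq <= 0.5)).all():
            return make_panel(g)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but non-trivial scenario for fast end-to-end runs."""
    return SimulationConfig(N=30, L=2_000_000, c=1e-8, U=3.0,
                            generations=120, trait_scale=1.0)


@pytest.fixture(scope="session")
def default_run():
    """Thirty replicates of the default N=100 benchmark scenario.

    This is the expensive session fixture behind the scaled-down
    reproduction checks; every stochastic acceptance assertion shares it.
    """
    summary, replicates = evaluate.run_scenario(
        default_scenario(100), n_replicates=30, base_seed=20201023)
    return summary, replicates
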