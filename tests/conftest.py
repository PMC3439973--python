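"""Shared fixtures: library stats, toy coverage, small simulations."""

import math

import numpy as np
import pytest

from probsv.fragments import ConcordantIndex, LibraryStats
from probsv.likelihood import ModelParams
from probsv.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def stats():
    # Lmin/Lmax = 0.1%/99.9% quantiles of Normal(200, 20), 50 bp reads
    return LibraryStats(lmin=138, lmax=262, lavg=200.0, readlength=50)


@pytest.fixture(scope="session")
def params():
    return ModelParams(lam=0.3, lavg=200.0, readlength=50, p_err=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_coverage(extents, chrom="chr1", length=10_000_000):
    starts = np.array([e[0] for e in extents], dtype=np.int64)
    ends = np.array([e[1] for e in extents], dtype=np.int64)
    return ConcordantIndex({chrom: (starts, ends)}, {chrom: length})


@pytest.fixture(scope="session")
def empty_coverage():
    return make_coverage([], length=10_000_000)


@pytest.fixture(scope="session")
def small_sim():
    """500 kb diploid simulation with 6 deletions and 2 inversions."""
    from probsv.simulate import default_sv_panel

    config = SimConfig(seed=11, ref_length=500_000, lam=0.3)
    svs = default_sv_panel(500_000, n_del=6, n_inv=2, seed=11, margin=5_000,
                           del_length=(150, 1200), inv_length=(500, 2000))
    return simulate_dataset(config, svs)


class ToyColumn:
    """Stand-in per-column likelihood for sampler tests: a Poisson pull toward
    ``mu`` supporters plus a constant log-odds bonus."""

    def __init__(self, mu=2.0, bonus=1.0, log_perr=math.log(0.01)):
        self.mu = mu
        self.bonus = bonus
        self._log_perr = log_perr

    def log_target_term(self, k):
        return self.bonus + k * math.log(self.mu) - self.mu - math.lgamma(k + 1)

    def log_lambda(self, k):
        return self.log_target_term(k) - k * self._log_perr


class ToyParams:
    log_perr = math.log(0.01)
    eta = 1e-3


@pytest.fixture(scope="session")
def toy_params():
    return ToyParams()
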