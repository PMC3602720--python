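import numpy as np
import pytest

from illnessdeath import (CoefficientSet, IndividualRecord, LikelihoodSettings)


@pytest.fixture
def const_theta():
    """Age-constant intensities: q12=0.08, q13=0.05, q23=0.3, Markov."""
    return CoefficientSet(beta_12=(np.log(0.08), 0.0),
                          beta_13=(np.log(0.05), 0.0),
                          beta_23=(np.log(0.3), 0.0), gamma=0.0)


@pytest.fixture
def bench_theta():
    from illnessdeath import benchmark_theta
    return benchmark_theta()


@pytest.fixture
def fine_settings():
    return LikelihoodSettings(h=0.25, integ_res=0.01)


def make_record(id, visits, death=None, censor=None, cov=()):
    return IndividualRecord(id, visits, death_age=death, censor_age=censor,
                            covariates=np.asarray(cov, dtype=float))


@pytest.fixture
def pattern_records():
    """One record per pattern A-F."""
    return {
        "A": make_record("a", [(60, 1), (62, 1), (64, 2)], death=65.3),
        "B": make_record("b", [(60, 1), (62, 2), (64, 2)], censor=64.0),
        "C": make_record("c", [(60, 1), (62, 1)], death=63.7),
        "D": make_record("d", [(60, 1), (62, 1), (64, 1)], censor=64.0),
        "E": make_record("e", [(70, 2), (72, 2)], death=73.1),
        "F": make_record("f", [(70, 2), (72, 2)], censor=72.0),
    }


def chain_likelihood(l12, l13, l23, A_b, visits, A_N, died, dt=1e-3):
    """Independent oracle: discrete-time three-state chain at step dt.

    Computes the probability (density for exact deaths) of the observed
    panel data under constant hazards, marginalising the unobserved onset
    time by forward propagation with visit-state conditioning.
    """
    p = np.array([1.0, 0.0]) if visits[0][1] == 1 else np.array([0.0, 1.0])
    n = int(round((A_N - A_b) / dt))
    vi = {int(round((a - A_b) / dt)): s for a, s in visits[1:]}
    for i in range(n):
        if i in vi:
            s = vi[i]
            p = p * np.array([s == 1, s == 2], dtype=float)
        p = np.array([p[0] * (1 - (l12 + l13) * dt),
                      p[0] * l12 * dt + p[1] * (1 - l23 * dt)])
    if died:
        return p[0] * l13 + p[1] * l23
    if n in vi:
        s = vi[n]
        p = p * np.array([s == 1, s == 2], dtype=float)
    return p.sum()
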