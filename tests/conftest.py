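import math

import numpy as np
import pytest
from hypothesis import settings

import txcycle as tx
from txcycle.params import phase_boundary_ages

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# study conditions: mESC-like phase structure and 13-hr doubling time
PHASE_FRACTIONS = (0.43, 0.29, 0.28)
TDIV = 780.0
T1, T2 = phase_boundary_ages(PHASE_FRACTIONS, TDIV)
TREP_MID_S = 0.5 * (T1 + T2)
KD_MATURE = math.log(2) / (7.1 * 60.0)  # 7.1-hr mature half-life scale


@pytest.fixture(scope="session")
def cellcycle_params():
    return tx.CellCycleParams(mu=100.0, cv=0.05, phase_fractions=PHASE_FRACTIONS,
                              tdiv=TDIV)


@pytest.fixture(scope="session")
def oct4_like():
    """Oct4-like gene with dosage compensation matched to a 1.28 G2/G1 fold."""
    alpha = tx.alpha_from_eta(1.28 / 2.0, 0.009, 0.02)
    return tx.KineticParams(kon=0.009, koff=0.02, kini=2.2, tres=3.5,
                            kd=KD_MATURE, trep=TREP_MID_S, tdiv=TDIV, alpha=alpha)


@pytest.fixture(scope="session")
def nanog_like():
    alpha = tx.alpha_from_eta(1.51 / 2.0, 0.002, 0.007)
    return tx.KineticParams(kon=0.002, koff=0.007, kini=0.84, tres=3.5,
                            kd=KD_MATURE, trep=TREP_MID_S, tdiv=TDIV, alpha=alpha)


@pytest.fixture(scope="session")
def fast_cycle_params():
    """Small-count parameter set for quick exact FSP/Gillespie comparisons."""
    return tx.KineticParams(kon=0.2, koff=0.3, kini=0.5, tres=2.0, kd=0.02,
                            trep=130.0, tdiv=300.0, alpha=0.6)


@pytest.fixture(scope="session")
def oct4_population(oct4_like, cellcycle_params):
    """600-cell asynchronous Oct4-like population (fixed seed)."""
    return tx.sample_population(oct4_like, cellcycle_params, 600, seed=101)


def pop_arrays(cells):
    ages = np.array([c.age for c in cells])
    mature = np.array([c.mature for c in cells])
    totals = np.array([sum(c.nascent_signals) for c in cells])
    dna = np.array([c.dna_content for c in cells])
    return ages, mature, totals, dna
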