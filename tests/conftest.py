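import itertools

import numpy as np
import pytest

from respiroferm import build_census_fixture, build_toy_model
from respiroferm.fixtures import EXCLUSIONS
from respiroferm.census import run_census


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model()


@pytest.fixture(scope="session")
def census_fixture():
    return build_census_fixture()


@pytest.fixture(scope="session")
def fixture_census_result(census_fixture):
    model, _ = census_fixture
    return run_census(model, exclusions=EXCLUSIONS)


def brute_force_fba(model, objective, sense="max"):
    """Independent FBA oracle: exhaustive enumeration of basic feasible
    solutions (vertices of {S v = 0, l <= v <= u}) for tiny networks.

    Every assignment of a subset of reactions to one of its bounds is tried;
    the remaining free fluxes are solved from the steady-state system.  The
    optimum over all vertices equals the LP optimum for bounded feasible
    problems.  Only use for networks with at most ~8 reactions.
    """
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.compounds)
    n = len(rxn_ids)
    assert n <= 8, "oracle is exponential; keep the network tiny"
    S = np.zeros((len(met_ids), n))
    for j, rid in enumerate(rxn_ids):
        for met, coeff in model.reactions[rid].stoichiometry.items():
            S[met_ids.index(met), j] = coeff
    lo = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    hi = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    obj = np.array([1.0 if r == objective else 0.0 for r in rxn_ids])

    best = None
    for fixed_mask in itertools.product([0, 1, 2], repeat=n):
        # 0 = free, 1 = at lower bound, 2 = at upper bound
        free = [j for j in range(n) if fixed_mask[j] == 0]
        v = np.where(np.array(fixed_mask) == 2, hi, lo).astype(float)
        v[free] = 0.0
        rhs = -S @ v
        if free:
            A = S[:, free]
            if np.linalg.matrix_rank(A) < len(free):
                continue  # not a vertex: free fluxes under-determined
            x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free] = x
        if np.max(np.abs(S @ v)) > 1e-7:
            continue
        if np.any(v < lo - 1e-7) or np.any(v > hi + 1e-7):
            continue
        value = float(obj @ v)
        if best is None:
            best = value
        elif sense == "max":
            best = max(best, value)
        else:
            best = min(best, value)
    return best
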