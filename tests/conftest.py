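"""Shared fixtures: small hand-built populations and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hfcpipe.fecundity import IndividualHistory, YearlyPopulationRecord
from hfcpipe.variants import MISSING, GenotypeMatrix


@pytest.fixture(scope="session")
def toy_population():
    """Closed 5-female, 5-year population: every calf belongs to one of the
    five females and the yearly abundance counts exactly these females, so
    the de-lifing centering identity must hold."""
    histories = [
        IndividualHistory("w1", birth_year=1985, calving_years={2001, 2004}),
        IndividualHistory("w2", birth_year=1984, calving_years={2002}),
        IndividualHistory("w3", birth_year=1980, calving_years={2000, 2003}),
        IndividualHistory("w4", birth_year=1983, calving_years=set()),
        IndividualHistory("w5", birth_year=1982, calving_years={2004}),
    ]
    years = range(2000, 2005)
    calves = {y: sum(y in h.calving_years for h in histories) for y in years}
    records = [
        YearlyPopulationRecord(year=y, calves_observed=calves[y], adult_females_alive=5)
        for y in years
    ]
    return histories, records


def build_matrix(calls, positions=None, scaffolds=None, depth=None, biallelic=None, ids=None):
    """Construct a GenotypeMatrix from a plain nested list of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if scaffolds is None:
        scaffolds = ["s1"] * n_sites
    if biallelic is None:
        biallelic = [True] * n_sites
    if ids is None:
        ids = [f"i{k}" for k in range(n_ind)]
    sites = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "biallelic": biallelic,
        }
    )
    return GenotypeMatrix(
        individuals=list(ids),
        sites=sites,
        calls=calls,
        depth=None if depth is None else np.asarray(depth),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort reused by read-only tests."""
    from hfcpipe import simulate

    cfg = simulate.SimConfig(
        n_females=40, n_unsampled_females=10, n_sites=1500, n_scaffolds=4, seed=42
    )
    histories, records, truth = simulate.simulate_life_histories(cfg)
    matrix = simulate.simulate_genotypes(cfg, truth)
    return cfg, histories, records, truth, matrix
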