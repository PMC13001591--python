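import dataclasses

import numpy as np
import pandas as pd
import pytest

import coccitrend as ct


def make_records(rows):
    """Record DataFrame from (year, day, treatment, replicate, trap, species, adults) tuples."""
    return pd.DataFrame(rows, columns=ct.RECORD_COLUMNS)


@pytest.fixture(scope="session")
def default_scenario():
    return ct.study_default_scenario()


@pytest.fixture(scope="session")
def default_run(default_scenario):
    """One full default-scenario dataset (seed 0), culled and aggregated."""
    cfg, species = default_scenario
    cfg = dataclasses.replace(cfg, seed=0)
    records = ct.generate_scenario(cfg, species)
    registry = ct.registry_from_profiles(species)
    aggregates = ct.aggregate(ct.cull(records), registry)
    return {
        "config": cfg,
        "species": species,
        "records": records,
        "registry": registry,
        "aggregates": aggregates,
        "habitat_map": ct.HabitatMap(dict(cfg.treatments)),
        "weights": ct.PredationWeights.from_registry(registry),
    }


@pytest.fixture()
def small_scenario():
    """A small two-habitat scenario for structural checks."""
    flat = ct.LogTrajectory((1993, 1996), (np.log(2.0), np.log(2.0)))
    sp = [
        ct.SpeciesProfile(
            "Coleomegilla maculata", ct.Origin.NATIVE, 50.0, 1993,
            {h: flat for h in ct.HABITATS},
        ),
        ct.SpeciesProfile(
            "Harmonia axyridis", ct.Origin.EXOTIC, 100.0, 1994,
            {h: flat for h in ct.HABITATS},
        ),
    ]
    cfg = ct.ScenarioConfig(
        years=(1993, 1996),
        treatments={"A": "annual", "B": "perennial"},
        replicates=2,
        weeks=(130, 137, 144),
        traps_per_plot=3,
        trap_missingness=0.2,
        dispersion=2.0,
        seed=11,
    )
    return cfg, sp
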