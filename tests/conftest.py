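"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

import predslice as ps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast simulation scenario for unit tests (seconds, not minutes)."""
    return ps.SimConfig(
        genome=ps.GenomeSpec(n_chromosomes=3, markers_per_chromosome=120,
                             qtn_per_chromosome=12),
        scheme=ps.SelectionScheme(n_sires=5, n_dams=60,
                                  offspring_per_generation=240),
        n_generations=3, burn_in_generations=4, burn_in_size=60)


@pytest.fixture(scope="session")
def tiny_population(tiny_config):
    pop, realized = ps.run_generations(tiny_config, seed=11)
    return pop, realized


@pytest.fixture(scope="session")
def noselect_population(tiny_config):
    """Random-parent control of the tiny scenario (no truncation selection)."""
    from dataclasses import replace
    # enough random parents (Ne ~ 140) that drift cannot masquerade as a trend
    cfg = replace(tiny_config,
                  scheme=replace(tiny_config.scheme, select=False,
                                 n_sires=60, n_dams=80))
    pop, realized = ps.run_generations(cfg, seed=12)
    return pop, realized


@pytest.fixture
def small_genotypes(rng):
    """60 individuals x 80 markers drawn at Hardy-Weinberg frequencies."""
    p = rng.uniform(0.1, 0.9, size=80)
    dosages = (rng.random((60, 80, 2)) < p[None, :, None]).sum(axis=2).astype(np.int8)
    ids = [f"i{k}" for k in range(60)]
    return ps.GenotypeMatrix(dosages, ids, [f"m{k}" for k in range(80)])
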