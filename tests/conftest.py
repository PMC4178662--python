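import logging
from dataclasses import dataclass, replace

import numpy as np
import pytest

from popsel import pipeline as pl
from popsel.config import RunConfig
from popsel.simulate import SimConfig, default_scenario, simulate_dataset

logging.getLogger("popsel").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def dataset():
    """Default-scenario synthetic dataset shared across the suite."""
    return simulate_dataset(default_scenario(), seed=1)


@dataclass
class Analysis:
    dataset: object
    keep: dict
    poly: dict
    tracts: list
    call: object
    fixed: dict
    fixed_df: object
    per_class: object
    dnds: object
    spectra: dict
    diversity_spectra: dict


@pytest.fixture(scope="session")
def analysis(dataset, run_config) -> Analysis:
    rng = np.random.default_rng(7)
    keep, poly = pl.filter_stage(dataset.table, run_config)
    tracts = pl.ibd_stage(dataset.table, poly, run_config)
    call, fixed, fixed_df, per_class, dnds = pl.divergence_stage(
        dataset.alignment, dataset.table, dataset.class_map,
        dataset.bundle, keep, run_config)
    spectra, _ = pl.afs_stage(dataset.table, dataset.class_map, call,
                              tracts, keep, run_config, rng)
    div_spec = pl.diversity_stage(dataset.table, dataset.class_map, tracts,
                                  keep, run_config, rng)
    return Analysis(dataset, keep, poly, tracts, call, fixed, fixed_df,
                    per_class, dnds, spectra, div_spec)


@pytest.fixture(scope="session")
def two_gene_config() -> SimConfig:
    """A genome sized to hold exactly two genes on one contig."""
    cfg = replace(default_scenario(), n_contigs=1, contig_length=7_500,
                  n_ibd_tracts=0)
    assert 2 * (cfg.gene_span() + cfg.spacer) + cfg.spacer \
        <= cfg.contig_length + cfg.gene_span()
    return cfg
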