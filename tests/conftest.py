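"""Shared fixtures: small and full-size synthetic experiments.

Session-scoped so the expensive simulate + preprocess work is done once
and reused across test modules.
"""

from __future__ import annotations

import pytest

import dyeswap as ds

TINY_CATEGORIES = {"immune_response": 30, "apoptosis": 15, "cell_cycle": 10}


def tiny_config(**overrides) -> ds.GeneratorConfig:
    """A fast, small experiment: 120 clones, one condition."""
    defaults = dict(
        n_clones=120,
        conditions=[("cond_a", "slow", 24, "LPS")],
        category_scheme=dict(TINY_CATEGORIES),
        de_fraction=0.1,
        seed=42,
    )
    defaults.update(overrides)
    return ds.GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_experiment() -> ds.SimulatedExperiment:
    return ds.simulate_experiment(tiny_config(), seed=42)


@pytest.fixture(scope="session")
def tiny_ratio_sets(tiny_experiment) -> dict[str, ds.RatioSet]:
    out = {}
    for slide in tiny_experiment.slides:
        ratios, _ = ds.preprocess_slide(slide)
        out[slide.slide_id] = ratios
    return out


@pytest.fixture(scope="session")
def tiny_stats(tiny_experiment, tiny_ratio_sets):
    """Per-gene statistics for the tiny experiment's single condition."""
    s1, s2 = tiny_experiment.design.pairs["cond_a"]
    matrix = ds.combine_dye_swap(tiny_ratio_sets[s1], tiny_ratio_sets[s2])
    return ds.gene_statistics(matrix)


@pytest.fixture(scope="session")
def fullsize_experiment() -> ds.SimulatedExperiment:
    """Full platform size (1818 clones), one condition, default planting."""
    config = ds.GeneratorConfig(
        conditions=[("cond_a", "slow", 24, "LPS")], seed=101)
    return ds.simulate_experiment(config, seed=101)


@pytest.fixture(scope="session")
def fullsize_stats(fullsize_experiment):
    exp = fullsize_experiment
    rs = {}
    for slide in exp.slides:
        ratios, _ = ds.preprocess_slide(slide)
        rs[slide.slide_id] = ratios
    s1, s2 = exp.design.pairs["cond_a"]
    matrix = ds.combine_dye_swap(rs[s1], rs[s2])
    return ds.gene_statistics(matrix)
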