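import pytest

from isoreact import (
    AssignmentConfig,
    SyntheticConfig,
    nitrogen15_table,
    parse_formula,
)


@pytest.fixture(scope="session")
def n15_table():
    """Isotope table with ¹⁵N as principal nitrogen at 98.2% enrichment."""
    return nitrogen15_table()


@pytest.fixture(scope="session")
def study_config(n15_table):
    """Assignment config of the chloramination study (compound-1 limits)."""
    return AssignmentConfig(table=n15_table)


@pytest.fixture(scope="session")
def small_synthetic(n15_table):
    """A small, fixed-seed synthetic experiment shared across tests."""
    from isoreact import simulate_peaklists, simulate_products

    cfg = SyntheticConfig(seed=42, steps=30, dropout=0.1)
    formulas, true_net, weights = simulate_products(cfg)
    peaklists, truth = simulate_peaklists(formulas, cfg)
    return cfg, formulas, true_net, weights, peaklists, truth


@pytest.fixture()
def salicylate():
    return parse_formula("C7H6O3")
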