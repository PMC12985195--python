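"""Shared fixtures: small synthetic cohorts and the planted-pair scenario."""

from __future__ import annotations

import numpy as np
import pytest

import mirpair as m

#: Scale factor giving a theoretical within-pair AUC of 0.95 at sigma=1:
#: Phi(d / sqrt(2 * (1 + 1))) = 0.95  =>  d = 2 * Phi^-1(0.95) ~= 3.29
PLANT_D = 3.2897072539029457


def planted_five_config(seed: int = 11, **overrides) -> tuple[m.SyntheticConfig, list[tuple[str, str]]]:
    """Default cohort with five disjoint planted pairs at theoretical AUC 0.95."""
    ids = sorted(m.load_default_panel().mirna_ids)
    planted, pairs = {}, []
    for i in range(5):
        a, b = ids[2 * i], ids[2 * i + 1]
        planted[a] = +PLANT_D / 2
        planted[b] = -PLANT_D / 2
        pairs.append((a, b))
    cfg = m.SyntheticConfig(seed=seed, planted=planted, **overrides)
    return cfg, pairs


@pytest.fixture(scope="session")
def default_panel() -> m.PanelDefinition:
    return m.load_default_panel()


@pytest.fixture(scope="session")
def null_cohort():
    """30+30 cohort, 48 assays, no planted effects."""
    ct, controls, truth = m.generate_cohort(m.SyntheticConfig(seed=29))
    return ct, controls, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """30+30 cohort with the five-planted-pair scenario (seed 11)."""
    cfg, pairs = planted_five_config(seed=11)
    ct, controls, truth = m.generate_cohort(cfg)
    return ct, controls, truth, pairs


@pytest.fixture(scope="session")
def planted_results(planted_cohort):
    """Full single-pair screen of the planted cohort (computed once)."""
    ct, _, truth, pairs = planted_cohort
    return m.evaluate_all_pairs(ct)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
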