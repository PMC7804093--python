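"""Shared fixtures and simulation scenarios for the test suite.

The scenario builders define the study conditions used by the statistical
behaviour tests (family selection, parameter recovery, selection-rule
calibration); each takes a replicate seed so tests control their own
replication.
"""

import numpy as np
import pytest

from larvaldelta import load_table1_fixture, load_table2_fixture, paper_like_scenario
from larvaldelta.synthetic import SimConfig

ALL_SPECIES = ("Ac", "Gm", "Hc", "Msp", "Oj")


def gamma_positives_config(seed: int) -> SimConfig:
    """Delta data with gamma positives (shape 2), ~200 positive cells.

    400 cells (2 areas × 2 seasons × 20 surveys × 5 species) with presence
    probability ≈ 0.5, so each replicate carries ≈ 195 positive
    observations; positive means ≈ e^3 keep the integer rounding of the
    continuous gamma draws mild.
    """
    return SimConfig(
        n_surveys_per_stratum=20,
        abundance_median={s: 300.0 for s in ALL_SPECIES},
        abundance_sigma=0.8,
        presence_intercept=0.0,
        presence_abundance_slope=0.0,
        presence_species={"Gm": 0.4, "Hc": 0.6},
        presence_season={"spring_summer": -0.5},
        positive_intercept=3.0,
        positive_species={"Hc": 0.5, "Gm": 0.3},
        positive_season={"spring_summer": -0.4},
        gamma_shape=2.0,
        seed=seed,
    )


def poisson_counts_config(seed: int) -> SimConfig:
    """Same design as :func:`gamma_positives_config` with Poisson positives
    of mean 3 (the low-count regime typical of parasitized-larva cells)."""
    return SimConfig(
        n_surveys_per_stratum=20,
        abundance_median={s: 300.0 for s in ALL_SPECIES},
        abundance_sigma=0.8,
        presence_intercept=0.0,
        presence_abundance_slope=0.0,
        presence_species={"Gm": 0.4, "Hc": 0.6},
        presence_season={"spring_summer": -0.5},
        positive_family="poisson_log",
        positive_intercept=float(np.log(3.0)),
        seed=seed,
    )


def recovery_config(seed: int) -> SimConfig:
    """Parameter-recovery conditions: 50 surveys per stratum (1000 cells),
    abundant cells (medians 600–1500 larvae) so the n_collected cap on
    positive draws essentially never binds, and positive means ≈ e^3 so the
    ceil-to-integer bias on the log scale stays below ~0.03."""
    return SimConfig(
        n_surveys_per_stratum=50,
        abundance_median={"Ac": 1200.0, "Gm": 800.0, "Hc": 1500.0, "Msp": 600.0, "Oj": 600.0},
        abundance_sigma=0.6,
        presence_intercept=-3.0,
        presence_abundance_slope=0.35,
        presence_species={"Gm": 0.7, "Hc": 0.5, "Msp": -0.3, "Oj": -0.2},
        presence_season={"spring_summer": -0.6},
        presence_area={"ISM": 0.4},
        positive_intercept=3.0,
        positive_species={"Gm": 0.3, "Hc": 0.6, "Msp": -0.2, "Oj": -0.1},
        positive_season={"spring_summer": -0.5},
        positive_area={"ISM": 0.3},
        gamma_shape=2.0,
        seed=seed,
    )


def null_effect_config(seed: int) -> SimConfig:
    """200 cells where abundance truly has no effect on either part."""
    return SimConfig(
        n_surveys_per_stratum=10,
        abundance_median={s: 300.0 for s in ALL_SPECIES},
        abundance_sigma=0.8,
        presence_intercept=0.0,
        presence_abundance_slope=0.0,
        positive_intercept=3.0,
        gamma_shape=2.0,
        seed=seed,
    )


def season_signal_config(seed: int) -> SimConfig:
    """200 cells with a pure season effect (both parts) and no abundance effect."""
    return SimConfig(
        n_surveys_per_stratum=10,
        abundance_median={s: 300.0 for s in ALL_SPECIES},
        abundance_sigma=0.8,
        presence_intercept=0.3,
        presence_season={"spring_summer": -1.0},
        presence_abundance_slope=0.0,
        positive_intercept=3.0,
        positive_season={"spring_summer": -0.6},
        gamma_shape=2.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def paper_like_dataset():
    from larvaldelta import generate_dataset

    return generate_dataset(paper_like_scenario(seed=7))
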