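"""Shared fixtures.

The session-scoped "battery" fixtures run the scaled study conditions
(N = 500 diploids on a 300 kb arm-center-arm chromosome with per-base
rates x10, 10N burn-in, 20 replicates per scenario; N = 300 for the
decay-of-diversity designs).  They are computed once per session and
shared by the calibration and landscape-contrast tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from nemascape import (
    DFEConfig,
    GenotypeMatrix,
    desk_scale_config,
    pi_window,
)
from nemascape.experiments import run_replicates

STUDY_SEED = 20250921  # fixed seed for the test-suite study conditions
N_REPS = 20
DESK_L = 300_000


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def four_hap_fixture() -> GenotypeMatrix:
    """2 diploids / 4 haplotypes, 2 segregating sites with derived counts
    (2, 1): the worked fixture behind several frozen statistic values."""
    haps = np.array(
        [
            [1, 1, 0, 0],
            [1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix.from_haplotypes(
        positions=np.array([100, 200]), haplotypes=haps, sequence_length=1000
    )


def _final_samples(results):
    return [r.final_sample for r in results]


@pytest.fixture(scope="session")
def eq_neutral_outcross():
    cfg = desk_scale_config()
    return _final_samples(run_replicates(cfg, N_REPS, STUDY_SEED, cell=1))


@pytest.fixture(scope="session")
def eq_neutral_selfing():
    cfg = desk_scale_config(selfing_rate=1.0)
    return _final_samples(run_replicates(cfg, N_REPS, STUDY_SEED, cell=2))


@pytest.fixture(scope="session")
def eq_neutral_partial():
    cfg = desk_scale_config(selfing_rate=0.9)
    return _final_samples(run_replicates(cfg, N_REPS, STUDY_SEED, cell=3))


@pytest.fixture(scope="session")
def eq_selection_outcross():
    """Outcrossing with the combined selection regime (neutral + 10%
    deleterious + 1% beneficial): the study's canonical non-neutral case."""
    cfg = desk_scale_config(dfe=DFEConfig.with_beneficial())
    return _final_samples(run_replicates(cfg, N_REPS, STUDY_SEED, cell=4))


@pytest.fixture(scope="session")
def eq_neutral_212_selfing():
    cfg = desk_scale_config(selfing_rate=1.0, mut_multipliers=(2.0, 1.0, 2.0))
    return _final_samples(run_replicates(cfg, N_REPS, STUDY_SEED, cell=5))


N_DECAY = 300  # decay designs run at a smaller desk scale (see docs)


@pytest.fixture(scope="session")
def decay_selection_switch():
    """Outcrossing burn-in with the combined selection regime, then 100%
    selfing; arm-window pi tracked to generation N post-switch."""
    from nemascape.experiments import decay_experiment

    base = desk_scale_config(
        N=N_DECAY, dfe=DFEConfig.with_beneficial(), sample_size=50
    )
    return decay_experiment(
        target_selfing=1.0,
        record_every=150,
        horizon=300,
        reps=N_REPS,
        base_config=base,
        base_seed=STUDY_SEED + 6,
    )


@pytest.fixture(scope="session")
def eq_selection_selfing_decay_scale():
    """Always-selfing equilibrium under the same selection regime: the
    reference level the switched populations decay towards."""
    cfg = desk_scale_config(
        N=N_DECAY, selfing_rate=1.0, dfe=DFEConfig.with_beneficial(), sample_size=50
    )
    return _final_samples(run_replicates(cfg, N_REPS, STUDY_SEED, cell=7))


@pytest.fixture(scope="session")
def decay_neutral_switch():
    """Neutral outcrossing burn-in, then 100% selfing: replicate variance
    of pi grows through the transient approach to the selfing equilibrium."""
    from nemascape.experiments import decay_experiment

    base = desk_scale_config(N=N_DECAY, sample_size=50)
    return decay_experiment(
        target_selfing=1.0,
        record_every=200,
        horizon=400,
        reps=N_REPS,
        base_config=base,
        base_seed=STUDY_SEED + 8,
    )


def domain_pi_per_site(gm: GenotypeMatrix, model) -> tuple[float, float]:
    """(arm, center) per-site nucleotide diversity of one sample."""
    b1, b2 = model.domain_edges
    L = model.length_bp
    pi_left = pi_window(gm, (0, b1))
    pi_center = pi_window(gm, (b1, b2))
    pi_right = pi_window(gm, (b2, L))
    arm = (pi_left + pi_right) / (b1 + (L - b2))
    center = pi_center / (b2 - b1)
    return arm, center
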