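"""Shared fixtures: one fully processed synthetic run reused across tests."""

import warnings

import pytest

from heterotherm import classifier as cls
from heterotherm import respirometry, simulate


def recover(run):
    """Raw trace → drift-corrected → MR → state segmentation."""
    corrected = respirometry.drift_correct(run.raw, fio2=run.config.fio2)
    mt = respirometry.compute_vo2(corrected, fio2=run.config.fio2, rq=run.config.rq)
    mt = respirometry.mass_specific_mr(mt, run.metadata.body_mass_g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = cls.segment_run(mt.data, run.resting_windows(), t_skin=run.tskin)
    return mt, seg


@pytest.fixture(scope="session")
def sim_run():
    return simulate.generate_run(simulate.SimConfig(profile="cave_dry", seed=7))


@pytest.fixture(scope="session")
def processed(sim_run):
    mt, seg = recover(sim_run)
    return sim_run, mt, seg
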