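"""Shared fixtures: one synthetic subject with cached calibrations."""

from __future__ import annotations

import dataclasses

import pytest

from insolegrf import io, pipeline, synthetic


@pytest.fixture(scope="session")
def config():
    return io.RunConfig()


@pytest.fixture(scope="session")
def subject():
    return synthetic.generate_subject("S01", 42)


@pytest.fixture(scope="session")
def subject_clean(subject):
    """Same subject with drift-free, noise-free sensors."""
    def clean(s):
        return dataclasses.replace(s, drift_rate=0.0, noise_sd=0.0)
    return dataclasses.replace(
        subject, hind_sensor=clean(subject.hind_sensor),
        fore_sensor=clean(subject.fore_sensor))


@pytest.fixture(scope="session")
def sensor_cals(subject, config):
    """Stage-one calibrations from noisy three-step trials."""
    return {
        region: pipeline.process_calibration_trial(
            synthetic.generate_calibration_trial(subject, region, seed=i + 2),
            config)
        for i, region in enumerate(("hind", "fore"))
    }


@pytest.fixture(scope="session")
def sensor_cals_clean(subject_clean, config):
    return {
        region: pipeline.process_calibration_trial(
            synthetic.generate_calibration_trial(subject_clean, region,
                                                 seed=i + 2, noise=False),
            config)
        for i, region in enumerate(("hind", "fore"))
    }


@pytest.fixture(scope="session")
def processed_trial(subject, sensor_cals, config):
    """One processed noisy walking trial with a 0.37 s clock offset."""
    trial = synthetic.generate_walking_trial(subject, 1.0, seed=5,
                                             clock_offset=0.37)
    return trial, pipeline.process_walking_trial(trial, sensor_cals, config)
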