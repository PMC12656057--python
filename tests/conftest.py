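"""Shared fixtures: small deterministic cohorts and segments.

The session-scoped 500-event cohort backs the separability and
end-to-end cross-validation checks; everything else uses small
purpose-built recordings.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ictalnet as ic

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def synth_config() -> ic.SynthConfig:
    return ic.SynthConfig(seed=7)


@pytest.fixture()
def background_recording(synth_config) -> ic.Recording:
    return ic.generate_background(synth_config, duration_s=10.0, seed=11)


@pytest.fixture()
def seizure_segment(synth_config) -> ic.Segment:
    """One preprocessed 10-s ABSZ window."""
    rec = ic.generate_seizure("ABSZ", synth_config, 10.0, seed=13)
    rec = ic.preprocess(rec)
    return ic.segment_events(rec)[0]


@pytest.fixture(scope="session")
def tiny_cohort() -> ic.SynthCohort:
    """Small balanced cohort for pipeline plumbing tests."""
    cfg = ic.SynthConfig(
        n_events=20, n_patients=6, seed=3,
        class_proportions=(0.2, 0.2, 0.2, 0.2, 0.2),
        duration_range=(3.0, 15.0),
    )
    return ic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort500():
    """500-event separable cohort, preprocessed, windowed and featurized.

    Equal class proportions so that every class reaches every fold of a
    5-fold patient-stratified split.  Shared across the separability and
    end-to-end tests; treat as read-only.
    """
    cfg = ic.SynthConfig(
        n_events=500, n_patients=25, seed=42,
        class_proportions=(0.2, 0.2, 0.2, 0.2, 0.2),
    )
    cohort = ic.generate_cohort(cfg)
    segments = []
    for rec in cohort.recordings:
        segments.extend(ic.segment_events(ic.preprocess(rec)))
    X = ic.FeatureExtractor().transform(segments)
    y = np.array([int(s.label) for s in segments])
    patients = np.array([s.patient_id for s in segments])
    return dict(segments=segments, X=X, y=y, patients=patients)
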