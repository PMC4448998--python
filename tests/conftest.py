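"""Shared fixtures: small noise-free synthetic recordings."""

import numpy as np
import pytest

import embryoquant as eq


@pytest.fixture(scope="session")
def toy_model():
    return eq.generate_reference_model(n_rounds=2, seed=1)


@pytest.fixture(scope="session")
def clean_recording(toy_model):
    """Noise-free recording of one expressing founder lineage, 20 stacks."""
    spec = eq.GroundTruthSpec(
        programs={"ABa": eq.ExpressionProgram.constant(50.0)},
        n_fluor_stacks=20,
    )
    camera = eq.CameraConfig(shot_noise=False, read_noise_sd=0.0)
    rec, truth = eq.generate_recording(toy_model, spec, camera=camera, seed=7)
    return rec, truth


@pytest.fixture(scope="session")
def normalized_series(clean_recording):
    rec, _ = clean_recording
    series = eq.reconstruct_series(rec)
    return eq.normalize_recording(series, rec.anchors)
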