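"""Shared fixtures: small rendered scenes, boxes and rotation samples.

Everything is generated programmatically and seeded; session scope keeps
the rendering cost paid once.
"""

from __future__ import annotations

import pytest

from torsionlab.preprocess import boxes_from_frames, make_rotation_samples
from torsionlab.synthetic import (SceneParams, WaveformParams,
                                  generate_waveform, render_eye_frame,
                                  render_sequence)


@pytest.fixture(scope="session")
def scene():
    return SceneParams(texture_seed=42)


@pytest.fixture(scope="session")
def noisy_scene():
    return SceneParams(texture_seed=42, noise_sd=2.0)


@pytest.fixture(scope="session")
def frame0(scene):
    img, mask, _ = render_eye_frame(scene, 0.0)
    return img, mask


@pytest.fixture(scope="session")
def small_box_set():
    """Iris boxes from a short canonical-pose sequence (two scenes)."""
    boxes = []
    for i in (7, 8):
        sc = SceneParams(texture_seed=i)
        wf = WaveformParams(label="normal", drift_amplitude=0.0,
                            noise_sd=0.05, duration=2.4)
        ser = generate_waveform(wf, seed=i)
        seq = render_sequence(ser, sc, frames_per_sample=1)
        boxes.extend(boxes_from_frames(seq.frames, seq.masks,
                                       strategy="oracle"))
    return boxes


@pytest.fixture(scope="session")
def rotation_samples(small_box_set):
    return make_rotation_samples(small_box_set, len(small_box_set) // 3,
                                 seed=3)
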