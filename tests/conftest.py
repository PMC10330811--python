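"""Shared fixtures.

The reference scene and the four tracker variants run once per session;
several tests (including the end-to-end and ablation checks) reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

import ceustrack as ct


@pytest.fixture(scope="session")
def default_scene_data():
    """The package's reference 200-frame scene (seed 0) with ground truth."""
    spec = ct.default_scene(seed=0)
    seq, gt = ct.render_video(spec)
    return spec, seq, gt


@pytest.fixture(scope="session")
def ablation_runs(default_scene_data):
    """Track the reference scene with all four module combinations."""
    _, seq, gt = default_scene_data
    configs = {
        "full": ct.TrackerConfig(),
        "tma": ct.TrackerConfig(use_template_update=False),
        "tu": ct.TrackerConfig(use_attention=False),
        "plain": ct.TrackerConfig(use_attention=False, use_template_update=False),
    }
    return {name: ct.run(seq, gt.boxes[0], cfg) for name, cfg in configs.items()}


@pytest.fixture(scope="session")
def static_scene_data():
    """A motionless scene: breathing and drift both zero."""
    spec = ct.SceneSpec(
        frame_shape=(96, 128),
        n_frames=30,
        breathing_amplitude=(0.0, 0.0),
        drift_velocity=(0.0, 0.0),
        seed=11,
    )
    seq, gt = ct.render_video(spec)
    return spec, seq, gt


def textured_frame(shape=(96, 128), seed=0, sigma=2.0):
    """Smooth random texture in [0.2, 0.8] — well-conditioned for LK flow."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    return 0.2 + 0.6 * raw


def shifted(frame, dx, dy):
    """Subpixel translation by cubic interpolation (content moves by +dx,+dy)."""
    from scipy import ndimage

    return ndimage.shift(frame, (dy, dx), order=3, mode="nearest")
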