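"""Shared fixtures: synthetic sequences are expensive, so the shipped
default-noise benchmark sequences are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from tubesteer.synthetic import (
    Scene,
    SequenceScenario,
    TubeState,
    VirtualTubeParams,
    generate_sequence,
)

FLUOR_SEED = 11
BRIGHT_SEED = 5


def _tube_scene(modality: str, direction_deg: float = 10.0) -> Scene:
    kwargs = {"modality": modality}
    if modality == "brightfield":
        kwargs["gaussian_noise_sd"] = 1.5
        direction_deg = 0.0
    return Scene(tube=TubeState(anchor=(0.0, 250.0), tip=(200.0, 250.0),
                                direction_deg=direction_deg), **kwargs)


@pytest.fixture(scope="session")
def fluor_sequence():
    """50 default-noise fluorescence frames of a slowly growing tube."""
    scenario = SequenceScenario(
        scene=_tube_scene("fluorescence"), n_frames=50, grow_tube=True,
        tube_params=VirtualTubeParams(growth_rate_um_min=60.0))
    return generate_sequence(scenario, seed=FLUOR_SEED)


@pytest.fixture(scope="session")
def bright_sequence_slow():
    """50 brightfield frames at the default (slow) growth rate."""
    scenario = SequenceScenario(
        scene=_tube_scene("brightfield"), n_frames=50, grow_tube=True,
        tube_params=VirtualTubeParams(growth_rate_um_min=12.0))
    return generate_sequence(scenario, seed=BRIGHT_SEED)


@pytest.fixture(scope="session")
def bright_sequence_fast():
    """30 brightfield frames at fast growth (~4 px/frame tip advance)."""
    scenario = SequenceScenario(
        scene=_tube_scene("brightfield"), n_frames=30, grow_tube=True,
        tube_params=VirtualTubeParams(growth_rate_um_min=160.0))
    return generate_sequence(scenario, seed=BRIGHT_SEED)


def track_fluorescence(frames, truth):
    """Run the fluorescence tip tracker over a sequence."""
    from tubesteer.tracking_fluor import ROI, FluorescenceTipTracker

    tip0 = tuple(truth.tip_px()[0])
    tracker = FluorescenceTipTracker(ROI(tip0, 40))
    return [tracker.track(f) for f in frames]


def tracking_errors(dets, truth):
    """(tip error px, direction error deg) over valid detections."""
    pos = np.array([d.position for d in dets])
    valid = np.array([d.valid for d in dets])
    dirs = np.array([d.direction_deg for d in dets])
    tip_err = np.linalg.norm(pos[valid] - truth.tip_px()[valid], axis=1)
    dd = (dirs[valid] - truth.directions_deg()[valid] + 180) % 360 - 180
    return valid, tip_err, dd
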