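"""Shared fixtures: random gaze streams and small synthetic cohorts."""

import numpy as np
import pytest

from vrfix import GazeRecording


def random_stream(
    seed: int,
    n: int = 300,
    rate_hz: float = 45.0,
    step_deg: float = 1.0,
    gap_prob: float = 0.02,
) -> GazeRecording:
    """A pseudo-random gaze stream exercising every classifier rule.

    The gaze direction performs an angular random walk (exponential step
    sizes around ``step_deg``), occasionally holding still to create
    fixation-like runs; timestamps carry jitter plus occasional long gaps
    that trip the acquisition-frequency guard; the head drifts slowly.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz + rng.normal(0.0, 0.002, size=n - 1)
    dt = np.maximum(dt, 1e-3)
    gaps = rng.random(n - 1) < gap_prob
    dt[gaps] += rng.uniform(0.04, 0.2, size=int(gaps.sum()))
    t = np.concatenate([[0.0], np.cumsum(dt)])

    head = np.array([0.0, 1.6, 0.0]) + np.cumsum(
        rng.normal(0.0, 2e-4, size=(n, 3)), axis=0
    )
    # angular random walk of the gaze direction
    theta = np.zeros(n)
    phi = np.zeros(n)
    hold = rng.random(n) < 0.6  # hold still often enough to form fixations
    steps = np.radians(rng.exponential(step_deg, size=n))
    azim = rng.uniform(0.0, 2.0 * np.pi, size=n)
    theta[1:] = np.cumsum(np.where(hold, 0.0, steps * np.cos(azim))[1:])
    phi[1:] = np.cumsum(np.where(hold, 0.0, steps * np.sin(azim))[1:])
    dist = rng.uniform(2.0, 4.0, size=n)
    dirs = np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(phi), np.cos(theta) * np.cos(phi)],
        axis=1,
    )
    gaze = head + dist[:, None] * dirs
    return GazeRecording(
        subject_id=f"rand{seed}",
        t=t,
        gaze=gaze,
        head=head,
        left_blink=np.zeros(n),
        right_blink=np.zeros(n),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Ten preprocessed subjects under the default simulation conditions."""
    from vrfix import remove_blinks, simulate_cohort, trim_to_protocol

    sessions = simulate_cohort(10, seed=101)
    events = sessions[0].events
    regions = sessions[0].protocol.regions
    recordings = []
    for sess in sessions:
        rec, _ = remove_blinks(sess.recording)
        recordings.append(trim_to_protocol(rec, events))
    return sessions, recordings, events, regions
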