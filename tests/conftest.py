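"""Shared fixtures: the standard synthetic acquisitions and their pipeline runs.

Session-scoped so the end-to-end simulations are rendered and analyzed once
and reused by the module tests and the acceptance tests.
"""

import warnings
from collections import Counter

import numpy as np
import pytest

from lnulm.pipeline import PipelineConfig, run_pipeline
from lnulm.synthetic import default_fixture


@pytest.fixture(scope="session")
def fx40():
    """Default noiseless fixture: 200 frames, 128x128, 40 bubbles, seed 42."""
    return default_fixture(seed=42)


@pytest.fixture(scope="session")
def fx80():
    """Denser fixture (80 bubbles) used for subtype threshold/label checks."""
    return default_fixture(seed=42, n_bubbles=80)


@pytest.fixture(scope="session")
def fx80_noisy():
    """80-bubble fixture at 20 dB peak SNR (noise sd = peak amplitude / 10)."""
    return default_fixture(seed=42, n_bubbles=80, noise_sd=0.1)


def _run(fx, out_dir):
    cfg = PipelineConfig(out_dir=str(out_dir), seed=42, low_rank=2, save_intermediate=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            cfg,
            movie=fx["movie"],
            roi_vertices_um=fx["roi_vertices_um"],
            hilum_um=fx["hilum_um"],
        )


@pytest.fixture(scope="session")
def run40(fx40, tmp_path_factory):
    return _run(fx40, tmp_path_factory.mktemp("run40"))


@pytest.fixture(scope="session")
def run80(fx80, tmp_path_factory):
    return _run(fx80, tmp_path_factory.mktemp("run80"))


@pytest.fixture(scope="session")
def run80_noisy(fx80_noisy, tmp_path_factory):
    return _run(fx80_noisy, tmp_path_factory.mktemp("run80n"))


def match_to_truth(recovered_tracks, truth_tracks, gate_um=60.0):
    """Map each recovered track to the truth track it follows.

    Per recovered localization, vote for the nearest same-frame truth
    position within ``gate_um``; a track is assigned the truth id with the
    most votes, or None if no localization matched.
    """
    per_truth = {
        t.track_id: dict(zip(t.frames, map(tuple, t.positions_um))) for t in truth_tracks
    }
    assignment = {}
    for r in recovered_tracks:
        votes = Counter()
        for f, p in zip(r.frames, r.positions_um):
            best, bd = None, gate_um
            for t in truth_tracks:
                q = per_truth[t.track_id].get(int(f))
                if q is not None:
                    d = float(np.hypot(p[0] - q[0], p[1] - q[1]))
                    if d < bd:
                        bd, best = d, t.track_id
            if best is not None:
                votes[best] += 1
        assignment[r.track_id] = votes.most_common(1)[0][0] if votes else None
    return assignment


@pytest.fixture(scope="session")
def truth_matcher():
    return match_to_truth
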