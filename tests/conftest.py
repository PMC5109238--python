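"""Shared fixtures: generated movies and session-scoped trained classifiers."""

import numpy as np
import pandas as pd
import pytest

from mitoscreen.classify import train_phase_classifier, training_set_from_movie
from mitoscreen.synthetic import (
    CellScript,
    MovieSpec,
    division_schedule,
    gen_timelapse_movie,
)

#: noise level ~10% of the rendered nuclear signal amplitude
NOISY_SD = 16.0


def make_movie_spec(
    nebd_frame: int = 8,
    anaphase_frame: int = 16,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_cells: int = 3,
    frame_count: int = 30,
    frame_interval_min: float = 3.0,
    divides: bool = True,
) -> MovieSpec:
    sched = division_schedule(nebd_frame, anaphase_frame, frame_count)
    return MovieSpec(
        frame_count=frame_count,
        frame_interval_min=frame_interval_min,
        cells=[
            CellScript(phase_schedule=list(sched), divides=divides)
            for _ in range(n_cells)
        ],
        image_size=(160, 160),
        noise_sd=noise_sd,
        seed=seed,
    )


def _train(noise_sd: float, seeds=(1, 2)):
    xs, ys = [], []
    for s in seeds:
        stack, truth = gen_timelapse_movie(make_movie_spec(seed=s, noise_sd=noise_sd))
        x, y = training_set_from_movie(stack, truth)
        xs.append(x)
        ys.append(y)
    return train_phase_classifier(
        pd.concat(xs, ignore_index=True), np.concatenate(ys), seed=0
    )


@pytest.fixture(scope="session")
def classifier_clean():
    """Phase classifier trained on noise-free generator movies."""
    return _train(0.0)


@pytest.fixture(scope="session")
def classifier_noisy():
    """Phase classifier trained at the noisy imaging condition."""
    return _train(NOISY_SD)


@pytest.fixture()
def interphase_frame():
    """One noise-free frame with 5 well-separated interphase nuclei."""
    spec = MovieSpec(
        frame_count=1,
        frame_interval_min=3.0,
        cells=[
            CellScript(phase_schedule=[("interphase", 0, 1)], divides=False)
            for _ in range(5)
        ],
        image_size=(200, 200),
        seed=11,
    )
    stack, truth = gen_timelapse_movie(spec)
    return stack[0], truth
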