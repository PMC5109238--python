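"""Synthetic multi-plate mimic screens with planted hits.

Per-cell mitotic durations are drawn from a log-normal distribution (the
empirical duration histograms of live-cell screens are right-skewed)
whose median is ``baseline * hit multiplier * plate factor``.  Plate
factors emulate plate-wide temporal-sampling differences that the
plate-normalization step must remove; hits are planted as per-mimic
duration multipliers.  The well-to-mimic layout is identical across
replicates.
"""

from __future__ import annotations

import math

import numpy as np

from ..screen import Plate, ScreenDataset, Well

__all__ = ["gen_screen_plates", "mimic_name"]


def mimic_name(i: int) -> str:
    return f"mimic_{i + 1:03d}"


def gen_screen_plates(
    n_mimics: int = 135,
    cells_per_well: int = 80,
    replicates: int = 2,
    plate_sampling_factors: dict[str, float] | None = None,
    hits: dict[str, float] | None = None,
    baseline_duration_min: float = 22.0,
    sigma_log: float = 0.25,
    plate_capacity: int = 96,
    seed: int = 0,
) -> ScreenDataset:
    """Generate a replicated screen dataset.

    Parameters
    ----------
    plate_sampling_factors : dict, optional
        Plate id -> multiplicative duration factor (default 1.0 for every
        plate).  Plate ids are ``r<replicate>p<plate>`` with both indices
        1-based, e.g. ``r1p2``.
    hits : dict, optional
        Mimic id -> duration multiplier (> 0) for planted hits.
    """
    hits = hits or {}
    for m, mult in hits.items():
        if mult <= 0:
            raise ValueError(f"hit multiplier for {m} must be positive")
    factors = plate_sampling_factors or {}
    rng = np.random.default_rng(seed)
    n_plates = math.ceil(n_mimics / plate_capacity)
    plates = []
    for rep in range(1, replicates + 1):
        for p in range(n_plates):
            plate_id = f"r{rep}p{p + 1}"
            factor = factors.get(plate_id, 1.0)
            wells = []
            for slot, mi in enumerate(
                range(p * plate_capacity, min((p + 1) * plate_capacity, n_mimics))
            ):
                mimic = mimic_name(mi)
                median = baseline_duration_min * hits.get(mimic, 1.0) * factor
                durations = median * np.exp(
                    rng.normal(0.0, sigma_log, size=cells_per_well)
                )
                wells.append(Well(f"{plate_id}_w{slot + 1:02d}", mimic, durations))
            plates.append(Plate(plate_id, rep, wells))
    return ScreenDataset(plates=plates)
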