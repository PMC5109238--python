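"""Synthetic pulse-labeling counts from an asynchronous cycling population.

Cells are assigned uniform positions in a cycle of length ``Tc`` with a
single S-phase window of length ``Ts``; a cell is EdU-positive if in S at
the first pulse and BrdU-positive if in S at the second pulse ``Ti``
hours later.  Under this uniform-phase model the expected fractions are
``E[BrdU+]/n = Ts/Tc`` and ``E[EdU+BrdU-]/n = Ti/Tc``, which is what the
leaving-fraction estimators invert.
"""

from __future__ import annotations

import numpy as np

from ..kinetics import DualPulseCounts, ExitCounts

__all__ = ["gen_dual_pulse_counts", "gen_cycle_exit_counts"]


def gen_dual_pulse_counts(
    tc_hours: float,
    ts_hours: float,
    ti_hours: float,
    n_cells: int,
    seed: int = 0,
) -> DualPulseCounts:
    """Simulate one specimen's dual-pulse label-class counts.

    Requires ``0 < Ts < Tc`` and ``0 < Ti < Ts`` (the second pulse lands
    before any first-pulse S-phase cell could traverse all of S).
    """
    if not 0 < ts_hours < tc_hours:
        raise ValueError("need 0 < Ts < Tc")
    if not 0 < ti_hours < ts_hours:
        raise ValueError("need 0 < Ti < Ts")
    rng = np.random.default_rng(seed)
    # Cycle position at the first pulse; S phase occupies [0, Ts).
    x = rng.uniform(0.0, tc_hours, size=n_cells)
    edu = x < ts_hours
    x2 = (x + ti_hours) % tc_hours
    brdu = x2 < ts_hours
    return DualPulseCounts(
        n_edu_brdu_pos=int(np.sum(edu & brdu)),
        n_edu_pos_brdu_neg=int(np.sum(edu & ~brdu)),
        n_brdu_pos=int(np.sum(brdu)),
        n_proliferating=int(n_cells),
        ti_hours=ti_hours,
    )


def gen_cycle_exit_counts(
    exit_fraction: float, n_labeled: int, seed: int = 0
) -> ExitCounts:
    """Binomial draw of Ki67-negative cells among pulse-labeled cells."""
    if not 0.0 <= exit_fraction <= 1.0:
        raise ValueError("exit_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    exited = int(rng.binomial(n_labeled, exit_fraction))
    return ExitCounts(n_brdu_pos=n_labeled, n_brdu_pos_ki67_neg=exited)
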