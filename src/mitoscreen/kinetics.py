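"""Cell-cycle kinetics from pulse-labeling counts, plus tissue normalizations.

Dual-pulse labeling: an asynchronously cycling population receives a first
S-phase label (EdU), then a second one (BrdU) after an inter-pulse
interval ``Ti``.  Under a steady state with uniform cycle positions, the
fraction of cycling cells inside S phase at any instant is ``Ts/Tc`` and
the fraction that *leaves* S during the interval is ``Ti/Tc``, which gives
the classical leaving-fraction estimators

    Ts = Ti * n_BrdU+ / n_EdU+BrdU-
    Tc = Ti * n_proliferating / n_EdU+BrdU-

where ``n_BrdU+`` counts cells in S at the second pulse and
``n_EdU+BrdU-`` cells that were in S at the first pulse but had exited by
the second.  Cycle exit is scored separately as the fraction of
pulse-labeled cells that are no longer cycling (Ki67-negative) at
fixation.

Also included: the per-100-micrometre ventricular-surface cell-density
normalization used for layer-marker counts, and a simple region-of-interest
intensity ratio for immunofluorescence normalized against a reference
stain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import UndefinedRatioError, ValidationError

__all__ = [
    "DualPulseCounts",
    "ExitCounts",
    "DensityMeasure",
    "estimate_s_phase",
    "estimate_cycle",
    "bootstrap_dual_pulse",
    "cycle_exit_fraction",
    "density_per_surface",
    "roi_intensity_ratio",
]


@dataclass(frozen=True)
class DualPulseCounts:
    """Per-specimen dual-pulse labeling counts.

    Attributes
    ----------
    n_edu_brdu_pos : int
        Cells in S phase at both pulses (EdU+ BrdU+).
    n_edu_pos_brdu_neg : int
        Cells that left S phase during the inter-pulse interval.
    n_brdu_pos : int
        Cells in S phase at the second pulse (regardless of EdU).
    n_proliferating : int
        Marker-defined cycling cells (the Tc denominator); how the cycling
        population is gated is the caller's choice.
    ti_hours : float
        Inter-pulse interval.
    """

    n_edu_brdu_pos: int
    n_edu_pos_brdu_neg: int
    n_brdu_pos: int
    n_proliferating: int
    ti_hours: float

    def __post_init__(self) -> None:
        for name in ("n_edu_brdu_pos", "n_edu_pos_brdu_neg", "n_brdu_pos", "n_proliferating"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_brdu_pos > self.n_proliferating:
            raise ValidationError("n_brdu_pos cannot exceed n_proliferating")
        if self.ti_hours <= 0:
            raise ValidationError("ti_hours must be positive")


@dataclass(frozen=True)
class ExitCounts:
    """Cycle-exit scoring: label-positive cells split by Ki67 status."""

    n_brdu_pos: int
    n_brdu_pos_ki67_neg: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_brdu_pos_ki67_neg <= self.n_brdu_pos:
            raise ValidationError("need 0 <= n_brdu_pos_ki67_neg <= n_brdu_pos")


@dataclass(frozen=True)
class DensityMeasure:
    count: int
    surface_length_um: float
    density_per_100um: float
    relative_density: float | None = None


def estimate_s_phase(counts: DualPulseCounts) -> float:
    """S-phase duration Ts = Ti * n_BrdU+ / n_EdU+BrdU-, hours."""
    if counts.n_edu_pos_brdu_neg == 0:
        raise UndefinedRatioError(
            "no cells left S phase during the interval; Ts is undefined"
        )
    return counts.ti_hours * counts.n_brdu_pos / counts.n_edu_pos_brdu_neg


def estimate_cycle(counts: DualPulseCounts) -> float:
    """Total cycle duration Tc = Ti * n_proliferating / n_EdU+BrdU-, hours."""
    if counts.n_edu_pos_brdu_neg == 0:
        raise UndefinedRatioError(
            "no cells left S phase during the interval; Tc is undefined"
        )
    if counts.n_proliferating == 0:
        raise UndefinedRatioError("no proliferating cells; Tc is undefined")
    return counts.ti_hours * counts.n_proliferating / counts.n_edu_pos_brdu_neg


def bootstrap_dual_pulse(
    counts: DualPulseCounts,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Point estimates and percentile bootstrap CIs for (Ts, Tc).

    Cells are resampled by a multinomial draw over the four label classes
    (EdU+BrdU+, EdU+BrdU-, EdU-BrdU+, other cycling), preserving the
    specimen's total cycling-cell count.  Resamples with no leaving cells
    are redrawn implicitly by yielding infinite estimates that are dropped;
    their number is reported.
    """
    rng = np.random.default_rng(seed)
    a = counts.n_edu_brdu_pos
    b = counts.n_edu_pos_brdu_neg
    c = counts.n_brdu_pos - counts.n_edu_brdu_pos
    if c < 0:
        raise ValidationError("n_brdu_pos must include n_edu_brdu_pos")
    n = counts.n_proliferating
    d = n - a - b - c
    if d < 0:
        raise ValidationError("label-class counts exceed n_proliferating")
    probs = np.array([a, b, c, d], dtype=float) / n
    draws = rng.multinomial(n, probs, size=n_boot)
    with np.errstate(divide="ignore"):
        ts = counts.ti_hours * (draws[:, 0] + draws[:, 2]) / draws[:, 1]
        tc = counts.ti_hours * n / draws[:, 1]
    ok = np.isfinite(ts)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        "ts_hours": estimate_s_phase(counts),
        "tc_hours": estimate_cycle(counts),
        "ts_ci": tuple(np.percentile(ts[ok], [lo, hi])),
        "tc_ci": tuple(np.percentile(tc[ok], [lo, hi])),
        "n_boot": int(n_boot),
        "n_degenerate_resamples": int((~ok).sum()),
    }


def cycle_exit_fraction(
    counts: ExitCounts, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Fraction of labeled cells that exited the cycle, with Wilson CI."""
    if counts.n_brdu_pos == 0:
        raise UndefinedRatioError("no labeled cells; exit fraction undefined")
    p = counts.n_brdu_pos_ki67_neg / counts.n_brdu_pos
    lo, hi = proportion_confint(
        counts.n_brdu_pos_ki67_neg, counts.n_brdu_pos, alpha=alpha, method="wilson"
    )
    # guard against float round-off at the k=0 / k=n boundaries
    return p, (float(min(lo, p)), float(max(hi, p)))


def density_per_surface(
    count: int, surface_length_um: float, control_mean: float | None = None
) -> DensityMeasure:
    """Marker-positive cells per 100 um of ventricular surface.

    ``control_mean`` (same units, cells per 100 um) yields the relative
    density, i.e. fold of the control-group average.
    """
    if surface_length_um <= 0:
        raise UndefinedRatioError("surface length must be positive")
    density = count * 100.0 / surface_length_um
    rel = density / control_mean if control_mean else None
    return DensityMeasure(
        count=count,
        surface_length_um=surface_length_um,
        density_per_100um=density,
        relative_density=rel,
    )


def roi_intensity_ratio(signal_mean: float, reference_mean: float) -> float:
    """Mean signal intensity normalized by a reference stain's mean."""
    if reference_mean <= 0:
        raise UndefinedRatioError("reference mean must be positive")
    return signal_mean / reference_mean
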