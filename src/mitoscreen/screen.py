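"""Screen statistics: plate normalization, per-mimic z-scores, group tests.

A high-content screen distributes a library of perturbations (here miRNA
mimics) across multi-well plates, imaging each well and measuring a
per-cell mitotic duration.  Plates are imaged at slightly different
temporal sampling rates, inflating or deflating apparent durations by a
plate-wide factor; durations are therefore rescaled per plate to a common
location before scoring.  Each mimic is summarised per replicate by the
mean duration of its well(s), standardised against all mimics of that
replicate (z-score), averaged across replicates and ranked.

Group comparisons follow the reporting conventions of classical
cell-biology statistics: a Kolmogorov-Smirnov normality check and an F
variance check decide between Student's and Welch's two-tailed t-test,
with Bonferroni correction across pairs in multi-group designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "Well",
    "Plate",
    "ScreenDataset",
    "ComparisonReport",
    "normalize_plate",
    "zscore_mimics",
    "compare_groups",
    "compare_groups_pairwise",
]


@dataclass
class Well:
    well_id: str
    mimic_id: str
    durations_min: np.ndarray

    def __post_init__(self) -> None:
        self.durations_min = np.asarray(self.durations_min, dtype=float)
        if np.any(self.durations_min <= 0):
            raise ValidationError(f"well {self.well_id}: durations must be positive")


@dataclass
class Plate:
    plate_id: str
    replicate: int
    wells: list[Well]

    def all_durations(self) -> np.ndarray:
        if not self.wells:
            return np.empty(0)
        return np.concatenate([w.durations_min for w in self.wells])


@dataclass
class ScreenDataset:
    """Per-plate, per-well mitotic duration samples for a mimic library."""

    plates: list[Plate]

    def all_durations(self) -> np.ndarray:
        return np.concatenate([p.all_durations() for p in self.plates])

    def replicates(self) -> list[int]:
        return sorted({p.replicate for p in self.plates})

    def mimics(self) -> list[str]:
        return sorted({w.mimic_id for p in self.plates for w in p.wells})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plates:
            for w in p.wells:
                for d in w.durations_min:
                    rows.append((p.plate_id, p.replicate, w.well_id, w.mimic_id, d))
        return pd.DataFrame(
            rows, columns=["plate", "replicate", "well", "mimic", "duration_min"]
        )


def _location(x: np.ndarray, method: str) -> float:
    if method == "median-scale":
        return float(np.median(x))
    if method == "mean-scale":
        return float(np.mean(x))
    raise ValueError("method must be 'median-scale' or 'mean-scale'")


def normalize_plate(dataset: ScreenDataset, method: str = "median-scale") -> ScreenDataset:
    """Rescale each plate's durations to the global location.

    Every duration on a plate is divided by the plate's location statistic
    (median by default, robust to the right-skewed duration distribution)
    and multiplied by the same statistic over the whole dataset, removing
    plate-wide temporal-sampling factors while preserving within-plate
    ordering.
    """
    for p in dataset.plates:
        if p.all_durations().size == 0:
            raise ValidationError(f"plate {p.plate_id} is empty; cannot normalize")
    global_stat = _location(dataset.all_durations(), method)
    new_plates = []
    for p in dataset.plates:
        scale = global_stat / _location(p.all_durations(), method)
        wells = [
            Well(w.well_id, w.mimic_id, w.durations_min * scale) for w in p.wells
        ]
        new_plates.append(Plate(p.plate_id, p.replicate, wells))
    return ScreenDataset(plates=new_plates)


def zscore_mimics(dataset: ScreenDataset, per_cell: bool = False) -> pd.DataFrame:
    """Standardise per-mimic mitotic durations and rank mimics.

    Within each replicate, every mimic is summarised by the mean duration
    over its well(s) (or scored against the pooled per-cell values when
    ``per_cell`` is set) and standardised by the mean and standard
    deviation of all such data points of the replicate; replicate z-scores
    are then averaged per mimic and mimics ranked by mean z, descending
    (rank 1 = strongest mitotic delay).

    Returns a DataFrame indexed by mimic with columns ``z_rep<r>`` per
    replicate, ``mean_z`` and ``rank``.
    """
    mimics = dataset.mimics()
    if len(mimics) < 2:
        raise ValidationError("need at least 2 mimics to z-score")
    zcols = {}
    for rep in dataset.replicates():
        per_mimic: dict[str, list[np.ndarray]] = {}
        for p in dataset.plates:
            if p.replicate != rep:
                continue
            for w in p.wells:
                per_mimic.setdefault(w.mimic_id, []).append(w.durations_min)
        stats_ = {m: np.concatenate(v) for m, v in per_mimic.items()}
        # population sd of all data points of the replicate
        if per_cell:
            pooled = np.concatenate(list(stats_.values()))
            mu, sd = float(pooled.mean()), float(pooled.std(ddof=0))
            if sd == 0:
                raise DegenerateDataError("zero global sd; cannot z-score")
            z = {m: float((v.mean() - mu) / sd) for m, v in stats_.items()}
        else:
            means = pd.Series({m: float(v.mean()) for m, v in stats_.items()})
            sd = float(means.std(ddof=0))
            if sd == 0:
                raise DegenerateDataError("zero global sd; cannot z-score")
            z = ((means - means.mean()) / sd).to_dict()
        zcols[f"z_rep{rep}"] = pd.Series(z)
    table = pd.DataFrame(zcols).reindex(mimics)
    table["mean_z"] = table[[c for c in table.columns]].mean(axis=1)
    table["rank"] = table["mean_z"].rank(ascending=False, method="first").astype(int)
    table.index.name = "mimic"
    return table.sort_values("rank")


@dataclass
class ComparisonReport:
    """Two-sample comparison with the checks that motivated the test choice."""

    test_name: str
    labels: tuple[str, str]
    n: tuple[int, int]
    mean_diff: float
    ks_pvalues: tuple[float, float]
    normal: bool
    f_pvalue: float
    equal_variance: bool
    p_value: float
    adjusted_p: float
    alpha: float
    m_comparisons: int | None = None
    decisions: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.adjusted_p < self.alpha

    def to_text(self) -> str:
        lines = [
            f"compare {self.labels[0]} (n={self.n[0]}) vs {self.labels[1]} (n={self.n[1]})",
            f"  mean difference: {self.mean_diff:.4g}",
            f"  KS normality p: {self.ks_pvalues[0]:.3g}, {self.ks_pvalues[1]:.3g}"
            f" -> {'normal' if self.normal else 'non-normal'}",
            f"  F-test p: {self.f_pvalue:.3g}"
            f" -> {'equal' if self.equal_variance else 'unequal'} variance",
            f"  test: {self.test_name}, p = {self.p_value:.4g}"
            + (
                f", Bonferroni (m={self.m_comparisons}) adjusted p = {self.adjusted_p:.4g}"
                if self.m_comparisons
                else ""
            ),
            f"  significant at alpha={self.alpha}: {self.significant}",
        ]
        return "\n".join(lines)


def _ks_normal_p(x: np.ndarray) -> float:
    # KS against a normal with estimated parameters; the estimation makes
    # the nominal p conservative (documented caveat).
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        return 0.0
    return float(stats.kstest(x, "norm", args=(mu, sd)).pvalue)


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = stats.f.sf(f, len(a) - 1, len(b) - 1)
    return float(2 * min(p, 1 - p))


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    m_comparisons: int | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonReport:
    """Two-tailed two-sample comparison with recorded test selection.

    Runs a Kolmogorov-Smirnov normality check on each sample and an F-test
    for variance equality, then applies Student's t-test when both samples
    look normal with equal variances and Welch's t-test otherwise (Welch is
    also the fallback for non-normal samples, being the more conservative
    choice).  ``m_comparisons`` applies a Bonferroni correction
    ``p_adj = min(1, m * p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 observations")
    decisions: list[str] = []
    ks_a, ks_b = _ks_normal_p(a), _ks_normal_p(b)
    normal = ks_a > alpha and ks_b > alpha
    decisions.append(f"KS normality: p=({ks_a:.3g},{ks_b:.3g}), normal={normal}")
    f_p = _f_test_p(a, b)
    equal_var = f_p > alpha
    decisions.append(f"F-test: p={f_p:.3g}, equal_variance={equal_var}")
    if normal and equal_var:
        test_name = "Student t"
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    else:
        test_name = "Welch t"
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    decisions.append(f"selected {test_name}")
    adjusted = min(1.0, m_comparisons * p) if m_comparisons else p
    return ComparisonReport(
        test_name=test_name,
        labels=labels,
        n=(len(a), len(b)),
        mean_diff=float(np.mean(a) - np.mean(b)),
        ks_pvalues=(ks_a, ks_b),
        normal=normal,
        f_pvalue=f_p,
        equal_variance=equal_var,
        p_value=p,
        adjusted_p=adjusted,
        alpha=alpha,
        m_comparisons=m_comparisons,
        decisions=decisions,
    )


def compare_groups_pairwise(
    samples: dict[str, Sequence[float]], alpha: float = 0.05
) -> list[ComparisonReport]:
    """All pairwise comparisons with Bonferroni correction across pairs."""
    names = sorted(samples)
    pairs = [(x, y) for i, x in enumerate(names) for y in names[i + 1 :]]
    m = len(pairs)
    return [
        compare_groups(samples[x], samples[y], alpha=alpha, m_comparisons=m, labels=(x, y))
        for x, y in pairs
    ]
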