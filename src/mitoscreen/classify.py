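"""Per-object feature extraction and SVM mitotic-phase classification.

Each segmented object is described by a fixed-length, ordered vector of
shape descriptors (area, eccentricity, solidity, perimeter-squared over
area), chromatin intensity and texture summaries (mean, spread, maximum,
gradient statistics) and the nuclear/cytoplasmic reporter ratio.  A
support vector machine with a radial-basis kernel and probability
estimates maps feature vectors to the six mitotic phases; the trained
model is stored together with its feature ordering and training seed so a
saved classifier can never be applied to differently ordered features.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from skimage import measure
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import TrainingError
from .segmentation import LabeledFrame, compute_ibb_ratio

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "PhaseClassifier",
    "train_phase_classifier",
    "training_set_from_movie",
]

#: Fixed feature ordering; recorded with every trained classifier.
FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "eccentricity",
    "solidity",
    "perimeter2_over_area",
    "chromatin_mean",
    "chromatin_sd",
    "chromatin_max",
    "gradient_mean",
    "gradient_sd",
    "ibb_ratio",
)


def extract_features(frame: LabeledFrame) -> pd.DataFrame:
    """Feature vectors for every object of a frame.

    Requires cytoplasmic rings (``grow_cytoplasm``) so the reporter ratio
    is defined.  Returns a DataFrame indexed by object label with
    ``FEATURE_NAMES`` columns; the ratio is also written back onto each
    :class:`~mitoscreen.segmentation.SegmentedObject`.
    """
    chrom = frame.image[0]
    gy, gx = np.gradient(chrom)
    grad = np.hypot(gy, gx)
    rows = {}
    props = {
        p.label: p for p in measure.regionprops(frame.labels, intensity_image=chrom)
    }
    for lab, obj in sorted(frame.objects.items()):
        p = props[lab]
        m = frame.labels == lab
        vals = chrom[m]
        ratio = compute_ibb_ratio(obj.mean_reporter_nuclear, obj.mean_reporter_ring)
        obj.ibb_ratio = ratio
        rows[lab] = (
            float(p.area),
            float(p.eccentricity),
            float(p.solidity),
            float(p.perimeter**2 / p.area) if p.area > 0 else 0.0,
            float(vals.mean()),
            float(vals.std()),
            float(vals.max()),
            float(grad[m].mean()),
            float(grad[m].std()),
            ratio,
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))


@dataclass
class PhaseClassifier:
    """A trained phase classifier with its frozen feature ordering."""

    pipeline: Pipeline
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int

    def _matrix(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in features.columns]
            if missing:
                raise ValueError(f"features missing columns {missing}")
            return features[list(self.feature_names)].to_numpy(dtype=float)
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {x.shape[1]}"
            )
        return x

    def predict(self, features) -> np.ndarray:
        return self.pipeline.predict(self._matrix(features))

    def predict_proba(self, features) -> pd.DataFrame:
        """Class probability vectors (rows sum to 1)."""
        proba = self.pipeline.predict_proba(self._matrix(features))
        index = features.index if isinstance(features, pd.DataFrame) else None
        return pd.DataFrame(proba, columns=list(self.classes), index=index)

    def save(self, path) -> None:
        joblib.dump(
            {
                "pipeline": self.pipeline,
                "feature_names": self.feature_names,
                "classes": self.classes,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PhaseClassifier":
        blob = joblib.load(path)
        return cls(
            pipeline=blob["pipeline"],
            feature_names=tuple(blob["feature_names"]),
            classes=tuple(blob["classes"]),
            seed=int(blob["seed"]),
        )


def train_phase_classifier(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    c: float = 10.0,
    gamma: str | float = "scale",
) -> PhaseClassifier:
    """Train the radial-kernel SVM phase classifier.

    Requires at least two classes and at least 5 annotated examples per
    class; training is deterministic given ``seed``.
    """
    y = np.asarray(labels)
    counts = Counter(y)
    if len(counts) < 2:
        raise TrainingError("need at least 2 classes to train")
    scarce = sorted(cls for cls, n in counts.items() if n < 5)
    if scarce:
        raise TrainingError(
            f"need >= 5 examples per class; too few for: {', '.join(scarce)}"
        )
    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=c,
                    gamma=gamma,
                    probability=True,
                    random_state=seed,
                ),
            ),
        ]
    )
    if isinstance(features, pd.DataFrame):
        if set(FEATURE_NAMES) <= set(features.columns):
            names = tuple(FEATURE_NAMES)
        else:
            names = tuple(features.columns)
        x = features[list(names)].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = tuple(f"f{i}" for i in range(x.shape[1]))
    pipeline.fit(x, y)
    return PhaseClassifier(
        pipeline=pipeline,
        feature_names=names,
        classes=tuple(pipeline.classes_),
        seed=seed,
    )


def training_set_from_movie(
    stack: np.ndarray,
    truth,
    window: int = 33,
    offset: float = -20.0,
    min_area: int = 20,
    ring_width: int = 3,
    match_radius_px: float = 6.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build an annotated training set from a movie with known truth.

    Segments every frame, matches each object to the nearest ground-truth
    centroid within ``match_radius_px`` and labels it with that cell's
    scripted phase — the synthetic stand-in for manual phase annotation.

    Parameters
    ----------
    truth : mitoscreen.synthetic.GroundTruth
        The generator's truth channel for ``stack``.
    """
    from .segmentation import grow_cytoplasm, segment_frame  # cycle-free

    feats, labels = [], []
    for f in range(stack.shape[0]):
        lf = segment_frame(
            stack[f], frame_index=f, window=window, offset=offset, min_area=min_area
        )
        if not lf.objects:
            continue
        lf = grow_cytoplasm(lf, ring_width=ring_width)
        table = extract_features(lf)
        cells = [
            (np.asarray(c.centroids[f]), c.phases[f])
            for c in truth.cells.values()
            if f in c.phases
        ]
        for lab in table.index:
            pos = np.asarray(lf.objects[lab].centroid)
            if not cells:
                continue
            dists = [np.linalg.norm(pos - cpos) for cpos, _ in cells]
            k = int(np.argmin(dists))
            if dists[k] <= match_radius_px:
                feats.append(table.loc[lab])
                labels.append(cells[k][1])
    if not feats:
        raise TrainingError("no segmented object matched a ground-truth cell")
    return pd.DataFrame(feats).reset_index(drop=True), np.asarray(labels)
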