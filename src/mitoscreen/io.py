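"""Readers and writers for the package's on-disk formats.

Image stacks are multi-page TIFF with axes ``TCYX`` (frame-major,
channel-interleaved) recorded in the file metadata.  Tables are plain
UTF-8 comma-separated files whose first line is a versioned schema
comment (``# mitoscreen-table v1 <schema>``); every table the package
writes is readable by its own reader (closed round-trip).  Annotation
coordinates are micrometres; image-table coordinates are 0-based pixel
indices.  Generation and run parameters are echoed to JSON sidecars.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError
from .geometry import AnaphaseAnnotation
from .kinetics import DualPulseCounts
from .screen import Plate, ScreenDataset, Well

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_table",
    "read_table",
    "write_annotations",
    "read_annotations",
    "write_screen",
    "read_screen",
    "write_dual_pulse_counts",
    "read_dual_pulse_counts",
    "write_params_json",
]

TABLE_MAGIC = "# mitoscreen-table v1"


# ---------------------------------------------------------------- image stacks

def write_image_stack(path, stack: np.ndarray, metadata: dict | None = None) -> None:
    """Write a (frames, 2, H, W) stack as multi-page TIFF (axes TCYX)."""
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise FormatError(f"expected (frames, 2, H, W), got {stack.shape}")
    meta = {"axes": "TCYX"}
    if metadata:
        meta.update(metadata)
    tifffile.imwrite(path, stack.astype(np.float32), metadata=meta)


def read_image_stack(path) -> tuple[np.ndarray, dict]:
    """Read a stack written by :func:`write_image_stack`.

    Returns ``(stack, metadata)`` with ``stack`` of shape
    (frames, 2, H, W).  Raises :class:`FormatError` for single-channel or
    corrupt files, naming the failing page where the reader reports one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            stack = series.asarray()
            meta = dict(tif.shaped_metadata[0]) if tif.shaped_metadata else {}
    except FormatError:
        raise
    except Exception as exc:  # corrupt / truncated
        raise FormatError(f"cannot read TIFF {path.name}: {exc}") from exc
    if stack.ndim == 3 and axes in ("QYX", "TYX", "ZYX", "IYX"):
        raise FormatError(
            f"{path.name}: single-channel stack; the timing pipeline needs "
            "2 channels (chromatin + reporter)"
        )
    if stack.ndim == 2:
        raise FormatError(f"{path.name}: single page; expected a 2-channel movie")
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise FormatError(
            f"{path.name}: expected (frames, 2, H, W), got shape {stack.shape}"
        )
    return stack, meta


# --------------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path, schema: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{TABLE_MAGIC} {schema}\n")
        df.to_csv(fh, index=False)


def read_table(path, expect_schema: str | None = None) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(TABLE_MAGIC):
            raise FormatError(f"{path.name}: missing '{TABLE_MAGIC}' header line")
        schema = header[len(TABLE_MAGIC) :].strip()
        if expect_schema is not None and schema != expect_schema:
            raise FormatError(
                f"{path.name}: schema '{schema}', expected '{expect_schema}'"
            )
        return pd.read_csv(fh)


# ---------------------------------------------------------------- annotations

ANNOTATION_SCHEMA = "annotations"
_ANNOTATION_COLS = ["cell_id", "group", "point_type", "x_um", "y_um", "z_um"]


def write_annotations(annotations: list[AnaphaseAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        for pt in (ann.centrosome_1, ann.centrosome_2):
            rows.append((ann.cell_id, ann.group, "centrosome", *pt))
        for pt in ann.surface_points:
            rows.append((ann.cell_id, ann.group, "surface", *pt))
    write_table(pd.DataFrame(rows, columns=_ANNOTATION_COLS), path, ANNOTATION_SCHEMA)


def read_annotations(path) -> list[AnaphaseAnnotation]:
    """Read and validate an annotation table.

    Every cell needs exactly 2 centrosome rows and at least 3 surface
    rows; offending cells are reported together.  A missing ``group``
    column defaults to a single group with a warning; non-numeric
    coordinates raise a parse error naming the row.
    """
    df = read_table(path, expect_schema=ANNOTATION_SCHEMA)
    required = {"cell_id", "point_type", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
    if "group" not in df.columns:
        warnings.warn("no 'group' column; assigning all cells to one group")
        df["group"] = "default"
    for col in ("x_um", "y_um", "z_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the schema line, one for the header row (1-based)
            raise ValidationError(
                f"non-numeric coordinate in column {col}, file row {bad[0] + 3}"
            )
        df[col] = coerced
    bad_cells = []
    annotations = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        cent = sub[sub.point_type == "centrosome"][["x_um", "y_um", "z_um"]].to_numpy()
        surf = sub[sub.point_type == "surface"][["x_um", "y_um", "z_um"]].to_numpy()
        if cent.shape[0] != 2 or surf.shape[0] < 3:
            bad_cells.append(str(cell_id))
            continue
        annotations.append(
            AnaphaseAnnotation(
                cell_id=str(cell_id),
                centrosome_1=cent[0],
                centrosome_2=cent[1],
                surface_points=surf,
                group=str(sub["group"].iloc[0]),
            )
        )
    if bad_cells:
        raise ValidationError(
            "cells must have exactly 2 centrosomes and >= 3 surface points; "
            f"invalid: {', '.join(bad_cells)}"
        )
    return annotations


# --------------------------------------------------------------------- screen

SCREEN_SCHEMA = "screen"


def write_screen(dataset: ScreenDataset, path) -> None:
    write_table(dataset.to_frame(), path, SCREEN_SCHEMA)


def read_screen(path) -> ScreenDataset:
    df = read_table(path, expect_schema=SCREEN_SCHEMA)
    plates = []
    for (plate_id, rep), sub in df.groupby(["plate", "replicate"], sort=True):
        wells = [
            Well(str(well_id), str(wsub["mimic"].iloc[0]), wsub["duration_min"].to_numpy())
            for well_id, wsub in sub.groupby("well", sort=True)
        ]
        plates.append(Plate(str(plate_id), int(rep), wells))
    return ScreenDataset(plates=plates)


# ------------------------------------------------------------------- kinetics

DUAL_PULSE_SCHEMA = "dual-pulse-counts"


def write_dual_pulse_counts(counts: dict[str, DualPulseCounts], path) -> None:
    rows = [
        {
            "specimen": name,
            "n_edu_brdu_pos": c.n_edu_brdu_pos,
            "n_edu_pos_brdu_neg": c.n_edu_pos_brdu_neg,
            "n_brdu_pos": c.n_brdu_pos,
            "n_proliferating": c.n_proliferating,
            "ti_hours": c.ti_hours,
        }
        for name, c in counts.items()
    ]
    write_table(pd.DataFrame(rows), path, DUAL_PULSE_SCHEMA)


def read_dual_pulse_counts(path) -> dict[str, DualPulseCounts]:
    df = read_table(path, expect_schema=DUAL_PULSE_SCHEMA)
    return {
        str(r.specimen): DualPulseCounts(
            n_edu_brdu_pos=int(r.n_edu_brdu_pos),
            n_edu_pos_brdu_neg=int(r.n_edu_pos_brdu_neg),
            n_brdu_pos=int(r.n_brdu_pos),
            n_proliferating=int(r.n_proliferating),
            ti_hours=float(r.ti_hours),
        )
        for r in df.itertuples()
    }


def write_params_json(params: dict, path) -> None:
    """Echo generation/run parameters to a JSON sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
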