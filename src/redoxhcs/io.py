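"""On-disk formats: multichannel TIFF fields, plate layouts, CSV tables.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``; row 0 is the image top.
* Fields are stored one single-plane grayscale TIFF per channel, named
  ``{well}_{field:02d}_{channel}.tif`` or, for time-lapse,
  ``{well}_{field:02d}_t{timepoint:03d}_{channel}.tif``.
  Channel identity comes from the file name, never from file order.
* Missing values in CSV are empty fields, never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import os
import re
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, ValidationError

CHANNEL_NAMES = ("ex405", "ex488", "nuclear", "tmrm")
REQUIRED_CHANNELS = ("ex405", "ex488")
LAYOUT_ROLES = ("negative_control", "positive_control", "treatment", "empty")

_FIELD_FILE_RE = re.compile(
    r"^(?P<well>[A-Za-z]+\d+)_(?P<field>\d+)(?:_t(?P<tp>\d+))?"
    r"_(?P<channel>ex405|ex488|nuclear|tmrm)\.tiff?$"
)


@dataclass
class FieldImage:
    """One acquired field: a named map channel -> 2-D intensity array.

    ``ex405`` and ``ex488`` are required; ``nuclear`` (H2B marker) and
    ``tmrm`` are optional. All channels must share one shape and be
    non-negative.
    """

    channels: dict[str, np.ndarray]
    well_id: str = "A01"
    field_index: int = 0
    timepoint_index: int = 0
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        for name in REQUIRED_CHANNELS:
            if name not in self.channels:
                raise ValidationError(
                    f"field {self.well_id}/{self.field_index}: missing required "
                    f"channel {name!r}"
                )
        shapes = {name: np.asarray(img).shape for name, img in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise FormatError(
                f"field {self.well_id}/{self.field_index}: channel shape mismatch "
                f"{shapes}"
            )
        for name, img in self.channels.items():
            arr = np.asarray(img)
            if arr.ndim != 2:
                raise FormatError(
                    f"field {self.well_id}/{self.field_index}: channel {name!r} "
                    f"is not a 2-D image"
                )
            if np.any(arr < 0):
                raise ValidationError(
                    f"field {self.well_id}/{self.field_index}: channel {name!r} "
                    f"has negative intensities"
                )
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class PlateLayout:
    """Well -> role/treatment map.

    Columns: ``well_id`` (unique), ``role`` (one of
    negative_control / positive_control / treatment / empty),
    ``treatment_label`` (free text), ``concentration`` (value+unit text).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("well_id", "role"):
            if col not in t.columns:
                raise FormatError(f"plate layout missing column {col!r}")
        for col in ("treatment_label", "concentration"):
            if col not in t.columns:
                t[col] = ""
        if t["well_id"].duplicated().any():
            dups = t.loc[t["well_id"].duplicated(), "well_id"].tolist()
            raise ValidationError(f"duplicate well ids in layout: {dups}")
        bad = set(t["role"]) - set(LAYOUT_ROLES)
        if bad:
            raise ValidationError(
                f"unknown roles {sorted(bad)}; expected one of {LAYOUT_ROLES}"
            )
        self.table = t.reset_index(drop=True)
        if not self.wells_with_role("negative_control"):
            warnings.warn(
                "plate layout has no negative_control wells; Z' and "
                "fold-change computations will fail",
                stacklevel=2,
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        return cls(pd.read_csv(path, dtype={"well_id": str}, keep_default_na=False))

    def to_csv(self, path: str | Path) -> None:
        _atomic_to_csv(self.table, path)

    def wells_with_role(self, role: str) -> list[str]:
        return self.table.loc[self.table["role"] == role, "well_id"].tolist()

    def role_of(self, well_id: str) -> str | None:
        hit = self.table.loc[self.table["well_id"] == well_id, "role"]
        return None if hit.empty else str(hit.iloc[0])

    @property
    def well_ids(self) -> list[str]:
        return self.table["well_id"].tolist()


def field_filename(
    well_id: str, field_index: int, channel: str, timepoint_index: int | None = None
) -> str:
    """Canonical file name for one channel of one field."""
    if channel not in CHANNEL_NAMES:
        raise ValidationError(f"unknown channel {channel!r}")
    stem = f"{well_id}_{field_index:02d}"
    if timepoint_index is not None:
        stem += f"_t{timepoint_index:03d}"
    return f"{stem}_{channel}.tif"


def write_field(
    fimg: FieldImage, out_dir: str | Path, with_timepoint: bool = False
) -> list[Path]:
    """Write one TIFF per channel; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    tp = fimg.timepoint_index if with_timepoint else None
    for name, img in fimg.channels.items():
        p = out_dir / field_filename(fimg.well_id, fimg.field_index, name, tp)
        tifffile.imwrite(p, np.asarray(img))
        paths.append(p)
    return paths


def read_plate(
    root_path: str | Path, layout: PlateLayout | None = None
) -> list[FieldImage]:
    """Read every field under ``root_path`` following the naming convention.

    A field is emitted for every (well, field, timepoint) that has both an
    ex405 and an ex488 file; the nuclear and tmrm channels are attached when
    present. A group with one roGFP channel but not the other is a
    :class:`FormatError`; layout wells with no images produce a warning.
    """
    root = Path(root_path)
    groups: dict[tuple[str, int, int], dict[str, Path]] = {}
    for p in sorted(root.glob("*.tif")) + sorted(root.glob("*.tiff")):
        m = _FIELD_FILE_RE.match(p.name)
        if m is None:
            continue
        key = (m["well"], int(m["field"]), int(m["tp"] or 0))
        groups.setdefault(key, {})[m["channel"]] = p

    fields = []
    for (well, fidx, tp), files in sorted(groups.items()):
        for req in REQUIRED_CHANNELS:
            if req not in files:
                raise FormatError(
                    f"field {well}/{fidx}/t{tp}: missing channel {req!r}"
                )
        channels = {name: tifffile.imread(files[name]) for name in sorted(files)}
        shapes = {name: img.shape for name, img in channels.items()}
        if len(set(shapes.values())) != 1:
            raise FormatError(
                f"field {well}/{fidx}/t{tp}: channel shape mismatch {shapes}"
            )
        fields.append(
            FieldImage(
                channels=channels, well_id=well, field_index=fidx, timepoint_index=tp
            )
        )

    if layout is not None:
        imaged = {f.well_id for f in fields}
        missing = [w for w in layout.well_ids if w not in imaged
                   and layout.role_of(w) != "empty"]
        if missing:
            warnings.warn(f"layout wells with no images: {missing}", stacklevel=2)
    return fields


def _atomic_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write CSV via a temp file + atomic rename so readers never see a
    partial table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_cell_table(records: Iterable, path: str | Path) -> None:
    """Write per-cell records (CellRecord dataclasses or a DataFrame) to CSV.

    Missing ratios (no valid pixels) become empty cells, not zeros.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [dataclasses.asdict(r) for r in records]
        if rows:
            df = pd.DataFrame(rows)
        else:
            from .quantify import CellRecord  # header-only table

            df = pd.DataFrame(
                columns=[f.name for f in dataclasses.fields(CellRecord)]
            )
    _atomic_to_csv(df, path)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_well_table(summaries: Iterable, path: str | Path) -> None:
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    _atomic_to_csv(df, path)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("label map has labels exceeding uint16 range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_ratio_image(ratio: np.ma.MaskedArray, path: str | Path) -> None:
    """32-bit float ratio TIFF plus a uint8 validity-mask sidecar."""
    path = Path(path)
    data = np.ma.filled(ratio.astype(np.float32), np.nan)
    tifffile.imwrite(path, data)
    mask_path = path.with_name(path.stem + "_mask.tif")
    tifffile.imwrite(mask_path, (~np.ma.getmaskarray(ratio)).astype(np.uint8))


def load_config_file(path: str | Path) -> Mapping:
    """Load a YAML (or JSON, a YAML subset) run-config mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"config file {path} does not contain a mapping")
    return data
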