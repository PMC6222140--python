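"""Per-pixel ratio images and per-cell / per-well feature tables.

The assay readout is the 405/488 excitation ratio of mt-roGFP: oxidation
raises the 405-excited emission and lowers the 488-excited one, so a rising
ratio reports mitochondrial oxidation. Because both channels share one
emission band, the ratio is invariant to overall gain — multiplying both
channels by any positive constant leaves every readout unchanged.

Per-cell ratio convention: the mean of per-pixel ratios over the ROI's
valid pixels (pixels whose ex488 clears the intensity floor). The
alternative — the ratio of ROI-mean intensities — is available via
``ratio_mode="roi_mean"`` and weights bright pixels more heavily.
Granularity is the coefficient of variation of ex488 pixel intensities
within the ROI, a scale-free texture statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, UndefinedCorrelationError, ValidationError
from .io import FieldImage, PlateLayout
from .segment import LabelMap, SegmentationParams, ring_rois, segment_intensity, \
    segment_nuclei, subtract_background

DEFAULT_INTENSITY_FLOOR = 9.0  # counts; 3x the default camera read-noise sd


@dataclass
class CellRecord:
    """One segmented cell's features. ``ratio`` is None when the ROI has no
    valid ratio pixels (missing, never zero)."""

    well_id: str
    field_index: int
    timepoint_index: int
    cell_label: int
    area_px: int
    mean_405: float
    mean_488: float
    mean_nuclear: float | None
    mean_tmrm: float | None
    granularity: float
    ratio: float | None
    n_valid_ratio_px: int


@dataclass
class WellSummary:
    """Per-well aggregate of cell records. Numeric summaries are None for
    empty wells; sd requires at least two cells."""

    well_id: str
    n_cells: int
    ratio_mean: float | None
    ratio_sd: float | None
    ratio_median: float | None
    tmrm_mean: float | None
    fraction_high_ratio: float | None


def ratio_image(
    ex405: np.ndarray,
    ex488: np.ndarray,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
) -> np.ma.MaskedArray:
    """Per-pixel 405/488 ratio; pixels with ex488 below the floor are masked.

    Inputs must be background-corrected and share one shape. The result
    never contains infinities: division only happens on valid pixels.
    """
    ex405 = np.asarray(ex405, dtype=float)
    ex488 = np.asarray(ex488, dtype=float)
    if ex405.shape != ex488.shape:
        raise ValidationError(
            f"channel shapes differ: {ex405.shape} vs {ex488.shape}"
        )
    invalid = ex488 < intensity_floor
    data = np.divide(ex405, ex488, out=np.zeros_like(ex405), where=~invalid)
    return np.ma.MaskedArray(data, mask=invalid)


def _roi_means(values: np.ndarray, labels: np.ndarray, n_labels: int) -> np.ndarray:
    sums = np.bincount(labels.ravel(), weights=values.ravel(), minlength=n_labels + 1)
    counts = np.bincount(labels.ravel(), minlength=n_labels + 1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def measure_rois(
    rois: LabelMap,
    field: FieldImage,
    ratio: np.ma.MaskedArray,
    ratio_mode: str = "pixel_mean",
) -> list[CellRecord]:
    """Per-ROI features over background-corrected channels.

    ``ratio_mode``: ``pixel_mean`` (default) averages per-pixel ratios over
    valid pixels; ``roi_mean`` divides the ROI-summed ex405 by ex488 over
    the same valid pixels.
    """
    if rois.kind not in ("cell", "ring"):
        raise ValidationError("measure_rois expects a cell or ring label map")
    if ratio_mode not in ("pixel_mean", "roi_mean"):
        raise ValidationError("ratio_mode must be 'pixel_mean' or 'roi_mean'")
    labels = rois.labels
    if labels.shape != field.shape:
        raise ValidationError("ROI map and field shapes differ")
    ids = rois.ids
    if ids.size == 0:
        return []
    n_max = int(ids.max())
    area = np.bincount(labels.ravel(), minlength=n_max + 1)

    ex405 = np.asarray(field.channels["ex405"], dtype=float)
    ex488 = np.asarray(field.channels["ex488"], dtype=float)
    mean405 = _roi_means(ex405, labels, n_max)
    mean488 = _roi_means(ex488, labels, n_max)
    sq488 = _roi_means(ex488 * ex488, labels, n_max)
    with np.errstate(invalid="ignore"):
        var488 = np.maximum(sq488 - mean488**2, 0.0)
        gran = np.where(mean488 > 0, np.sqrt(var488) / np.where(mean488 > 0,
                                                                mean488, 1.0), 0.0)

    mean_nuc = (
        _roi_means(np.asarray(field.channels["nuclear"], dtype=float), labels, n_max)
        if "nuclear" in field.channels
        else None
    )
    mean_tmrm = (
        _roi_means(np.asarray(field.channels["tmrm"], dtype=float), labels, n_max)
        if "tmrm" in field.channels
        else None
    )

    valid = ~np.ma.getmaskarray(ratio)
    vlabels = np.where(valid, labels, 0)
    n_valid = np.bincount(vlabels.ravel(), minlength=n_max + 1)
    n_valid[0] = 0
    rdata = np.ma.getdata(ratio)
    rsum = np.bincount(vlabels.ravel(), weights=np.where(valid, rdata, 0.0).ravel(),
                       minlength=n_max + 1)
    sum405v = np.bincount(vlabels.ravel(), weights=np.where(valid, ex405, 0.0).ravel(),
                          minlength=n_max + 1)
    sum488v = np.bincount(vlabels.ravel(), weights=np.where(valid, ex488, 0.0).ravel(),
                          minlength=n_max + 1)

    records = []
    for lab in ids:
        lab = int(lab)
        nv = int(n_valid[lab])
        if nv == 0:
            r = None
        elif ratio_mode == "pixel_mean":
            r = float(rsum[lab] / nv)
        else:
            r = float(sum405v[lab] / sum488v[lab]) if sum488v[lab] > 0 else None
        records.append(
            CellRecord(
                well_id=field.well_id,
                field_index=field.field_index,
                timepoint_index=field.timepoint_index,
                cell_label=lab,
                area_px=int(area[lab]),
                mean_405=float(mean405[lab]),
                mean_488=float(mean488[lab]),
                mean_nuclear=float(mean_nuc[lab]) if mean_nuc is not None else None,
                mean_tmrm=float(mean_tmrm[lab]) if mean_tmrm is not None else None,
                granularity=float(gran[lab]),
                ratio=r,
                n_valid_ratio_px=nv,
            )
        )
    return records


def analyze_field(
    field: FieldImage,
    params: SegmentationParams | None = None,
    mode: str = "nuclear-ring",
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
    background_reference: dict[str, np.ndarray] | None = None,
    ratio_mode: str = "pixel_mean",
) -> list[CellRecord]:
    """Background-correct, segment (either mode) and measure one field."""
    params = params or SegmentationParams()
    if mode not in ("intensity", "nuclear-ring"):
        raise ValidationError("mode must be 'intensity' or 'nuclear-ring'")
    refs = background_reference or {}
    corr = {
        name: subtract_background(img, refs.get(name))
        for name, img in field.channels.items()
    }
    if mode == "intensity":
        rois = segment_intensity(corr["ex405"], params)
    else:
        if "nuclear" not in corr:
            raise ValidationError(
                f"field {field.well_id}/{field.field_index}: nuclear-ring mode "
                f"requires a nuclear channel"
            )
        nuclei = segment_nuclei(corr["nuclear"], params)
        rois = ring_rois(nuclei, params)
    corrected = FieldImage(
        channels=corr,
        well_id=field.well_id,
        field_index=field.field_index,
        timepoint_index=field.timepoint_index,
        pixel_size_um=field.pixel_size_um,
    )
    rimg = ratio_image(corr["ex405"], corr["ex488"], intensity_floor)
    return measure_rois(rois, corrected, rimg, ratio_mode=ratio_mode)


def default_high_ratio_gate(
    records: list[CellRecord], layout: PlateLayout, sd_mult: float = 3.0
) -> float:
    """Negative-control mean + ``sd_mult`` * sd of per-cell ratios."""
    neg_wells = set(layout.wells_with_role("negative_control"))
    vals = np.array(
        [r.ratio for r in records if r.well_id in neg_wells and r.ratio is not None]
    )
    if len(vals) < 2:
        raise ConfigurationError(
            "high-ratio gate needs >= 2 negative-control cells with a ratio"
        )
    return float(vals.mean() + sd_mult * vals.std(ddof=1))


def well_summary(
    records: list[CellRecord],
    layout: PlateLayout,
    high_ratio_gate: float | None = None,
) -> list[WellSummary]:
    """Aggregate cell records per well.

    The high-ratio gate defaults to negative-control mean + 3 sd, recomputed
    from this plate's control cells. Layout wells (other than ``empty``)
    with no cells are reported with n_cells = 0 and absent summaries.
    """
    if high_ratio_gate is None:
        high_ratio_gate = default_high_ratio_gate(records, layout)
    elif high_ratio_gate <= 0:
        raise ValidationError("high_ratio_gate must be > 0")
    by_well: dict[str, list[CellRecord]] = {}
    for r in records:
        by_well.setdefault(r.well_id, []).append(r)
    wells = [w for w in layout.well_ids if layout.role_of(w) != "empty"]
    wells += [w for w in by_well if w not in set(wells)]

    out = []
    for w in wells:
        recs = by_well.get(w, [])
        ratios = np.array([r.ratio for r in recs if r.ratio is not None])
        tmrms = np.array([r.mean_tmrm for r in recs if r.mean_tmrm is not None])
        n = len(recs)
        out.append(
            WellSummary(
                well_id=w,
                n_cells=n,
                ratio_mean=float(ratios.mean()) if len(ratios) else None,
                ratio_sd=float(ratios.std(ddof=1)) if len(ratios) >= 2 else None,
                ratio_median=float(np.median(ratios)) if len(ratios) else None,
                tmrm_mean=float(tmrms.mean()) if len(tmrms) else None,
                fraction_high_ratio=(
                    float((ratios > high_ratio_gate).mean()) if len(ratios) else None
                ),
            )
        )
    return out


def correlate(x, y) -> float:
    """Pearson product-moment correlation of two per-cell feature vectors.

    Requires equal lengths >= 3 and finite values; zero variance raises
    UndefinedCorrelationError rather than returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("correlate expects two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("correlate requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: zero variance in an input"
        )
    return float(stats.pearsonr(x, y).statistic)
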