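"""Single-cell time-lapse analysis.

Dying cells reported by the mt-roGFP probe show a biphasic 405/488 ratio
time course: a moderate surge preceding mitochondrial outer-membrane
permeabilization, then a drastic secondary rise once the intermembrane-space
reporter has been fully released. This module tracks nuclei across frames,
extracts per-track ratio / TMRM trajectories, fits piecewise-constant
change-point models to the ratio, and orders the TMRM-loss event against
the redox-rise event.

Change-point model
------------------
For a trajectory ``y[0..n)`` we fit piecewise-constant models with 0, 1 or
2 change points by exhaustive least squares (each segment's level is its
mean) and select the model order by BIC,

    BIC(m) = n * ln(RSS_m / n) + p_m * ln(n),   p_m = 2 m + 1,

counting one parameter per level and per change-point location. The RSS is
floored at a tiny multiple of the squared data range so that noiseless data
do not produce ``ln 0`` and so that the selected change points are invariant
to affine rescaling of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .segment import LabelMap


@dataclass
class Track:
    """One nucleus followed over a contiguous frame range."""

    track_id: int
    start_frame: int
    labels: list[int] = field(default_factory=list)  # per-frame cell label
    centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.labels) - 1

    def label_at(self, frame: int) -> int | None:
        if self.start_frame <= frame <= self.end_frame:
            return self.labels[frame - self.start_frame]
        return None


@dataclass
class Trajectory:
    """Per-track time series of the 405/488 ratio and (optionally) TMRM.

    Missing frames (e.g. no valid ratio pixels) are NaN.
    """

    track_id: int
    t: np.ndarray
    ratio: np.ndarray
    tmrm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.t.shape != self.ratio.shape:
            raise ValidationError("trajectory t and ratio lengths differ")
        if self.tmrm is not None:
            self.tmrm = np.asarray(self.tmrm, dtype=float)
            if self.tmrm.shape != self.ratio.shape:
                raise ValidationError("trajectory tmrm length differs from ratio")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class RedoxEvent:
    """Fitted biphasic ratio-rise description for one cell."""

    n_changepoints_detected: int
    t_surge: int | None = None
    t_secondary: int | None = None
    level_baseline: float | None = None
    level_surge: float | None = None
    level_final: float | None = None


def track_nuclei(
    label_maps: list[LabelMap | np.ndarray], max_displacement_px: float = 5.0
) -> list[Track]:
    """Greedy nearest-neighbour centroid linking, frame to frame.

    Links longer than ``max_displacement_px`` are rejected; unmatched
    detections start new tracks; tracks not matched in a frame terminate
    (no gap closing, no division handling).
    """
    if len(label_maps) < 2:
        raise ValidationError("tracking requires at least 2 frames")
    frames = []
    for lm in label_maps:
        labels = lm.labels if isinstance(lm, LabelMap) else np.asarray(lm)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        if ids.size:
            cents = ndimage.center_of_mass(labels > 0, labels, ids)
        else:
            cents = []
        frames.append(list(zip(ids.tolist(), [tuple(c) for c in cents])))

    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    for lab, cent in frames[0]:
        tr = Track(track_id=next_id, start_frame=0, labels=[lab], centroids=[cent])
        tracks.append(tr)
        active.append(tr)
        next_id += 1

    for fidx in range(1, len(frames)):
        dets = frames[fidx]
        links = []  # (distance, track_pos, det_pos)
        for ti, tr in enumerate(active):
            py, px = tr.centroids[-1]
            for di, (_, (cy, cx)) in enumerate(dets):
                d = float(np.hypot(py - cy, px - cx))
                if d <= max_displacement_px:
                    links.append((d, ti, di))
        links.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        assign: dict[int, int] = {}
        for d, ti, di in links:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            assign[ti] = di
        survivors = []
        for ti, tr in enumerate(active):
            if ti in assign:
                lab, cent = dets[assign[ti]]
                tr.labels.append(lab)
                tr.centroids.append(cent)
                survivors.append(tr)
        for di, (lab, cent) in enumerate(dets):
            if di not in used_d:
                tr = Track(
                    track_id=next_id, start_frame=fidx, labels=[lab], centroids=[cent]
                )
                tracks.append(tr)
                survivors.append(tr)
                next_id += 1
        active = survivors
    return tracks


def extract_trajectories(
    tracks: list[Track],
    ratio_images: list[np.ma.MaskedArray],
    ring_rois: list[LabelMap | np.ndarray],
    tmrm_images: list[np.ndarray] | None = None,
) -> list[Trajectory]:
    """Mean valid-pixel ratio (and TMRM) over each track's ring ROI per frame.

    A frame whose ROI has no valid ratio pixels yields NaN at that frame.
    """
    n_frames = len(ratio_images)
    if len(ring_rois) != n_frames or (
        tmrm_images is not None and len(tmrm_images) != n_frames
    ):
        raise ValidationError("frame counts of images and ROIs differ")
    rois = [
        (lm.labels if isinstance(lm, LabelMap) else np.asarray(lm)) for lm in ring_rois
    ]
    out = []
    for tr in tracks:
        t = np.arange(tr.start_frame, tr.end_frame + 1)
        ratio = np.full(t.shape, np.nan)
        tmrm = np.full(t.shape, np.nan) if tmrm_images is not None else None
        for i, frame in enumerate(t):
            lab = tr.labels[i]
            mask = rois[frame] == lab
            if not mask.any():
                continue
            rimg = ratio_images[frame]
            valid = mask & ~np.ma.getmaskarray(rimg)
            if valid.any():
                ratio[i] = float(np.ma.getdata(rimg)[valid].mean())
            if tmrm is not None:
                tmrm[i] = float(np.asarray(tmrm_images[frame])[mask].mean())
        out.append(Trajectory(track_id=tr.track_id, t=t, ratio=ratio, tmrm=tmrm))
    return out


def _segment_sse(y: np.ndarray):
    """Return sse(i, j) giving sum of squared residuals of y[i:j] about its
    mean, via cumulative sums."""
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(i: int, j: int) -> float:
        n = j - i
        s = s1[j] - s1[i]
        return float(s2[j] - s2[i] - s * s / n)

    return sse


def detect_biphasic(
    traj: Trajectory | np.ndarray,
    max_changepoints: int = 2,
    min_segment_len: int = 3,
) -> RedoxEvent:
    """Fit 0/1/2-change-point piecewise-constant models; pick order by BIC.

    The search over change-point locations is exhaustive; least-squares ties
    are broken toward the earliest change points. Trajectories shorter than
    ``3 * min_segment_len`` are rejected.
    """
    y = traj.ratio if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    y = y[~np.isnan(y)]
    n = len(y)
    if n < 3 * min_segment_len:
        raise ValidationError(
            f"trajectory too short ({n} frames) for change-point fitting with "
            f"min_segment_len={min_segment_len}"
        )
    if max_changepoints not in (0, 1, 2):
        raise ValidationError("max_changepoints must be 0, 1 or 2")
    sse = _segment_sse(y)
    scale = float(np.ptp(y))
    floor = n * (1e-12 * max(scale, 1e-30)) ** 2

    candidates = {0: (sse(0, n), ())}
    if max_changepoints >= 1:
        best = None
        for c in range(min_segment_len, n - min_segment_len + 1):
            r = sse(0, c) + sse(c, n)
            if best is None or r < best[0]:
                best = (r, (c,))
        candidates[1] = best
    if max_changepoints >= 2:
        best = None
        for c1 in range(min_segment_len, n - 2 * min_segment_len + 1):
            left = sse(0, c1)
            for c2 in range(c1 + min_segment_len, n - min_segment_len + 1):
                r = left + sse(c1, c2) + sse(c2, n)
                if best is None or r < best[0]:
                    best = (r, (c1, c2))
        candidates[2] = best

    best_m, best_bic = 0, None
    for m, cand in sorted(candidates.items()):
        if cand is None:
            continue
        rss = max(cand[0], floor)
        bic = n * np.log(rss / n) + (2 * m + 1) * np.log(n)
        if best_bic is None or bic < best_bic - 1e-9:
            best_m, best_bic = m, bic

    rss, cps = candidates[best_m]
    bounds = [0, *cps, n]
    levels = [float(y[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    if best_m == 0:
        return RedoxEvent(n_changepoints_detected=0, level_baseline=levels[0])
    if best_m == 1:
        return RedoxEvent(
            n_changepoints_detected=1,
            t_surge=cps[0],
            level_baseline=levels[0],
            level_surge=levels[1],
        )
    return RedoxEvent(
        n_changepoints_detected=2,
        t_surge=cps[0],
        t_secondary=cps[1],
        level_baseline=levels[0],
        level_surge=levels[1],
        level_final=levels[2],
    )


def order_events(
    traj: Trajectory,
    tmrm_loss_fraction: float = 0.5,
    ratio_rise_sd_mult: float = 3.0,
    baseline_frames: int = 5,
    persistence_frames: int = 2,
) -> int | None:
    """Signed lag (frames) between TMRM loss and ratio rise for one cell.

    ``t_tmrm`` is the first frame at which TMRM stays at or below
    ``tmrm_loss_fraction`` of its baseline level for ``persistence_frames``
    consecutive frames; ``t_ratio`` is defined analogously for the ratio
    exceeding baseline mean + ``ratio_rise_sd_mult`` * baseline sd. The
    persistence requirement debounces single-frame noise crossings. Returns
    ``t_ratio - t_tmrm`` (positive: TMRM loss first), or None when either
    threshold is never crossed.
    """
    if traj.tmrm is None:
        raise ValidationError("order_events requires a trajectory with TMRM")
    if len(traj) < baseline_frames + 1:
        raise ValidationError(
            f"trajectory needs more than {baseline_frames} baseline frames"
        )
    ratio, tmrm = traj.ratio, traj.tmrm
    base_r = ratio[:baseline_frames]
    base_m = tmrm[:baseline_frames]
    if np.isnan(base_r).any() or np.isnan(base_m).any():
        raise ValidationError("baseline window contains missing frames")
    r_mean = float(base_r.mean())
    r_sd = float(base_r.std(ddof=1)) if baseline_frames > 1 else 0.0
    if r_sd > 0:
        r_gate = ratio >= r_mean + ratio_rise_sd_mult * r_sd
    else:  # noiseless baseline: any genuine rise counts
        r_gate = ratio > r_mean
    m_gate = tmrm <= tmrm_loss_fraction * float(base_m.mean())

    t_ratio = _first_sustained(r_gate, persistence_frames, start=baseline_frames)
    t_tmrm = _first_sustained(m_gate, persistence_frames, start=0)
    if t_ratio is None or t_tmrm is None:
        return None
    return int(traj.t[t_ratio] - traj.t[t_tmrm])


def _first_sustained(gate: np.ndarray, persistence: int, start: int) -> int | None:
    gate = np.asarray(gate, dtype=bool)
    run = 0
    for i in range(start, len(gate)):
        run = run + 1 if gate[i] else 0
        if run >= persistence:
            return i - persistence + 1
    return None
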