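"""Fully ground-truthed synthetic mt-roGFP plates, time-lapses and flow tables.

The assay this package analyses images cells that stably express a
mitochondrially targeted redox-sensitive GFP (mt-roGFP) together with a
nuclear H2B marker and, optionally, the potentiometric dye TMRM. Oxidation
of the probe raises its 405-nm-excited emission and lowers its
488-nm-excited emission, so the per-cell 405/488 emission ratio reports the
oxidized fraction of the probe. No public image data exist for the assay,
so this module renders synthetic fields with known per-cell ground truth:

* probe photophysics as a linear blend of reduced and oxidized emission
  coefficients (:class:`ProbeCalibration`), calibrated so resting cells
  read a ratio of 0.5 and a fully oxidized cell reads ~4.4x that;
* cell geometry as elliptical nuclei with a perinuclear mitochondrial halo
  carrying multiplicative speckle texture and a radial falloff;
* camera noise as Poisson shot noise plus Gaussian read noise, clipped to
  the sensor bit depth;
* single-cell kinetics as a biphasic ratio trajectory (baseline, pre-MOMP
  surge, ramp during reporter release, post-release plateau) with a
  logistic TMRM decay;
* flow-style event tables as lognormal mixtures with ground-truth
  population ids.

Every output is a pure function of its spec and a seed; per-field and
per-trajectory substreams are derived from the master seed by fixed
counter offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import PlacementError, ValidationError
from .io import FieldImage, PlateLayout
from .kinetics import Trajectory

# fixed substream tags (stable counter offsets off the master seed)
_STREAM_GEOMETRY = 1
_STREAM_TEXTURE = 2
_STREAM_SAMPLING = 3
_STREAM_NOISE = 4
_STREAM_TRAJECTORY = 5
_STREAM_FLOW = 6

# rendering scale constants (arbitrary emission units)
_NUCLEAR_BRIGHTNESS = 3.0
_TMRM_BRIGHTNESS = 3.0
_TEXTURE_SHAPE = 4.0  # gamma shape for mito speckle; CV = 1/sqrt(shape)
_TEXTURE_SMOOTH_SIGMA = 1.0  # px; mitochondria are filamentous, not iid pixels
_TEXTURE_FLOOR = 0.3  # diffuse out-of-focus component under the speckle
_HALO_FALLOFF = 0.8  # e-folding of halo signal in normalized radius units
_NUCLEAR_OVERLAP = 0.6  # mito signal projected over the nucleus (widefield)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class ProbeCalibration:
    """Emission coefficients of the reduced/oxidized probe per excitation line.

    ``ratio(f) = em405(f) / em488(f)`` is strictly increasing in the
    oxidized fraction f because oxidation raises the 405-excited emission
    and lowers the 488-excited one. ``f_baseline`` is the resting oxidized
    fraction of untreated cells; the default calibration places it so that
    resting cells read ratio 0.5 and a fully oxidized cell reads ~2.2
    (a ~4.4-fold dynamic range).
    """

    a_red_405: float = 1.0
    a_ox_405: float = 4.0
    a_red_488: float = 4.0
    a_ox_488: float = 1.8
    f_baseline: float = 1.0 / 4.1  # solves ratio(f) = 0.5 for the defaults

    def __post_init__(self) -> None:
        for name in ("a_red_405", "a_ox_405", "a_red_488", "a_ox_488"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.a_ox_405 > self.a_red_405:
            raise ValidationError("oxidation must raise the 405-excited emission")
        if not self.a_ox_488 < self.a_red_488:
            raise ValidationError("oxidation must lower the 488-excited emission")
        if not 0.0 <= self.f_baseline <= 1.0:
            raise ValidationError("f_baseline must lie in [0, 1]")

    def emission(self, f) -> tuple[np.ndarray, np.ndarray]:
        """Expected (em405, em488) for oxidized fraction(s) f in [0, 1]."""
        f = np.asarray(f, dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise ValidationError("oxidized fraction must lie in [0, 1]")
        em405 = (1.0 - f) * self.a_red_405 + f * self.a_ox_405
        em488 = (1.0 - f) * self.a_red_488 + f * self.a_ox_488
        return em405, em488

    def ratio(self, f) -> np.ndarray:
        em405, em488 = self.emission(f)
        return em405 / em488

    @property
    def dynamic_range(self) -> float:
        """ratio(1) / ratio(f_baseline)."""
        return float(self.ratio(1.0) / self.ratio(self.f_baseline))

    def oxidized_fraction_for_ratio(self, r) -> np.ndarray:
        """Invert ratio(f) = r on [0, 1] (closed form; ratio is monotone)."""
        r = np.asarray(r, dtype=float)
        alpha = self.a_ox_405 - self.a_red_405
        beta = self.a_ox_488 - self.a_red_488
        f = (r * self.a_red_488 - self.a_red_405) / (alpha - r * beta)
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValidationError(f"ratio {r} outside the calibration's range")
        return np.clip(f, 0.0, 1.0)

    @classmethod
    def with_baseline_ratio(
        cls,
        target_ratio: float = 0.5,
        a_red_405: float = 1.0,
        a_ox_405: float = 4.0,
        a_red_488: float = 4.0,
        a_ox_488: float = 1.8,
    ) -> "ProbeCalibration":
        """Root-find f_baseline so that resting cells read ``target_ratio``."""
        def g(f):
            return ((1 - f) * a_red_405 + f * a_ox_405) / (
                (1 - f) * a_red_488 + f * a_ox_488
            ) - target_ratio

        if g(0.0) * g(1.0) > 0:
            raise ValidationError(
                f"target ratio {target_ratio} outside the calibration's range"
            )
        f0 = float(optimize.brentq(g, 0.0, 1.0, xtol=1e-14))
        return cls(a_red_405, a_ox_405, a_red_488, a_ox_488, f0)


def probe_response(f, cal: ProbeCalibration) -> tuple[np.ndarray, np.ndarray]:
    """Expected (em405, em488) emissions for oxidized fraction f."""
    return cal.emission(f)


PerCellRule = float | Sequence[float] | Callable[[np.random.Generator, int], np.ndarray]


@dataclass
class SceneSpec:
    """Geometry and biology of one synthetic field.

    ``min_spacing_px`` is the minimum allowed nucleus-centre spacing; small
    values force touching cells (the crowded-monolayer regime in which
    intensity-only segmentation merges neighbours).
    ``oxidized_fraction`` / ``tmrm_level`` may be a scalar, a per-cell
    sequence, or a callable ``(rng, n) -> array``; None means every cell
    rests at the calibration's baseline oxidized fraction.
    """

    n_cells: int = 30
    field_shape: tuple[int, int] = (256, 256)
    nucleus_radius_px: tuple[float, float] = (6.0, 1.0)  # (mean, sd)
    cyto_extent_px: float = 6.0
    min_spacing_px: float = 26.0
    oxidized_fraction: PerCellRule | None = None
    tmrm_level: PerCellRule = 1.0
    brightness_cv: float = 0.3
    background_level: float = 100.0
    background_gradient: tuple[float, float] | None = None  # counts/px (row, col)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.nucleus_radius_px[0] <= 0 or self.cyto_extent_px <= 0:
            raise ValidationError("all radii must be > 0")
        if self.min_spacing_px <= 0:
            raise ValidationError("min_spacing_px must be > 0")
        if self.background_level < 0:
            raise ValidationError("background_level must be >= 0")


@dataclass
class NoiseSpec:
    """Camera model: scaled-Poisson shot noise plus Gaussian read noise.

    ``photon_scale`` converts emission units to expected counts, so a pixel
    with expected signal s is drawn as Poisson(photon_scale * s +
    background); shot-noise variance therefore equals the expected count.
    Rendered values are clipped to [0, 2**bit_depth - 1].
    """

    photon_scale: float = 60.0
    read_noise_sd: float = 3.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValidationError("photon_scale must be > 0")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")
        if not 1 <= self.bit_depth <= 32:
            raise ValidationError("bit_depth must be in [1, 32]")


@dataclass
class GroundTruth:
    """Per-field ground truth; per-cell arrays are indexed by label - 1."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    true_oxidized_fraction: np.ndarray
    true_ratio: np.ndarray
    true_tmrm: np.ndarray
    centers: np.ndarray  # (n, 2) row/col nucleus centres

    @property
    def n_cells(self) -> int:
        return len(self.true_oxidized_fraction)


def _resolve_rule(
    rule: PerCellRule | None, default: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    if rule is None:
        return np.full(n, default)
    if callable(rule):
        return np.asarray(rule(rng, n), dtype=float)
    arr = np.asarray(rule, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if len(arr) != n:
        raise ValidationError(f"per-cell rule has length {len(arr)}, expected {n}")
    return arr.copy()


def beta_sampler(mean: float, sd: float) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Moment-matched Beta sampler on [0, 1] for per-cell oxidized fractions."""
    if not 0 < mean < 1:
        raise ValidationError("beta_sampler mean must lie in (0, 1)")
    var = sd * sd
    max_var = mean * (1 - mean)
    if var >= max_var:
        raise ValidationError("beta_sampler sd too large for the given mean")
    k = mean * (1 - mean) / var - 1
    a, b = mean * k, (1 - mean) * k

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.beta(a, b, size=n)

    return sample


def mixture_sampler(
    responding_fraction: float,
    responder: Callable[[np.random.Generator, int], np.ndarray],
    nonresponder: Callable[[np.random.Generator, int], np.ndarray],
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Per-cell sampler for partially responding wells.

    Drug-treated wells are cell-level mixtures: a ``responding_fraction`` of
    cells draw their oxidized fraction from ``responder``, the rest from
    ``nonresponder``.
    """
    if not 0.0 <= responding_fraction <= 1.0:
        raise ValidationError("responding_fraction must lie in [0, 1]")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        resp = rng.random(n) < responding_fraction
        out = nonresponder(rng, n)
        out[resp] = responder(rng, n)[resp]
        return out

    return sample


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    spacing: float,
    margin: float,
) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 2))
    lo = np.array([margin, margin])
    hi = np.array(shape, dtype=float) - margin
    if np.any(hi <= lo):
        raise PlacementError(
            f"field {shape} too small for margin {margin:.1f} px"
        )
    centers: list[np.ndarray] = []
    max_tries = 500 * n
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} nuclei with min spacing {spacing} px in a "
                f"{shape[0]}x{shape[1]} field (placed {len(centers)})"
            )
        tries += 1
        p = lo + rng.random(2) * (hi - lo)
        if all(np.hypot(*(p - q)) >= spacing for q in centers):
            centers.append(p)
    return np.asarray(centers)


def render_field(
    scene: SceneSpec, cal: ProbeCalibration | None = None, seed: int = 0
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Noise-free expected-emission render of one field (emission units).

    Returns per-channel float arrays (background not included) plus the
    ground truth. Geometry, texture and any sampled per-cell biology depend
    only on ``seed``, never on the oxidized-fraction values themselves, so
    raising a cell's oxidized fraction re-scales its emissions without
    moving a single pixel.
    """
    cal = cal or ProbeCalibration()
    H, W = scene.field_shape
    rng_geom = _rng(seed, _STREAM_GEOMETRY)
    rng_tex = _rng(seed, _STREAM_TEXTURE)
    rng_samp = _rng(seed, _STREAM_SAMPLING)
    n = scene.n_cells

    mean_r, sd_r = scene.nucleus_radius_px
    margin = mean_r  # nuclei stay inside; halos may clip at the border
    centers = _place_centers(rng_geom, n, (H, W), scene.min_spacing_px, margin)
    radii = np.clip(
        rng_geom.normal(mean_r, sd_r, size=n), 0.5 * mean_r, 1.5 * mean_r
    )
    elong = rng_geom.uniform(0.9, 1.15, size=n)
    angles = rng_geom.uniform(0, np.pi, size=n)
    s = math.sqrt(math.log1p(scene.brightness_cv**2))
    brightness = rng_geom.lognormal(-0.5 * s * s, s, size=n)

    f_cell = _resolve_rule(scene.oxidized_fraction, cal.f_baseline, rng_samp, n)
    if np.any((f_cell < 0) | (f_cell > 1)):
        raise ValidationError("oxidized fractions must lie in [0, 1]")
    tmrm_cell = _resolve_rule(scene.tmrm_level, 1.0, rng_samp, n)

    nuc_lab = np.zeros((H, W), dtype=np.int32)
    cell_lab = np.zeros((H, W), dtype=np.int32)
    best_rho = np.full((H, W), np.inf)
    best_nuc_rho = np.full((H, W), np.inf)
    crops = []
    for i in range(n):
        a = radii[i] * elong[i]
        b = radii[i] / elong[i]
        r_eff = math.sqrt(a * b)
        rho_out = 1.0 + scene.cyto_extent_px / r_eff
        half = int(math.ceil(max(a, b) * rho_out)) + 1
        cy, cx = centers[i]
        r0, r1 = max(int(cy) - half, 0), min(int(cy) + half + 1, H)
        c0, c1 = max(int(cx) - half, 0), min(int(cx) + half + 1, W)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy, dx = yy - cy, xx - cx
        ct, st = math.cos(angles[i]), math.sin(angles[i])
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        rho = np.hypot(u, v)
        box = (slice(r0, r1), slice(c0, c1))

        upd = (rho <= rho_out) & (rho < best_rho[box])
        cell_lab[box][upd] = i + 1
        best_rho[box][upd] = rho[upd]
        nupd = (rho <= 1.0) & (rho < best_nuc_rho[box])
        nuc_lab[box][nupd] = i + 1
        best_nuc_rho[box][nupd] = rho[nupd]

        # speckle drawn per cell in cell order: independent of the f values
        raw = rng_tex.gamma(_TEXTURE_SHAPE, 1.0 / _TEXTURE_SHAPE, size=rho.shape)
        smooth = ndimage.gaussian_filter(raw, _TEXTURE_SMOOTH_SIGMA)
        tex = _TEXTURE_FLOOR + (1.0 - _TEXTURE_FLOOR) * smooth
        ntex = rng_tex.gamma(16.0, 1.0 / 16.0, size=rho.shape)
        crops.append((box, rho, tex, ntex))

    em405, em488 = cal.emission(f_cell) if n else (np.empty(0), np.empty(0))
    channels = {
        name: np.zeros((H, W)) for name in ("ex405", "ex488", "nuclear", "tmrm")
    }
    for i, (box, rho, tex, ntex) in enumerate(crops):
        lab = i + 1
        own = cell_lab[box] == lab
        in_nuc = nuc_lab[box] == lab
        # perinuclear halo dominates; a weaker projected component covers
        # the nucleus, as mitochondria above/below it do in widefield
        weight = np.where(
            rho <= 1.0,
            _NUCLEAR_OVERLAP,
            np.exp(-(rho - 1.0) / _HALO_FALLOFF),
        )
        mito_tex = brightness[i] * tex * weight
        for name, em in (("ex405", em405[i]), ("ex488", em488[i])):
            ch = channels[name][box]
            ch[own] += em * mito_tex[own]
        ch = channels["tmrm"][box]
        ch[own] += _TMRM_BRIGHTNESS * tmrm_cell[i] * mito_tex[own]
        ch = channels["nuclear"][box]
        ch[in_nuc] += _NUCLEAR_BRIGHTNESS * brightness[i] * ntex[in_nuc]

    truth = GroundTruth(
        nucleus_labels=nuc_lab,
        cell_labels=cell_lab,
        true_oxidized_fraction=f_cell,
        true_ratio=(em405 / em488) if n else np.empty(0),
        true_tmrm=tmrm_cell,
        centers=centers,
    )
    return channels, truth


def generate_field(
    scene: SceneSpec,
    cal: ProbeCalibration | None = None,
    noise: NoiseSpec | None = None,
    *,
    seed: int | None = None,
    well_id: str = "A01",
    field_index: int = 0,
    timepoint_index: int = 0,
) -> tuple[FieldImage, GroundTruth]:
    """Render one four-channel field with camera noise; deterministic in seed.

    ``seed`` defaults to ``noise.seed``; passing it explicitly lets a plate
    simulation hand every field its own substream.
    """
    cal = cal or ProbeCalibration()
    noise = noise or NoiseSpec()
    seed = noise.seed if seed is None else seed
    signal, truth = render_field(scene, cal, seed=seed)
    rng_noise = _rng(seed, _STREAM_NOISE)
    H, W = scene.field_shape
    background = np.full((H, W), float(scene.background_level))
    if scene.background_gradient is not None:
        gy, gx = scene.background_gradient
        yy, xx = np.mgrid[0:H, 0:W]
        background = background + gy * yy + gx * xx
    maxval = 2**noise.bit_depth - 1
    channels = {}
    for name in ("ex405", "ex488", "nuclear", "tmrm"):
        expected = noise.photon_scale * signal[name] + background
        counts = rng_noise.poisson(expected).astype(float)
        if noise.read_noise_sd > 0:
            counts += rng_noise.normal(0.0, noise.read_noise_sd, size=counts.shape)
        channels[name] = np.clip(np.rint(counts), 0, maxval).astype(np.uint16)
    fimg = FieldImage(
        channels=channels,
        well_id=well_id,
        field_index=field_index,
        timepoint_index=timepoint_index,
    )
    return fimg, truth


# Default per-role biology of a screening plate: negative-control cells rest
# near the probe baseline with modest spread; positive-control wells hold a
# maximum-response drug dose, so their cells are strongly oxidized with
# collapsed TMRM.
DEFAULT_ROLE_OXIDATION = {
    "positive_control": (0.85, 0.08),
    "treatment": (0.85, 0.08),
}
_NEGATIVE_SD = 0.04


def role_oxidation_sampler(
    role: str, cal: ProbeCalibration
) -> Callable[[np.random.Generator, int], np.ndarray]:
    if role == "negative_control":
        return beta_sampler(cal.f_baseline, _NEGATIVE_SD)
    mean, sd = DEFAULT_ROLE_OXIDATION.get(role, DEFAULT_ROLE_OXIDATION["treatment"])
    return beta_sampler(mean, sd)


def simulate_plate(
    layout: PlateLayout,
    scene: SceneSpec | None = None,
    cal: ProbeCalibration | None = None,
    noise: NoiseSpec | None = None,
    *,
    n_fields: int = 1,
    seed: int = 0,
    oxidation_by_role: dict[str, tuple[float, float]] | None = None,
) -> list[tuple[FieldImage, GroundTruth]]:
    """Simulate every non-empty layout well; per-field substreams off ``seed``.

    ``oxidation_by_role`` overrides the (mean, sd) of the Beta-distributed
    per-cell oxidized fraction for a role. Positive/treatment wells get
    tmrm level 0.2 (collapsed potential), negative wells 1.0.
    """
    scene = scene or SceneSpec()
    cal = cal or ProbeCalibration()
    noise = noise or NoiseSpec()
    out = []
    counter = 0
    for well in layout.well_ids:
        role = layout.role_of(well)
        if role == "empty":
            continue
        if oxidation_by_role and role in oxidation_by_role:
            sampler = beta_sampler(*oxidation_by_role[role])
        else:
            sampler = role_oxidation_sampler(role, cal)
        tmrm = 1.0 if role == "negative_control" else 0.2
        for fidx in range(n_fields):
            sc = SceneSpec(**{**scene.__dict__, "oxidized_fraction": sampler,
                              "tmrm_level": tmrm})
            fimg, truth = generate_field(
                sc, cal, noise,
                seed=int(np.random.SeedSequence(seed, spawn_key=(7, counter))
                         .generate_state(1)[0] % (2**31)),
                well_id=well, field_index=fidx,
            )
            out.append((fimg, truth))
            counter += 1
    return out


def crowded_scene(**overrides) -> SceneSpec:
    """Tight adherent monolayer: nuclei nearly touching, halos overlapping.

    The regime in which intensity-only segmentation merges neighbours and
    the nuclear-marker-seeded ring segmentation earns its keep.
    """
    base = dict(n_cells=70, min_spacing_px=12.0, field_shape=(256, 256))
    base.update(overrides)
    return SceneSpec(**base)


def sparse_scene(**overrides) -> SceneSpec:
    """Well-separated cells: both segmentation modes resolve every cell."""
    base = dict(n_cells=25, min_spacing_px=40.0, field_shape=(256, 256))
    base.update(overrides)
    return SceneSpec(**base)


# a moderate-response treated arm (partial oxidation) gives the realistic
# screening window in which segmentation quality visibly moves Z'
MODERATE_RESPONSE_OXIDATION = {"positive_control": (0.55, 0.08)}


@dataclass
class KineticParams:
    """Biphasic single-cell redox trajectory parameters (frames, ratio units).

    The ratio holds at ``r_baseline``, steps to ``r_surge`` at ``t_surge``
    (the pre-permeabilization surge), ramps to ``r_released`` over
    [t_release, t_secondary) as the intermembrane-space reporter leaves the
    mitochondria, and plateaus at ``r_secondary`` afterwards. TMRM decays as
    a logistic sigmoid crossing half its initial level at
    ``tmrm_half_loss_time`` — by default *before* the redox surge, matching
    the observed event order in drug-treated cells.
    """

    r_baseline: float = 0.4
    r_surge: float = 0.65
    r_released: float = 1.2
    r_secondary: float = 2.0
    t_surge: int = 20
    t_release: int = 35
    t_secondary: int = 50
    tmrm_half_loss_time: float = 12.0
    tmrm_decay_tau: float = 2.5
    trajectory_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not (self.r_baseline < self.r_surge < self.r_released <= self.r_secondary):
            raise ValidationError(
                "ratio levels must satisfy r_baseline < r_surge < r_released "
                "<= r_secondary"
            )
        if not (0 <= self.t_surge < self.t_release < self.t_secondary):
            raise ValidationError(
                "change times must satisfy 0 <= t_surge < t_release < t_secondary"
            )
        if self.trajectory_noise_sd < 0:
            raise ValidationError("trajectory_noise_sd must be >= 0")
        if self.tmrm_decay_tau <= 0:
            raise ValidationError("tmrm_decay_tau must be > 0")


def piecewise_ratio(k: KineticParams, t) -> np.ndarray:
    """Noise-free analytic ratio trajectory at frame(s) t."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, k.r_baseline)
    out[t >= k.t_surge] = k.r_surge
    ramp = (t >= k.t_release) & (t < k.t_secondary)
    frac = (t[ramp] - k.t_release) / (k.t_secondary - k.t_release)
    out[ramp] = k.r_surge + frac * (k.r_released - k.r_surge)
    out[t >= k.t_secondary] = k.r_secondary
    return out


def tmrm_decay(k: KineticParams, t) -> np.ndarray:
    """Monotone non-increasing logistic TMRM level, 0.5 at the half-loss time."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + np.exp((t - k.tmrm_half_loss_time) / k.tmrm_decay_tau))


def simulate_redox_trajectory(
    k: KineticParams, n_frames: int, seed: int = 0, track_id: int = 0
) -> tuple[Trajectory, KineticParams]:
    """Simulate one cell's ratio/TMRM time course; returns the trajectory and
    the ground-truth parameters it was generated from."""
    if n_frames <= k.t_secondary:
        raise ValidationError(
            f"n_frames ({n_frames}) must exceed t_secondary ({k.t_secondary})"
        )
    t = np.arange(n_frames)
    ratio = piecewise_ratio(k, t)
    tmrm = tmrm_decay(k, t)
    if k.trajectory_noise_sd > 0:
        rng = _rng(seed, _STREAM_TRAJECTORY, track_id)
        ratio = ratio + rng.normal(0.0, k.trajectory_noise_sd, size=n_frames)
        tmrm = tmrm + rng.normal(0.0, k.trajectory_noise_sd, size=n_frames)
    traj = Trajectory(track_id=track_id, t=t, ratio=ratio, tmrm=tmrm)
    return traj, k


def generate_flow_events(
    n: int,
    populations: Sequence[tuple[float, float, float, float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Flow-style per-event intensity table from a lognormal mixture.

    Each population is ``(fraction, mean405, mean488, mean_marker, sd)``
    with ``sd`` the lognormal sigma (geometric spread) applied independently
    to each channel; medians equal the stated means. The ground-truth
    population id is retained in the ``population`` column. Fractions must
    sum to 1 within 1e-9.
    """
    if n <= 0:
        raise ValidationError("n must be > 0")
    fracs = np.array([p[0] for p in populations], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"population fractions sum to {fracs.sum():.12f}, not 1"
        )
    rng = _rng(seed, _STREAM_FLOW)
    counts = rng.multinomial(n, fracs)
    rows = []
    for pid, ((_, m405, m488, mmark, sd), cnt) in enumerate(zip(populations, counts)):
        z = rng.normal(0.0, 1.0, size=(cnt, 3))
        i405 = m405 * np.exp(sd * z[:, 0])
        i488 = m488 * np.exp(sd * z[:, 1])
        mark = mmark * np.exp(sd * z[:, 2])
        rows.append(
            pd.DataFrame(
                {"i405": i405, "i488": i488, "marker": mark, "population": pid}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    perm = rng.permutation(len(table))
    table = table.iloc[perm].reset_index(drop=True)
    table.insert(0, "event_id", np.arange(len(table)))
    return table


def make_layout(
    n_negative: int = 4,
    n_positive: int = 4,
    n_treatment: int = 0,
    plate_rows: str = "ABCDEFGH",
    plate_cols: int = 12,
) -> PlateLayout:
    """Convenience row-major screening layout for synthetic plates."""
    wells = [f"{r}{c:02d}" for r in plate_rows for c in range(1, plate_cols + 1)]
    need = n_negative + n_positive + n_treatment
    if need > len(wells):
        raise ValidationError("layout does not fit on the plate")
    roles = (
        ["negative_control"] * n_negative
        + ["positive_control"] * n_positive
        + ["treatment"] * n_treatment
    )
    labels = (
        ["mock"] * n_negative
        + ["max_response"] * n_positive
        + [f"compound_{i + 1}" for i in range(n_treatment)]
    )
    table = pd.DataFrame(
        {
            "well_id": wells[:need],
            "role": roles,
            "treatment_label": labels,
            "concentration": [""] * need,
        }
    )
    return PlateLayout(table)
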