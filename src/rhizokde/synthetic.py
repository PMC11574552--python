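"""Seeded synthetic microcosm scenes for the full analysis pipeline.

Emulates the structure of a transparent-soil timelapse dataset: a cohort of
roots imaged at several timepoints, each root covered by a column of square
tiles (3.2×3.2 mm at 6.21 µm/px by default), with granular soil particles
(250–1250 µm), a manually-traceable root, and bacterial patches of three
population types planted with known spatial laws:

* MB (mobile bacteria): in the pore space with probability
  ∝ exp(−dr/λ_r)·exp(−dp/λ_p), concentrating activity within ~200 µm of the
  root and particle surfaces;
* RB (root biofilm): uniform on the root surface at ``da ≥ d_min_tip``
  (the biofilm-free tip zone, default 794.26 µm, growing with time);
* PB (particle biofilm): uniform on particle perimeter pixels, preferring
  perimeters near the root.

Every scene ships with its ground truth (masks, planted patch table with
recomputable covariates, placement parameters), so downstream stages are
testable by round-trip.  All randomness flows from a single seed through
named substreams, one per root and stage.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from scipy import ndimage

from .metrics import CalibrationModel, paper_default_calibration
from .segmentation import (
    CLASS_INDEX,
    CLASS_NAMES,
    CovariateCalculator,
    RootGeometry,
    rasterize_root,
)


def substream(seed: int, *names) -> np.random.Generator:
    """Independent generator for a named stage of a seeded run."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class PlacementModel:
    """Spatial and temporal laws for planting bacterial patches.

    Counts are per tile per timepoint (Poisson means, modulated by the
    per-class temporal weights); areas and cells-per-patch are lognormal.
    The quantitative patch-size and cells-per-patch distributions are free
    generator parameters (no field consensus exists); defaults are chosen to
    give patches of tens to hundreds of pixels at the default resolution.
    """

    # MB law: weight ∝ exp(−dr/λ_r)·exp(−dp/λ_p) over pore pixels, with an
    # extra exp(−da/λ_a) tip bias at early timepoints (mobile bacteria reach
    # the tip first, then spread along the root)
    mb_lambda_r_um: float = 100.0
    mb_lambda_p_um: float = 100.0
    mb_tip_bias_lambda_um: dict = field(default_factory=lambda: {
        12: 1500.0, 24: 2500.0, 36: None, 48: None})
    # RB: uniform on the root surface beyond the tip-exclusion zone
    rb_d_min_tip_um: float = 794.26
    rb_tip_exclusion_growth_um_per_h: float = 20.0
    # PB: uniform on particle perimeter pixels, within max dr of the root
    pb_max_dr_um: float = 100.0
    # Poisson mean patch counts per tile at temporal weight 1
    counts_per_tile: dict = field(default_factory=lambda: {
        "MB": 6.0, "RB": 3.0, "PB": 3.0})
    # temporal modulation: MB peaks at 12–24 h, biofilms build up with time
    temporal_weights: dict = field(default_factory=lambda: {
        "MB": {12: 1.0, 24: 1.0, 36: 0.45, 48: 0.3},
        "RB": {12: 0.25, 24: 0.6, 36: 0.85, 48: 1.0},
        "PB": {12: 0.2, 24: 0.5, 36: 0.8, 48: 1.0},
    })
    # lognormal (median µm², sigma of log) patch areas per class
    area_median_um2: dict = field(default_factory=lambda: {
        "MB": 3000.0, "RB": 2500.0, "PB": 1500.0})
    area_sigma_log: float = 0.6
    # lognormal cells per patch
    cells_median: dict = field(default_factory=lambda: {
        "MB": 150.0, "RB": 400.0, "PB": 400.0})
    cells_sigma_log: float = 0.7

    def __post_init__(self) -> None:
        for v in (self.mb_lambda_r_um, self.mb_lambda_p_um,
                  self.rb_d_min_tip_um, self.pb_max_dr_um):
            if not v > 0:
                raise ValueError("placement scale parameters must be > 0")
        if set(self.counts_per_tile) != {"MB", "RB", "PB"}:
            raise ValueError("counts must cover exactly MB, RB, PB")

    def tip_exclusion_um(self, timepoint_h: float) -> float:
        g = self.rb_tip_exclusion_growth_um_per_h
        return self.rb_d_min_tip_um + g * max(0.0, timepoint_h - 12.0)


@dataclass
class SceneConfig:
    """Geometry, resolution, optics and noise of the synthetic microcosm."""

    tile_width_mm: float = 3.2
    tile_height_mm: float = 3.2
    pixel_size_um: float = 6.21
    particle_diameter_range_um: tuple[float, float] = (250.0, 1250.0)
    particle_packing_fraction: float = 0.5
    root_width_um: float = 300.0
    root_curvature: float = 0.35      # lateral wiggle amplitude, fraction of tile width
    n_roots: int = 12
    timepoints_h: tuple[float, ...] = (12.0, 24.0, 36.0, 48.0)
    tiles_per_root_range: tuple[int, int] = (2, 6)
    placement: PlacementModel = field(default_factory=PlacementModel)
    calibration_slope: float = 39.0
    calibration_intercept: float = 331.0
    background_level: float = 0.0
    noise_sd: float = 0.0
    label_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.tile_width_mm, self.tile_height_mm, self.pixel_size_um,
                  self.root_width_um):
            if not v > 0:
                raise ValueError("lengths must be strictly positive")
        lo, hi = self.particle_diameter_range_um
        if not 0 < lo < hi:
            raise ValueError("particle diameter range must satisfy 0 < low < high")
        if not 0 <= self.particle_packing_fraction < 1:
            raise ValueError("packing fraction must lie in [0, 1)")
        if np.any(np.diff(self.timepoints_h) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")

    @property
    def tile_shape_px(self) -> tuple[int, int]:
        h = int(round(self.tile_height_mm * 1000.0 / self.pixel_size_um))
        w = int(round(self.tile_width_mm * 1000.0 / self.pixel_size_um))
        return h, w

    def calibration(self) -> CalibrationModel:
        return CalibrationModel(self.calibration_slope, self.calibration_intercept)


@dataclass
class SceneGroundTruth:
    """One rendered tile plus everything needed to verify recovery."""

    config: SceneConfig
    root_id: int
    tile_id: int
    timepoint_h: float
    intensity: np.ndarray         # float, background+noise included
    probstack: np.ndarray         # (5, H, W) float32, rows sum to 1
    labelmap: np.ndarray          # includes ROOT=5
    particle_mask: np.ndarray
    root_mask: np.ndarray
    pore_mask: np.ndarray
    geometry: RootGeometry        # tile-local coordinates, global arc lengths
    patches: pd.DataFrame         # planted ground truth with true covariates
    achieved_packing: float
    seed: int


# ---------------------------------------------------------------------------
# particles

def generate_particles(config: SceneConfig, seed, shape_px=None,
                       attempt_factor: int = 50):
    """Non-overlapping soil-particle discs by rejection sampling.

    Diameters are uniform over the configured range; discs are placed until
    the target packing fraction is reached or the attempt cap
    (``attempt_factor`` × the expected disc count) runs out, in which case a
    warning reports the achieved fraction.  Returns ``(mask, achieved)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = shape_px if shape_px is not None else config.tile_shape_px
    px = config.pixel_size_um
    target = config.particle_packing_fraction
    mask = np.zeros((h, w), dtype=bool)
    if target == 0:
        return mask, 0.0
    lo, hi = config.particle_diameter_range_um
    mean_disc_px = np.pi * ((lo + hi) / 4.0 / px) ** 2
    expected = max(1, int(np.ceil(target * h * w / mean_disc_px)))
    attempts_left = attempt_factor * expected
    total_px = h * w
    yy, xx = np.ogrid[:h, :w]
    while mask.sum() / total_px < target and attempts_left > 0:
        attempts_left -= 1
        d = rng.uniform(lo, hi)
        r_px = d / 2.0 / px
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        r0 = max(int(np.floor(cy - r_px)) - 1, 0)
        r1 = min(int(np.ceil(cy + r_px)) + 1, h)
        c0 = max(int(np.floor(cx - r_px)) - 1, 0)
        c1 = min(int(np.ceil(cx + r_px)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        sub_y = yy[r0:r1] + 0.5
        sub_x = xx[:, c0:c1] + 0.5
        disc = (sub_x - cx) ** 2 + (sub_y - cy) ** 2 <= r_px ** 2
        if not disc.any():
            continue
        if mask[r0:r1, c0:c1][disc].any():
            continue
        mask[r0:r1, c0:c1] |= disc
    achieved = mask.sum() / total_px
    if achieved < target - 1e-12:
        warnings.warn(
            f"particle packing fraction {achieved:.3f} achieved "
            f"(target {target:.3f}); attempt cap reached", stacklevel=2)
    return mask, float(achieved)


# ---------------------------------------------------------------------------
# root

def generate_root(config: SceneConfig, seed, shape_px=None,
                  tip_margin_um: float | None = None):
    """Smooth root entering from the top edge, tip inside the canvas.

    The centreline is a gently sinusoidal vertical curve; the boundary is the
    centreline buffered to the root width (round cap at the tip), and the
    mask is the boundary polygon rasterized at pixel centers.  Centreline
    vertices are ordered tip-first with cumulative arc length attached.
    Returns ``(RootGeometry, mask)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = shape_px if shape_px is not None else config.tile_shape_px
    px = config.pixel_size_um
    width_um = config.root_width_um
    if width_um / px <= 2:
        raise ValueError("root width must exceed 2 pixels at this resolution")
    if width_um >= w * px:
        raise ValueError("root width must be smaller than the tile width")
    h_um, w_um = h * px, w * px
    if tip_margin_um is None:
        tip_margin_um = 0.45 * config.tile_height_mm * 1000.0
    y_tip = h_um - tip_margin_um
    n_pts = max(16, int(y_tip / (4 * px)))
    ys = np.linspace(0.0, y_tip, n_pts)
    amp = config.root_curvature * 0.5 * w_um * rng.uniform(0.3, 1.0)
    phase = rng.uniform(0, 2 * np.pi)
    wavelength = rng.uniform(1.2, 2.5) * h_um
    x0 = w_um / 2.0 + rng.uniform(-0.08, 0.08) * w_um
    xs = x0 + amp * np.sin(2 * np.pi * ys / wavelength + phase)
    xs = np.clip(xs, width_um, w_um - width_um)
    centreline = np.column_stack([xs, ys])[::-1]  # tip-first
    line = shapely.LineString(centreline)
    poly = line.buffer(width_um / 2.0, quad_segs=16)
    boundary = np.asarray(poly.exterior.coords)
    geom = RootGeometry(centreline=centreline, boundary=boundary)
    mask = rasterize_root(geom, (h, w), px)
    return geom, mask


# ---------------------------------------------------------------------------
# patch placement

def _perimeter(mask: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Free pixels 8-adjacent to the mask."""
    grown = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
    return grown & ~mask & free


def place_patches(config: SceneConfig, particle_mask: np.ndarray,
                  root_mask: np.ndarray, geometry: RootGeometry,
                  timepoint_h: float, seed,
                  n_tiles: int = 1,
                  counts: dict | None = None) -> pd.DataFrame:
    """Sample planted patches for one scene and timepoint.

    Returns a table of (class, cx_um, cy_um, area_um2, cells) rows; centroids
    are pixel centers drawn independently from each class's spatial law;
    pixels already claimed by another class are rejected and redrawn, so the
    rendered ground truth stays unambiguous.  ``counts`` overrides the
    Poisson draw with exact per-class counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pm = config.placement
    px = config.pixel_size_um
    pore = ~particle_mask & ~root_mask
    calc = CovariateCalculator(particle_mask, root_mask, geometry, px)

    if counts is None:
        counts = {}
        for cls in ("MB", "RB", "PB"):
            weight = pm.temporal_weights[cls].get(timepoint_h, 1.0)
            lam = pm.counts_per_tile[cls] * weight * n_tiles
            counts[cls] = int(rng.poisson(lam))

    # cross-class exclusion: planted patches of different classes must not
    # overlap once painted, so candidate centroids keep a margin of the two
    # patch radii from every patch of another class already placed
    placed_xy: list[tuple[float, float]] = []
    placed_r: list[float] = []
    placed_cls: list[str] = []

    def sample_pixels(cls, rows, cols, n, radii_um, prob=None):
        """IID draws from a class's law; redraw conflicted candidates."""
        if len(rows) == 0 or n == 0:
            return np.empty((0, 2)), np.array([], dtype=int)
        cdf = None if prob is None else np.cumsum(prob)
        pts, kept = [], []
        for i in range(n):
            r_i = radii_um[i]
            for _attempt in range(100):
                if cdf is None:
                    j = int(rng.integers(len(rows)))
                else:
                    j = min(int(np.searchsorted(cdf, rng.random())),
                            len(rows) - 1)
                x = (cols[j] + 0.5) * px
                y = (rows[j] + 0.5) * px
                ok = True
                # painting confines each region to twice its nominal radius,
                # so this margin guarantees disjoint cross-class regions
                for (ox, oy), orr, ocls in zip(placed_xy, placed_r, placed_cls):
                    if ocls != cls and \
                            (x - ox) ** 2 + (y - oy) ** 2 < \
                            (2.0 * (r_i + orr) + 3 * px) ** 2:
                        ok = False
                        break
                if ok:
                    placed_xy.append((x, y))
                    placed_r.append(r_i)
                    placed_cls.append(cls)
                    pts.append((x, y))
                    kept.append(i)
                    break
        return (np.asarray(pts) if pts else np.empty((0, 2)),
                np.asarray(kept, dtype=int))

    min_area = 4 * px * px

    def draw_sizes(cls, n):
        areas = np.exp(rng.normal(np.log(pm.area_median_um2[cls]),
                                  pm.area_sigma_log, n))
        areas = np.clip(areas, min_area, None)
        cells = np.maximum(1, np.round(np.exp(rng.normal(
            np.log(pm.cells_median[cls]), pm.cells_sigma_log, n)))).astype(int)
        return areas, cells

    frames = []

    def emit(cls, pts, kept, areas, cells):
        if len(pts) == 0:
            return
        frames.append(pd.DataFrame({
            "class": cls, "cx_um": pts[:, 0], "cy_um": pts[:, 1],
            "area_um2": areas[kept], "cells": cells[kept]}))

    # MB: pore pixels weighted by exp(-dr/λr)·exp(-dp/λp)·exp(-da/λa(t))
    n_mb = counts.get("MB", 0)
    if n_mb > 0:
        rows, cols = np.nonzero(pore)
        logw = -calc.dr_map[rows, cols] / pm.mb_lambda_r_um
        if particle_mask.any():
            logw = logw - calc.dp_map[rows, cols] / pm.mb_lambda_p_um
        lam_a = pm.mb_tip_bias_lambda_um.get(timepoint_h)
        if lam_a:
            pts_all = np.column_stack([(cols + 0.5) * px, (rows + 0.5) * px])
            logw = logw - calc(pts_all)[:, 2] / lam_a
        wts = np.exp(logw - logw.max())
        wts /= wts.sum()
        areas, cells = draw_sizes("MB", n_mb)
        pts, kept = sample_pixels("MB", rows, cols, n_mb,
                                  np.sqrt(areas / np.pi), wts)
        emit("MB", pts, kept, areas, cells)

    # RB: root-surface pixels beyond the tip-exclusion distance
    n_rb = counts.get("RB", 0)
    if n_rb > 0:
        surf = _perimeter(root_mask, pore)
        rows, cols = np.nonzero(surf)
        if len(rows):
            pts_all = np.column_stack([(cols + 0.5) * px, (rows + 0.5) * px])
            da = calc(pts_all)[:, 2]
            legal = da >= pm.tip_exclusion_um(timepoint_h)
            rows, cols = rows[legal], cols[legal]
        if len(rows) == 0:
            warnings.warn("no legal RB support (root shorter than the "
                          "tip-exclusion distance); planting no RB patches",
                          stacklevel=2)
        else:
            areas, cells = draw_sizes("RB", n_rb)
            pts, kept = sample_pixels("RB", rows, cols, n_rb,
                                      np.sqrt(areas / np.pi))
            emit("RB", pts, kept, areas, cells)

    # PB: particle perimeter pixels, preferring perimeters near the root
    n_pb = counts.get("PB", 0)
    if n_pb > 0 and particle_mask.any():
        perim = _perimeter(particle_mask, pore)
        rows, cols = np.nonzero(perim)
        if len(rows):
            sel = calc.dr_map[rows, cols] <= pm.pb_max_dr_um
            if not sel.any():
                warnings.warn("no particle perimeter within pb_max_dr of the"
                              " root; sampling the whole perimeter",
                              stacklevel=2)
            else:
                rows, cols = rows[sel], cols[sel]
        areas, cells = draw_sizes("PB", n_pb)
        pts, kept = sample_pixels("PB", rows, cols, n_pb,
                                  np.sqrt(areas / np.pi))
        emit("PB", pts, kept, areas, cells)
    elif n_pb > 0:
        warnings.warn("no particles in scene; planting no PB patches",
                      stacklevel=2)

    if not frames:
        return pd.DataFrame({"class": pd.Series(dtype=object),
                             "cx_um": pd.Series(dtype=float),
                             "cy_um": pd.Series(dtype=float),
                             "area_um2": pd.Series(dtype=float),
                             "cells": pd.Series(dtype=int)})
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# rendering

def render_scene(planted: pd.DataFrame, particle_mask: np.ndarray,
                 root_mask: np.ndarray, calibration: CalibrationModel,
                 pixel_size_um: float, seed,
                 background_level: float = 0.0, noise_sd: float = 0.0,
                 label_flip_rate: float = 0.0):
    """Paint planted patches into an intensity image and probability stack.

    Each patch becomes a compact pixel region of (approximately) its drawn
    area grown around its centroid within the pore space; the region's total
    intensity equals ``calibration.predict(cells)`` exactly (integerized)
    before background and noise.  The probability stack is one-hot from the
    ground-truth labels with optional label-flip noise.  Patches of different
    classes claiming the same centroid pixel raise an error — ground truth
    must stay unambiguous.

    Returns ``(intensity, probstack, labelmap, realized)`` where ``realized``
    is the planted table with realized areas/centroids attached.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = particle_mask.shape
    px = pixel_size_um
    labelmap = np.full((h, w), CLASS_INDEX["PORE"], dtype=np.uint8)
    labelmap[particle_mask] = CLASS_INDEX["PARTICLE"]
    paintable = ~particle_mask & ~root_mask
    intensity = np.zeros((h, w), dtype=float)

    realized_rows = []
    p_class = planted["class"].to_numpy() if len(planted) else np.array([])
    p_cx = planted["cx_um"].to_numpy(float) if len(planted) else np.array([])
    p_cy = planted["cy_um"].to_numpy(float) if len(planted) else np.array([])
    p_area = planted["area_um2"].to_numpy(float) if len(planted) else np.array([])
    p_cells = planted["cells"].to_numpy() if len(planted) else np.array([])
    for k in range(len(p_class)):
        cls_name = p_class[k]
        npix = max(1, int(round(p_area[k] / (px * px))))
        col_c = int(p_cx[k] / px)
        row_c = int(p_cy[k] / px)
        if not paintable[row_c, col_c]:
            owner = "ROOT" if root_mask[row_c, col_c] else \
                CLASS_NAMES[labelmap[row_c, col_c]]
            # coincident patches of the same class merge harmlessly; any
            # other collision would make the ground truth ambiguous
            if owner != cls_name:
                raise ValueError(
                    f"planted {cls_name} patch at "
                    f"({p_cx[k]:.0f}, {p_cy[k]:.0f}) µm overlaps {owner}; "
                    "ground truth must stay unambiguous")
        # grow a compact region of the npix nearest paintable pixels, capped
        # at twice the nominal patch radius so cross-class regions placed
        # with the matching margin can never collide
        r_nom = np.sqrt(npix / np.pi)
        rad = int(np.ceil(2 * r_nom)) + 2
        r0, r1 = max(row_c - rad, 0), min(row_c + rad + 1, h)
        c0, c1 = max(col_c - rad, 0), min(col_c + rad + 1, w)
        sub = paintable[r0:r1, c0:c1]
        rows, cols = np.nonzero(sub)
        chosen = None
        if len(rows):
            d2 = (rows + r0 - row_c) ** 2 + (cols + c0 - col_c) ** 2
            within = d2 <= (2 * r_nom) ** 2
            rows, cols, d2 = rows[within], cols[within], d2[within]
        if len(rows):
            order = np.argsort(d2, kind="stable")[:npix]
            chosen = (rows[order] + r0, cols[order] + c0)
        if chosen is None or len(chosen[0]) == 0:
            warnings.warn("no free pixels left to paint a patch; skipping",
                          stacklevel=2)
            continue
        rows_c, cols_c = chosen
        labelmap[rows_c, cols_c] = CLASS_INDEX[cls_name]
        paintable[rows_c, cols_c] = False
        total = int(round(float(calibration.predict(p_cells[k]))))
        n_got = len(rows_c)
        base, extra = divmod(total, n_got)
        vals = np.full(n_got, base, dtype=float)
        vals[:extra] += 1
        intensity[rows_c, cols_c] += vals
        realized_rows.append({
            "class": cls_name,
            "cells": int(p_cells[k]),
            "area_um2": n_got * px * px,
            "total_intensity": total,
            "cx_um": (np.mean(cols_c) + 0.5) * px,
            "cy_um": (np.mean(rows_c) + 0.5) * px,
        })

    realized = pd.DataFrame(
        realized_rows, columns=["class", "cells", "area_um2",
                                "total_intensity", "cx_um", "cy_um"])

    intensity += background_level
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
        intensity = np.clip(intensity, 0.0, None)

    # probability stack: one-hot ground truth (root pixels presented as PORE,
    # since the classifier never sees the manual root trace)
    stack_labels = labelmap.copy()
    stack_labels[root_mask] = CLASS_INDEX["PORE"]
    if label_flip_rate > 0:
        flip = rng.random((h, w)) < label_flip_rate
        offsets = rng.integers(1, len(CLASS_NAMES), size=(h, w))
        flipped = (stack_labels + offsets) % len(CLASS_NAMES)
        stack_labels = np.where(flip, flipped, stack_labels).astype(np.uint8)
    probstack = np.zeros((len(CLASS_NAMES), h, w), dtype=np.float32)
    for k in range(len(CLASS_NAMES)):
        probstack[k][stack_labels == k] = 1.0

    full_labels = labelmap.copy()
    full_labels[root_mask] = 5  # ROOT overlay
    return intensity, probstack, full_labels, realized


# ---------------------------------------------------------------------------
# scene and cohort assembly

def generate_scene(config: SceneConfig, root_id: int = 0,
                   timepoint_h: float = 24.0, seed: int | None = None,
                   counts: dict | None = None) -> SceneGroundTruth:
    """One single-tile scene: masks, geometry, planted patches, rendering."""
    if seed is None:
        seed = config.seed
    shape = config.tile_shape_px
    particle_mask, achieved = generate_particles(
        config, substream(seed, "particles", root_id), shape)
    geometry, root_mask = generate_root(
        config, substream(seed, "root", root_id), shape)
    particle_mask &= ~root_mask  # root trace overrides particles
    planted = place_patches(config, particle_mask, root_mask, geometry,
                            timepoint_h,
                            substream(seed, "patches", root_id, timepoint_h),
                            counts=counts)
    intensity, probstack, labelmap, realized = render_scene(
        planted, particle_mask, root_mask, config.calibration(),
        config.pixel_size_um, substream(seed, "render", root_id, timepoint_h),
        config.background_level, config.noise_sd, config.label_flip_rate)
    pore_mask = ~particle_mask & ~root_mask
    gt = _attach_covariates(realized, particle_mask, root_mask, geometry,
                            config.pixel_size_um)
    gt.insert(0, "timepoint_h", timepoint_h)
    gt.insert(0, "tile_id", 0)
    gt.insert(0, "root_id", root_id)
    return SceneGroundTruth(
        config=config, root_id=root_id, tile_id=0, timepoint_h=timepoint_h,
        intensity=intensity, probstack=probstack, labelmap=labelmap,
        particle_mask=particle_mask, root_mask=root_mask, pore_mask=pore_mask,
        geometry=geometry, patches=gt, achieved_packing=achieved, seed=seed)


def _attach_covariates(realized: pd.DataFrame, particle_mask, root_mask,
                       geometry, pixel_size_um) -> pd.DataFrame:
    out = realized.copy()
    if len(out) == 0:
        for c in ("dp_um", "dr_um", "da_um"):
            out[c] = pd.Series(dtype=float)
        return out
    calc = CovariateCalculator(particle_mask, root_mask, geometry, pixel_size_um)
    cov = calc(out[["cx_um", "cy_um"]].to_numpy())
    out["dp_um"], out["dr_um"], out["da_um"] = cov[:, 0], cov[:, 1], cov[:, 2]
    return out


def write_scene_dir(scene: SceneGroundTruth, out_dir: str | Path) -> None:
    """Write one tile's artifact set (TIFFs, geometry, config, ground truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "intensity.tif",
                     np.clip(np.round(scene.intensity), 0, 65535).astype(np.uint16))
    tifffile.imwrite(out_dir / "probstack.tif", scene.probstack)
    scene.geometry.to_json(out_dir / "root_geometry.json")
    meta = {
        "pixel_size_um": scene.config.pixel_size_um,
        "root_id": scene.root_id,
        "tile_id": scene.tile_id,
        "timepoint_h": scene.timepoint_h,
        "seed": scene.seed,
        "achieved_packing": scene.achieved_packing,
        "tile_width_mm": scene.config.tile_width_mm,
        "tile_height_mm": scene.config.tile_height_mm,
    }
    (out_dir / "scene_config.json").write_text(json.dumps(meta, indent=1))
    scene.patches.to_csv(out_dir / "ground_truth_patches.csv", index=False)


def _window_geometry(geometry: RootGeometry, y_offset_um: float) -> RootGeometry:
    """Translate whole-root geometry into tile-local coordinates.

    Arc lengths stay global, so da keeps meaning distance from the root tip
    even on tiles that do not contain the tip.
    """
    shift = np.array([0.0, y_offset_um])
    return RootGeometry(centreline=geometry.centreline - shift,
                        boundary=geometry.boundary - shift,
                        tip=geometry.tip - shift,
                        arc_length=geometry.arc_length.copy())


def generate_cohort(config: SceneConfig, out_dir: str | Path | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Full synthetic dataset: n_roots × timepoints × 2–6 tiles per root.

    Each root occupies a vertical column of tiles imaged from the tip (tile
    0, bottom) to the mature zone; soil and root geometry are generated once
    per root on the whole column and cropped into tiles; patches are planted
    per timepoint.  Writes the dataset tree ``root_<k>/t<h>/tile_<j>/...``
    when ``out_dir`` is given and returns the cohort ground-truth table.
    """
    if seed is None:
        seed = config.seed
    tile_h, tile_w = config.tile_shape_px
    px = config.pixel_size_um
    all_rows = []
    for root_id in range(config.n_roots):
        rng_root = substream(seed, "layout", root_id)
        lo, hi = config.tiles_per_root_range
        n_tiles = int(rng_root.integers(lo, hi + 1))
        canvas = (n_tiles * tile_h, tile_w)
        particle_mask, achieved = generate_particles(
            config, substream(seed, "particles", root_id), canvas)
        geometry, root_mask = generate_root(
            config, substream(seed, "root", root_id), canvas)
        particle_mask &= ~root_mask
        for t in config.timepoints_h:
            planted = place_patches(
                config, particle_mask, root_mask, geometry, t,
                substream(seed, "patches", root_id, t), n_tiles=n_tiles)
            intensity, probstack, labelmap, realized = render_scene(
                planted, particle_mask, root_mask, config.calibration(), px,
                substream(seed, "render", root_id, t),
                config.background_level, config.noise_sd,
                config.label_flip_rate)
            root_all = labelmap == 5
            for j in range(n_tiles):
                # tile 0 = tip tile (bottom of the canvas)
                r1 = canvas[0] - j * tile_h
                r0 = r1 - tile_h
                y_off = r0 * px
                tile_pm = particle_mask[r0:r1]
                tile_rm = root_all[r0:r1]
                geom_tile = _window_geometry(geometry, y_off)
                in_tile = ((realized["cy_um"] >= y_off)
                           & (realized["cy_um"] < r1 * px))
                local = realized[in_tile].copy()
                local["cy_um"] = local["cy_um"] - y_off
                gt = _attach_covariates(local, tile_pm, tile_rm, geom_tile, px)
                gt.insert(0, "timepoint_h", t)
                gt.insert(0, "tile_id", j)
                gt.insert(0, "root_id", root_id)
                all_rows.append(gt)
                if out_dir is not None:
                    scene = SceneGroundTruth(
                        config=config, root_id=root_id, tile_id=j,
                        timepoint_h=t,
                        intensity=intensity[r0:r1],
                        probstack=probstack[:, r0:r1],
                        labelmap=labelmap[r0:r1],
                        particle_mask=tile_pm, root_mask=tile_rm,
                        pore_mask=~tile_pm & ~tile_rm,
                        geometry=geom_tile, patches=gt,
                        achieved_packing=achieved, seed=seed)
                    write_scene_dir(
                        scene,
                        Path(out_dir) / f"root_{root_id}" / f"t{int(t)}"
                        / f"tile_{j}")
    cohort = pd.concat(all_rows, ignore_index=True) if all_rows else \
        pd.DataFrame()
    if out_dir is not None and len(cohort):
        cohort.to_csv(Path(out_dir) / "ground_truth_patches.csv", index=False)
        (Path(out_dir) / "cohort_config.json").write_text(json.dumps(
            {"seed": seed, "n_roots": config.n_roots,
             "timepoints_h": list(config.timepoints_h),
             "pixel_size_um": config.pixel_size_um}, indent=1))
    return cohort


def root_lengths_mm(config: SceneConfig, seed: int | None = None) -> dict:
    """Centreline length (mm) of every root in the cohort layout."""
    if seed is None:
        seed = config.seed
    tile_h, tile_w = config.tile_shape_px
    out = {}
    for root_id in range(config.n_roots):
        rng_root = substream(seed, "layout", root_id)
        lo, hi = config.tiles_per_root_range
        n_tiles = int(rng_root.integers(lo, hi + 1))
        canvas = (n_tiles * tile_h, tile_w)
        geometry, _ = generate_root(config, substream(seed, "root", root_id),
                                    canvas)
        out[root_id] = geometry.length_um / 1000.0
    return out
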