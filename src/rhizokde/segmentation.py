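"""Scene labelling and patch extraction.

Turns per-pixel class-probability stacks plus a manually traced root geometry
into a labelled scene, then decomposes each bacterial class mask into compact
*patches* (watershed regions) carrying an area, a mean fluorescence intensity
and a spatial covariate vector ``x = (dp, dr, da)``:

``dp``  Euclidean distance (µm) to the nearest soil-particle surface,
``dr``  Euclidean distance (µm) to the nearest root surface,
``da``  arc length (µm) along the traced root centreline from the root tip.

Conventions: arrays are indexed ``[row, col]``; physical coordinates are
``(x, y)`` in µm with pixel ``(0, 0)`` at top-left and pixel centers at
``(col + 0.5, row + 0.5) * pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, local_maxima
from skimage.segmentation import watershed as _skimage_watershed

#: Segmentation classes, in fixed order. The order is also the argmax
#: tie-break order (lowest index wins).
CLASS_NAMES = ("PARTICLE", "PORE", "MB", "RB", "PB")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}
#: Manual root tracing overrides classifier output; encoded past the 5 classes.
ROOT_LABEL = 5
BACTERIAL_CLASSES = ("MB", "RB", "PB")

#: Columns of the patches.csv interchange table.
PATCH_COLUMNS = [
    "patch_id", "root_id", "tile_id", "timepoint_h", "class",
    "area_um2", "mean_intensity", "cx_um", "cy_um",
    "dp_um", "dr_um", "da_um",
]


@dataclass
class PixelGrid:
    """A 2-D scalar field with physical pixel size."""

    data: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("PixelGrid data must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PixelGrid values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def points_to_indices(self, points_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (x, y) µm points to (row, col) pixel indices; errors if outside."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        cols = np.floor(pts[:, 0] / self.pixel_size_um).astype(int)
        rows = np.floor(pts[:, 1] / self.pixel_size_um).astype(int)
        h, w = self.shape
        if np.any((rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)):
            raise ValueError("point outside grid")
        return rows, cols


@dataclass
class ClassProbabilityStack:
    """Per-pixel probabilities for the five segmentation classes."""

    probs: np.ndarray  # (5, H, W)
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[0] != len(CLASS_NAMES):
            raise ValueError(f"probability stack must have {len(CLASS_NAMES)} pages")
        if np.any(np.isnan(self.probs)):
            raise ValueError("NaN probabilities in stack")
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")


@dataclass
class RootGeometry:
    """Traced root: ordered centreline from the tip plus a boundary polygon.

    ``arc_length[i]`` is the cumulative distance (µm) of ``centreline[i]``
    from the root tip along the trace.  For a geometry windowed to one image
    tile the arc lengths keep their whole-root values (the tip itself may lie
    outside the tile), so ``da`` always means distance from the *root* tip.
    """

    centreline: np.ndarray          # (n, 2) µm, ordered tip-first
    boundary: np.ndarray            # (m, 2) µm, closed (first == last vertex)
    tip: np.ndarray = None          # (2,) µm; defaults to centreline[0]
    arc_length: np.ndarray = None   # (n,) µm; computed if omitted

    def __post_init__(self) -> None:
        self.centreline = np.asarray(self.centreline, dtype=float)
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.centreline.ndim != 2 or self.centreline.shape[0] < 2:
            raise ValueError("centreline needs at least 2 vertices")
        if self.tip is None:
            self.tip = self.centreline[0].copy()
        self.tip = np.asarray(self.tip, dtype=float)
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.centreline, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc lengths must be strictly increasing")

    @property
    def length_um(self) -> float:
        return float(self.arc_length[-1])

    def resampled(self, spacing_um: float) -> tuple[np.ndarray, np.ndarray]:
        """Centreline resampled to ~uniform spacing; returns (points, s)."""
        s = self.arc_length
        n = max(2, int(np.ceil((s[-1] - s[0]) / spacing_um)) + 1)
        si = np.linspace(s[0], s[-1], n)
        x = np.interp(si, s, self.centreline[:, 0])
        y = np.interp(si, s, self.centreline[:, 1])
        return np.column_stack([x, y]), si

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centreline_um": self.centreline.tolist(),
            "arc_length_um": self.arc_length.tolist(),
            "boundary_um": self.boundary.tolist(),
            "tip_um": self.tip.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RootGeometry":
        d = json.loads(Path(path).read_text())
        return cls(
            centreline=np.asarray(d["centreline_um"]),
            boundary=np.asarray(d["boundary_um"]),
            tip=np.asarray(d["tip_um"]),
            arc_length=np.asarray(d["arc_length_um"]),
        )


def argmax_classify(stack: ClassProbabilityStack) -> np.ndarray:
    """Label each pixel with its maximum-probability class.

    Ties break by fixed class order PARTICLE < PORE < MB < RB < PB (argmax
    returns the first maximum).  Returns an int label map without ROOT.
    """
    return np.argmax(stack.probs, axis=0).astype(np.uint8)


def rasterize_root(geometry: RootGeometry, shape: tuple[int, int],
                   pixel_size_um: float) -> np.ndarray:
    """Rasterize the boundary polygon: pixels whose centers fall inside.

    Uses the even-odd rule on the closed polygon.  Raises if the polygon is
    empty or not explicitly closed (first vertex must equal last).
    """
    poly = np.asarray(geometry.boundary, dtype=float)
    if poly.size == 0:
        raise ValueError("empty boundary polygon")
    if poly.shape[0] < 4 or not np.allclose(poly[0], poly[-1]):
        raise ValueError("boundary polygon must be closed (first vertex == last)")
    h, w = shape
    xs = (np.arange(w) + 0.5) * pixel_size_um
    ys = (np.arange(h) + 0.5) * pixel_size_um
    gx, gy = np.meshgrid(xs, ys)
    polygon = shapely.Polygon(poly)
    inside = shapely.contains_xy(polygon, gx.ravel(), gy.ravel())
    return inside.reshape(h, w)


def overlay_root(labelmap: np.ndarray, root_mask: np.ndarray) -> np.ndarray:
    """ROOT overrides any classifier label inside the traced polygon."""
    out = labelmap.astype(np.uint8).copy()
    out[root_mask] = ROOT_LABEL
    return out


def watershed_decompose(class_mask: np.ndarray,
                        intensity: PixelGrid | None = None,
                        min_seed_separation_px: int = 3) -> np.ndarray:
    """Split a binary class mask into compact regions by shape.

    Seeds are regional maxima of the Euclidean distance transform of the mask
    (minimum separation ``min_seed_separation_px``); flooding runs on the
    negated distance transform, so merged blobs split at their necks while a
    single convex blob passes through unchanged.  Returns an int label image
    (0 = background) whose labelled pixels exactly partition the mask.
    """
    mask = np.asarray(class_mask, dtype=bool)
    if intensity is not None and intensity.shape != mask.shape:
        raise ValueError("mask and intensity grids have different shapes")
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    dt = ndimage.distance_transform_edt(mask)
    # true regional maxima of the distance transform (plateaus adjacent to
    # higher values excluded), merged when closer than the seed separation
    maxima = local_maxima(dt) & mask
    if min_seed_separation_px > 1:
        maxima = ndimage.binary_dilation(
            maxima, structure=disk(min_seed_separation_px))
    markers, _ = ndimage.label(maxima, structure=np.ones((3, 3), bool))
    labels = _skimage_watershed(-dt, markers, mask=mask)
    # Plateau-only components can end up without a peak; keep them whole.
    missed = mask & (labels == 0)
    if missed.any():
        extra = cc_label(missed, connectivity=2)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    return labels


class CovariateCalculator:
    """Precomputed distance-transform maps and centreline lookup for a scene.

    ``dp``/``dr`` are sampled from the Euclidean distance transforms of the
    particle/root mask complements (zero on or inside the mask); ``da`` is the
    arc length of the nearest vertex of the centreline resampled to one-pixel
    spacing.
    """

    def __init__(self, particle_mask: np.ndarray, root_mask: np.ndarray,
                 geometry: RootGeometry, pixel_size_um: float):
        self.pixel_size_um = float(pixel_size_um)
        self.shape = particle_mask.shape
        self.dp_map = ndimage.distance_transform_edt(~np.asarray(particle_mask, bool))
        self.dp_map *= self.pixel_size_um
        self.dr_map = ndimage.distance_transform_edt(~np.asarray(root_mask, bool))
        self.dr_map *= self.pixel_size_um
        pts, s = geometry.resampled(self.pixel_size_um)
        self._tree = cKDTree(pts)
        self._s = s

    def __call__(self, points_um: np.ndarray) -> np.ndarray:
        """Covariates at (x, y) µm points; returns (n, 3) array of (dp, dr, da)."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        grid = PixelGrid(np.zeros(self.shape), self.pixel_size_um)
        rows, cols = grid.points_to_indices(pts)
        dp = self.dp_map[rows, cols]
        dr = self.dr_map[rows, cols]
        _, idx = self._tree.query(pts)
        da = self._s[idx]
        return np.column_stack([dp, dr, da])


def compute_covariates(point_um, particle_mask, root_mask,
                       geometry: RootGeometry, pixel_size_um: float):
    """(dp, dr, da) in µm at a single (x, y) µm point."""
    calc = CovariateCalculator(particle_mask, root_mask, geometry, pixel_size_um)
    return tuple(calc(point_um)[0])


def extract_patches(labels: np.ndarray, class_name: str, intensity: PixelGrid,
                    covariates: CovariateCalculator, timepoint_h: float,
                    root_id, tile_id, min_area_px: int = 4) -> pd.DataFrame:
    """Patch table for one class's watershed label image.

    Per region: ``area_um2`` = pixel count × pixel area, ``mean_intensity`` =
    mean image intensity over the region, centroid = unweighted pixel-center
    mean.  Regions below ``min_area_px`` pixels are dropped as segmentation
    noise.
    """
    px = intensity.pixel_size_um
    rows = []
    for rp in regionprops(labels, intensity_image=intensity.data):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid  # (row, col)
        cx_um = (cx + 0.5) * px
        cy_um = (cy + 0.5) * px
        dp, dr, da = covariates([(cx_um, cy_um)])[0]
        rows.append({
            "patch_id": rp.label, "root_id": root_id, "tile_id": tile_id,
            "timepoint_h": timepoint_h, "class": class_name,
            "area_um2": rp.area * px * px,
            "mean_intensity": float(rp.intensity_mean),
            "cx_um": cx_um, "cy_um": cy_um,
            "dp_um": dp, "dr_um": dr, "da_um": da,
        })
    if not rows:
        return _empty_patch_frame()
    return pd.DataFrame(rows, columns=PATCH_COLUMNS)


def _empty_patch_frame() -> pd.DataFrame:
    dtypes = {c: float for c in PATCH_COLUMNS}
    dtypes.update(patch_id=int, root_id=object, tile_id=object,
                  **{"class": object})
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in dtypes.items()})


def segment_scene(scene_dir: str | Path, timepoint_h: float | None = None,
                  root_id=None, tile_id=None,
                  min_area_px: int = 4) -> pd.DataFrame:
    """Full per-tile pipeline: read artifacts, label, decompose, extract.

    Expects ``probstack.tif``, ``intensity.tif``, ``root_geometry.json`` and
    ``scene_config.json`` in ``scene_dir`` (the synthetic generator's layout).
    Returns the patch table for the three bacterial classes.
    """
    scene_dir = Path(scene_dir)
    for name in ("probstack.tif", "intensity.tif", "root_geometry.json"):
        if not (scene_dir / name).exists():
            raise FileNotFoundError(f"missing upstream artifact: {scene_dir / name}")
    meta = json.loads((scene_dir / "scene_config.json").read_text())
    px = float(meta["pixel_size_um"])
    if timepoint_h is None:
        timepoint_h = meta.get("timepoint_h")
    if root_id is None:
        root_id = meta.get("root_id")
    if tile_id is None:
        tile_id = meta.get("tile_id")

    probs = tifffile.imread(scene_dir / "probstack.tif").astype(float)
    stack = ClassProbabilityStack(probs, px)
    intensity = PixelGrid(tifffile.imread(scene_dir / "intensity.tif").astype(float), px)
    geometry = RootGeometry.from_json(scene_dir / "root_geometry.json")

    labelmap = argmax_classify(stack)
    root_mask = rasterize_root(geometry, labelmap.shape, px)
    labelmap = overlay_root(labelmap, root_mask)
    particle_mask = labelmap == CLASS_INDEX["PARTICLE"]
    calc = CovariateCalculator(particle_mask, root_mask, geometry, px)

    frames = []
    for cls in BACTERIAL_CLASSES:
        mask = labelmap == CLASS_INDEX[cls]
        labels = watershed_decompose(mask, intensity)
        frames.append(extract_patches(labels, cls, intensity, calc,
                                      timepoint_h, root_id, tile_id,
                                      min_area_px=min_area_px))
    out = pd.concat(frames, ignore_index=True)
    out["patch_id"] = np.arange(1, len(out) + 1)
    return out
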