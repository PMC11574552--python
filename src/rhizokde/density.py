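"""Weighted Parzen-window density model of bacterial occupancy.

The probability density of finding a bacterium at position ``x`` in covariate
space (any subset of ``dp``, ``dr``, ``da``) is estimated from N detected
patches as

    p~(x) = (1/M) Σ_i A_i I_i K(x − x_i; h_i),     M = Σ_i A_i I_i,

where ``A_i`` is the patch area (µm²), ``I_i`` its mean fluorescence, and K a
top-hat (Parzen) kernel constant inside the ellipsoid ``Σ_j (u_j/h_j)² ≤ 1``
and zero outside, normalized to unit integral:

    K(u; h) = C = 1 / (V_n Π_j h_j)   inside,   V_1=2, V_2=π, V_3=4π/3.

The bandwidth is isotropic and set to the patch radius, h_i = √(A_i/π).
A *null* model applies the same machinery to every pixel of a support class
(typically the pore space) with unit weight, giving the density expected if
all of that space were equally likely to be occupied.  The mean cell density
is ρ(x) = p~(x)·Q̄ with Q̄ the average calibrated bacterial quantity per root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import (
    CLASS_INDEX,
    CovariateCalculator,
    RootGeometry,
)

COVARIATE_COLUMNS = {"dp": "dp_um", "dr": "dr_um", "da": "da_um"}

#: Default bandwidth floor: one pixel-equivalent at the default 6.21 µm/px
#: resolution, so no kernel has (near-)zero measure.
DEFAULT_H_FLOOR_UM = 6.21


def unit_ball_volume(n: int) -> float:
    """Volume of the n-dimensional unit ball, n ∈ {1, 2, 3}."""
    if n not in (1, 2, 3):
        raise ValueError("kernel dimensionality must be 1, 2 or 3")
    return {1: 2.0, 2: math.pi, 3: 4.0 * math.pi / 3.0}[n]


def kernel_value(u, h) -> np.ndarray | float:
    """Top-hat ellipsoid kernel K(u; h), unit integral.

    ``u``: offset vector(s) (µm), shape (n,) or (m, n); ``h``: bandwidth
    vector (µm), all entries > 0.  Returns C = 1/(V_n Π h_j) where
    Σ (u_j/h_j)² ≤ 1 (boundary counts as inside), else 0.
    """
    u = np.asarray(u, dtype=float)
    h = np.asarray(h, dtype=float)
    scalar = u.ndim == 1
    u = np.atleast_2d(u)
    n = u.shape[1]
    if h.ndim == 0:
        h = np.full(n, float(h))
    if np.any(h <= 0):
        raise ValueError("bandwidths must be > 0")
    c = 1.0 / (unit_ball_volume(n) * np.prod(h))
    inside = np.sum((u / h) ** 2, axis=1) <= 1.0
    out = np.where(inside, c, 0.0)
    return float(out[0]) if scalar else out


@dataclass
class GridSpec:
    """Evaluation grid in covariate space: per-axis bin edges, named axes."""

    names: tuple[str, ...]
    edges: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        if len(self.names) != len(self.edges):
            raise ValueError("one edge array per axis required")
        for e in self.edges:
            if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be increasing 1-D arrays")

    @property
    def ndim(self) -> int:
        return len(self.names)

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @property
    def widths(self) -> tuple[np.ndarray, ...]:
        return tuple(np.diff(e) for e in self.edges)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    def cell_volumes(self) -> np.ndarray:
        vols = np.array(1.0)
        for w in self.widths:
            vols = np.multiply.outer(vols, w)
        return vols


def default_grid(covariates: tuple[str, ...]) -> GridSpec:
    """dp, dr ∈ [0, 500] µm at 10 µm bins; da ∈ [0, 10000] µm at 500 µm bins."""
    edges = []
    for name in covariates:
        if name in ("dp", "dr"):
            edges.append(np.arange(0.0, 500.0 + 1e-9, 10.0))
        elif name == "da":
            edges.append(np.arange(0.0, 10000.0 + 1e-9, 500.0))
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return GridSpec(tuple(covariates), tuple(edges))


@dataclass
class DensityField:
    """Gridded estimate of p~ over a covariate subspace.

    ``values`` holds the density (µm⁻ⁿ) at grid-cell centers.  ``coverage``
    is the Riemann sum over the grid: it falls below 1 exactly by the mass of
    kernel support overhanging the grid or the unattainable covariate region
    (no boundary renormalization is applied).
    """

    grid: GridSpec
    values: np.ndarray
    M: float                 # total fluorescence weight Σ A_i I_i
    N: int                   # number of patches
    kind: str = "model"      # "model" | "null" | "empty"
    meta: dict = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        return float(np.sum(self.values * self.grid.cell_volumes()))

    def riemann_sum(self) -> float:
        return self.coverage

    def marginal(self, name: str) -> "DensityField":
        """Integrate out every axis except ``name``."""
        axis_keep = self.grid.names.index(name)
        vals = self.values
        for ax in reversed(range(self.grid.ndim)):
            if ax == axis_keep:
                continue
            vals = np.sum(vals * self.grid.widths[ax].reshape(
                [-1 if k == ax else 1 for k in range(vals.ndim)]), axis=ax)
        return DensityField(GridSpec((name,), (self.grid.edges[axis_keep],)),
                            vals, self.M, self.N, self.kind, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        mesh = np.meshgrid(*self.grid.centers, indexing="ij")
        d = {f"{n}_center": m.ravel() for n, m in zip(self.grid.names, mesh)}
        d["density"] = self.values.ravel()
        return pd.DataFrame(d)


def _patch_arrays(patches: pd.DataFrame, covariates: tuple[str, ...]):
    cols = [COVARIATE_COLUMNS[c] for c in covariates]
    missing = [c for c in cols if c not in patches.columns]
    if missing:
        raise ValueError(f"patches lack covariate columns {missing}")
    x = patches[cols].to_numpy(dtype=float)
    a = patches["area_um2"].to_numpy(dtype=float)
    i = patches["mean_intensity"].to_numpy(dtype=float)
    return x, a, i


def estimate_density(patches: pd.DataFrame, covariates: tuple[str, ...] = ("dp", "dr"),
                     grid: GridSpec | None = None,
                     h_floor_um: float = DEFAULT_H_FLOOR_UM,
                     weights: np.ndarray | None = None,
                     bandwidths: np.ndarray | None = None) -> DensityField:
    """Weighted Parzen-window estimate of p~ on a covariate grid.

    Each patch contributes its fluorescence weight ``A_i I_i / M`` spread
    uniformly over the ellipsoid of radius ``h_i = max(√(A_i/π), h_floor)``
    centred at its covariate vector; the field is evaluated at grid-cell
    centers.  ``weights``/``bandwidths`` override the defaults (used by the
    null model's unit-weight pseudo-patches).
    """
    if len(patches) == 0:
        raise ValueError("at least one patch is required")
    covariates = tuple(covariates)
    if grid is None:
        grid = default_grid(covariates)
    if grid.names != covariates:
        raise ValueError("grid axes do not match requested covariates")
    x, a, i = _patch_arrays(patches, covariates)
    w = a * i if weights is None else np.asarray(weights, dtype=float)
    h = np.sqrt(a / math.pi) if bandwidths is None else np.asarray(bandwidths, float)
    h = np.maximum(h, h_floor_um)

    # canonical accumulation order: the estimate is a sum, so sorting makes
    # the field (and M) bit-identical under any permutation of the table
    order = np.lexsort((w, h) + tuple(x[:, ax] for ax in range(x.shape[1] - 1, -1, -1)))
    x, w, h = x[order], w[order], h[order]
    m = float(w.sum())
    if m <= 0:
        raise ValueError(
            "degenerate weighting: total fluorescence M = Σ A_i·I_i is zero")

    n = len(covariates)
    c_norm = 1.0 / (unit_ball_volume(n) * h ** n)
    centers = grid.centers
    values = np.zeros(grid.shape, dtype=float)
    cell_vols = grid.cell_volumes()
    min_width = min(float(wd.min()) for wd in grid.widths)

    def deposit_point_mass(k) -> None:
        """Sub-grid kernel: all of the patch's weight lands in its cell."""
        idx = []
        for ax in range(n):
            e = grid.edges[ax]
            if not e[0] <= x[k, ax] <= e[-1]:
                return  # outside the grid; counts as truncation
            idx.append(min(int(np.searchsorted(e, x[k, ax], side="right")) - 1,
                           len(e) - 2))
        idx = tuple(idx)
        values[idx] += (w[k] / m) / cell_vols[idx]

    # Each kernel is evaluated only on the grid cells its support can touch.
    # Kernels narrower than the grid resolution would cover no cell center
    # and silently lose their mass, so they (and any kernel that covers no
    # center) deposit their full weight into the containing cell instead.
    tiny = 2.0 * h <= min_width
    if tiny.any():
        flat = np.zeros(values.size, dtype=float)
        in_grid = np.ones(int(tiny.sum()), dtype=bool)
        idx_nd = []
        for ax in range(n):
            e = grid.edges[ax]
            xi = x[tiny, ax]
            in_grid &= (xi >= e[0]) & (xi <= e[-1])
            idx_nd.append(np.minimum(np.searchsorted(e, xi, side="right") - 1,
                                     len(e) - 2))
        lin = np.ravel_multi_index([np.maximum(ix, 0) for ix in idx_nd],
                                   grid.shape)
        np.add.at(flat, lin[in_grid], (w[tiny][in_grid] / m))
        values += flat.reshape(grid.shape) / cell_vols

    for k in np.nonzero(~tiny)[0]:
        sq = None
        idx_ranges = []
        ok = True
        for ax in range(n):
            lo = np.searchsorted(centers[ax], x[k, ax] - h[k], side="left")
            hi = np.searchsorted(centers[ax], x[k, ax] + h[k], side="right")
            if lo >= hi:
                ok = False
                break
            idx_ranges.append((lo, hi))
        if not ok:
            deposit_point_mass(k)
            continue
        for ax, (lo, hi) in enumerate(idx_ranges):
            d = (centers[ax][lo:hi] - x[k, ax]) / h[k]
            term = (d * d).reshape([-1 if j == ax else 1 for j in range(n)])
            sq = term if sq is None else sq + term
        inside = sq <= 1.0
        if inside.any():
            region = tuple(slice(lo, hi) for lo, hi in idx_ranges)
            values[region] += np.where(inside, (w[k] / m) * c_norm[k], 0.0)
        else:
            deposit_point_mass(k)

    return DensityField(grid, values, M=m, N=len(w),
                        meta={"h_floor_um": h_floor_um,
                              "covariates": list(covariates)})


def null_model(labelmap: np.ndarray, particle_mask: np.ndarray,
               root_mask: np.ndarray, geometry: RootGeometry,
               pixel_size_um: float, support_class: str = "PORE",
               covariates: tuple[str, ...] = ("dp", "dr"),
               grid: GridSpec | None = None, subsample: float = 1.0,
               seed: int | None = None) -> DensityField:
    """Density expected if every pixel of a support class were equally likely.

    Each support pixel becomes a pseudo-patch of pixel area, unit intensity,
    and bandwidth equal to the pixel radius √(pixel_area/π); the estimator is
    then identical to :func:`estimate_density`.  ``subsample`` (0, 1] keeps a
    seeded uniform fraction of the support pixels for tractability.
    """
    if support_class == "ROOT":
        support = np.asarray(root_mask, bool)
    elif support_class in CLASS_INDEX:
        support = np.asarray(labelmap) == CLASS_INDEX[support_class]
    else:
        raise ValueError(f"unknown support class {support_class!r}")
    rows, cols = np.nonzero(support)
    if len(rows) == 0:
        raise ValueError(f"support class {support_class!r} is empty")
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    if subsample < 1.0:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(rows)) < subsample
        rows, cols = rows[keep], cols[keep]
    pts = np.column_stack([(cols + 0.5) * pixel_size_um,
                           (rows + 0.5) * pixel_size_um])
    calc = CovariateCalculator(particle_mask, root_mask, geometry, pixel_size_um)
    cov = calc(pts)
    table = pd.DataFrame({
        "dp_um": cov[:, 0], "dr_um": cov[:, 1], "da_um": cov[:, 2],
        "area_um2": pixel_size_um ** 2, "mean_intensity": 1.0,
    })
    h_pix = pixel_size_um / math.sqrt(math.pi)
    out = estimate_density(table, covariates, grid, h_floor_um=h_pix)
    out.kind = "null"
    out.meta.update(support_class=support_class, subsample=subsample)
    return out


@dataclass
class CellDensityField:
    """ρ(x) = p~(x)·Q̄ — mean bacterial cells per µmⁿ of covariate space."""

    grid: GridSpec
    values: np.ndarray
    Q_bar: float    # average calibrated cells per root
    R: int          # number of roots
    base: DensityField = None

    def riemann_sum(self) -> float:
        return float(np.sum(self.values * self.grid.cell_volumes()))


def mean_cell_density(pfield: DensityField, patches: pd.DataFrame,
                      calibration, R: int,
                      pixel_size_um: float) -> CellDensityField:
    """Scale p~ by the average calibrated bacterial quantity per root.

    Q̄ = (Σ over patches of calibrated cell count) / R.
    """
    if R <= 0:
        raise ValueError("R (number of roots) must be positive")
    from .metrics import intensity_to_cells
    cells = intensity_to_cells(patches, calibration, pixel_size_um)
    q_bar = float(np.sum(cells)) / R
    return CellDensityField(pfield.grid, pfield.values * q_bar,
                            Q_bar=q_bar, R=R, base=pfield)


def temporal_density(patches: pd.DataFrame,
                     covariates: tuple[str, ...] = ("dp", "dr"),
                     grid: GridSpec | None = None,
                     timepoints: list[float] | None = None,
                     h_floor_um: float = DEFAULT_H_FLOOR_UM,
                     ) -> dict[float, DensityField]:
    """One independently normalized density field per timepoint, shared grid."""
    covariates = tuple(covariates)
    if grid is None:
        grid = default_grid(covariates)
    if timepoints is None:
        timepoints = sorted(patches["timepoint_h"].unique())
    out: dict[float, DensityField] = {}
    for t in timepoints:
        sub = patches[patches["timepoint_h"] == t]
        if len(sub) == 0 or float((sub["area_um2"] * sub["mean_intensity"]).sum()) <= 0:
            out[t] = DensityField(grid, np.zeros(grid.shape), M=0.0, N=0,
                                  kind="empty")
        else:
            out[t] = estimate_density(sub, covariates, grid, h_floor_um)
    return out


class ParzenDensityModel:
    """Bacterial-occupancy density model, statsmodels-style.

    Built from a patch table (the ``patches.csv`` interchange format); ``fit``
    evaluates the weighted Parzen estimator on the covariate grid and returns
    a :class:`ParzenDensityResults`.

    Parameters
    ----------
    patches : DataFrame
        Patch table with ``area_um2``, ``mean_intensity`` and covariate
        columns ``dp_um``/``dr_um``/``da_um``.
    covariates : tuple of str
        Covariate subspace to model, e.g. ``("dp", "dr")``.
    grid : GridSpec, optional
        Evaluation grid; the field's documented default otherwise.
    class_name : str, optional
        Restrict to one bacterial class (MB, RB or PB).
    """

    def __init__(self, patches: pd.DataFrame,
                 covariates: tuple[str, ...] = ("dp", "dr"),
                 grid: GridSpec | None = None,
                 class_name: str | None = None,
                 h_floor_um: float = DEFAULT_H_FLOOR_UM):
        if class_name is not None:
            patches = patches[patches["class"] == class_name]
        self.patches = patches.reset_index(drop=True)
        self.covariates = tuple(covariates)
        self.grid = grid if grid is not None else default_grid(self.covariates)
        self.class_name = class_name
        self.h_floor_um = h_floor_um

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ParzenDensityModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, by_timepoint: bool = False) -> "ParzenDensityResults":
        if by_timepoint:
            fields = temporal_density(self.patches, self.covariates, self.grid,
                                      h_floor_um=self.h_floor_um)
            return ParzenDensityResults(self, None, temporal=fields)
        field = estimate_density(self.patches, self.covariates, self.grid,
                                 self.h_floor_um)
        return ParzenDensityResults(self, field)


class ParzenDensityResults:
    """Fitted occupancy density: the field(s), diagnostics and reporting."""

    def __init__(self, model: ParzenDensityModel, field: DensityField | None,
                 temporal: dict[float, DensityField] | None = None):
        self.model = model
        self.field = field
        self.temporal = temporal

    def cell_density(self, calibration, R: int,
                     pixel_size_um: float) -> CellDensityField:
        return mean_cell_density(self.field, self.model.patches, calibration,
                                 R, pixel_size_um)

    def summary(self) -> str:
        lines = ["Parzen occupancy density model",
                 "=" * 34,
                 f"covariates:      {', '.join(self.model.covariates)}",
                 f"class:           {self.model.class_name or 'all'}",
                 f"patches (N):     {len(self.model.patches)}"]
        fields = self.temporal if self.temporal is not None else \
            ({None: self.field} if self.field is not None else {})
        for t, f in fields.items():
            tag = "" if t is None else f"  t={t:g} h"
            lines.append(f"M = {f.M:.6g}, grid coverage = {f.coverage:.4f}, "
                         f"kind = {f.kind}{tag}")
        return "\n".join(lines)

    def plot(self, ax=None, timepoint: float | None = None, **imshow_kw):
        """Heatmap (2-D grids) or line plot (1-D) of the density field."""
        import matplotlib.pyplot as plt

        field = self.field if timepoint is None else self.temporal[timepoint]
        if ax is None:
            _, ax = plt.subplots()
        g = field.grid
        if g.ndim == 2:
            extent = (g.edges[0][0], g.edges[0][-1], g.edges[1][0], g.edges[1][-1])
            im = ax.imshow(field.values.T, origin="lower", extent=extent,
                           aspect="auto", **imshow_kw)
            ax.set_xlabel(f"{g.names[0]} (µm)")
            ax.set_ylabel(f"{g.names[1]} (µm)")
            plt.colorbar(im, ax=ax, label="p~ (µm⁻²)")
        elif g.ndim == 1:
            ax.plot(g.centers[0], field.values)
            ax.set_xlabel(f"{g.names[0]} (µm)")
            ax.set_ylabel("p~ (µm⁻¹)")
        else:
            raise ValueError("plotting supports 1-D and 2-D grids only")
        return ax
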