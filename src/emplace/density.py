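"""Density maps and map algebra for low-resolution EM.

A :class:`DensityMap` is a regular 3D grid with isotropic voxels and a physical
origin: array index (i, j, k) sits at ``origin + (i, j, k) * voxel`` in Å
(0-based, voxel-centered).  Axis 0/1/2 of the value array are x/y/z.

Operations: simulation of density from atomic or bead models (isotropic
Gaussians, one per particle, weighted by mass), normalized cross-correlation,
Fourier low-pass filtering, mirroring, cyclic symmetrization, difference
mapping, Fourier shell correlation, and model-vs-map volume coverage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import gemmi
import numpy as np
from scipy import ndimage

from emplace.structures import AtomicModel, BeadModel, RESIDUE_MASS_DA

#: Å^3 of molecular volume per Dalton, for mass-based contour levels
VOLUME_PER_DALTON = 1.21


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined: empty mask or constant values over the mask."""


def gaussian_sigma(resolution: float) -> float:
    """Real-space Gaussian width for a stated resolution.

    sigma = resolution / (pi * sqrt(2)), so the Fourier amplitude of the
    kernel falls to 1/e at spatial frequency 1/resolution.
    """
    return resolution / (np.pi * np.sqrt(2.0))


@dataclass
class DensityMap:
    """Regular 3D density grid with isotropic voxel size and physical origin."""

    values: np.ndarray
    voxel: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    resolution: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("density values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if not (self.voxel > 0):
            raise ValueError("voxel size must be positive")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self, values: np.ndarray | None = None) -> "DensityMap":
        out = dataclasses.replace(self)
        out.values = self.values.copy() if values is None else np.asarray(values)
        return out

    def physical_center(self) -> np.ndarray:
        """Physical position of the grid's geometric center."""
        n = np.asarray(self.shape, dtype=float)
        return np.asarray(self.origin) + (n - 1) / 2.0 * self.voxel

    def index_to_physical(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * self.voxel

    def physical_to_index(self, pos) -> np.ndarray:
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / self.voxel

    def same_grid(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and abs(self.voxel - other.voxel) <= tol
                and np.allclose(self.origin, other.origin, atol=tol))


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O


def read_density(path) -> DensityMap:
    """Read an MRC/CCP4 2014 map.  Axis order is normalized on read."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    m = gemmi.read_ccp4_map(str(path))
    mode = m.header_i32(4)
    if mode not in (0, 1, 2):
        raise ValueError(f"unsupported MRC mode {mode}; expected 0, 1, or 2")
    m.setup(float("nan"))
    values = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    vx = cell.a / m.grid.nu
    vy = cell.b / m.grid.nv
    vz = cell.c / m.grid.nw
    if not (np.isclose(vx, vy, rtol=1e-5) and np.isclose(vx, vz, rtol=1e-5)):
        raise ValueError(f"non-cubic voxels unsupported: {(vx, vy, vz)}")
    origin = (m.header_float(50), m.header_float(51), m.header_float(52))
    if not np.all(np.isfinite(values)):
        raise ValueError(f"map {path} contains non-finite values after setup")
    return DensityMap(values=values, voxel=float(vx), origin=origin)


def write_density(dmap: DensityMap, path) -> None:
    """Write an MRC/CCP4 2014 map (mode 2, float32)."""
    vals = np.ascontiguousarray(dmap.values, dtype=np.float32)
    grid = gemmi.FloatGrid(vals)
    n = dmap.shape
    grid.unit_cell = gemmi.UnitCell(dmap.voxel * n[0], dmap.voxel * n[1],
                                    dmap.voxel * n[2], 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.set_header_float(50, dmap.origin[0])
    m.set_header_float(51, dmap.origin[1])
    m.set_header_float(52, dmap.origin[2])
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# density simulation


def _model_points_weights(model) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(model, BeadModel):
        return model.centers, model.weights
    if isinstance(model, AtomicModel):
        ca = model.ca_model()
        if ca.n_atoms:
            return ca.xyz, np.full(ca.n_atoms, RESIDUE_MASS_DA)
        return model.xyz, np.full(model.n_atoms, RESIDUE_MASS_DA)
    raise TypeError(f"cannot simulate density from {type(model).__name__}")


def stamp_gaussians(values: np.ndarray, origin, voxel: float,
                    points: np.ndarray, weights: np.ndarray, sigma: float,
                    cutoff_sigmas: float = 4.0) -> None:
    """Accumulate normalized isotropic Gaussians into `values` in place.

    Each point contributes ``w * G(|r - c|; sigma)`` with G integrating to 1,
    truncated at `cutoff_sigmas`·sigma.
    """
    origin = np.asarray(origin, dtype=float)
    shape = values.shape
    norm = (2.0 * np.pi) ** -1.5 / sigma**3
    half = int(np.ceil(cutoff_sigmas * sigma / voxel))
    for c, w in zip(points, weights):
        ci = (np.asarray(c) - origin) / voxel
        lo = np.maximum(np.floor(ci).astype(int) - half, 0)
        hi = np.minimum(np.floor(ci).astype(int) + half + 2, shape)
        if np.any(lo >= hi):
            continue
        ax = [(np.arange(lo[d], hi[d]) - ci[d]) * voxel for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            w * norm * np.exp(-0.5 * d2 / sigma**2))


def simulate_density(model, resolution: float, voxel: float,
                     padding: float | None = None,
                     grid_like: DensityMap | None = None,
                     weights: np.ndarray | None = None) -> DensityMap:
    """Simulate a density map from an atomic or bead model.

    Each particle contributes an isotropic Gaussian of width
    sigma = resolution/(pi*sqrt(2)), weighted by its mass and normalized so the
    map integral (× voxel³) equals the total weight.  Without `grid_like`, the
    grid covers the model plus `padding` (default 2 × resolution) on all sides.
    """
    if resolution < 2.0 * voxel:
        raise ValueError("resolution must be at least twice the voxel size")
    points, w = _model_points_weights(model)
    if len(points) == 0:
        raise ValueError("cannot simulate density from an empty model")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(points),):
            raise ValueError("weights length does not match particle count")
    sigma = gaussian_sigma(resolution)
    if grid_like is not None:
        origin = np.asarray(grid_like.origin)
        shape = grid_like.shape
        voxel = grid_like.voxel
    else:
        if padding is None:
            padding = 2.0 * resolution
        lo = points.min(axis=0) - padding
        hi = points.max(axis=0) + padding
        shape = tuple(int(np.ceil((hi[d] - lo[d]) / voxel)) + 1 for d in range(3))
        origin = lo
    values = np.zeros(shape, dtype=float)
    stamp_gaussians(values, origin, voxel, points, w, sigma)
    return DensityMap(values=values, voxel=voxel, origin=tuple(origin),
                      resolution=resolution)


# ---------------------------------------------------------------------------
# correlation


def _resolve_mask(a: np.ndarray, b: np.ndarray, mask) -> np.ndarray:
    if mask is None:
        return np.ones(a.shape, dtype=bool)
    if isinstance(mask, np.ndarray):
        if mask.shape != a.shape:
            raise ValueError("mask shape does not match map shape")
        return mask.astype(bool)
    if mask == "overlap":
        ta = 1e-6 * np.abs(a).max() if a.size else 0.0
        tb = 1e-6 * np.abs(b).max() if b.size else 0.0
        return (np.abs(a) > ta) & (np.abs(b) > tb)
    raise ValueError(f"unknown mask spec {mask!r}")


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError("constant values: correlation undefined")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def normalized_cross_correlation(map_a: DensityMap, map_b: DensityMap,
                                 mask="overlap") -> float:
    """Pearson correlation of two same-grid maps over a mask region.

    mask: 'overlap' (voxels where both maps are nonzero), None (whole grid),
    or an explicit boolean array.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid; resample first")
    m = _resolve_mask(map_a.values, map_b.values, mask)
    if not m.any():
        raise UndefinedCorrelationError("empty mask")
    return pearson(map_a.values[m].ravel().astype(float),
                   map_b.values[m].ravel().astype(float))


def ncc_translation_scan(map_a: DensityMap, map_b: DensityMap) -> np.ndarray:
    """NCC of map_b circularly shifted against map_a, for every integer shift.

    FFT-based: returns an array of the maps' shape where entry (i, j, k) is the
    whole-grid Pearson correlation of map_a with map_b rolled by (i, j, k).
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    a = map_a.values.astype(float)
    b = map_b.values.astype(float)
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError("constant map: correlation undefined")
    # sum_x a(x) * b(x - s) for all circular shifts s, via the correlation theorem
    cross = np.fft.irfftn(np.fft.rfftn(a) * np.conj(np.fft.rfftn(b)),
                          s=a.shape, axes=(0, 1, 2))
    return np.clip(cross / (na * nb), -1.0, 1.0)


# ---------------------------------------------------------------------------
# filtering, mirroring, symmetrization, difference


def lowpass_filter(dmap: DensityMap, resolution: float) -> DensityMap:
    """Gaussian low-pass: Fourier amplitude falls to 1/e at 1/resolution.

    The zero-frequency term is untouched, so the mean value is preserved.
    """
    if resolution < 2.0 * dmap.voxel:
        raise ValueError("resolution must be at least twice the voxel size")
    vals = dmap.values.astype(float)
    f = [np.fft.fftfreq(n, d=dmap.voxel) for n in vals.shape[:2]]
    fz = np.fft.rfftfreq(vals.shape[2], d=dmap.voxel)
    f2 = (f[0][:, None, None] ** 2 + f[1][None, :, None] ** 2
          + fz[None, None, :] ** 2)
    ft = np.fft.rfftn(vals) * np.exp(-f2 * resolution**2)
    out = dmap.copy(values=np.fft.irfftn(ft, s=vals.shape, axes=(0, 1, 2)))
    out.resolution = resolution
    return out


def mirror_map(dmap: DensityMap) -> DensityMap:
    """Reflect the map through the yz-plane through the grid center.

    An involution: mirroring twice returns the original bit-exactly.
    """
    return dmap.copy(values=dmap.values[::-1].copy())


def _rotate_about_axis(values: np.ndarray, axis: np.ndarray, angle: float,
                       center: np.ndarray) -> np.ndarray:
    """Trilinear resample of `values` rotated by `angle` about `axis` through
    `center` (all in index units)."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle)
    idx = np.indices(values.shape, dtype=float).reshape(3, -1).T
    # sample the source at R^-1 (x - c) + c
    src = rot.inv().apply(idx - center) + center
    out = ndimage.map_coordinates(values.astype(float), src.T, order=1,
                                  mode="constant", cval=0.0)
    return out.reshape(values.shape)


def apply_symmetry(dmap: DensityMap, order: int, axis=(0.0, 0.0, 1.0)) -> DensityMap:
    """Average the map over the cyclic group C_order about `axis` through the
    grid center.

    For C2 about a principal grid axis the rotation is an exact index flip
    (no interpolation); general angles use trilinear resampling.
    """
    if order < 2:
        raise ValueError("symmetry order must be >= 2")
    axis = np.asarray(axis, dtype=float)
    vals = dmap.values.astype(float)
    principal = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])]
    unit = axis / np.linalg.norm(axis)
    acc = vals.copy()
    if order == 2 and any(np.allclose(np.abs(unit), p) for p in principal):
        ax_idx = int(np.argmax(np.abs(unit)))
        flip_axes = tuple(d for d in range(3) if d != ax_idx)
        acc += np.flip(vals, axis=flip_axes)
    else:
        center = (np.asarray(vals.shape, dtype=float) - 1) / 2.0
        for k in range(1, order):
            acc += _rotate_about_axis(vals, unit, 2.0 * np.pi * k / order, center)
    return dmap.copy(values=acc / order)


def resample_onto(dmap: DensityMap, grid_like: DensityMap) -> DensityMap:
    """Trilinear resampling of `dmap` onto the grid of `grid_like`."""
    if dmap.same_grid(grid_like):
        return dmap.copy()
    idx = np.indices(grid_like.shape, dtype=float).reshape(3, -1).T
    pos = np.asarray(grid_like.origin) + idx * grid_like.voxel
    src = (pos - np.asarray(dmap.origin)) / dmap.voxel
    vals = ndimage.map_coordinates(dmap.values.astype(float), src.T, order=1,
                                   mode="constant", cval=0.0)
    return DensityMap(values=vals.reshape(grid_like.shape), voxel=grid_like.voxel,
                      origin=grid_like.origin, resolution=dmap.resolution)


def difference_map(map_a: DensityMap, map_b: DensityMap,
                   common_resolution: float = 35.0) -> DensityMap:
    """Difference density A − B after filtering both to a common resolution.

    Both maps are low-passed to `common_resolution`, intensity-normalized to
    zero mean and unit variance over a common support mask (voxels where either
    filtered map exceeds 10% of its maximum), then subtracted voxelwise.
    Stain-EM intensity scales are arbitrary, hence the normalization.
    """
    if not map_a.same_grid(map_b):
        map_b = resample_onto(map_b, map_a)
    fa = lowpass_filter(map_a, common_resolution).values
    fb = lowpass_filter(map_b, common_resolution).values
    support = (fa > 0.1 * fa.max()) | (fb > 0.1 * fb.max())
    if not support.any():
        support = np.ones(fa.shape, dtype=bool)

    def _norm(v):
        mu = v[support].mean()
        sd = v[support].std()
        return (v - mu) if sd == 0 else (v - mu) / sd

    return map_a.copy(values=_norm(fa) - _norm(fb))


# ---------------------------------------------------------------------------
# Fourier shell correlation


@dataclass
class FscCurve:
    """Fourier shell correlation per spatial-frequency shell."""

    frequency: np.ndarray       # shell centers, 1/Å
    correlation: np.ndarray     # per-shell FSC in [-1, 1]
    n_voxels: np.ndarray        # Fourier voxels per shell

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.frequency, self.correlation]),
                   header="frequency_1_per_A\tfsc", delimiter="\t")

    @staticmethod
    def from_text(path) -> "FscCurve":
        arr = np.loadtxt(path)
        return FscCurve(frequency=arr[:, 0], correlation=arr[:, 1],
                        n_voxels=np.zeros(len(arr), dtype=int))


def fsc(map_a: DensityMap, map_b: DensityMap) -> FscCurve:
    """Fourier shell correlation between two same-grid maps.

    Shell width is one Fourier voxel; FSC per shell is the normalized real part
    of the cross-spectrum.
    """
    if not map_a.same_grid(map_b):
        raise ValueError("maps must share a grid")
    fa = np.fft.fftn(map_a.values.astype(float))
    fb = np.fft.fftn(map_b.values.astype(float))
    freqs = [np.fft.fftfreq(n, d=map_a.voxel) for n in map_a.shape]
    fmag = np.sqrt(freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
                   + freqs[2][None, None, :] ** 2)
    # shell index in units of the smallest frequency step
    df = 1.0 / (max(map_a.shape) * map_a.voxel)
    shell = np.round(fmag / df).astype(int)
    nshell = shell.max() + 1
    num = np.bincount(shell.ravel(), weights=(fa * np.conj(fb)).real.ravel(),
                      minlength=nshell)
    da = np.bincount(shell.ravel(), weights=np.abs(fa.ravel()) ** 2, minlength=nshell)
    db = np.bincount(shell.ravel(), weights=np.abs(fb.ravel()) ** 2, minlength=nshell)
    cnt = np.bincount(shell.ravel(), minlength=nshell)
    # keep shells up to Nyquist, skip the DC shell for the curve's start? DC kept:
    denom = np.sqrt(da * db)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    nyq = 1.0 / (2.0 * map_a.voxel)
    f_centers = np.arange(nshell) * df
    keep = (f_centers <= nyq) & (cnt > 0)
    # drop the DC shell (frequency 0) — uninformative offset term
    keep[0] = False
    return FscCurve(frequency=f_centers[keep], correlation=np.clip(corr[keep], -1, 1),
                    n_voxels=cnt[keep])


class ResolutionEstimate(NamedTuple):
    resolution: float    # Å
    crossed: bool        # False when the curve never falls below the threshold


def resolution_at(curve: FscCurve, threshold: float) -> ResolutionEstimate:
    """Resolution (Å) at the first downward crossing of `threshold`.

    Linear interpolation between shells; if the curve never crosses, returns
    the Nyquist wavelength with crossed=False.
    """
    f = curve.frequency
    c = curve.correlation
    for i in range(len(c) - 1):
        if c[i] >= threshold > c[i + 1]:
            frac = (c[i] - threshold) / (c[i] - c[i + 1])
            fx = f[i] + frac * (f[i + 1] - f[i])
            return ResolutionEstimate(resolution=1.0 / fx, crossed=True)
    if len(c) and c[-1] < threshold:
        return ResolutionEstimate(resolution=1.0 / f[0], crossed=True)
    return ResolutionEstimate(resolution=1.0 / f[-1] if len(f) else np.inf,
                              crossed=False)


# ---------------------------------------------------------------------------
# volume coverage


def mass_based_contour(dmap: DensityMap, mass_da: float) -> float:
    """Contour level enclosing a volume of 1.21 Å³/Da × mass."""
    target_voxels = mass_da * VOLUME_PER_DALTON / dmap.voxel**3
    flat = np.sort(dmap.values.ravel())[::-1]
    k = int(np.clip(round(target_voxels), 1, flat.size))
    return float(flat[k - 1])


def volume_coverage(dmap: DensityMap, beads: BeadModel,
                    contour: float | None = None,
                    mass_da: float | None = None,
                    envelope_pad: float | None = None) -> float:
    """Fraction of above-contour map volume covered by the model envelope.

    The envelope is the union of bead spheres dilated by `envelope_pad`
    (default: half the map's declared resolution, accounting for the blur of
    the reconstruction).  The contour defaults to the level enclosing the
    model's expected molecular volume (1.21 Å³/Da × mass).
    """
    if contour is None:
        if mass_da is None:
            mass_da = float(beads.weights.sum())
        contour = mass_based_contour(dmap, mass_da)
    if dmap.values.size and contour > dmap.values.max():
        raise ValueError("contour level above map maximum: coverage undefined")
    if envelope_pad is None:
        envelope_pad = (dmap.resolution or 2.0 * dmap.voxel) / 2.0
    above = np.argwhere(dmap.values >= contour)
    if len(above) == 0:
        return 0.0
    if beads.n_beads == 0:
        return 0.0
    pos = np.asarray(dmap.origin) + above * dmap.voxel
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    covered = np.zeros(len(pos), dtype=bool)
    for center, radius in zip(beads.centers, beads.radii):
        hit = tree.query_ball_point(center, float(radius + envelope_pad))
        covered[hit] = True
    return float(covered.sum() / len(above))
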