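"""Global rigid-body fitting into density maps with fit-significance statistics.

The global search draws uniform random initial placements (Haar-uniform
rotations, translations uniform over the map box) and hill-climbs each with
small translation/rotation steps.  The search objective is a fast surrogate —
the mass-weighted sum of the Gaussian-smoothed map sampled at the body's bead
positions, normalized by the local map intensity — whose numerator equals the
inner product of the body's simulated density with the map.  Optimized poses
are clustered with tight angular/shift thresholds (symmetry-aware when the map
has a point group), and the top cluster representatives are polished and
rescored with the exact normalized cross-correlation between the body's
simulated density and the map.

Fit significance follows the empirical-null recipe: NCC scores are mapped
through Fisher's z-transform, a robust Gaussian null (median / 1.4826·MAD) is
fitted to the bulk, and two-sided P-values are read from its tails.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import ndtr

from emplace.density import (
    DensityMap,
    gaussian_sigma,
    lowpass_filter,
    mirror_map,
    pearson,
    stamp_gaussians,
)
from emplace.geom import Pose, quat_from_rotation, rotation_angle_deg
from emplace.structures import AtomicModel, BeadModel, RESIDUE_MASS_DA


@dataclass
class RigidFit:
    """One candidate placement of a rigid body."""

    pose: Pose
    ncc: float
    center: tuple[float, float, float]  # transformed body centroid, Å
    cluster_size: int = 1
    zscore: float = 0.0
    pvalue: float = 1.0

    def __post_init__(self):
        if not (-1.0 <= self.ncc <= 1.0):
            raise ValueError("ncc must lie in [-1, 1]")


@dataclass
class FitLibrary:
    """Clustered fits of one body, sorted by NCC descending."""

    body_name: str
    fits: list[RigidFit]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fits = sorted(self.fits, key=lambda f: -f.ncc)

    def __len__(self) -> int:
        return len(self.fits)

    @property
    def best(self) -> RigidFit:
        return self.fits[0]

    def to_text(self, path) -> None:
        """Delimited text (one fit per row) plus a JSON parameter sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("qw\tqx\tqy\tqz\ttx\tty\ttz\tncc\tcluster_size\tzscore\tpvalue\n")
            for f in self.fits:
                q = f.pose.quaternion
                t = f.pose.translation
                fh.write("\t".join(repr(float(v)) for v in (*q, *t)) +
                         f"\t{float(f.ncc)!r}\t{int(f.cluster_size)}"
                         f"\t{float(f.zscore)!r}\t{float(f.pvalue)!r}\n")
        sidecar = {"body_name": self.body_name, "params": self.params}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def from_text(path, centroid=(0.0, 0.0, 0.0)) -> "FitLibrary":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        fits = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                v = line.split()
                pose = Pose(quaternion=tuple(map(float, v[0:4])),
                            translation=tuple(map(float, v[4:7])))
                fits.append(RigidFit(
                    pose=pose, ncc=float(v[7]),
                    center=tuple(pose.apply(np.asarray(centroid))),
                    cluster_size=int(v[8]), zscore=float(v[9]), pvalue=float(v[10])))
        return FitLibrary(body_name=sidecar["body_name"], fits=fits,
                          params=sidecar["params"])


@dataclass
class FitOptions:
    """Search-budget and metric parameters for :func:`global_fit`."""

    n_starts: int = 10_000
    n_opt_steps: int = 100
    cluster_angle: float = 1.0          # degrees
    cluster_shift: float = 1.0          # Å
    resolution: float | None = None     # Å; default: the map's declared resolution
    translation_step: float = 0.25      # initial step, voxels
    rotation_step: float = 2.0          # initial step, degrees
    polish_top: int = 200               # clusters polished with the exact NCC
    polish_steps: int = 300
    keep_top: int | None = None         # library truncation length
    symmetry: tuple | None = None       # (axis xyz, order); axis through map center
    mask_cut: float = 0.2               # envelope mask level for the exact NCC
    laplacian: bool = True              # Laplacian-filtered exact NCC
    # orientational scan at the top distinct candidate sites: small bodies are
    # nearly spherical at low resolution, so the random search rarely lands a
    # well-oriented start at the right site — score a fixed orientation set at
    # each site and polish the best ones
    site_scan_top: int = 40             # number of distinct sites scanned
    site_scan_orientations: int = 48    # orientations per site
    site_scan_keep: int = 1             # best orientations polished per site
    site_separation: float = 10.0       # Å between distinct sites


def _body_points(body) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(body, BeadModel):
        return body.centers, body.weights, body.parent[0] if body.parent else "body"
    if isinstance(body, AtomicModel):
        ca = body.ca_model()
        if ca.n_atoms == 0:
            raise ValueError("body has no CA atoms")
        return ca.xyz, np.full(ca.n_atoms, RESIDUE_MASS_DA), ca.chains()[0]
    raise TypeError(f"cannot fit {type(body).__name__}")


def trilinear(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at fractional index positions (zero outside)."""
    idx = np.atleast_2d(idx)
    nx, ny, nz = values.shape
    flat = values.ravel()
    i0 = np.floor(idx).astype(np.intp)
    x0, y0, z0 = i0.T
    inside = ((x0 >= 0) & (x0 <= nx - 2) & (y0 >= 0) & (y0 <= ny - 2)
              & (z0 >= 0) & (z0 <= nz - 2))
    out = np.zeros(len(idx))
    if not inside.any():
        return out
    sub = idx[inside]
    i0 = i0[inside]
    fx, fy, fz = (sub - i0).T
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
    base = (i0[:, 0] * ny + i0[:, 1]) * nz + i0[:, 2]
    c000 = flat[base]
    c001 = flat[base + 1]
    c010 = flat[base + nz]
    c011 = flat[base + nz + 1]
    c100 = flat[base + ny * nz]
    c101 = flat[base + ny * nz + 1]
    c110 = flat[base + ny * nz + nz]
    c111 = flat[base + ny * nz + nz + 1]
    out[inside] = (gx * (gy * (gz * c000 + fz * c001) + fy * (gz * c010 + fz * c011))
                   + fx * (gy * (gz * c100 + fz * c101) + fy * (gz * c110 + fz * c111)))
    return out


def _hill_climb_batch(scorer: "SurrogateScorer", rots0: np.ndarray,
                      p0: np.ndarray, pts0: np.ndarray, weights: np.ndarray,
                      t_step: float, r_step_deg: float, budget: int,
                      min_t: float = 0.05, min_r: float = 0.02):
    """All-starts-in-lockstep version of the greedy hill climb.

    Every start carries its own direction pointer and step sizes, so the move
    sequence of each start is identical to the serial climb; batching only
    amortizes the objective evaluations.  Returns (R, p, score) arrays.
    """
    n = len(p0)
    R = rots0.copy()
    p = p0.copy()
    best = scorer.batch(np.einsum("kj,nij->nki", pts0, R) + p[:, None, :], p, weights)
    evals = np.ones(n, dtype=int)
    t = np.full(n, t_step)
    r = np.full(n, np.radians(r_step_deg))
    dir_idx = np.zeros(n, dtype=int)
    improved_any = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    min_r_rad = np.radians(min_r)

    while active.any():
        ai = np.flatnonzero(active)
        di = dir_idx[ai]
        is_trans = di < 6
        p_new = p[ai].copy()
        R_new = R[ai].copy()
        ti = np.flatnonzero(is_trans)
        if len(ti):
            p_new[ti] += _DIRS[di[ti]] * t[ai][ti, None]
        ri = np.flatnonzero(~is_trans)
        if len(ri):
            axes = _DIRS[di[ri] - 6]
            rv = axes * r[ai][ri, None]
            mats = Rotation.from_rotvec(rv).as_matrix()
            R_new[ri] = np.einsum("nij,njk->nik", mats, R[ai][ri])
        cand_pts = np.einsum("kj,nij->nki", pts0, R_new) + p_new[:, None, :]
        s = scorer.batch(cand_pts, p_new, weights)
        evals[ai] += 1
        better = s > best[ai]
        acc = ai[better]
        if len(acc):
            R[acc] = R_new[better]
            p[acc] = p_new[better]
            best[acc] = s[better]
            improved_any[acc] = True
        rej = ai[~better]
        dir_idx[rej] += 1
        wrapped = rej[dir_idx[rej] >= 12]
        if len(wrapped):
            stale = wrapped[~improved_any[wrapped]]
            t[stale] *= 0.5
            r[stale] *= 0.5
            dir_idx[wrapped] = 0
            improved_any[wrapped] = False
            tiny = stale[(t[stale] <= min_t) & (r[stale] <= min_r_rad)]
            active[tiny] = False
        active &= evals < budget
    return R, p, best


class SurrogateScorer:
    """Fast fitting objective used during the global hill climb.

    score(R, p) = Σ_i w_i · S(R x_i + p) / N(p), where S is the map convolved
    with the simulation Gaussian (so the numerator equals the inner product of
    the body's simulated density with the map) and N is the local root-mean-
    square map intensity around p, floored to avoid blow-ups in empty regions.

    With `laplacian=True` the fields are built from the Laplacian-filtered
    map: since ⟨lap(sim), lap(map)⟩ = Σ_i w_i (G_σ ⊛ lap²(map))(x_i), the
    surrogate then shares its optima with the Laplacian exact metric.
    """

    def __init__(self, dmap: DensityMap, resolution: float, body_radius: float,
                 laplacian: bool = False):
        sigma = gaussian_sigma(resolution)
        if laplacian:
            from scipy import ndimage as _ndi
            noise_cut = min(3.0 * dmap.voxel, resolution / 2.0)
            lap = _ndi.laplace(lowpass_filter(dmap, noise_cut).values)
            num_base = dmap.copy(values=_ndi.laplace(lap))
            nrm_base = dmap.copy(values=lap**2)
            resolution = float(np.hypot(resolution, noise_cut))
        else:
            num_base = dmap
            nrm_base = dmap.copy(values=dmap.values.astype(float) ** 2)
        self.smooth = lowpass_filter(num_base, resolution).values
        width = max(2.0 * dmap.voxel, body_radius + sigma)
        local_ms = lowpass_filter(nrm_base, np.pi * np.sqrt(2.0) * width).values
        norm = np.sqrt(np.clip(local_ms, 0.0, None))
        self.floor = 0.05 * float(norm.max()) if norm.size else 1.0
        self.norm = np.maximum(norm, self.floor)
        self.origin = np.asarray(dmap.origin)
        self.voxel = dmap.voxel

    def __call__(self, pts: np.ndarray, p: np.ndarray, weights: np.ndarray) -> float:
        idx = (pts - self.origin) / self.voxel
        num = float(np.dot(weights, trilinear(self.smooth, idx)))
        den = max(float(trilinear(self.norm, (p - self.origin) / self.voxel)[0]),
                  self.floor)
        return num / den

    def batch(self, pts: np.ndarray, p: np.ndarray,
              weights: np.ndarray) -> np.ndarray:
        """Score a batch: pts (n, k, 3) bead positions, p (n, 3) centroids."""
        n, k, _ = pts.shape
        idx = (pts.reshape(-1, 3) - self.origin) / self.voxel
        vals = trilinear(self.smooth, idx).reshape(n, k)
        num = vals @ weights
        den = np.maximum(trilinear(self.norm, (p - self.origin) / self.voxel),
                         self.floor)
        return num / den


class ExactNCCScorer:
    """Masked-Pearson NCC of the body's simulated density against the map.

    The mask is a threshold mask on the simulated density: voxels above
    `mask_cut` of its maximum, i.e. the body's own envelope.  A tight mask
    keeps the correlation sensitive to the body's shape rather than to
    neighboring density in crowded assemblies.  With `laplacian=True` (the
    fitting default) both simulation and map are Laplacian-filtered before
    correlating — the standard remedy against small bodies being attracted
    into the smooth interior of larger densities.  Simulation and map live on
    the same grid, evaluated on the bounding subgrid of the transformed body.
    """

    def __init__(self, dmap: DensityMap, resolution: float,
                 mask_cut: float = 0.2, laplacian: bool = True):
        self.map = dmap
        self.sigma = gaussian_sigma(resolution)
        self.cut = 4.0
        self.mask_cut = float(mask_cut)
        self.laplacian = bool(laplacian)
        self._lap_map = None
        if self.laplacian:
            from scipy import ndimage as _ndi
            # kill out-of-band voxel noise before the Laplacian; the cutoff
            # sits well below the map resolution so in-band shape is kept
            noise_cut = min(3.0 * dmap.voxel, resolution / 2.0)
            filtered = lowpass_filter(dmap, noise_cut).values
            self._lap_map = _ndi.laplace(filtered)
            # simulate at the matching effective resolution (Gaussians
            # compose), so a perfect pose on a clean map correlates to 1
            self.sigma = gaussian_sigma(np.hypot(resolution, noise_cut))

    def __call__(self, pts: np.ndarray, weights: np.ndarray) -> float:
        dmap = self.map
        margin = self.cut * self.sigma
        lo = np.floor((pts.min(axis=0) - margin - dmap.origin) / dmap.voxel).astype(int)
        hi = np.ceil((pts.max(axis=0) + margin - dmap.origin) / dmap.voxel).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, dmap.shape)
        if np.any(hi - lo < 2):
            return -1.0
        sub_origin = dmap.origin + lo * dmap.voxel
        sim = np.zeros(tuple(hi - lo), dtype=float)
        stamp_gaussians(sim, sub_origin, dmap.voxel, pts, weights, self.sigma,
                        cutoff_sigmas=self.cut)
        mx = sim.max()
        if mx <= 0:
            return -1.0
        mask = sim > self.mask_cut * mx
        if mask.sum() < 8:
            return -1.0
        if self.laplacian:
            from scipy import ndimage as _ndi
            sub = self._lap_map[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            sim = _ndi.laplace(sim)
        else:
            sub = dmap.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        a = sub[mask].astype(float)
        b = sim[mask]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return -1.0
        return pearson(a, b)


_DIRS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                  [0, 0, 1], [0, 0, -1]], dtype=float)


def _hill_climb(score_fn, rot0: np.ndarray, p0: np.ndarray, pts0: np.ndarray,
                weights: np.ndarray, t_step: float, r_step_deg: float,
                budget: int, min_t: float = 0.05, min_r: float = 0.02):
    """Greedy derivative-free hill climb over rigid poses.

    Moves cycle through ±x/±y/±z translations and rotations about the world
    axes; a successful move is repeated while it keeps improving; when a full
    cycle fails, both step sizes are halved.  `budget` counts objective
    evaluations.  Returns (rotation matrix, centroid position, score, evals).
    """
    R = rot0
    p = p0.copy()
    best = score_fn(pts0 @ R.T + p, p, weights)
    evals = 1
    t = t_step
    r = np.radians(r_step_deg)

    def rot_mats(angle):
        return [Rotation.from_rotvec(d * angle).as_matrix() for d in _DIRS]

    rmats = rot_mats(r)
    while evals < budget and (t > min_t or r > np.radians(min_r)):
        improved_any = False
        for mi in range(12):
            while evals < budget:
                if mi < 6:
                    p_new = p + _DIRS[mi] * t
                    R_new = R
                else:
                    R_new = rmats[mi - 6] @ R
                    p_new = p
                s = score_fn(pts0 @ R_new.T + p_new, p_new, weights)
                evals += 1
                if s > best:
                    best, R, p = s, R_new, p_new
                    improved_any = True
                else:
                    break
            if evals >= budget:
                break
        if not improved_any:
            t *= 0.5
            r *= 0.5
            rmats = rot_mats(r)
    return R, p, best, evals


def _sym_ops(symmetry, center) -> list[tuple[Rotation, np.ndarray]]:
    """Rotation ops (R_k, c) of the cyclic group; identity first."""
    ops = [(Rotation.identity(), np.zeros(3))]
    if symmetry is None:
        return ops
    axis, order = np.asarray(symmetry[0], dtype=float), int(symmetry[1])
    axis = axis / np.linalg.norm(axis)
    c = np.asarray(center, dtype=float)
    for k in range(1, order):
        ops.append((Rotation.from_rotvec(axis * 2 * np.pi * k / order), c))
    return ops


def cluster_fits(fits: list[RigidFit], angle_thresh: float = 1.0,
                 shift_thresh: float = 1.0, symmetry=None,
                 center=(0.0, 0.0, 0.0)) -> list[RigidFit]:
    """Greedy clustering of fits in descending score order.

    A fit joins the first existing cluster whose representative is within BOTH
    the angular threshold (2·arccos|q1·q2|, degrees) and the shift threshold
    (Euclidean distance of transformed body centroids, Å) — after mapping
    through each operator of the map's cyclic symmetry group when given as
    ``symmetry=(axis, order)`` about `center`.  Representatives keep member
    counts; ties in score break by insertion order.
    """
    if angle_thresh <= 0 or shift_thresh <= 0:
        raise ValueError("cluster thresholds must be positive")
    ordered = sorted(range(len(fits)), key=lambda i: (-fits[i].ncc, i))
    ops = _sym_ops(symmetry, center)
    n_ops = len(ops)
    cos_thresh = np.cos(np.radians(angle_thresh) / 2.0)

    def variants(fit: RigidFit) -> tuple[np.ndarray, np.ndarray]:
        """(n_ops, 4) quaternions (w,x,y,z) and (n_ops, 3) centers."""
        r = fit.pose.rotation
        ctr = np.asarray(fit.center)
        qs = np.empty((n_ops, 4))
        cs = np.empty((n_ops, 3))
        for k, (op_r, op_c) in enumerate(ops):
            x, y, z, w = (op_r * r).as_quat()
            qs[k] = (w, x, y, z)
            cs[k] = op_r.apply(ctr - op_c) + op_c
        return qs, cs

    reps: list[RigidFit] = []
    cap = 64
    rep_q = np.empty((cap, n_ops, 4))
    rep_c = np.empty((cap, n_ops, 3))
    for i in ordered:
        fit = fits[i]
        q = np.asarray(fit.pose.quaternion)
        ctr = np.asarray(fit.center)
        m = len(reps)
        joined = False
        if m:
            close = (np.linalg.norm(rep_c[:m] - ctr, axis=2) <= shift_thresh)
            close &= np.abs(rep_q[:m] @ q) >= cos_thresh
            hits = np.flatnonzero(close.any(axis=1))
            if len(hits):
                reps[int(hits[0])].cluster_size += 1
                joined = True
        if not joined:
            rep = RigidFit(pose=fit.pose, ncc=fit.ncc, center=fit.center,
                           cluster_size=1, zscore=fit.zscore, pvalue=fit.pvalue)
            if m == cap:
                rep_q = np.concatenate([rep_q, np.empty((cap, n_ops, 4))])
                rep_c = np.concatenate([rep_c, np.empty((cap, n_ops, 3))])
                cap *= 2
            rep_q[m], rep_c[m] = variants(rep)
            reps.append(rep)
    return reps


def expand_symmetry(library: FitLibrary, symmetry, center) -> FitLibrary:
    """Add the symmetry images of every fit to a symmetry-reduced library.

    Clustering with a point group keeps one representative per equivalence
    class; for assembling a complex that contains the symmetry-related copies
    as separate bodies, each fit must be available at every equivalent site.
    Scores and significance carry over (the map is symmetric).
    """
    ops = _sym_ops(symmetry, center)
    fits: list[RigidFit] = []
    for fit in library.fits:
        for k, (op_r, op_c) in enumerate(ops):
            if k == 0:
                fits.append(fit)
                continue
            sym_pose = Pose.from_rotation(op_r, translation=tuple(
                op_c - op_r.apply(op_c)))
            pose = sym_pose.compose(fit.pose)
            fits.append(RigidFit(
                pose=pose, ncc=fit.ncc,
                center=tuple(sym_pose.apply(np.asarray(fit.center))),
                cluster_size=fit.cluster_size, zscore=fit.zscore,
                pvalue=fit.pvalue))
    return FitLibrary(body_name=library.body_name, fits=fits,
                      params={**library.params, "symmetry_expanded": True})


def fit_pvalues(scores) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-null fit significance for a set of NCC scores.

    Scores are Fisher z-transformed (atanh), a robust Gaussian null is fitted
    to the bulk (location = median, scale = 1.4826 × MAD), and two-sided
    P-values are computed from its tails.  P-values are invariant under adding
    a constant to all z-scores.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores to fit a null")
    if scores.size < 30:
        warnings.warn("fewer than 30 scores: the empirical null is unreliable",
                      stacklevel=2)
    if np.any(np.abs(scores) >= 1.0):
        warnings.warn("scores at ±1 clipped before the z-transform", stacklevel=2)
        scores = np.clip(scores, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(scores)
    med = np.median(z)
    mad = np.median(np.abs(z - med))
    scale = max(1.4826 * mad, 1e-12)
    zc = (z - med) / scale
    pvals = 2.0 * ndtr(-np.abs(zc))
    return zc, pvals


def global_fit(body, dmap: DensityMap, n_starts: int | None = None,
               n_opt_steps: int | None = None, seed: int = 0,
               options: FitOptions | None = None) -> FitLibrary:
    """Fit one rigid body into a density map by global search.

    Draws `n_starts` uniform random placements, hill-climbs each on the
    surrogate objective, clusters the results (1°/1 Å by default,
    symmetry-aware when ``options.symmetry`` is set), rescales the cluster
    representatives with the exact NCC (polishing the top ones), and returns
    the library with z-scores and empirical-null P-values.  Deterministic
    given `seed`.
    """
    opts = options or FitOptions()
    if n_starts is not None:
        opts.n_starts = n_starts
    if n_opt_steps is not None:
        opts.n_opt_steps = n_opt_steps
    pts, weights, name = _body_points(body)
    if len(pts) < 4:
        raise ValueError("body needs at least 4 particles for rigid fitting")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) body")
    if np.ptp(dmap.values) == 0:
        raise ValueError("cannot fit into a constant map")
    resolution = opts.resolution or dmap.resolution
    if resolution is None:
        raise ValueError("no resolution: set options.resolution or map.resolution")

    centroid = pts.mean(axis=0)
    pts0 = pts - centroid
    body_radius = float(np.sqrt((pts0**2).sum(axis=1).mean()))
    surrogate = SurrogateScorer(dmap, resolution, body_radius,
                                laplacian=opts.laplacian)
    exact = ExactNCCScorer(dmap, resolution, mask_cut=opts.mask_cut,
                           laplacian=opts.laplacian)
    map_center = dmap.physical_center()

    rng = np.random.default_rng(seed)
    rots = Rotation.random(opts.n_starts, random_state=rng)
    box_lo = np.asarray(dmap.origin)
    box_hi = box_lo + (np.asarray(dmap.shape) - 1) * dmap.voxel
    positions = rng.uniform(box_lo, box_hi, size=(opts.n_starts, 3))

    t_step = opts.translation_step * dmap.voxel
    R_all, p_all, s_all = _hill_climb_batch(
        surrogate, rots.as_matrix(), positions, pts0, weights,
        t_step, opts.rotation_step, opts.n_opt_steps)
    raw_poses: list[tuple[Pose, np.ndarray, float]] = []
    for i in range(opts.n_starts):
        R, p, s = R_all[i], p_all[i], float(s_all[i])
        rot = Rotation.from_matrix(R)
        pose = Pose(quaternion=quat_from_rotation(rot),
                    translation=tuple(p - R @ centroid))
        raw_poses.append((pose, p, s))
    # rank-preserving rescale of the surrogate score into the RigidFit ncc
    # slot; the exact NCC rescoring below replaces these values
    smax = max(1e-12, max(abs(s) for _, _, s in raw_poses))
    raw = [RigidFit(pose=pose, ncc=0.999 * s / smax, center=tuple(p))
           for pose, p, s in raw_poses]
    reps = cluster_fits(raw, opts.cluster_angle, opts.cluster_shift,
                        symmetry=opts.symmetry, center=map_center)

    # single exact evaluation of every cluster representative, then polish the
    # best of them under the exact metric (the surrogate only proposes)
    rescored: list[RigidFit] = []
    for rep in reps:
        s = exact(rep.pose.apply(pts), weights)
        rescored.append(RigidFit(pose=rep.pose, ncc=float(s), center=rep.center,
                                 cluster_size=rep.cluster_size))
    rescored.sort(key=lambda f: -f.ncc)

    def exact_obj(xyz, p, w):
        return exact(xyz, w)

    def _polish(R0: np.ndarray, p0: np.ndarray, cluster_size: int) -> RigidFit:
        # rotation step starts at 4°: wide enough to travel out of the
        # orientation-scan spacing, halved on failure down to fine steps
        R, p, s, _ = _hill_climb(exact_obj, R0, p0, pts0, weights,
                                 0.25 * dmap.voxel, 4.0, opts.polish_steps)
        rot = Rotation.from_matrix(R)
        pose = Pose(quaternion=quat_from_rotation(rot),
                    translation=tuple(p - R @ centroid))
        return RigidFit(pose=pose, ncc=float(s), center=tuple(p),
                        cluster_size=cluster_size)

    # orientational scan at the top distinct sites
    site_fits: list[RigidFit] = []
    if opts.site_scan_top and opts.site_scan_orientations:
        sites: list[np.ndarray] = []
        for f in rescored:
            pos = np.asarray(f.center)
            if all(np.linalg.norm(pos - s) > opts.site_separation for s in sites):
                sites.append(pos)
            if len(sites) >= opts.site_scan_top:
                break
        rot_rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        rot_set = Rotation.random(opts.site_scan_orientations, random_state=rot_rng)
        mats = rot_set.as_matrix()
        for pos in sites:
            scores = [exact(pts0 @ mats[k].T + pos, weights)
                      for k in range(len(mats))]
            order = np.argsort(scores)[::-1]
            for k in order[:opts.site_scan_keep]:
                site_fits.append(_polish(mats[k], pos.copy(), 1))
            # the remaining scanned orientations enter the library unpolished:
            # the EM score alone cannot rank orientations of near-spherical
            # bodies, so downstream restraint-based selection needs the full
            # orientational diversity at every candidate site
            for k in order[opts.site_scan_keep:]:
                rot = Rotation.from_matrix(mats[k])
                pose = Pose(quaternion=quat_from_rotation(rot),
                            translation=tuple(pos - mats[k] @ centroid))
                site_fits.append(RigidFit(pose=pose, ncc=float(scores[k]),
                                          center=tuple(pos)))

    polished: list[RigidFit] = list(site_fits)
    for ci, rep in enumerate(rescored):
        if ci < opts.polish_top:
            polished.append(_polish(rep.pose.matrix, np.asarray(rep.center),
                                    rep.cluster_size))
        else:
            polished.append(rep)
    # polishing can merge basins: cluster once more, then attach significance
    merged = cluster_fits(polished, opts.cluster_angle, opts.cluster_shift,
                          symmetry=opts.symmetry, center=map_center)
    merged.sort(key=lambda f: -f.ncc)
    if len(merged) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, p = fit_pvalues([f.ncc for f in merged])
        for fit, zi, pi in zip(merged, z, p):
            fit.zscore = float(zi)
            fit.pvalue = float(pi)
    if opts.keep_top:
        merged = merged[:opts.keep_top]
    params = {
        "n_starts": opts.n_starts, "n_opt_steps": opts.n_opt_steps,
        "cluster_angle": opts.cluster_angle, "cluster_shift": opts.cluster_shift,
        "resolution": resolution, "seed": seed,
        "polish_top": opts.polish_top, "polish_steps": opts.polish_steps,
        "symmetry": None if opts.symmetry is None else
            [list(map(float, opts.symmetry[0])), int(opts.symmetry[1])],
    }
    return FitLibrary(body_name=name, fits=merged, params=params)


def handedness_test(body, dmap: DensityMap, seed: int = 0,
                    options: FitOptions | None = None) -> dict:
    """Compare fit significance in a map versus its mirror image.

    Runs :func:`global_fit` against the map and its mirrored copy and compares
    the best fits' P-values; the preferred hand is the map with the smaller
    best P-value, flagged inconclusive when they differ by less than one order
    of magnitude.
    """
    lib_native = global_fit(body, dmap, seed=seed, options=options)
    lib_mirror = global_fit(body, mirror_map(dmap), seed=seed, options=options)

    # one POOLED empirical null over both maps' fit scores: per-library nulls
    # have independently estimated scales and their P-values cannot be
    # compared across hands
    pooled = np.array([f.ncc for f in lib_native.fits]
                      + [f.ncc for f in lib_mirror.fits])
    pooled = np.clip(pooled, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(pooled)
    med = np.median(z)
    scale = max(1.4826 * np.median(np.abs(z - med)), 1e-12)

    from scipy.stats import norm as _norm

    def _pooled_p(ncc: float) -> tuple[float, float]:
        zi = (np.arctanh(np.clip(ncc, -1 + 1e-12, 1 - 1e-12)) - med) / scale
        log10p = float((np.log(2.0) + _norm.logcdf(-abs(zi))) / np.log(10.0))
        return float(2.0 * _norm.cdf(-abs(zi))), log10p

    p_nat, lp_nat = _pooled_p(lib_native.best.ncc)
    p_mir, lp_mir = _pooled_p(lib_mirror.best.ncc)
    ratio_log10 = lp_mir - lp_nat
    if abs(ratio_log10) < 1.0:
        preferred = "inconclusive"
    else:
        preferred = "native" if ratio_log10 > 0 else "mirrored"
    return {
        "pvalue_native": p_nat,
        "pvalue_mirrored": p_mir,
        "ncc_native": lib_native.best.ncc,
        "ncc_mirrored": lib_mirror.best.ncc,
        "log10_pvalue_ratio": ratio_log10,
        "preferred_hand": preferred,
        "library_native": lib_native,
        "library_mirrored": lib_mirror,
    }
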