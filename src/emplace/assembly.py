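"""Monte Carlo assembly of full-complex configurations from precomputed fits.

`sample_configurations` recombines each body's fit library by simulated
annealing: every configuration comes from an independent run that starts from
a random fit assignment and re-draws one body's fit index per step under the
Metropolis criterion with a geometric temperature schedule.  The best state of
each run is kept and rescored with the exact composite objective.

`refine_continuous` then lets the domains move in continuous space (small
rigid perturbations, annealed Metropolis) with the EM cross-correlation
recomputed during the optimization.  `hinge_split_refit` covers the two-lobe
protocol: split a fitted model at a flexible hinge into two super-rigid
bodies, fit the lobes independently into a second map, and refine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from emplace.density import DensityMap
from emplace.fitting import ExactNCCScorer, FitLibrary, FitOptions, global_fit
from emplace.geom import Pose, quat_from_rotation
from emplace.restraints import (
    Assembly,
    AssemblyConfiguration,
    DEFAULT_CONN_SLACK,
    DEFAULT_WEIGHTS,
    DEFAULT_XL_CAP,
    DEFAULT_XL_SIGMA,
    DEFAULT_XL_THRESHOLD,
    LINKER_EXTENSION_PER_RESIDUE,
    composite_score,
)
from emplace.structures import AtomicModel, Crosslink, RigidBody, segment_rigid_bodies


@dataclass
class McOptions:
    """Sampling parameters for :func:`sample_configurations`."""

    n_configs: int = 200
    n_steps: int = 5_000
    #: initial temperature in score units; None auto-calibrates to the 90th
    #: percentile of |move delta| at random states, so the hot phase accepts
    #: most moves regardless of the restraint scale
    t_start: float | None = None
    t_end: float = 0.01        # cold enough to resolve per-fit EM differences
    #: number of annealing cycles per run; >1 reheats mid-run (best-of-run
    #: keeps the best state ever visited) at the cost of shallower cooling
    anneal_cycles: int = 1
    #: the best `quench_top` runs get a deterministic greedy quench (full
    #: coordinate descent over each body's library) before final ranking: a
    #: desk-scale run cannot visit every fit index in its cold phase, so the
    #: zero-temperature limit of the move set is applied exhaustively
    quench_top: int = 20
    quench_sweeps: int = 6
    weights: tuple = DEFAULT_WEIGHTS
    xl_threshold: float = DEFAULT_XL_THRESHOLD
    xl_sigma: float = DEFAULT_XL_SIGMA
    xl_cap: float = DEFAULT_XL_CAP
    conn_slack: float = DEFAULT_CONN_SLACK


#: the full published-protocol budgets
PUBLISHED_SCALE = McOptions(n_configs=10_000, n_steps=60_000)


def _temperature(step: int, n_steps: int, t0: float, t1: float) -> float:
    if t0 <= 0 or t1 <= 0:
        return 0.0  # greedy limit
    if n_steps <= 1:
        return t1
    return t0 * (t1 / t0) ** (step / (n_steps - 1))


class _McEngine:
    """Precomputed per-fit geometry for fast delta scoring."""

    def __init__(self, assembly: Assembly, libraries: dict[str, FitLibrary],
                 crosslinks: list[Crosslink], opts: McOptions):
        self.assembly = assembly
        self.opts = opts
        self.names = assembly.body_names
        self.nb = len(self.names)
        for name in self.names:
            if name not in libraries or len(libraries[name]) == 0:
                raise ValueError(f"body {name} has an empty fit library")
        self.libs = [libraries[n] for n in self.names]
        self.nf = [len(lib) for lib in self.libs]
        self.ncc = [np.array([f.ncc for f in lib.fits]) for lib in self.libs]

        combos = assembly.map_crosslinks(crosslinks)
        self.link_combos = combos
        # Cα rows each body must expose (crosslink sites + linker termini)
        needed: list[set[int]] = [set() for _ in range(self.nb)]
        for cands in combos:
            for b1, r1, b2, r2 in cands:
                needed[b1].add(r1)
                needed[b2].add(r2)
        for b1, r1, b2, r2, _ in assembly.linkers:
            needed[b1].add(r1)
            needed[b2].add(r2)
        self.rowpos = [{r: i for i, r in enumerate(sorted(s))} for s in needed]

        # transformed coordinates per (body, fit): Cα sites, beads, bound sphere
        self.site_xyz: list[list[list[tuple]]] = []
        self.bead_xyz: list[list[np.ndarray]] = []
        self.sphere: list[list[tuple]] = []
        for bi in range(self.nb):
            rows = sorted(self.rowpos[bi])
            ref_sites = assembly.ca.xyz[rows] if rows else np.zeros((0, 3))
            brows = np.flatnonzero(assembly.bead_body == bi)
            ref_beads = assembly.beads.centers[brows]
            per_fit_sites, per_fit_beads, per_fit_sph = [], [], []
            for fit in self.libs[bi].fits:
                s = fit.pose.apply(ref_sites) if len(ref_sites) else ref_sites
                b = fit.pose.apply(ref_beads) if len(ref_beads) else ref_beads
                per_fit_sites.append([tuple(x) for x in s])
                per_fit_beads.append(b)
                if len(b):
                    c = b.mean(axis=0)
                    r = float(np.sqrt(((b - c) ** 2).sum(axis=1)).max())
                else:
                    c, r = np.zeros(3), 0.0
                per_fit_sph.append((tuple(c), r))
            self.site_xyz.append(per_fit_sites)
            self.bead_xyz.append(per_fit_beads)
            self.sphere.append(per_fit_sph)
        self.bead_r = [assembly.beads.radii[np.flatnonzero(assembly.bead_body == bi)]
                       for bi in range(self.nb)]
        self.rmax = [float(r.max()) if len(r) else 0.0 for r in self.bead_r]

        # links/linkers affected by each body
        self.links_of_body: list[list[int]] = [[] for _ in range(self.nb)]
        for li, cands in enumerate(combos):
            bodies = {c[0] for c in cands} | {c[2] for c in cands}
            for bi in bodies:
                self.links_of_body[bi].append(li)
        self.linkers_of_body: list[list[int]] = [[] for _ in range(self.nb)]
        for ki, (b1, _, b2, _, _) in enumerate(assembly.linkers):
            self.linkers_of_body[b1].append(ki)
            if b2 != b1:
                self.linkers_of_body[b2].append(ki)
        self._clash_cache: dict[tuple, float] = {}

    # -- term evaluations ---------------------------------------------------

    def link_penalty(self, li: int, idx) -> float:
        cands = self.link_combos[li]
        if not cands:
            return 0.0
        thr, sig = self.opts.xl_threshold, self.opts.xl_sigma
        dmin = math.inf
        for b1, r1, b2, r2 in cands:
            p = self.site_xyz[b1][idx[b1]][self.rowpos[b1][r1]]
            q = self.site_xyz[b2][idx[b2]][self.rowpos[b2][r2]]
            d = math.dist(p, q)
            if d < dmin:
                dmin = d
        if dmin <= thr:
            return 0.0
        return min(((dmin - thr) / sig) ** 2, self.opts.xl_cap)

    def linker_penalty(self, ki: int, idx) -> float:
        b1, r1, b2, r2, n_linker = self.assembly.linkers[ki]
        p = self.site_xyz[b1][idx[b1]][self.rowpos[b1][r1]]
        q = self.site_xyz[b2][idx[b2]][self.rowpos[b2][r2]]
        gap = math.dist(p, q)
        allowed = n_linker * LINKER_EXTENSION_PER_RESIDUE + self.opts.conn_slack
        if gap <= allowed:
            return 0.0
        return ((gap - allowed) / LINKER_EXTENSION_PER_RESIDUE) ** 2

    def pair_clash(self, b1: int, f1: int, b2: int, f2: int) -> float:
        if b1 > b2:
            b1, f1, b2, f2 = b2, f2, b1, f1
        key = (b1, f1, b2, f2)
        cached = self._clash_cache.get(key)
        if cached is not None:
            return cached
        c1, rad1 = self.sphere[b1][f1]
        c2, rad2 = self.sphere[b2][f2]
        if math.dist(c1, c2) > rad1 + rad2 + self.rmax[b1] + self.rmax[b2]:
            self._clash_cache[key] = 0.0
            return 0.0
        d = cdist(self.bead_xyz[b1][f1], self.bead_xyz[b2][f2])
        overlap = self.bead_r[b1][:, None] + self.bead_r[b2][None, :] - d
        val = float(np.sum(np.clip(overlap, 0.0, None) ** 2))
        if len(self._clash_cache) < 2_000_000:
            self._clash_cache[key] = val
        return val

    def body_energy(self, bi: int, idx) -> float:
        """All score terms that involve body bi, at the current assignment."""
        w_em, w_xl, w_conn, w_clash = self.opts.weights
        e = -w_em * self.ncc[bi][idx[bi]]
        for li in self.links_of_body[bi]:
            e += w_xl * self.link_penalty(li, idx)
        for ki in self.linkers_of_body[bi]:
            e += w_conn * self.linker_penalty(ki, idx)
        for bj in range(self.nb):
            if bj != bi:
                e += w_clash * self.pair_clash(bi, idx[bi], bj, idx[bj])
        return e

    def total_energy(self, idx) -> float:
        w_em, w_xl, w_conn, w_clash = self.opts.weights
        e = -w_em * sum(self.ncc[bi][idx[bi]] for bi in range(self.nb))
        e += w_xl * sum(self.link_penalty(li, idx)
                        for li in range(len(self.link_combos)))
        e += w_conn * sum(self.linker_penalty(ki, idx)
                          for ki in range(len(self.assembly.linkers)))
        for b1 in range(self.nb):
            for b2 in range(b1 + 1, self.nb):
                e += w_clash * self.pair_clash(b1, idx[b1], b2, idx[b2])
        return e

    def calibrate_t_start(self, seed: int, n_probe: int = 80) -> float:
        """Initial temperature: the 90th percentile of |single-move delta| at
        random states, capped at the EM reorganization scale (≈ w_em).

        Spending the schedule far above the EM scale only randomizes; the
        crosslink-scale barriers that remain at the cap are crossed by the
        post-run greedy quench, not by heat.
        """
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11B]))
        deltas = []
        for _ in range(n_probe):
            idx = [int(rng.integers(self.nf[bi])) for bi in range(self.nb)]
            bi = int(rng.integers(self.nb))
            e_old = self.body_energy(bi, idx)
            idx[bi] = int(rng.integers(self.nf[bi]))
            deltas.append(abs(self.body_energy(bi, idx) - e_old))
        deltas = [d for d in deltas if d > 0]
        t90 = float(np.percentile(deltas, 90)) if deltas else 1.0
        w_em = self.opts.weights[0]
        return min(t90, 1.2 * w_em) if w_em > 0 else t90

    def run(self, rng: np.random.Generator, n_steps: int, t_start: float):
        idx = [int(rng.integers(self.nf[bi])) for bi in range(self.nb)]
        energy = self.total_energy(idx)
        best_idx = list(idx)
        best_e = energy
        t0, t1 = t_start, self.opts.t_end
        cycle_len = max(1, n_steps // max(1, self.opts.anneal_cycles))
        for step in range(n_steps):
            bi = int(rng.integers(self.nb))
            new_f = int(rng.integers(self.nf[bi]))
            old_f = idx[bi]
            if new_f == old_f:
                continue
            e_old = self.body_energy(bi, idx)
            idx[bi] = new_f
            e_new = self.body_energy(bi, idx)
            delta = e_new - e_old
            if delta <= 0:
                accept = True
            else:
                temp = _temperature(step % cycle_len, cycle_len, t0, t1)
                accept = temp > 0 and rng.random() < math.exp(-delta / temp)
            if accept:
                energy += delta
                if energy < best_e:
                    best_e = energy
                    best_idx = list(idx)
            else:
                idx[bi] = old_f
        return best_idx, best_e

    def _coord_sweep(self, idx) -> bool:
        changed = False
        for bi in range(self.nb):
            current = idx[bi]
            e_best = self.body_energy(bi, idx)
            f_best = current
            for f in range(self.nf[bi]):
                if f == current:
                    continue
                idx[bi] = f
                e = self.body_energy(bi, idx)
                if e < e_best - 1e-12:
                    e_best, f_best = e, f
            idx[bi] = f_best
            if f_best != current:
                changed = True
        return changed

    def _pair_energy(self, b1: int, b2: int, idx) -> float:
        w_clash = self.opts.weights[3]
        return (self.body_energy(b1, idx) + self.body_energy(b2, idx)
                - w_clash * self.pair_clash(b1, idx[b1], b2, idx[b2]))

    def _swap_sweep(self, idx, site_radius: float = 8.0,
                    max_cands: int = 8) -> bool:
        """Try exchanging the sites of every body pair: single-body moves
        cannot cross a two-body occupancy barrier."""
        changed = False
        centers = [np.asarray([f.center for f in lib.fits]) for lib in self.libs]
        for b1 in range(self.nb):
            for b2 in range(b1 + 1, self.nb):
                c1 = np.asarray(self.libs[b1].fits[idx[b1]].center)
                c2 = np.asarray(self.libs[b2].fits[idx[b2]].center)
                if np.linalg.norm(c1 - c2) < site_radius:
                    continue
                cands1 = np.flatnonzero(
                    np.linalg.norm(centers[b1] - c2, axis=1) <= site_radius)
                cands2 = np.flatnonzero(
                    np.linalg.norm(centers[b2] - c1, axis=1) <= site_radius)
                if len(cands1) == 0 or len(cands2) == 0:
                    continue
                cands1 = cands1[:max_cands]
                cands2 = cands2[:max_cands]
                old1, old2 = idx[b1], idx[b2]
                e_old = self._pair_energy(b1, b2, idx)
                best = (e_old, old1, old2)
                for f1 in cands1:
                    idx[b1] = int(f1)
                    for f2 in cands2:
                        idx[b2] = int(f2)
                        e = self._pair_energy(b1, b2, idx)
                        if e < best[0] - 1e-12:
                            best = (e, int(f1), int(f2))
                idx[b1], idx[b2] = best[1], best[2]
                if (best[1], best[2]) != (old1, old2):
                    changed = True
        return changed

    def quench(self, idx, max_sweeps: int = 6):
        """Greedy quench: coordinate descent over each body's library plus
        pairwise site-exchange sweeps, until stable."""
        idx = list(idx)
        for _round in range(max_sweeps):
            changed = self._coord_sweep(idx)
            changed |= self._swap_sweep(idx)
            if not changed:
                break
        return idx, self.total_energy(idx)

    def configuration(self, idx) -> AssemblyConfiguration:
        poses = {self.names[bi]: self.libs[bi].fits[idx[bi]].pose
                 for bi in range(self.nb)}
        em = {self.names[bi]: float(self.ncc[bi][idx[bi]]) for bi in range(self.nb)}
        return AssemblyConfiguration(
            poses=poses, fit_indices={self.names[bi]: int(idx[bi])
                                      for bi in range(self.nb)}, em_ncc=em)


def sample_configurations(assembly: Assembly, libraries: dict[str, FitLibrary],
                          crosslinks: list[Crosslink],
                          n_configs: int | None = None,
                          n_steps: int | None = None,
                          seed: int = 0,
                          options: McOptions | None = None
                          ) -> list[AssemblyConfiguration]:
    """Generate configurations by simulated-annealing MC recombination of fits.

    Each configuration comes from an independent run (random initial fit
    assignment, `n_steps` single-body re-draws with Metropolis acceptance on a
    geometric schedule); the best state per run is kept.  The returned list is
    ranked by total score ascending (best first).  Runs are reproducible given
    `seed` and independent across run index.
    """
    opts = options or McOptions()
    if n_configs is not None:
        opts.n_configs = n_configs
    if n_steps is not None:
        opts.n_steps = n_steps
    engine = _McEngine(assembly, libraries, crosslinks, opts)
    t_start = opts.t_start if opts.t_start is not None else \
        engine.calibrate_t_start(seed)
    streams = np.random.SeedSequence(seed).spawn(opts.n_configs)
    results = []
    for run, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        idx, energy = engine.run(rng, opts.n_steps, t_start)
        results.append((energy, run, idx))
    results.sort(key=lambda t: (t[0], t[1]))
    if opts.quench_top:
        quenched = []
        for energy, run, idx in results[:opts.quench_top]:
            q_idx, q_e = engine.quench(idx, opts.quench_sweeps)
            quenched.append((q_e, run, q_idx))
        results = quenched + results[opts.quench_top:]
        results.sort(key=lambda t: (t[0], t[1]))
    configs = []
    for energy, run, idx in results:
        config = engine.configuration(idx)
        composite_score(assembly, config, crosslinks, weights=opts.weights,
                        em_scores=config.em_ncc,
                        xl_threshold=opts.xl_threshold, xl_sigma=opts.xl_sigma,
                        xl_cap=opts.xl_cap, conn_slack=opts.conn_slack)
        configs.append(config)
    return configs


# ---------------------------------------------------------------------------
# continuous refinement


@dataclass
class RefineOptions:
    n_steps: int = 2_000
    max_translation_voxels: float = 1.0
    max_rotation_deg: float = 2.0
    t_start: float = 1.0
    t_end: float = 0.01
    weights: tuple = DEFAULT_WEIGHTS
    xl_threshold: float = DEFAULT_XL_THRESHOLD
    xl_sigma: float = DEFAULT_XL_SIGMA
    xl_cap: float = DEFAULT_XL_CAP
    conn_slack: float = DEFAULT_CONN_SLACK


def refine_continuous(assembly: Assembly, config: AssemblyConfiguration,
                      dmap: DensityMap, crosslinks: list[Crosslink],
                      n_steps: int | None = None, seed: int = 0,
                      options: RefineOptions | None = None,
                      resolution: float | None = None) -> AssemblyConfiguration:
    """Refine a configuration with small rigid moves in continuous space.

    Monte Carlo with annealed Metropolis acceptance; per move one body is
    perturbed (translation ≤ 1 voxel, rotation ≤ 2° about the body centroid)
    and the EM cross-correlation of that body is recomputed against the map.
    The returned configuration's total is never worse than the input's.
    """
    opts = options or RefineOptions()
    if n_steps is not None:
        opts.n_steps = n_steps
    res = resolution or dmap.resolution
    if res is None:
        raise ValueError("no resolution for EM rescoring")
    scorer = ExactNCCScorer(dmap, res)
    w = opts.weights
    rng = np.random.default_rng(seed)

    def score_config(cfg: AssemblyConfiguration) -> float:
        breakdown = composite_score(
            assembly, cfg, crosslinks, weights=w, em_scores=None, dmap=dmap,
            resolution=res, xl_threshold=opts.xl_threshold,
            xl_sigma=opts.xl_sigma, xl_cap=opts.xl_cap,
            conn_slack=opts.conn_slack)
        return breakdown.total

    poses = dict(config.poses)
    current = AssemblyConfiguration(poses=dict(poses))
    energy = score_config(current)
    best_poses = dict(poses)
    best_e = energy
    names = assembly.body_names
    max_t = opts.max_translation_voxels * dmap.voxel
    for step in range(opts.n_steps):
        name = names[int(rng.integers(len(names)))]
        pose = poses[name]
        bi = assembly.body_index[name]
        centroid_now = pose.apply(assembly.centroids[bi])
        if rng.random() < 0.5:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = direction * rng.uniform(0.0, max_t)
            new_pose = Pose(quaternion=pose.quaternion,
                            translation=tuple(np.asarray(pose.translation) + shift))
        else:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.radians(rng.uniform(0.0, opts.max_rotation_deg))
            rot = Rotation.from_rotvec(axis * angle)
            # rotate about the body's current centroid: basin-preserving
            new_r = rot * pose.rotation
            new_t = (np.asarray(centroid_now) - new_r.apply(assembly.centroids[bi]))
            new_pose = Pose(quaternion=quat_from_rotation(new_r),
                            translation=tuple(new_t))
        trial_poses = dict(poses)
        trial_poses[name] = new_pose
        trial = AssemblyConfiguration(poses=trial_poses)
        e_new = score_config(trial)
        delta = e_new - energy
        if delta <= 0:
            accept = True
        else:
            temp = _temperature(step, opts.n_steps, opts.t_start, opts.t_end)
            accept = rng.random() < math.exp(-delta / temp)
        if accept:
            poses = trial_poses
            energy = e_new
            if energy < best_e:
                best_e = energy
                best_poses = dict(poses)
    out = AssemblyConfiguration(poses=best_poses)
    total = score_config(out)
    if total > score_config(AssemblyConfiguration(poses=dict(config.poses))):
        out = AssemblyConfiguration(poses=dict(config.poses))
        score_config(out)
    return out


# ---------------------------------------------------------------------------
# hinge-split two-lobe protocol


@dataclass
class HingeRefitResult:
    assembly: Assembly
    configuration: AssemblyConfiguration
    libraries: dict[str, FitLibrary]


def hinge_split_refit(model: AtomicModel, hinge: tuple[int, int],
                      dmap: DensityMap, crosslinks: list[Crosslink] | None = None,
                      seed: int = 0, fit_options: FitOptions | None = None,
                      refine_options: RefineOptions | None = None,
                      hinge_chain: str | None = None) -> HingeRefitResult:
    """Split a model into two lobes at a hinge and refit them independently.

    The hinge (residue range, inclusive) must lie inside one chain.  The hinge
    chain is cut before and after the hinge; every other chain joins the lobe
    whose hinge-chain half has the nearer centroid.  Both super-bodies are
    fitted into `dmap` by global search, combined, and refined continuously.
    """
    lo, hi = int(hinge[0]), int(hinge[1])
    ca = model.ca_model()
    if hinge_chain is None:
        for chain in ca.chains():
            resnums = ca.resnum[ca.chain == chain]
            if len(resnums) and resnums.min() < lo and resnums.max() > hi:
                hinge_chain = chain
                break
    if hinge_chain is None:
        raise ValueError(f"hinge {lo}-{hi} lies inside no chain of the model")
    res_of = ca.resnum[ca.chain == hinge_chain]
    half1 = (hinge_chain, int(res_of.min()), lo - 1)
    half2 = (hinge_chain, hi + 1, int(res_of.max()))

    def _centroid(member):
        c, a, b = member
        sel = (ca.chain == c) & (ca.resnum >= a) & (ca.resnum <= b)
        return ca.xyz[sel].mean(axis=0)

    lobe1 = [half1]
    lobe2 = [half2]
    c1, c2 = _centroid(half1), _centroid(half2)
    for chain in ca.chains():
        if chain == hinge_chain:
            continue
        resnums = ca.resnum[ca.chain == chain]
        member = (chain, int(resnums.min()), int(resnums.max()))
        d1 = np.linalg.norm(_centroid(member) - c1)
        d2 = np.linalg.norm(_centroid(member) - c2)
        (lobe1 if d1 <= d2 else lobe2).append(member)

    bodies = segment_rigid_bodies(model, {"lobe1": lobe1, "lobe2": lobe2})
    assembly = Assembly(model, bodies)
    libraries = {}
    for bi, body in enumerate(bodies):
        sel = np.flatnonzero(assembly.bead_body == bi)
        beads = assembly.beads
        sub = type(beads)(centers=beads.centers[sel], radii=beads.radii[sel],
                          parent=[beads.parent[i] for i in sel],
                          spans=[beads.spans[i] for i in sel])
        if sub.n_beads < 8:  # lobe too small for a stable bead fit
            sub = model.subset(body.atom_mask(model)).ca_model()
        lib = global_fit(sub, dmap, seed=seed + bi, options=fit_options)
        lib.body_name = body.name
        libraries[body.name] = lib
    config = AssemblyConfiguration(
        poses={name: lib.best.pose for name, lib in libraries.items()},
        em_ncc={name: lib.best.ncc for name, lib in libraries.items()})
    refined = refine_continuous(assembly, config, dmap, crosslinks or [],
                                seed=seed, options=refine_options)
    return HingeRefitResult(assembly=assembly, configuration=refined,
                            libraries=libraries)


# ---------------------------------------------------------------------------
# full-model rebuild


def rebuild_full_model(assembly: Assembly, config: AssemblyConfiguration,
                       model: AtomicModel | None = None) -> AtomicModel:
    """Apply body poses to the full-atom model and re-join flexible linkers.

    Atoms of each rigid body move by the body's pose.  Linker residues between
    two bodies of one chain are placed by straight-line Cα interpolation
    between the flanking transformed termini (each linker residue rides its
    interpolated Cα).  Leading/trailing tails move with the nearest body.
    """
    src = model if model is not None else assembly.model
    out_xyz = src.xyz.copy()
    moved = np.zeros(src.n_atoms, dtype=bool)
    for name, pose in config.poses.items():
        body = assembly.bodies[assembly.body_index[name]]
        mask = body.atom_mask(src)
        out_xyz[mask] = pose.apply(src.xyz[mask])
        moved |= mask

    # group body ranges per chain to locate gaps and tails
    per_chain: dict[str, list[tuple[int, int, str]]] = {}
    for name in config.poses:
        body = assembly.bodies[assembly.body_index[name]]
        for chain, lo, hi in body.members:
            per_chain.setdefault(chain, []).append((lo, hi, name))

    for chain, ranges in per_chain.items():
        ranges.sort()
        chain_mask = src.chain == chain
        resnums = src.resnum
        # tails ride the nearest body
        first_lo, _, first_name = ranges[0]
        _, last_hi, last_name = ranges[-1]
        head = chain_mask & (resnums < first_lo)
        tail = chain_mask & (resnums > last_hi)
        if head.any():
            out_xyz[head] = config.poses[first_name].apply(src.xyz[head])
            moved |= head
        if tail.any():
            out_xyz[tail] = config.poses[last_name].apply(src.xyz[tail])
            moved |= tail
        # linkers: straight-line Cα interpolation
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(ranges, ranges[1:]):
            gap_res = sorted(set(int(r) for r in resnums[
                chain_mask & (resnums > hi1) & (resnums < lo2)]))
            if not gap_res:
                continue
            a_sel = chain_mask & (resnums == hi1) & (src.atomname == "CA")
            b_sel = chain_mask & (resnums == lo2) & (src.atomname == "CA")
            if not a_sel.any() or not b_sel.any():
                continue
            a = out_xyz[a_sel][0]
            b = out_xyz[b_sel][0]
            n_seg = len(gap_res) + 1
            for j, rnum in enumerate(gap_res, start=1):
                target_ca = a + (b - a) * (j / n_seg)
                res_sel = chain_mask & (resnums == rnum)
                ca_sel = res_sel & (src.atomname == "CA")
                ref_ca = (src.xyz[ca_sel][0] if ca_sel.any()
                          else src.xyz[res_sel].mean(axis=0))
                out_xyz[res_sel] = src.xyz[res_sel] - ref_ca + target_ca
                moved |= res_sel

    rebuilt = AtomicModel(
        chain=src.chain.copy(), resnum=src.resnum.copy(),
        resname=src.resname.copy(), atomname=src.atomname.copy(),
        xyz=out_xyz, subunit_of_chain=dict(src.subunit_of_chain),
        copy_of_chain=dict(src.copy_of_chain))
    return rebuilt
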