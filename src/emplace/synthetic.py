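"""Synthetic ground-truth assemblies, simulated maps, and crosslink tables.

The generators emulate the statistical structure the pipeline assumes: a
multi-domain assembly with known ground-truth poses (optionally a two-lobed
C2-symmetric scaffold with one asymmetrically bound extra density), simulated
maps at 25–60 Å resolution with additive Gaussian noise, and crosslink tables
of true links plus a ~5% decoy fraction, the expected false-positive rate of
crosslinking MS at the usual confidence filter.

Bodies are compact self-avoiding Cα random walks (3.8 Å steps, compactness
bias); every 8th residue stands in for a crosslinkable lysine.  All outputs
are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from emplace.density import DensityMap, simulate_density
from emplace.geom import Pose, axis_angle_quat
from emplace.restraints import Assembly
from emplace.structures import (
    AtomicModel,
    Crosslink,
    RigidBody,
    coarse_grain,
    segment_rigid_bodies,
)

CA_STEP = 3.8           # Å, Cα-Cα virtual bond
MIN_SELF_DIST = 3.6     # Å, self-avoidance radius (non-adjacent residues)
LYSINE_SPACING = 8      # every 8th residue is crosslink-eligible


@dataclass
class SyntheticTruth:
    """Ground-truth assembly with known per-body placements.

    The model's coordinates ARE the ground truth: each body's true pose is the
    identity, and for C2-symmetric scaffolds the symmetry operator provides an
    equally valid placement of each body at its copy partner's site.
    """

    model: AtomicModel
    bodies: list[RigidBody]
    symmetry: tuple | None          # (axis, order) about the origin, or None
    symmetric_bodies: list[str]     # bodies covered by the symmetry
    seed: int
    params: dict = field(default_factory=dict)

    def assembly(self) -> Assembly:
        return Assembly(self.model, self.bodies)

    def true_centroid(self, body_name: str) -> np.ndarray:
        body = next(b for b in self.bodies if b.name == body_name)
        ca = self.model.ca_model()
        return ca.xyz[body.atom_mask(ca)].mean(axis=0)

    def equivalent_true_poses(self, body_name: str) -> list[Pose]:
        """Ground-truth pose plus its symmetry images, for recovery scoring."""
        poses = [Pose.identity()]
        if self.symmetry is not None and body_name in self.symmetric_bodies:
            axis, order = self.symmetry
            for k in range(1, order):
                poses.append(Pose(quaternion=axis_angle_quat(axis, 360.0 * k / order)))
        return poses

    def placement_error(self, body_name: str, pose: Pose) -> tuple[float, float]:
        """(centroid error Å, rotation error degrees) vs the nearest
        symmetry-equivalent ground-truth placement."""
        from emplace.geom import rotation_angle_deg

        c0 = self.true_centroid(body_name)
        best = (np.inf, np.inf)
        for true_pose in self.equivalent_true_poses(body_name):
            dt = float(np.linalg.norm(pose.apply(c0) - true_pose.apply(c0)))
            dr = rotation_angle_deg(pose.quaternion, true_pose.quaternion)
            if (dt, dr) < best:
                best = (dt, dr)
        return best


def _self_avoiding_chain(rng: np.random.Generator, n_res: int,
                         max_restarts: int = 200) -> np.ndarray:
    """Compact self-avoiding Cα walk: 3.8 Å steps; steps that grow the radius
    of gyration are kept with probability 0.3 only."""
    for _ in range(max_restarts):
        pts = [np.zeros(3)]
        ok = True
        for _i in range(1, n_res):
            placed = False
            for _attempt in range(60):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = pts[-1] + CA_STEP * d
                arr = np.asarray(pts[:-1])
                if len(arr) and np.min(np.linalg.norm(arr - cand, axis=1)) < MIN_SELF_DIST:
                    continue
                center = np.mean(pts, axis=0)
                grows = np.linalg.norm(cand - center) > np.linalg.norm(pts[-1] - center)
                if grows and rng.random() > 0.3:
                    continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            arr = np.asarray(pts)
            return arr - arr.mean(axis=0)
    raise RuntimeError(f"failed to grow a self-avoiding chain of {n_res} residues")


def helical_body(n_res: int = 200, radius: float = 25.0, pitch: float = 45.0,
                 turns: float = 1.5, seed: int = 0) -> AtomicModel:
    """A Cα chain following a helical path: a strongly chiral test body.

    A corkscrew cannot be superposed on its mirror image by any rotation, at
    any resolution — unlike compact globular chains, whose handedness washes
    out below ~20 Å.  Small positional jitter avoids a perfectly regular
    (and thus atypically smooth) density.
    """
    rng = np.random.default_rng(seed)
    # arc length per residue = CA_STEP; total angle = 2π·turns
    total_angle = 2 * np.pi * turns
    arc_per_angle = np.hypot(radius, pitch / (2 * np.pi))
    thetas = np.cumsum(np.full(n_res, CA_STEP / arc_per_angle))
    thetas = thetas / thetas[-1] * total_angle
    pts = np.column_stack([
        radius * np.cos(thetas),
        radius * np.sin(thetas),
        pitch * thetas / (2 * np.pi),
    ])
    pts += rng.normal(scale=0.8, size=pts.shape)
    pts -= pts.mean(axis=0)
    return _make_chain_model({"A": pts}, {"A": "HELIX"}, {"A": 1})


def _bead_clash(coords_a: np.ndarray, coords_b: np.ndarray,
                min_dist: float = 5.0) -> bool:
    if len(coords_a) == 0 or len(coords_b) == 0:
        return False
    return bool(np.min(cdist(coords_a, coords_b)) < min_dist)


def _make_chain_model(chains: dict[str, np.ndarray],
                      subunit_of_chain: dict[str, str],
                      copy_of_chain: dict[str, int]) -> AtomicModel:
    chain_ids, resnums, resnames, atomnames, xyz = [], [], [], [], []
    for cname, coords in chains.items():
        for i, c in enumerate(coords):
            chain_ids.append(cname)
            resnums.append(i + 1)
            resnames.append("ALA")
            atomnames.append("CA")
            xyz.append(c)
    return AtomicModel(
        chain=np.asarray(chain_ids, dtype=object),
        resnum=np.asarray(resnums),
        resname=np.asarray(resnames, dtype=object),
        atomname=np.asarray(atomnames, dtype=object),
        xyz=np.asarray(xyz),
        subunit_of_chain=subunit_of_chain,
        copy_of_chain=copy_of_chain,
    )


def _c2_image(coords: np.ndarray) -> np.ndarray:
    """180° rotation about the z axis through the origin."""
    out = coords.copy()
    out[:, 0] *= -1
    out[:, 1] *= -1
    return out


def generate_assembly(n_bodies: int = 3, body_size=80, symmetry: str = "none",
                      extra_body: bool = False, seed: int = 0,
                      lobe_offset: float = 55.0,
                      max_retries: int = 60) -> SyntheticTruth:
    """Generate a clash-free multi-body assembly with known poses.

    `n_bodies` distinct body types are grown as compact self-avoiding chains
    and placed around a lobe center without bead clashes.  With symmetry
    "C2" the whole lobe is duplicated by a 180° rotation about z (two-lobed
    scaffold); `extra_body` attaches one additional chain to exactly one lobe,
    breaking the symmetry (the Elp456-on-Elp123 topology).
    """
    if n_bodies < 1:
        raise ValueError("n_bodies must be >= 1")
    if symmetry not in ("none", "C2"):
        raise ValueError("symmetry must be 'none' or 'C2'")
    rng = np.random.default_rng(seed)
    sizes = ([int(body_size)] * n_bodies if np.isscalar(body_size)
             else [int(s) for s in body_size])
    if len(sizes) != n_bodies:
        raise ValueError("body_size list length must equal n_bodies")

    lobe = np.array([lobe_offset, 0.0, 0.0]) if symmetry == "C2" else np.zeros(3)
    placed: dict[str, np.ndarray] = {}
    subunit_of_chain: dict[str, str] = {}
    copy_of_chain: dict[str, int] = {}
    chain_letters = [chr(ord("A") + i) for i in range(26)]
    li = 0

    def _extent(coords) -> float:
        return float(np.linalg.norm(coords - coords.mean(axis=0), axis=1).max())

    def _place(coords0, anchor, occupied, base_offset):
        """Place around `anchor`, pushing outward until clash-free."""
        for _try in range(max_retries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = base_offset * (0.62 + 0.08 * (_try // 6))
            rot = Rotation.random(random_state=rng)
            cand = (rot.apply(coords0) + anchor + direction * offset
                    + rng.normal(scale=3.0, size=3))
            if not any(_bead_clash(cand, other) for other in occupied):
                return cand
        raise RuntimeError(
            "could not place a body without clashes; try fewer or smaller bodies")

    first_extent = 0.0
    for i in range(n_bodies):
        coords0 = _self_avoiding_chain(rng, sizes[i])
        if i == 0:
            rot = Rotation.random(random_state=rng)
            cand = rot.apply(coords0) + lobe
            first_extent = _extent(coords0)
        else:
            base = first_extent + _extent(coords0)
            cand = _place(coords0, lobe, list(placed.values()), base)
        cname = chain_letters[li]; li += 1
        placed[cname] = cand
        subunit_of_chain[cname] = f"S{i + 1}"
        copy_of_chain[cname] = 1

    symmetric_chains = list(placed)
    if symmetry == "C2":
        for cname in list(placed):
            image = _c2_image(placed[cname])
            cname2 = chain_letters[li]; li += 1
            placed[cname2] = image
            subunit_of_chain[cname2] = subunit_of_chain[cname]
            copy_of_chain[cname2] = 2
            symmetric_chains.append(cname2)

    if extra_body:
        size_x = sizes[0]
        coords0 = _self_avoiding_chain(rng, size_x)
        anchor = lobe + np.array([0.0, 0.0, 42.0])
        cand = _place(coords0, anchor, list(placed.values()), 12.0)
        cname = chain_letters[li]; li += 1
        placed[cname] = cand
        subunit_of_chain[cname] = "X1"
        copy_of_chain[cname] = 1

    model = _make_chain_model(placed, subunit_of_chain, copy_of_chain)
    ca = model.ca_model()
    body_defs = {}
    body_names_sym = []
    for cname in placed:
        resnums = ca.resnum[ca.chain == cname]
        name = f"{subunit_of_chain[cname]}.{copy_of_chain[cname]}"
        body_defs[name] = [(cname, int(resnums.min()), int(resnums.max()))]
        if cname in symmetric_chains:
            body_names_sym.append(name)
    bodies = segment_rigid_bodies(model, body_defs)
    return SyntheticTruth(
        model=model, bodies=bodies,
        symmetry=((0.0, 0.0, 1.0), 2) if symmetry == "C2" else None,
        symmetric_bodies=body_names_sym, seed=seed,
        params={"n_bodies": n_bodies, "body_size": sizes, "symmetry": symmetry,
                "extra_body": extra_body, "lobe_offset": lobe_offset})


def simulate_noisy_map(truth_or_model, resolution: float, noise_sd: float,
                       voxel: float, seed: int = 0,
                       grid_like: DensityMap | None = None,
                       padding: float | None = None) -> DensityMap:
    """Simulated map plus independent Gaussian voxel noise.

    noise sd = noise_sd × the standard deviation of the clean signal, so
    noise_sd is a relative (dimensionless) level.
    """
    model = (truth_or_model.model if isinstance(truth_or_model, SyntheticTruth)
             else truth_or_model)
    clean = simulate_density(model, resolution=resolution, voxel=voxel,
                             padding=padding, grid_like=grid_like)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    sd = float(clean.values.std())
    noisy = clean.values + rng.normal(0.0, noise_sd * sd, size=clean.shape)
    out = clean.copy(values=noisy)
    out.resolution = resolution
    return out


def _eligible_sites(truth: SyntheticTruth) -> list[tuple[str, str, int]]:
    """(subunit, chain, resnum) of every crosslink-eligible residue."""
    ca = truth.model.ca_model()
    sites = []
    for chain in ca.chains():
        resnums = np.sort(ca.resnum[ca.chain == chain])
        for r in resnums:
            if (int(r) - int(resnums[0])) % LYSINE_SPACING == 0:
                sites.append((truth.model.subunit_of_chain[chain], chain, int(r)))
    return sites


def simulate_crosslinks(truth: SyntheticTruth, n_links: int,
                        decoy_fraction: float = 0.05, reach: float = 30.0,
                        seed: int = 0, inter_fraction: float = 0.35
                        ) -> list[Crosslink]:
    """Sample a crosslink table from the ground truth.

    True links are drawn from eligible residue pairs with ground-truth Cα–Cα
    distance ≤ `reach` (a fraction `inter_fraction` from inter-subunit pairs,
    echoing the observed inter/intra ratio of crosslinking studies of large
    complexes); each link is independently a decoy with probability
    `decoy_fraction`, drawn from pairs farther than `reach`.  Confidence
    scores are drawn above the usual ld = 30 filter: true links around 40,
    decoys around 33, so decoy behavior is exercised downstream.
    """
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ca = truth.model.ca_model()
    sites = _eligible_sites(truth)
    if len(sites) < 4:
        raise ValueError("not enough crosslink-eligible residues")
    coords = np.array([
        ca.xyz[np.flatnonzero((ca.chain == c) & (ca.resnum == r))[0]]
        for _, c, r in sites])
    d = cdist(coords, coords)
    subunits = np.asarray([s for s, _, _ in sites], dtype=object)
    iu = np.triu_indices(len(sites), k=1)
    close = d[iu] <= reach
    inter = subunits[iu[0]] != subunits[iu[1]]
    pools = {
        "close_inter": np.flatnonzero(close & inter),
        "close_intra": np.flatnonzero(close & ~inter),
        "far": np.flatnonzero(~close),
    }
    if len(pools["close_inter"]) + len(pools["close_intra"]) == 0:
        raise ValueError("no eligible residue pairs within reach")

    def _draw_score(is_true: bool) -> float:
        loc, scale = (40.0, 5.0) if is_true else (33.0, 2.0)
        while True:
            v = rng.normal(loc, scale)
            if v >= 30.0:
                return float(v)

    links: list[Crosslink] = []
    seen = set()
    for _ in range(n_links):
        added = False
        for _attempt in range(200):
            is_decoy = rng.random() < decoy_fraction
            if is_decoy:
                pool = pools["far"]
            else:
                want_inter = rng.random() < inter_fraction
                pool = pools["close_inter"] if want_inter else pools["close_intra"]
                if len(pool) == 0:
                    pool = pools["close_intra"] if want_inter else pools["close_inter"]
            if len(pool) == 0:
                continue
            k = int(pool[rng.integers(len(pool))])
            i, j = int(iu[0][k]), int(iu[1][k])
            s1, _, r1 = sites[i]
            s2, _, r2 = sites[j]
            key = tuple(sorted(((s1, r1), (s2, r2))))
            if key in seen:
                continue
            seen.add(key)
            links.append(Crosslink(
                protein1=s1, residue1=r1, protein2=s2, residue2=r2,
                linker=("DSS" if rng.random() < 0.6 else "DSG"),
                ld_score=_draw_score(not is_decoy)))
            added = True
            break
        if not added:
            raise ValueError(
                f"not enough eligible residue pairs for {n_links} unique links")
    return links


@dataclass
class ElongatorLikeFixture:
    """The standard end-to-end test case: C2 scaffold + asymmetric ring."""

    truth: SyntheticTruth           # all 9 bodies (scaffold + ring)
    scaffold_truth: SyntheticTruth  # the 6 scaffold bodies only
    full_map: DensityMap
    scaffold_map: DensityMap
    crosslinks: list[Crosslink]
    ring_bodies: list[str]
    seed: int


#: scaled-down subunit sizes (residues): three scaffold types in two copies
#: echo the large/medium/small subunits of a two-lobed scaffold; the three
#: ring bodies echo a small hetero-hexamer-like extra density
SCAFFOLD_SIZES = (150, 100, 70)
RING_SIZES = (50, 40, 35)
FIXTURE_VOXEL = 4.0
FULL_MAP_RESOLUTION = 31.0
SCAFFOLD_MAP_RESOLUTION = 27.0
FIXTURE_NOISE_SD = 0.1


def elongator_like_fixture(seed: int = 0, n_links: int = 116,
                           decoy_fraction: float = 0.05,
                           inter_fraction: float = 41.0 / 116.0
                           ) -> ElongatorLikeFixture:
    """Two-lobed C2 scaffold (3 body types × 2 copies) plus an asymmetric
    3-body ring bound to one lobe, with maps and a crosslink table.

    Emits a scaffold-only map and a full map on a shared grid (27 and 31 Å),
    both with additive noise, and a crosslink table at the stated decoy rate.
    The table defaults to the census shape of the study system: 116 unique
    links of which 41 are inter-subunit.
    """
    rng = np.random.default_rng(seed)
    scaffold = generate_assembly(n_bodies=3, body_size=list(SCAFFOLD_SIZES),
                                 symmetry="C2", extra_body=False, seed=seed)

    # ring: three small bodies on a circle above lobe 1
    lobe = np.array([scaffold.params["lobe_offset"], 0.0, 0.0])
    ring_center = lobe + np.array([0.0, 0.0, 46.0])
    chains = {}
    ca = scaffold.model.ca_model()
    for cname in ca.chains():
        chains[cname] = ca.xyz[ca.chain == cname]
    subunit_of_chain = dict(scaffold.model.subunit_of_chain)
    copy_of_chain = dict(scaffold.model.copy_of_chain)
    occupied = list(chains.values())
    next_letter = chr(ord("A") + len(chains))
    ring_names = []
    for k, size in enumerate(RING_SIZES):
        coords0 = _self_avoiding_chain(rng, size)
        angle = 2 * np.pi * k / len(RING_SIZES)
        target = ring_center + 20.0 * np.array([np.cos(angle), np.sin(angle), 0.0])
        placedc = None
        for _try in range(80):
            rot = Rotation.random(random_state=rng)
            cand = rot.apply(coords0) + target + rng.normal(scale=3.0, size=3)
            if not any(_bead_clash(cand, o) for o in occupied):
                placedc = cand
                break
        if placedc is None:
            raise RuntimeError("could not place ring body without clashes")
        cname = next_letter
        next_letter = chr(ord(next_letter) + 1)
        chains[cname] = placedc
        occupied.append(placedc)
        subunit_of_chain[cname] = f"R{k + 1}"
        copy_of_chain[cname] = 1
        ring_names.append(f"R{k + 1}.1")

    model = _make_chain_model(chains, subunit_of_chain, copy_of_chain)
    ca_full = model.ca_model()
    body_defs = {}
    for cname in chains:
        resnums = ca_full.resnum[ca_full.chain == cname]
        name = f"{subunit_of_chain[cname]}.{copy_of_chain[cname]}"
        body_defs[name] = [(cname, int(resnums.min()), int(resnums.max()))]
    bodies = segment_rigid_bodies(model, body_defs)
    truth = SyntheticTruth(
        model=model, bodies=bodies, symmetry=((0.0, 0.0, 1.0), 2),
        symmetric_bodies=list(scaffold.symmetric_bodies), seed=seed,
        params={**scaffold.params, "ring_sizes": list(RING_SIZES)})

    # shared, C2-respecting grid: symmetric in x and y about the z axis
    xyz = model.ca_model().xyz
    pad = 2.0 * FULL_MAP_RESOLUTION
    half_xy = np.abs(xyz[:, :2]).max() + pad
    zlo, zhi = xyz[:, 2].min() - pad, xyz[:, 2].max() + pad
    half_z = max(abs(zlo), abs(zhi))
    n_xy = int(np.ceil(2 * half_xy / FIXTURE_VOXEL)) + 1
    n_z = int(np.ceil(2 * half_z / FIXTURE_VOXEL)) + 1
    if n_xy % 2 == 0:
        n_xy += 1  # odd count centers a voxel exactly on the symmetry axis
    if n_z % 2 == 0:
        n_z += 1
    origin = (-(n_xy - 1) / 2 * FIXTURE_VOXEL, -(n_xy - 1) / 2 * FIXTURE_VOXEL,
              -(n_z - 1) / 2 * FIXTURE_VOXEL)
    grid = DensityMap(values=np.zeros((n_xy, n_xy, n_z)), voxel=FIXTURE_VOXEL,
                      origin=origin)

    full_map = simulate_noisy_map(truth, FULL_MAP_RESOLUTION, FIXTURE_NOISE_SD,
                                  FIXTURE_VOXEL, seed=seed + 1, grid_like=grid)
    scaffold_map = simulate_noisy_map(
        scaffold, SCAFFOLD_MAP_RESOLUTION, FIXTURE_NOISE_SD, FIXTURE_VOXEL,
        seed=seed + 2, grid_like=grid)
    crosslinks = simulate_crosslinks(truth, n_links=n_links,
                                     decoy_fraction=decoy_fraction,
                                     reach=30.0, seed=seed + 3,
                                     inter_fraction=inter_fraction)
    return ElongatorLikeFixture(
        truth=truth, scaffold_truth=scaffold, full_map=full_map,
        scaffold_map=scaffold_map, crosslinks=crosslinks,
        ring_bodies=ring_names, seed=seed)
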