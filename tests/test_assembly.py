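import numpy as np
import pytest

from emplace.assembly import (
    McOptions,
    RefineOptions,
    hinge_split_refit,
    rebuild_full_model,
    refine_continuous,
    sample_configurations,
)
from emplace.density import simulate_density
from emplace.fitting import FitLibrary, FitOptions, RigidFit
from emplace.geom import Pose, axis_angle_quat
from emplace.restraints import Assembly, AssemblyConfiguration, composite_score
from emplace.structures import Crosslink, coarse_grain, segment_rigid_bodies
from emplace.synthetic import generate_assembly, simulate_crosslinks, \
    simulate_noisy_map

from conftest import make_model


def _library(body_name, poses_nccs, assembly):
    bi = assembly.body_index[body_name]
    c0 = assembly.centroids[bi]
    fits = [RigidFit(pose=p, ncc=s, center=tuple(p.apply(c0)))
            for p, s in poses_nccs]
    return FitLibrary(body_name=body_name, fits=fits)


@pytest.fixture(scope="module")
def three_body_case():
    """Three distinct bodies with ground-truth placements and crosslinks."""
    truth = generate_assembly(n_bodies=3, body_size=[70, 50, 40],
                              symmetry="none", seed=41)
    asm = truth.assembly()
    links = simulate_crosslinks(truth, 21, decoy_fraction=1.0 / 21.0,
                                reach=30.0, seed=42)
    return truth, asm, links


class TestSampleConfigurations:
    def test_greedy_limit_picks_good_fit(self):
        truth = generate_assembly(n_bodies=1, body_size=[40], symmetry="none",
                                  seed=51)
        asm = truth.assembly()
        good = Pose.identity()
        bad = Pose(translation=(40.0, 0, 0))
        lib = _library("S1.1", [(good, 0.9), (bad, 0.2)], asm)
        for seed in range(5):
            cfgs = sample_configurations(
                asm, {"S1.1": lib}, [], seed=seed,
                options=McOptions(n_configs=3, n_steps=200, t_start=1e-9,
                                  t_end=1e-12, quench_top=0))
            assert cfgs[0].fit_indices["S1.1"] == 0

    def test_empty_library_names_body(self, three_body_case):
        truth, asm, links = three_body_case
        libs = {n: _library(n, [(Pose.identity(), 0.5)], asm)
                for n in asm.body_names}
        libs["S2.1"] = FitLibrary(body_name="S2.1", fits=[])
        with pytest.raises(ValueError, match="S2.1"):
            sample_configurations(asm, libs, links, seed=0,
                                  options=McOptions(n_configs=1, n_steps=10))

    def test_ground_truth_recovery_from_decoy_libraries(self, three_body_case):
        """True placements win over decoy fits under crosslink+clash scoring."""
        truth, asm, links = three_body_case
        rng = np.random.default_rng(43)
        libs = {}
        for name in asm.body_names:
            entries = [(Pose.identity(), 0.9)]
            for _ in range(19):
                t = rng.uniform(-60, 60, 3)
                q = axis_angle_quat(rng.normal(size=3), rng.uniform(0, 180))
                # decoy placements score below the true fit, as real
                # misplacements do; crosslinks must still pick truth when a
                # decoy link disagrees
                entries.append((Pose(quaternion=q, translation=tuple(t)),
                                float(rng.uniform(0.5, 0.85))))
            libs[name] = _library(name, entries, asm)
        cfgs = sample_configurations(asm, libs, links, seed=44,
                                     options=McOptions(n_configs=40,
                                                       n_steps=2000))
        top = cfgs[0]
        for name, pose in top.poses.items():
            terr, _ = truth.placement_error(name, pose)
            assert terr < 10.0

    def test_fixed_seed_reproducible(self, three_body_case):
        truth, asm, links = three_body_case
        libs = {n: _library(n, [(Pose.identity(), 0.8),
                                (Pose(translation=(25.0, 0, 0)), 0.7)], asm)
                for n in asm.body_names}
        opts = McOptions(n_configs=5, n_steps=300)
        a = sample_configurations(asm, libs, links, seed=7, options=opts)
        b = sample_configurations(asm, libs, links, seed=7, options=opts)
        assert [c.fit_indices for c in a] == [c.fit_indices for c in b]
        assert [c.score.total for c in a] == [c.score.total for c in b]

    def test_rescoring_serialized_config_reproduces_total(self, tmp_path,
                                                          three_body_case):
        truth, asm, links = three_body_case
        libs = {n: _library(n, [(Pose.identity(), 0.8)], asm)
                for n in asm.body_names}
        cfgs = sample_configurations(asm, libs, links, seed=1,
                                     options=McOptions(n_configs=2, n_steps=50))
        top = cfgs[0]
        top.to_json(tmp_path / "cfg.json")
        back = AssemblyConfiguration.from_json(tmp_path / "cfg.json")
        rescored = composite_score(asm, back, links, em_scores=back.em_ncc)
        assert rescored.total == top.score.total

    def test_more_steps_does_not_hurt(self, three_body_case):
        """Best-of-run totals stochastically improve with the step budget."""
        truth, asm, links = three_body_case
        rng = np.random.default_rng(45)
        libs = {}
        for name in asm.body_names:
            entries = [(Pose.identity(), 0.9)]
            for _ in range(30):
                t = rng.uniform(-50, 50, 3)
                entries.append((Pose(translation=tuple(t)),
                                float(rng.uniform(0.5, 0.95))))
            libs[name] = _library(name, entries, asm)
        totals = {}
        for n_steps in (60, 2000):
            cfgs = sample_configurations(
                asm, libs, links, seed=9,
                options=McOptions(n_configs=20, n_steps=n_steps, quench_top=0))
            totals[n_steps] = np.median([c.score.total for c in cfgs])
        assert totals[2000] <= totals[60]


class TestRefineContinuous:
    @pytest.fixture(scope="class")
    def clean_case(self):
        truth = generate_assembly(n_bodies=1, body_size=[60], symmetry="none",
                                  seed=61)
        asm = truth.assembly()
        beads = coarse_grain(truth.model, bodies=truth.bodies)
        dmap = simulate_density(beads, 24.0, 4.0, padding=40.0)
        dmap.resolution = 24.0
        return truth, asm, dmap

    def test_already_optimal_not_degraded(self, clean_case):
        truth, asm, dmap = clean_case
        cfg = AssemblyConfiguration(poses={"S1.1": Pose.identity()})
        before = composite_score(asm, cfg, [], dmap=dmap).total
        out = refine_continuous(asm, cfg, dmap, [], seed=3,
                                options=RefineOptions(n_steps=200))
        assert out.score.total <= before + abs(before) * 0.01

    def test_displaced_configuration_recovers(self, clean_case):
        truth, asm, dmap = clean_case
        start = AssemblyConfiguration(
            poses={"S1.1": Pose(translation=(5.0, 0.0, 0.0))})
        out = refine_continuous(asm, start, dmap, [], seed=4,
                                options=RefineOptions(n_steps=800))
        terr, _ = truth.placement_error("S1.1", out.poses["S1.1"])
        assert terr < 2.0

    def test_seeded_trajectory_reproducible(self, clean_case):
        truth, asm, dmap = clean_case
        start = AssemblyConfiguration(
            poses={"S1.1": Pose(translation=(3.0, 0.0, 0.0))})
        opts = RefineOptions(n_steps=150)
        a = refine_continuous(asm, start, dmap, [], seed=5, options=opts)
        b = refine_continuous(asm, start, dmap, [], seed=5, options=opts)
        assert a.poses["S1.1"].quaternion == b.poses["S1.1"].quaternion
        assert a.poses["S1.1"].translation == b.poses["S1.1"].translation


class TestHingeSplit:
    def test_two_domain_toy_split(self):
        n = 60
        i = np.arange(n)
        coords = np.column_stack([i * 3.8, (i % 2) * 4.0, ((i // 2) % 2) * 3.0])
        model = make_model(coords, resnums=list(range(1, n + 1)))
        bodies = segment_rigid_bodies(model, {"whole": [("A", 1, n)]})
        from emplace.assembly import hinge_split_refit
        # only exercise the splitting logic: tiny search budget
        beads = coarse_grain(model)
        dmap = simulate_density(beads, 24.0, 4.0, padding=30.0)
        dmap.resolution = 24.0
        result = hinge_split_refit(
            model, (28, 33), dmap, seed=2,
            fit_options=FitOptions(n_starts=30, n_opt_steps=40, polish_top=5,
                                   polish_steps=60, site_scan_top=4),
            refine_options=RefineOptions(n_steps=50))
        names = [b.name for b in result.assembly.bodies]
        assert sorted(names) == ["lobe1", "lobe2"]
        linkers = dict(result.assembly.bodies[0].linker_neighbors)
        assert linkers.get("lobe2") == 6  # residues 28..33 excluded

    def test_null_change_control_reproduces_pose(self):
        """Splitting and refitting against an unchanged map lands both lobes
        back on their original positions."""
        # compact chain lobes of clearly different size, so neither fits the
        # other's site; the map is simulated from the split representation
        from emplace.synthetic import _self_avoiding_chain
        rng = np.random.default_rng(81)
        lobe1 = _self_avoiding_chain(rng, 83)
        lobe2 = _self_avoiding_chain(rng, 38)
        # place lobe2 so the 4-residue hinge is geometrically satisfiable
        lobe2 = lobe2 + (lobe1[-1] + np.array([13.0, 6.0, 3.0]) - lobe2[0])
        hinge_pts = np.array([lobe1[-1] + (lobe2[0] - lobe1[-1]) * f
                              for f in (0.2, 0.4, 0.6, 0.8)])
        coords = np.concatenate([lobe1, hinge_pts, lobe2])
        model = make_model(coords, resnums=list(range(1, 126)))
        split_bodies = segment_rigid_bodies(model, {
            "l1": [("A", 1, 83)], "l2": [("A", 88, 125)]})
        split_beads = coarse_grain(model, bodies=split_bodies)
        dmap = simulate_density(split_beads, 24.0, 4.0, padding=40.0)
        dmap.resolution = 24.0
        result = hinge_split_refit(
            model, (84, 87), dmap, seed=7,
            fit_options=FitOptions(n_starts=600, n_opt_steps=100,
                                   polish_top=30, polish_steps=250,
                                   site_scan_top=12),
            refine_options=RefineOptions(n_steps=100))
        asm = result.assembly
        for body in asm.bodies:
            rows = asm.ca_rows_of_body[asm.body_index[body.name]]
            ref = asm.ca.xyz[rows].mean(axis=0)
            moved = result.configuration.poses[body.name].apply(ref)
            assert np.linalg.norm(moved - ref) <= dmap.voxel, body.name

    def test_hinge_outside_chain_is_error(self):
        model = make_model(np.zeros((30, 3)))
        dmap = simulate_density(make_model(np.zeros((5, 3))), 20.0, 4.0)
        with pytest.raises(ValueError, match="hinge"):
            hinge_split_refit(model, (100, 110), dmap)


class TestRebuild:
    def test_identity_poses_reproduce_input(self, three_body_case):
        truth, asm, _ = three_body_case
        cfg = AssemblyConfiguration(
            poses={n: Pose.identity() for n in asm.body_names})
        rebuilt = rebuild_full_model(asm, cfg)
        np.testing.assert_allclose(rebuilt.xyz, truth.model.xyz, atol=1e-12)

    def test_moved_body_matches_pose_transform(self, three_body_case):
        truth, asm, _ = three_body_case
        pose = Pose(quaternion=axis_angle_quat((0, 0, 1), 30.0),
                    translation=(5.0, -3.0, 8.0))
        poses = {n: Pose.identity() for n in asm.body_names}
        name = asm.body_names[0]
        poses[name] = pose
        rebuilt = rebuild_full_model(asm, AssemblyConfiguration(poses=poses))
        mask = asm.bodies[0].atom_mask(truth.model)
        np.testing.assert_allclose(rebuilt.xyz[mask],
                                   pose.apply(truth.model.xyz[mask]),
                                   atol=1e-12)

    def test_linker_gaps_bounded_after_rebuild(self):
        n = 60
        model = make_model(np.arange(n)[:, None] * [3.8, 0, 0],
                           resnums=list(range(1, n + 1)))
        bodies = segment_rigid_bodies(model, {
            "n": [("A", 1, 25)], "c": [("A", 36, n)]})
        asm = Assembly(model, bodies)
        cfg = AssemblyConfiguration(poses={
            "n": Pose.identity(),
            "c": Pose(translation=(6.0, 4.0, 0.0)),
        })
        rebuilt = rebuild_full_model(asm, cfg)
        ca = rebuilt.ca_model()
        order = np.argsort(ca.resnum)
        xyz = ca.xyz[order]
        gaps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        assert gaps.max() <= 4.5
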