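"""Hydration counts, density grids, water sites and cavity components."""

import numpy as np
import pytest

from channelhydra.errors import DomainError
from channelhydra.hydration import (cavity_components, density_map,
                                    detect_water_sites,
                                    hydration_count_series)
from channelhydra.synthetic import SyntheticSpec, generate_arrays
from channelhydra.trajio import select

from conftest import make_system, water_system


def shell_fixture(n_inside=7, n_outside=100, n_frames=3):
    rng = np.random.default_rng(20)
    center = np.array([25.0, 25.0, 25.0])
    inside = center + rng.uniform(-2.5, 2.5, size=(n_inside, 3))
    theta = rng.uniform(0, 2 * np.pi, n_outside)
    far = center + np.column_stack(
        [np.cos(theta), np.sin(theta), np.zeros(n_outside)]
    ) * rng.uniform(10, 20, n_outside)[:, None]
    waters = np.vstack([inside, far])
    return water_system(waters, n_frames=n_frames,
                        extra=[("CA", "ALA", 1, "A", center)])


class TestHydrationCountSeries:
    def test_planted_shell_count(self):
        topo, traj = shell_fixture()
        series = hydration_count_series(traj, select(topo, "chain A"), 5.0)
        assert list(series.counts) == [7, 7, 7]

    def test_no_waters_is_zero(self):
        topo, traj = make_system(["CA"], ["ALA"], [1], ["A"],
                                 np.zeros((2, 1, 3)) + 10)
        series = hydration_count_series(traj, select(topo, "chain A"), 5.0)
        assert list(series.counts) == [0, 0]

    def test_water_exactly_at_shell_radius_counted(self):
        waters = np.array([[30.0, 25.0, 25.0]])  # exactly 5.0 from the CA
        topo, traj = water_system(waters,
                                  extra=[("CA", "ALA", 1, "A", (25, 25, 25))])
        series = hydration_count_series(traj, select(topo, "chain A"), 5.0)
        assert series.counts[0] == 1

    def test_monotone_in_shell_radius(self):
        topo, traj = shell_fixture(n_frames=2)
        sel = select(topo, "chain A")
        prev = None
        for shell in (3.0, 5.0, 8.0, 12.0, 25.0):
            counts = hydration_count_series(traj, sel, shell).counts
            if prev is not None:
                assert np.all(counts >= prev)
            prev = counts


class TestDensityMap:
    def test_immobile_water_probability_one(self):
        topo, traj = water_system(np.array([[10.3, 10.3, 10.3]]), n_frames=20,
                                  box=(20, 20, 20))
        grid = density_map(traj, select(topo, "water"), 1.0)
        assert grid.probability[10, 10, 10] == pytest.approx(1.0)
        assert grid.probability.sum() == pytest.approx(1.0)

    def test_restriction_excludes_distant_waters(self):
        topo, traj = water_system(
            np.array([[10.0, 10, 10], [30.0, 30, 30]]), n_frames=5,
            extra=[("OD1", "ASP", 61, "C", (14.0, 10, 10))])
        grid = density_map(traj, select(topo, "water"), 1.0,
                           restrict_within=(select(topo, "name OD1"), 3.0))
        assert grid.probability.sum() == 0.0

    def test_empty_restriction_selection_rejected(self):
        topo, traj = water_system(np.array([[10.0, 10, 10]]))
        with pytest.raises(DomainError):
            density_map(traj, select(topo, "water"), 1.0,
                        restrict_within=(select(topo, "resname XXX"), 3.0))

    def test_raw_counts_conserve_point_tally(self):
        rng = np.random.default_rng(21)
        n_frames, n_waters = 40, 25
        coords = rng.uniform(0, 30, size=(n_frames, n_waters, 3))
        topo, traj = water_system(coords[0], box=(30, 30, 30))
        traj = traj.from_arrays(topo, coords, (30, 30, 30))
        grid = density_map(traj, select(topo, "water"), 1.5, mode="counts")
        assert grid.counts.sum() == n_frames * n_waters


class TestDetectWaterSites:
    def test_threshold_above_max_is_empty(self):
        topo, traj = water_system(np.array([[10.3, 10.3, 10.3]]), n_frames=10)
        grid = density_map(traj, select(topo, "water"), 1.0)
        assert detect_water_sites(grid, traj, prob_threshold=1.5) == []

    def test_counts_mode_rejected(self):
        topo, traj = water_system(np.array([[10.3, 10.3, 10.3]]), n_frames=10)
        grid = density_map(traj, select(topo, "water"), 1.0, mode="counts")
        with pytest.raises(DomainError):
            detect_water_sites(grid, traj)

    def test_single_immobile_water_site(self):
        topo, traj = water_system(np.array([[10.3, 10.6, 10.2]]), n_frames=25,
                                  box=(20, 20, 20))
        grid = density_map(traj, select(topo, "water"), 1.0)
        sites = detect_water_sites(grid, traj, prob_threshold=0.4)
        assert len(sites) == 1
        assert sites[0].mean_simultaneous_count == pytest.approx(1.0)
        # occupied for the whole trajectory span
        assert sites[0].mean_residence_ps == pytest.approx(25 * traj.timestep)

    def test_w1_cluster_count_and_residence_match_manifest(
            self, paper_system, paper_trajectory):
        topo = paper_system.topology
        grid = density_map(paper_trajectory, select(topo, "water"), 1.0,
                           restrict_within=(select(topo, "chain C and resid 61"),
                                            5.0))
        sites = detect_water_sites(grid, paper_trajectory, 0.4)
        truth = paper_system.truth.w1
        w1 = min(sites, key=lambda s: np.linalg.norm(
            s.centroid - np.asarray(truth["centroid"])))
        assert 2.0 <= w1.mean_simultaneous_count <= 3.0
        assert w1.mean_simultaneous_count == pytest.approx(
            truth["mean_count_realized"], abs=1e-9)
        assert w1.mean_residence_ps == pytest.approx(
            truth["mean_residence_frames_realized"] * paper_trajectory.timestep,
            rel=1e-9)

    def test_planted_site_centroid_recovered_across_seeds(self):
        """Planted W1 centroid recovered within one voxel diagonal, 20/20."""
        for seed in range(20):
            system = generate_arrays(
                SyntheticSpec.paper_like(seed=3000 + seed, n_frames=120))
            traj = system.trajectory()
            topo = system.topology
            grid = density_map(traj, select(topo, "water"), 1.0,
                               restrict_within=(
                                   select(topo, "chain C and resid 61"), 5.0))
            sites = detect_water_sites(grid, traj, 0.4)
            truth_c = np.asarray(system.truth.w1["centroid"])
            best = min(np.linalg.norm(s.centroid - truth_c) for s in sites)
            assert best <= np.sqrt(3.0), f"seed {seed}: centroid off by {best}"


class TestCavityComponents:
    def two_blob_system(self, bridged_from=None, n_frames=4):
        blob_a = np.array([[10.0, 20, 20], [12.5, 20, 20], [11.0, 22, 20]])
        blob_b = blob_a + np.array([12.0, 0, 0])
        bridge = np.array([[15.5, 20, 20], [18.5, 20, 20], [19.5, 22, 20]])
        park = np.array([[40.0, 40, 40], [40, 40, 43.6], [40, 43.6, 40]])
        ca = np.array([[16.0, 20, 20]])
        frames = []
        for t in range(n_frames):
            on = bridged_from is not None and t >= bridged_from
            frames.append(np.vstack([blob_a, blob_b,
                                     bridge if on else park, ca]))
        return water_system(frames[0][:-1], extra=[("CA", "ARG", 24, "A",
                                                    ca[0])])[0], frames

    def make_traj(self, topo, frames):
        from channelhydra.trajio import Trajectory

        return Trajectory.from_arrays(topo, np.asarray(frames), (50, 50, 50))

    def test_two_blobs_two_components(self):
        topo, frames = self.two_blob_system(bridged_from=None)
        traj = self.make_traj(topo, frames)
        cav = cavity_components(traj, select(topo, "chain A"), 15.0, 3.5)
        assert list(cav.n_components) == [2, 2, 2, 2]

    def test_bridged_blobs_merge_to_one(self):
        topo, frames = self.two_blob_system(bridged_from=0)
        traj = self.make_traj(topo, frames)
        cav = cavity_components(traj, select(topo, "chain A"), 15.0, 3.5)
        assert list(cav.n_components) == [1, 1, 1, 1]

    def test_component_count_drops_at_planted_switch_frame(self):
        topo, frames = self.two_blob_system(bridged_from=2)
        traj = self.make_traj(topo, frames)
        cav = cavity_components(traj, select(topo, "chain A"), 15.0, 3.5)
        assert list(cav.n_components) == [2, 2, 1, 1]
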