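"""RMSF closed forms and stable-spatial-position classification."""

import numpy as np
import pytest

from channelhydra.errors import DomainError
from channelhydra.sidechain import (AngleSeries, atom_position_probability,
                                    classify_sps, rmsf_from_coords)
from channelhydra.trajio import select

from conftest import make_system


class TestRmsf:
    def test_immobile_atom_is_zero(self):
        coords = np.tile(np.array([[1.0, 2.0, 3.0]]), (50, 1, 1))
        assert rmsf_from_coords(coords)[0] == 0.0

    def test_alternating_displacement_closed_form(self):
        d = 0.7
        coords = np.zeros((1000, 1, 3))
        coords[::2, 0, 0] = d
        coords[1::2, 0, 0] = -d
        assert rmsf_from_coords(coords)[0] == pytest.approx(d)

    def test_isotropic_gaussian_jitter_sqrt3_sigma(self):
        sigma = 0.3
        rng = np.random.default_rng(7)
        coords = rng.normal(0, sigma, size=(20_000, 1, 3))
        assert rmsf_from_coords(coords)[0] == pytest.approx(
            sigma * np.sqrt(3), rel=0.02)

    def test_single_frame_rejected(self):
        with pytest.raises(DomainError):
            rmsf_from_coords(np.zeros((1, 2, 3)))


def planted_two_state(rng, n, centers=(40.0, 120.0), dwell=200, noise=5.0,
                      occupancies=(0.5, 0.5)):
    """Dwell-segment angle series; returns (chi, state) arrays."""
    state = np.empty(n, dtype=int)
    t = 0
    while t < n:
        s = rng.choice(len(centers), p=occupancies)
        d = int(rng.geometric(1.0 / dwell))
        state[t:t + d] = s
        t += d
    chi = np.asarray(centers)[state] + rng.normal(0, noise, n)
    return np.clip(chi, 0, 180), state


class TestClassifySps:
    def test_single_tight_state(self):
        rng = np.random.default_rng(8)
        chi = 60.0 + rng.normal(0, 3.0, 5000)
        model = classify_sps(AngleSeries("x", chi), baseline_deg=5.0)
        assert len(model.sps) == 1
        assert model.sps[0].center_deg == pytest.approx(60.0, abs=1.0)
        assert model.sps[0].occupancy > 0.93

    def test_square_wave_matches_planted_schedule(self):
        rng = np.random.default_rng(9)
        n = 10_000
        state = (np.arange(n) // 200) % 2  # strict square wave, dwell 200
        chi = np.where(state == 0, 40.0, 120.0) + rng.normal(0, 5.0, n)
        model = classify_sps(AngleSeries("x", np.clip(chi, 0, 180)),
                             baseline_deg=5.0)
        assert len(model.sps) == 2
        centers = sorted(sp.center_deg for sp in model.sps)
        assert centers[0] == pytest.approx(40.0, abs=2.0)
        assert centers[1] == pytest.approx(120.0, abs=2.0)
        for sp in model.sps:
            assert sp.occupancy == pytest.approx(0.5, abs=0.05)
        # schedule has n/200 - 1 = 49 state changes; classification may drop
        # a few frames as transient but must see nearly all switches
        planted = int(np.sum(state[1:] != state[:-1]))
        assert abs(model.n_transitions - planted) <= 2

    def test_uniform_angles_yield_no_sps(self):
        rng = np.random.default_rng(10)
        chi = rng.uniform(0, 180, 10_000)
        model = classify_sps(AngleSeries("x", chi), baseline_deg=5.0)
        assert model.sps == []
        assert model.transient_fraction == 1.0

    def test_occupancies_plus_transient_sum_to_one(self):
        rng = np.random.default_rng(11)
        chi, _ = planted_two_state(rng, 8000)
        model = classify_sps(AngleSeries("x", chi), baseline_deg=5.0)
        total = sum(sp.occupancy for sp in model.sps) + model.transient_fraction
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_frame_reversal_preserves_model(self):
        rng = np.random.default_rng(12)
        chi, _ = planted_two_state(rng, 6000)
        fwd = classify_sps(AngleSeries("x", chi), baseline_deg=5.0)
        rev = classify_sps(AngleSeries("x", chi[::-1]), baseline_deg=5.0)
        assert len(fwd.sps) == len(rev.sps)
        for a, b in zip(fwd.sps, rev.sps):
            assert a.center_deg == pytest.approx(b.center_deg, abs=1e-6)
            assert a.occupancy == pytest.approx(b.occupancy, abs=1e-9)
        assert fwd.n_transitions == rev.n_transitions

    @pytest.mark.parametrize("centers,occ", [
        ((60.0, 120.0), (0.6, 0.4)),
        ((40.0, 90.0, 140.0), (0.5, 0.3, 0.2)),
    ])
    def test_state_count_and_occupancy_recovery_over_seeds(self, centers, occ):
        """Planted 2-/3-state dynamics over 20 seeds: state count must match
        in at least 19 runs, occupancies within 0.05 of realized."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            chi, state = planted_two_state(rng, 10_000, centers=centers,
                                           dwell=150, noise=3.0,
                                           occupancies=occ)
            model = classify_sps(AngleSeries("x", chi), baseline_deg=5.0)
            if len(model.sps) != len(centers):
                continue
            realized = np.array([np.mean(state == k)
                                 for k in range(len(centers))])
            got = np.zeros(len(centers))
            for sp in model.sps:
                k = int(np.argmin(np.abs(np.asarray(centers) - sp.center_deg)))
                got[k] = sp.occupancy
            if np.all(np.abs(got - realized) <= 0.05):
                hits += 1
        assert hits >= 19

    def test_bad_baseline_rejected(self):
        with pytest.raises(DomainError):
            classify_sps(AngleSeries("x", np.full(200, 60.0)), baseline_deg=0)


class TestAtomPositionProbability:
    def test_immobile_atom_single_voxel(self):
        coords = np.tile(np.array([[10.2, 10.7, 10.4]]), (30, 1, 1))
        topo, traj = make_system(["ND2"], ["ASN"], [214], ["A"], coords,
                                 box=(20, 20, 20))
        grid = atom_position_probability(traj, select(topo, "name ND2"), 1.0)
        assert np.count_nonzero(grid.probability) == 1
        assert grid.probability.max() == pytest.approx(1.0)

    def test_two_site_hopping_mass_split(self):
        rng = np.random.default_rng(13)
        n = 4000
        at_a = rng.random(n) < 0.7
        pa, pb = np.array([5.5, 5.5, 5.5]), np.array([12.5, 12.5, 12.5])
        coords = np.where(at_a[:, None], pa, pb)[:, None, :]
        topo, traj = make_system(["ND2"], ["ASN"], [214], ["A"], coords,
                                 box=(20, 20, 20))
        grid = atom_position_probability(traj, select(topo, "name ND2"), 1.0)
        mass_a = grid.probability[5, 5, 5]
        mass_b = grid.probability[12, 12, 12]
        assert mass_a == pytest.approx(np.mean(at_a), abs=1e-12)
        assert mass_b == pytest.approx(1 - np.mean(at_a), abs=1e-12)
        assert mass_a == pytest.approx(0.7, abs=0.02)

    def test_total_mass_is_one_per_frame(self):
        rng = np.random.default_rng(14)
        coords = rng.uniform(0, 19, size=(100, 1, 3))
        topo, traj = make_system(["ND2"], ["ASN"], [214], ["A"], coords,
                                 box=(20, 20, 20))
        grid = atom_position_probability(traj, select(topo, "name ND2"), 1.0)
        assert grid.probability.sum() == pytest.approx(1.0, abs=1e-9)

    def test_multi_atom_selection_rejected(self):
        coords = np.zeros((10, 2, 3))
        topo, traj = make_system(["ND2", "CA"], ["ASN", "ASN"], [214, 214],
                                 ["A", "A"], coords)
        with pytest.raises(DomainError):
            atom_position_probability(traj, select(topo, "resid 214"), 1.0)
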