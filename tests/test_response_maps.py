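"""Tests for the binned apparent-interaction maps."""

import numpy as np
import pandas as pd
import pytest

from flocknoise import (
    FrontBackProfile,
    SimulationConfig,
    accumulate_polar_map,
    acceleration_sign_profile,
    alignment_modulation,
    front_back_profile,
    modulation_range,
    multi_neighbour_observed,
    pair_observations,
    predict_from_pairwise,
    simulate_flock,
    theta_phi_turning_map,
)


def make_obs(d, theta, phi, turn, accel):
    d = np.asarray(d, dtype=float)
    return pd.DataFrame(
        {
            "d": d,
            "theta": theta,
            "phi": phi,
            "d_fb": d * np.cos(theta),
            "d_lat": d * np.sin(theta),
            "turn": turn,
            "accel": accel,
        }
    )


class TestPolarMap:
    def test_single_observation_single_cell(self):
        obs = make_obs([3.0], [0.5], [0.0], [1.7], [-2.0])
        m = accumulate_polar_map(obs)
        assert m.counts.sum() == 1
        i, j = np.nonzero(m.counts)
        assert m.mean_turning[i[0], j[0]] == pytest.approx(1.7)
        assert m.mean_acceleration[i[0], j[0]] == pytest.approx(-2.0)
        assert np.isnan(m.mean_turning[m.counts == 0]).all()

    def test_binned_means_match_explicit_loop(self):
        rng = np.random.default_rng(0)
        n = 5000
        obs = make_obs(
            rng.uniform(0, 25, n),
            rng.uniform(-np.pi, np.pi, n),
            rng.uniform(-np.pi, np.pi, n),
            rng.standard_normal(n),
            rng.standard_normal(n),
        )
        m = accumulate_polar_map(obs)
        # explicit per-observation loop oracle
        sums = np.zeros_like(m.mean_turning)
        counts = np.zeros_like(m.counts)
        dropped = 0
        for d, th, tu in zip(obs["d"], obs["theta"], obs["turn"]):
            if d >= m.radial_edges[-1]:
                dropped += 1
                continue
            i = int(np.searchsorted(m.radial_edges, d, side="right") - 1)
            j = int(np.searchsorted(m.angular_edges, th, side="left") - 1)
            counts[i, j] += 1
            sums[i, j] += tu
        np.testing.assert_array_equal(m.counts, counts)
        with np.errstate(invalid="ignore"):
            np.testing.assert_allclose(
                np.where(counts > 0, m.mean_turning, 0.0),
                np.where(counts > 0, sums / np.maximum(counts, 1), 0.0),
                atol=1e-12,
            )
        assert m.dropped == dropped

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        n = 2000
        obs = make_obs(
            rng.uniform(0, 40, n),  # half outside the 20 a.u. outer edge
            rng.uniform(-np.pi, np.pi, n),
            np.zeros(n),
            rng.standard_normal(n),
            rng.standard_normal(n),
        )
        m = accumulate_polar_map(obs)
        assert m.counts.sum() + m.dropped == n

    def test_nonincreasing_edges_rejected(self):
        obs = make_obs([1.0], [0.0], [0.0], [0.0], [0.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            accumulate_polar_map(obs, radial_edges=np.array([0.0, 5.0, 5.0]))

    def test_mirror_symmetry_of_tracks(self):
        # reflecting all tracks about the x axis negates theta, phi and the
        # turning response, so per-cell |mean turning| is preserved at the
        # mirrored cell
        ts = simulate_flock(SimulationConfig(n_steps=1024, seed=8))
        mirrored = ts.__class__(
            ideal=ts.ideal * np.array([1.0, -1.0]),
            recorded=ts.recorded * np.array([1.0, -1.0]),
            displacements=ts.displacements * np.array([1.0, -1.0]),
            offsets=ts.offsets,
            config=ts.config,
        )
        a = pair_observations(ts)
        b = pair_observations(mirrored)
        np.testing.assert_allclose(b["theta"], -a["theta"], atol=1e-10)
        np.testing.assert_allclose(b["phi"], -a["phi"], atol=1e-10)
        np.testing.assert_allclose(b["turn"], -a["turn"], atol=1e-8)
        ma, mb = accumulate_polar_map(a), accumulate_polar_map(b)
        np.testing.assert_array_equal(ma.counts, mb.counts[:, ::-1])
        np.testing.assert_allclose(
            np.abs(ma.mean_turning), np.abs(mb.mean_turning[:, ::-1]), atol=1e-8
        )


class TestFrontBackProfile:
    def test_synthetic_boundary_crossing(self):
        prof = FrontBackProfile(
            edges=np.array([0.0, 2.5, 5.0, 7.5, 10.0]),
            counts=np.full(4, 1000),
            mean_response=np.array([-1.0, -1.0, 1.0, 1.0]),
            min_count=100,
        )
        _, crossing = acceleration_sign_profile(prof)
        assert crossing == pytest.approx(5.0)

    def test_all_positive_profile_has_no_crossing(self):
        prof = FrontBackProfile(
            edges=np.linspace(0, 10, 5),
            counts=np.full(4, 1000),
            mean_response=np.array([0.5, 1.0, 1.5, 2.0]),
            min_count=100,
        )
        table, crossing = acceleration_sign_profile(prof)
        assert crossing is None
        assert (table["mean_accel"] > 0).all()

    def test_profile_counts_conserved(self):
        rng = np.random.default_rng(2)
        n = 1000
        obs = make_obs(
            np.abs(rng.uniform(-25, 25, n)),
            np.zeros(n),
            np.zeros(n),
            np.zeros(n),
            rng.standard_normal(n),
        )
        obs["d_fb"] = rng.uniform(-25, 25, n)  # some outside [-15, 15]
        prof = front_back_profile(obs, "accel")
        assert prof.counts.sum() + prof.dropped == n


class TestThetaPhiMap:
    def test_single_cell_and_attraction_zone_filter(self):
        obs = make_obs([6.0, 6.0, 2.0], [0.3, 0.3, 0.3], [0.1, 0.1, 0.1],
                       [1.0, 3.0, 99.0], [0.0, 0.0, 0.0])
        m = theta_phi_turning_map(obs, r_min=5.0)
        assert m.counts.sum() == 2  # the d=2 observation is excluded
        assert m.excluded == 1
        i, j = np.nonzero(m.counts)
        assert m.mean_turning[i[0], j[0]] == pytest.approx(2.0)

    def test_negative_r_min_rejected(self):
        obs = make_obs([1.0], [0.0], [0.0], [0.0], [0.0])
        with pytest.raises(ValueError, match="r_min"):
            theta_phi_turning_map(obs, r_min=-1.0)


class TestAlignmentModulation:
    def test_recovers_known_phi_slope(self):
        rng = np.random.default_rng(3)
        n = 20000
        phi = rng.uniform(-0.5, 0.5, n)
        theta = rng.uniform(-np.pi, np.pi, n)
        obs = make_obs(np.full(n, 8.0), theta, phi, 0.9 * phi, np.zeros(n))
        assert alignment_modulation(obs) == pytest.approx(0.9, abs=0.05)

    def test_sign_reversal_across_theta_does_not_cancel(self):
        rng = np.random.default_rng(4)
        n = 20000
        phi = rng.uniform(-0.5, 0.5, n)
        theta = rng.uniform(-np.pi, np.pi, n)
        slope = np.where(np.abs(theta) < np.pi / 2, 0.8, -0.8)
        obs = make_obs(np.full(n, 8.0), theta, phi, slope * phi, np.zeros(n))
        assert alignment_modulation(obs) == pytest.approx(0.8, abs=0.05)


@pytest.fixture(scope="module")
def trio_flights():
    cfg = SimulationConfig(n_individuals=3, n_steps=1024)
    return [simulate_flock(cfg.with_seed(s)) for s in range(40, 50)]


class TestMultiNeighbour:
    def test_zero_noise_mass_at_ideal_offsets(self):
        cfg = SimulationConfig(n_individuals=3, n_steps=256, displacement_std=0.0)
        ts = simulate_flock(cfg.with_seed(1))
        m = multi_neighbour_observed([ts], "turn", min_count=1)
        centres = 0.5 * (m.fb1_edges[:-1] + m.fb1_edges[1:])
        occupied = {
            (round(abs(centres[i])), round(abs(centres[j])))
            for i, j in zip(*np.nonzero(m.counts))
        }
        # ideal configurations: neighbours at (|5|, |10|) or (|5|, |5|)
        assert occupied <= {(4, 9), (4, 10), (5, 10), (5, 5), (4, 4), (5, 9)}

    def test_random_ordering_symmetric_counts(self, trio_flights):
        m = multi_neighbour_observed(
            trio_flights, "turn", ordering="random", rng=np.random.default_rng(0)
        )
        # axis assignment is a fair coin per observation: the count matrix is
        # symmetric up to binomial noise
        asym = np.abs(m.counts - m.counts.T)
        scale = np.sqrt(np.maximum(m.counts + m.counts.T, 1))
        assert (asym <= 6 * scale + 10).all()

    def test_requires_three_individuals(self):
        ts = simulate_flock(SimulationConfig(n_steps=128, seed=2))
        with pytest.raises(ValueError, match="three-individual"):
            multi_neighbour_observed([ts], "turn")

    def test_unknown_response_kind_rejected(self, trio_flights):
        with pytest.raises(ValueError, match="response_kind"):
            multi_neighbour_observed(trio_flights, "speed")


class TestPredictFromPairwise:
    def test_zero_profile_predicts_zero(self):
        edges = np.linspace(-15, 15, 31)
        template = _make_template(edges)
        prof = FrontBackProfile(edges=edges, counts=np.full(30, 10),
                                mean_response=np.zeros(30))
        pred = predict_from_pairwise(prof, template)
        np.testing.assert_array_equal(pred.mean_response, 0.0)

    def test_linear_profile_closed_form(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        template = _make_template(edges)
        centres = 0.5 * (edges[:-1] + edges[1:])
        prof = FrontBackProfile(edges=edges, counts=np.full(3, 10),
                                mean_response=centres.copy())
        pred = predict_from_pairwise(prof, template)
        expected = 0.5 * (centres[:, None] + centres[None, :])
        np.testing.assert_allclose(pred.mean_response, expected, atol=1e-14)
        np.testing.assert_allclose(pred.mean_response, pred.mean_response.T, atol=0)

    def test_mismatched_edges_rejected(self):
        template = _make_template(np.linspace(-15, 15, 31))
        prof = FrontBackProfile(edges=np.linspace(-10, 10, 21),
                                counts=np.full(20, 10), mean_response=np.zeros(20))
        with pytest.raises(ValueError, match="match exactly"):
            predict_from_pairwise(prof, template)

    def test_modulation_range_empty_mask_rejected(self):
        template = _make_template(np.linspace(-15, 15, 31))
        with pytest.raises(ValueError, match="reliable"):
            modulation_range(template, np.zeros_like(template.counts, dtype=bool))


def _make_template(edges):
    from flocknoise import NeighbourPairMap

    nb = edges.size - 1
    return NeighbourPairMap(
        fb1_edges=edges,
        fb2_edges=edges,
        counts=np.zeros((nb, nb), dtype=int),
        mean_response=np.full((nb, nb), np.nan),
        response_kind="turn",
    )
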