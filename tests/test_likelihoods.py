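import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scrselect.capture_data import BilateralData, StateSpace, TrapArray
from scrselect.likelihoods import (MODEL_PARAMS, LatentState, ScalarParams,
                                   complete_data_loglik,
                                   detection_loglik_terms,
                                   detection_prob_royle, individual_loglik,
                                   integrated_loglik, log_prior,
                                   state_space_grid, trap_entry_prob,
                                   transform_params, untransform_params)

RNG = np.random.default_rng(2024)


def random_params(model_id, rng=RNG, lo=0.15, hi=0.85):
    vals = {}
    for n in MODEL_PARAMS[model_id]:
        vals[n] = rng.uniform(0.1, 3) if n.startswith("sigma") \
            else rng.uniform(lo, hi)
    return ScalarParams(model_id=model_id, **vals)


def single_cell_counts(y1, y2):
    both = y1 + y2
    return {"ydd": np.array([both]),
            "n_dot": np.array([int(both > 0)]),
            "n_ij": np.array([[int(both > 0)]]),
            "y_ij": np.array([[both]])}


class TestKernels:
    def test_entry_prob_at_zero_distance(self):
        assert trap_entry_prob(0.07, 0.3, 0.0) == 0.07

    def test_entry_prob_value(self):
        assert trap_entry_prob(0.05, 0.3, 0.3) == pytest.approx(
            0.05 * np.exp(-0.5), rel=1e-12)
        assert trap_entry_prob(0.05, 0.3, 0.3) == pytest.approx(0.030327,
                                                                abs=1e-6)

    def test_entry_prob_monotone_and_limit(self):
        d = np.linspace(0, 50, 200)
        eta = trap_entry_prob(0.5, 0.4, d)
        assert (np.diff(eta) <= 0).all()
        assert eta[-1] < 1e-12

    def test_royle_prob_value(self):
        assert detection_prob_royle(0.1, 0.2, 0.2) == pytest.approx(
            0.060653, abs=1e-6)

    def test_royle_prob_increases_with_sigma(self):
        assert detection_prob_royle(0.1, 0.4, 0.2) > \
            detection_prob_royle(0.1, 0.2, 0.2)


class TestCompleteDataLoglik:
    def test_single_cell_outcomes_are_proper(self):
        """For every model, the four (y1, y2) outcomes of one individual at
        one trap on one occasion have probabilities summing to 1."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            d2 = np.array([[rng.uniform(0, 1) ** 2]])
            for mid in ("M1", "M2", "M3", "M4"):
                p = random_params(mid, rng, lo=0.05, hi=0.95)
                u = rng.integers(0, 2, 1)
                tot = sum(
                    np.exp(detection_loglik_terms(
                        p, d2, p.sigma_of_sex(u),
                        single_cell_counts(a, b), K=1)[0])
                    for a, b in itertools.product((0, 1), (0, 1)))
                assert tot == pytest.approx(1.0, abs=1e-12)

    def test_entry_model_single_cell_probabilities(self):
        """Outcome masses are (1-eta)+eta(1-phi)^2, eta phi(1-phi) twice,
        and eta phi^2."""
        p = ScalarParams(model_id="M3", psi=0.5, phi=0.6, omega0=0.3,
                        sigma=0.5)
        d2 = np.array([[0.04]])
        eta = 0.3 * np.exp(-0.04 / (2 * 0.25))
        expected = {(0, 0): (1 - eta) + eta * 0.16,
                    (1, 0): eta * 0.6 * 0.4,
                    (0, 1): eta * 0.6 * 0.4,
                    (1, 1): eta * 0.36}
        for (a, b), val in expected.items():
            got = detection_loglik_terms(p, d2, np.array([0.5]),
                                         single_cell_counts(a, b), K=1)[0]
            assert np.exp(got) == pytest.approx(val, rel=1e-12)

    def test_certain_detection_kills_single_detections(self):
        """phi = 1 degenerates the entry model: every entry is a double
        detection, so a single-detector outcome has probability zero."""
        p = ScalarParams(model_id="M3", psi=0.5, phi=1.0, omega0=0.3,
                        sigma=0.5)
        got = detection_loglik_terms(p, np.array([[0.1]]), np.array([0.5]),
                                     single_cell_counts(1, 0), K=1)
        assert got[0] == -np.inf

    def test_individual_logliks_sum_to_total(self):
        rng = np.random.default_rng(8)
        space = StateSpace(0, 1, 0, 1)
        traps = TrapArray(rng.uniform(0.2, 0.8, (3, 2)), np.arange(1, 4))
        for mid in ("M1", "M2", "M3", "M4"):
            y1 = rng.integers(0, 2, (4, 3, 2)).astype(np.uint8)
            y2 = rng.integers(0, 2, (4, 3, 2)).astype(np.uint8)
            data = BilateralData(y1=y1, y2=y2, K=2, M=4, n_obs1=4, n_obs2=4)
            lat = LatentState(z=np.ones(4, np.int8),
                              u=rng.integers(0, 2, 4).astype(np.int8),
                              S=rng.uniform(0, 1, (4, 2)),
                              L=rng.permutation(4))
            p = random_params(mid, rng)
            total = complete_data_loglik(data, p, lat, traps)
            parts = sum(individual_loglik(i, data, p, lat, traps)
                        for i in range(4))
            assert parts == pytest.approx(total, abs=1e-10)

    def test_direct_model_matches_cell_product_oracle(self):
        """The direct-detection model with z=1 equals the product of
        independent Bernoulli masses over all 2 M J K cells."""
        rng = np.random.default_rng(12)
        M, J, K = 3, 2, 2
        traps = TrapArray(rng.uniform(0, 1, (J, 2)), np.arange(1, J + 1))
        y1 = rng.integers(0, 2, (M, J, K)).astype(np.uint8)
        y2 = rng.integers(0, 2, (M, J, K)).astype(np.uint8)
        data = BilateralData(y1=y1, y2=y2, K=K, M=M, n_obs1=M, n_obs2=M)
        p = random_params("M4", rng)
        lat = LatentState(z=np.ones(M, np.int8), u=np.zeros(M, np.int8),
                          S=rng.uniform(0, 1, (M, 2)), L=np.arange(M))
        oracle = 0.0
        for i in range(M):
            for j in range(J):
                d = np.linalg.norm(lat.S[i] - traps.coordinates[j])
                pj = detection_prob_royle(p.p0, p.sigma, d)
                for k in range(K):
                    for y in (y1[i, j, k], y2[i, j, k]):
                        oracle += np.log(pj if y else 1 - pj)
        assert complete_data_loglik(data, p, lat, traps) == \
            pytest.approx(oracle, abs=1e-10)

    def test_all_excluded_leaves_only_sex_prior(self):
        M = 3
        traps = TrapArray(np.array([[0.5, 0.5]]), np.array([1]))
        zero = np.zeros((M, 1, 2), np.uint8)
        data = BilateralData(y1=zero, y2=zero, K=2, M=M, n_obs1=0, n_obs2=0)
        lat = LatentState(z=np.zeros(M, np.int8),
                          u=np.array([1, 0, 1], np.int8),
                          S=np.full((M, 2), 0.5), L=np.arange(M))
        for mid in ("M1", "M2"):
            p = random_params(mid)
            expected = 2 * np.log(p.theta) + np.log(1 - p.theta)
            assert complete_data_loglik(data, p, lat, traps) == \
                pytest.approx(expected, abs=1e-12)
        for mid in ("M3", "M4"):
            p = random_params(mid)
            assert complete_data_loglik(data, p, lat, traps) == 0.0

    def test_detection_with_excluded_row_is_impossible(self):
        traps = TrapArray(np.array([[0.5, 0.5]]), np.array([1]))
        y = np.zeros((1, 1, 1), np.uint8)
        y1 = y.copy(); y1[0, 0, 0] = 1
        data = BilateralData(y1=y1, y2=y, K=1, M=1, n_obs1=1, n_obs2=0)
        p = random_params("M3")
        lat = LatentState(z=np.zeros(1, np.int8), u=np.zeros(1, np.int8),
                          S=np.array([[0.5, 0.5]]), L=np.arange(1))
        assert complete_data_loglik(data, p, lat, traps) == -np.inf


class TestPriorsAndTransforms:
    def test_natural_scale_prior_values(self):
        p = ScalarParams(model_id="M4", psi=0.5, p0=0.2, sigma=3.0, R=10.0)
        assert log_prior(p) == pytest.approx(-np.log(10.0))
        p1 = ScalarParams(model_id="M1", psi=0.5, theta=0.5, phi=0.5,
                         omega0=0.5, sigma_m=1.0, sigma_f=2.0, R=10.0)
        assert log_prior(p1) == pytest.approx(-2 * np.log(10.0))

    def test_out_of_support(self):
        p = ScalarParams(model_id="M4", psi=0.5, p0=0.2, sigma=10.0, R=10.0)
        assert log_prior(p) == -np.inf

    def test_transformed_prior_matches_finite_difference_jacobian(self):
        """The transformed-scale density equals the natural density times
        |d(natural)/d(transformed)|, checked numerically."""
        p = ScalarParams(model_id="M4", psi=0.31, p0=0.62, sigma=1.7, R=10.0)
        x = transform_params(p)
        eps = 1e-6
        log_jac = 0.0
        for i in range(len(x)):
            xp = x.copy(); xp[i] += eps
            xm = x.copy(); xm[i] -= eps
            up = untransform_params(xp, "M4").to_vector()
            um = untransform_params(xm, "M4").to_vector()
            log_jac += np.log((up[i] - um[i]) / (2 * eps))
        assert log_prior(p, on_transformed_scale=True) == pytest.approx(
            log_prior(p) + log_jac, abs=1e-6)

    def test_midpoints_map_to_zero(self):
        p = ScalarParams(model_id="M4", psi=0.5, p0=0.5, sigma=5.0, R=10.0)
        assert np.allclose(transform_params(p), 0.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        for mid in ("M1", "M2", "M3", "M4"):
            p = random_params(mid, rng, lo=0.01, hi=0.99)
            back = untransform_params(transform_params(p), mid, R=p.R)
            assert np.allclose(back.to_vector(), p.to_vector(), atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            untransform_params(np.array([np.inf, 0.0, 0.0]), "M4")


def brute_force_integrated(data, params, L, traps, space, gx, gy):
    """Exhaustive marginalization over z, missing sexes and the grid."""
    cells = state_space_grid(space, gx, gy)
    M = data.M
    sexed = params.model_id in ("M1", "M2")
    urange = list(itertools.product((0, 1), repeat=M)) if sexed else \
        [tuple([0] * M)]
    total = 0.0
    for z in itertools.product((0, 1), repeat=M):
        for u in urange:
            for cell_idx in itertools.product(range(len(cells)), repeat=M):
                S = cells[list(cell_idx)]
                lat = LatentState(z=np.array(z, np.int8),
                                  u=np.array(u, np.int8), S=S, L=L)
                ll = complete_data_loglik(data, params, lat, traps)
                if not np.isfinite(ll):
                    continue
                prior = np.prod([params.psi if zi else 1 - params.psi
                                 for zi in z]) / len(cells) ** M
                total += np.exp(ll) * prior
    return np.log(total)


class TestIntegratedLikelihood:
    space = StateSpace(0, 1, 0, 1)
    traps = TrapArray(np.array([[0.3, 0.5], [0.7, 0.5]]), np.array([1, 2]))

    def _data(self, rng):
        y1 = rng.integers(0, 2, (2, 2, 1)).astype(np.uint8)
        y2 = rng.integers(0, 2, (2, 2, 1)).astype(np.uint8)
        o1 = np.argsort(~y1.any(axis=(1, 2)))
        o2 = np.argsort(~y2.any(axis=(1, 2)))
        y1, y2 = y1[o1], y2[o2]
        return BilateralData(y1=y1, y2=y2, K=1, M=2,
                             n_obs1=int(y1.any(axis=(1, 2)).sum()),
                             n_obs2=int(y2.any(axis=(1, 2)).sum()))

    @pytest.mark.parametrize("mid", ["M1", "M2", "M3", "M4"])
    def test_matches_exhaustive_enumeration(self, mid):
        rng = np.random.default_rng(hash(mid) % 1000)
        for trial in range(4):
            data = self._data(rng)
            p = random_params(mid, rng)
            L = rng.permutation(2)
            il = integrated_loglik(data, p, L, self.traps, self.space,
                                   grid_resolution=(2, 2))
            oracle = brute_force_integrated(data, p, L, self.traps,
                                            self.space, 2, 2)
            assert il == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_single_cell_equals_complete_loglik(self):
        """psi=1 and a one-cell grid pins z=1 and s at the cell center."""
        y1 = np.ones((1, 2, 1), np.uint8)
        y2 = np.ones((1, 2, 1), np.uint8)
        data = BilateralData(y1=y1, y2=y2, K=1, M=1, n_obs1=1, n_obs2=1)
        p = ScalarParams(model_id="M3", psi=1 - 1e-14, phi=0.7, omega0=0.4,
                        sigma=0.5)
        center = state_space_grid(self.space, 1, 1)[0]
        lat = LatentState(z=np.ones(1, np.int8), u=np.zeros(1, np.int8),
                          S=center[None, :], L=np.arange(1))
        il = integrated_loglik(data, p, np.arange(1), self.traps, self.space,
                               grid_resolution=(1, 1))
        assert il == pytest.approx(
            complete_data_loglik(data, p, lat, self.traps), abs=1e-9)

    def test_all_zero_row_factor_below_one(self):
        zero = np.zeros((1, 2, 1), np.uint8)
        data = BilateralData(y1=zero, y2=zero, K=1, M=1, n_obs1=0, n_obs2=0)
        p = random_params("M3")
        il = integrated_loglik(data, p, np.arange(1), self.traps, self.space,
                               grid_resolution=(4, 4))
        assert -np.inf < il < 0.0

    def test_grid_refinement_converges(self, tiny_setup):
        data = tiny_setup["data"]
        p = ScalarParams(model_id="M3", psi=0.4, phi=0.85, omega0=0.05,
                        sigma=0.25)
        L = np.arange(data.M)
        coarse = integrated_loglik(data, p, L, tiny_setup["traps"],
                                   tiny_setup["space"],
                                   grid_resolution=(28, 28))
        fine = integrated_loglik(data, p, L, tiny_setup["traps"],
                                 tiny_setup["space"],
                                 grid_resolution=(56, 56))
        assert abs(fine - coarse) < 1e-3 * abs(fine)

    def test_sexed_model_with_common_scale_matches_sexless(self):
        """With sigma_m = sigma_f and no observed sexes, the sex covariate
        integrates out: the sexed entry model's integrated likelihood equals
        the sexless one's."""
        rng = np.random.default_rng(77)
        data = self._data(rng)
        p1 = ScalarParams(model_id="M1", psi=0.4, theta=0.37, phi=0.7,
                         omega0=0.3, sigma_m=0.5, sigma_f=0.5)
        p3 = ScalarParams(model_id="M3", psi=0.4, phi=0.7, omega0=0.3,
                         sigma=0.5)
        L = np.arange(2)
        il1 = integrated_loglik(data, p1, L, self.traps, self.space, (3, 3))
        il3 = integrated_loglik(data, p3, L, self.traps, self.space, (3, 3))
        assert il1 == pytest.approx(il3, abs=1e-10)
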