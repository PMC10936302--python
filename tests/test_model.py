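"""Tests for the cyclostationary Gaussian model and chi-squared calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitintent as gi
from gaitintent.exceptions import IllConditionedModelError, ModelFormatError
from gaitintent.model import GaussianCell, update_cell
from gaitintent.segmentation import PHASE_ORDER, GaitPhase, PhaseTimestep


def batch_mle(xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = xs.mean(axis=0)
    centered = xs - mu
    return mu, centered.T @ centered / len(xs)


class TestUpdateCell:
    def test_single_observation(self):
        cell = update_cell(None, [1.0, 2.0])
        assert cell.n == 1
        assert np.allclose(cell.mu, [1.0, 2.0])
        assert np.allclose(cell.sigma, 0.0)

    def test_two_scalar_observations_match_mle(self):
        cell = update_cell(update_cell(None, [0.0]), [2.0])
        assert cell.n == 2
        assert cell.mu[0] == pytest.approx(1.0)
        # MLE covariance divides by n: ((0-1)^2 + (2-1)^2) / 2 = 1
        assert cell.sigma[0, 0] == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        cell = update_cell(None, [1.0, 2.0])
        with pytest.raises(ValueError):
            update_cell(cell, [1.0, 2.0, 3.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=60),
        m=st.integers(min_value=1, max_value=5),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_recursive_equals_batch_mle(self, n, m, seed):
        """Single-pass recursion reproduces the batch ML estimates exactly."""
        rng = np.random.default_rng(seed)
        xs = rng.normal(scale=10.0, size=(n, m))
        cell = None
        for x in xs:
            cell = update_cell(cell, x)
        mu, sigma = batch_mle(xs)
        assert cell.n == n
        assert np.allclose(cell.mu, mu, atol=1e-10)
        assert np.allclose(cell.sigma, sigma, atol=1e-10)
        assert np.allclose(cell.sigma, cell.sigma.T, atol=1e-12)


class TestSquaredMahalanobis:
    def test_distance_to_own_mean_is_zero(self):
        cell = GaussianCell(5, np.array([1.0, -2.0]), np.eye(2))
        assert gi.squared_mahalanobis([1.0, -2.0], cell, ridge=0.0) == pytest.approx(0.0)

    def test_identity_covariance_is_squared_euclidean(self):
        cell = GaussianCell(5, np.zeros(2), np.eye(2))
        assert gi.squared_mahalanobis([3.0, 4.0], cell, ridge=0.0) == pytest.approx(25.0)

    def test_diagonal_covariance_hand_value(self):
        cell = GaussianCell(5, np.array([1.0, 2.0]), np.diag([2.0, 8.0]))
        # 2^2/2 + 4^2/8 = 4
        assert gi.squared_mahalanobis([3.0, 6.0], cell, ridge=0.0) == pytest.approx(4.0)

    def test_singular_covariance_raises_without_ridge(self):
        cell = GaussianCell(1, np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(IllConditionedModelError):
            gi.squared_mahalanobis([1.0, 1.0], cell, ridge=0.0)
        # the default ridge rescues degenerate cells
        assert gi.squared_mahalanobis([0.0, 0.0], cell, ridge=1e-6) == pytest.approx(0.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_affine_invariance(self, seed):
        """d2 is invariant under joint invertible affine maps of x, mu, Sigma."""
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 5)
        a = rng.normal(size=(m, m))
        sigma = a @ a.T + 0.5 * np.eye(m)
        mu = rng.normal(size=m)
        x = rng.normal(size=m)
        t = rng.normal(size=(m, m)) + 2 * np.eye(m)  # near-identity, invertible
        b = rng.normal(size=m)
        cell = GaussianCell(10, mu, sigma)
        cell_t = GaussianCell(10, t @ mu + b, t @ sigma @ t.T)
        d0 = gi.squared_mahalanobis(x, cell, ridge=0.0)
        d1 = gi.squared_mahalanobis(t @ x + b, cell_t, ridge=0.0)
        assert d1 == pytest.approx(d0, rel=1e-7)


class TestChiSquaredCalibration:
    def even_dof_cdf(self, x, dof):
        # closed form for even dof: 1 - e^{-x/2} * sum_{i<dof/2} (x/2)^i / i!
        return 1.0 - math.exp(-x / 2) * sum(
            (x / 2) ** i / math.factorial(i) for i in range(dof // 2)
        )

    def test_threshold_13p5_gives_cdf_0_99(self):
        val = gi.chi2_cdf(13.5, 4)
        assert round(val, 2) == 0.99
        assert val == pytest.approx(self.even_dof_cdf(13.5, 4), abs=1e-10)

    @pytest.mark.parametrize("dof", [2, 4, 6, 8])
    @pytest.mark.parametrize("x", [0.0, 1.0, 4.0, 13.5, 40.0])
    def test_matches_even_dof_closed_form(self, dof, x):
        assert gi.chi2_cdf(x, dof) == pytest.approx(self.even_dof_cdf(x, dof), abs=1e-10)

    def test_cdf_limits_and_monotonicity(self):
        xs = np.linspace(0, 100, 200)
        vals = [gi.chi2_cdf(x, 4) for x in xs]
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] > 1 - 1e-9

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gi.chi2_cdf(1.0, 0)
        with pytest.raises(ValueError):
            gi.chi2_cdf(-1.0, 4)

    def test_threshold_inverse_round_trip(self):
        assert gi.threshold_for_cdf(gi.chi2_cdf(13.5, 4), 4) == pytest.approx(13.5, abs=1e-6)

    def test_dof2_median_closed_form(self):
        assert gi.threshold_for_cdf(0.5, 2) == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_threshold_diverges_near_one(self):
        assert gi.threshold_for_cdf(1 - 1e-12, 4) > gi.threshold_for_cdf(0.999, 4) > 13.5
        with pytest.raises(ValueError):
            gi.threshold_for_cdf(1.0, 4)

    def test_self_samples_follow_chi2(self):
        """Squared distances of draws from a cell's own Gaussian follow chi2(m)."""
        rng = np.random.default_rng(42)
        m, n = 4, 20000
        a = rng.normal(size=(m, m))
        sigma = a @ a.T + np.eye(m)
        mu = rng.normal(size=m)
        cell = GaussianCell(n, mu, sigma)
        xs = rng.multivariate_normal(mu, sigma, size=n)
        d2 = np.array([gi.squared_mahalanobis(x, cell, ridge=0.0) for x in xs])
        assert d2.mean() == pytest.approx(m, abs=0.1)
        thr = gi.threshold_for_cdf(0.99, m)
        assert np.mean(d2 > thr) == pytest.approx(0.01, abs=0.004)


def _two_cycle_stream():
    """Two identical noiseless cycles of a toy 2-channel gait."""
    pts, xs = [], []
    lengths = {p: 5 for p in PHASE_ORDER}
    for _ in range(3):  # 3 cycles; the first run is dropped by fit
        for p in PHASE_ORDER:
            for k in range(1, lengths[p] + 1):
                pts.append(PhaseTimestep(p, k))
                xs.append([10.0 * k, -k])
    return np.array(xs, dtype=float), pts


class TestFit:
    def test_deterministic_cycles_give_zero_variance(self):
        xs, pts = _two_cycle_stream()
        res = gi.CyclostationaryGaitModel(xs, pts, dt=0.01).fit()
        for cell in res.cells.values():
            assert np.allclose(cell.sigma, 0.0)
        for p in PHASE_ORDER:
            assert res.timing.phase_steps_std[p] == 0.0
        assert res.timing.cycle_std == 0.0
        assert res.timing.cycle_mean == pytest.approx(20 * 0.01)

    def test_cell_counts_track_cycle_count(self, trained_results):
        n_cycles = trained_results.timing.n_cycles
        counts = [c.n for c in trained_results.cells.values()]
        # interior cells are visited once per cycle (boundary cells may
        # alternate due to grid jitter, and the first run is dropped)
        assert np.median(counts) == pytest.approx(n_cycles, abs=2)
        assert max(counts) <= n_cycles + 2

    def test_contiguous_timestep_range(self, trained_results):
        trained_results.check_contiguity()

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            gi.CyclostationaryGaitModel(np.empty((0, 2)), [], dt=0.01).fit()


class TestPersistence:
    def test_round_trip_is_lossless(self, trained_results, tmp_path):
        path = tmp_path / "model.json"
        trained_results.save(path)
        back = gi.GaitModelResults.load(path)
        assert back.m == trained_results.m
        assert back.dt == trained_results.dt
        assert set(back.cells) == set(trained_results.cells)
        for key, cell in trained_results.cells.items():
            assert back.cells[key].n == cell.n
            assert np.allclose(back.cells[key].mu, cell.mu, atol=1e-12)
            assert np.allclose(back.cells[key].sigma, cell.sigma, atol=1e-12)
        assert back.timing.cycle_mean == trained_results.timing.cycle_mean

    def test_missing_timing_block_rejected(self, trained_results, tmp_path):
        import json

        path = tmp_path / "model.json"
        trained_results.save(path)
        payload = json.loads(path.read_text())
        del payload["timing"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError):
            gi.GaitModelResults.load(path)

    def test_version_mismatch_rejected(self, trained_results, tmp_path):
        import json

        path = tmp_path / "model.json"
        trained_results.save(path)
        payload = json.loads(path.read_text())
        payload["format_version"] = "999"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError):
            gi.GaitModelResults.load(path)

    def test_resumed_training_matches_uninterrupted(self, tmp_path):
        xs, pts = _two_cycle_stream()
        rng = np.random.default_rng(0)
        xs = xs + rng.normal(scale=0.1, size=xs.shape)
        full = gi.CyclostationaryGaitModel(xs, pts, dt=0.01).fit()
        split = 40  # a run boundary: 40 = 2 full cycles of 20 frames
        part = gi.CyclostationaryGaitModel(xs[:split], pts[:split], dt=0.01).fit()
        path = tmp_path / "part.json"
        part.save(path)
        resumed = gi.GaitModelResults.load(path)
        resumed.update(xs[split:], pts[split:])
        for key, cell in full.cells.items():
            assert resumed.cells[key].n == cell.n
            assert np.allclose(resumed.cells[key].mu, cell.mu, atol=1e-10)
            assert np.allclose(resumed.cells[key].sigma, cell.sigma, atol=1e-10)


class TestResultsApi:
    def test_summary_mentions_core_quantities(self, trained_results):
        text = trained_results.summary()
        assert "cycle duration" in text
        assert "LDS" in text and "RSS" in text

    def test_missing_cell_lookup_raises(self, trained_results):
        with pytest.raises(KeyError):
            trained_results.squared_mahalanobis(
                np.zeros(4), GaitPhase.LDS, trained_results.max_k(GaitPhase.LDS) + 10
            )
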