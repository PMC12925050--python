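import numpy as np
import pytest
from scipy.stats import multivariate_normal

from leadtrack import (
    BeamGeometry,
    GaussianPDFParams,
    IdentifiabilityWarning,
    Observation2D,
    beam_frame,
    estimate_3d,
    estimate_from_ground_truth,
    fit_gaussian_ml,
    negative_log_likelihood,
    project_gaussian,
)
from leadtrack.estimation import VARIANCE_FLOOR, observations_from_ground_truth


def synth_observations(mu, sigmas, n, seed, meas_sd=0.0, arc=360.0, angle_offset=0.0):
    """Observations of 3D Gaussian samples seen over a gantry arc."""
    rng = np.random.default_rng(seed)
    angles = angle_offset + np.arange(n) * arc / n
    pts = np.asarray(mu) + rng.normal(size=(n, 3)) * np.asarray(sigmas)
    obs = []
    for i, (ang, p) in enumerate(zip(angles, pts)):
        a, b, _ = beam_frame(ang)
        noise = rng.normal(0, meas_sd, 2) if meas_sd else np.zeros(2)
        obs.append(Observation2D(i, float(ang), float(a @ p + noise[0]), float(b @ p + noise[1])))
    return obs, pts


class TestProjectGaussian:
    def test_isotropic_covariance_is_rotation_invariant(self):
        params = GaussianPDFParams(mu=np.zeros(3), sigma=4.0 * np.eye(3), meas_var=0.25)
        for theta in (0.0, 33.0, 120.0, 270.0):
            _, cov = project_gaussian(params, theta)
            np.testing.assert_allclose(cov, 4.25 * np.eye(2), atol=1e-12)

    def test_axis_aligned_at_zero_angle(self):
        sigma = np.diag([9.0, 25.0, 4.0])
        params = GaussianPDFParams(mu=np.array([1.0, 2.0, 3.0]), sigma=sigma, meas_var=0.25)
        mean, cov = project_gaussian(params, 0.0)
        np.testing.assert_allclose(mean, [1.0, 2.0])
        np.testing.assert_allclose(np.diag(cov), [9.25, 25.25])

    def test_matches_monte_carlo_projection(self, rng):
        A = rng.normal(size=(3, 3))
        sigma = A @ A.T + np.eye(3)
        mu = rng.normal(size=3)
        params = GaussianPDFParams(mu=mu, sigma=sigma, meas_var=0.0)
        theta = 47.0
        a, b, _ = beam_frame(theta)
        samples = rng.multivariate_normal(mu, sigma, size=200_000)
        uv = samples @ np.stack([a, b]).T
        mean, cov = project_gaussian(params, theta)
        np.testing.assert_allclose(mean, uv.mean(axis=0), atol=0.05)
        np.testing.assert_allclose(cov, np.cov(uv.T), rtol=0.03, atol=0.05)


class TestNegativeLogLikelihood:
    def test_density_at_mode_with_unit_covariance(self):
        # projected covariance is identity when sigma + meas_var sums to 1
        params = GaussianPDFParams(
            mu=np.zeros(3), sigma=0.5 * np.eye(3), meas_var=0.5
        )
        obs = [Observation2D(0, 0.0, 0.0, 0.0)]
        assert negative_log_likelihood(params, obs) == pytest.approx(np.log(2 * np.pi), abs=1e-12)

    def test_additivity_when_doubling_observations(self, rng):
        params = GaussianPDFParams(mu=rng.normal(size=3), sigma=3.0 * np.eye(3))
        obs, _ = synth_observations([0, 0, 0], [2, 2, 2], 20, seed=0)
        assert negative_log_likelihood(params, obs + obs) == pytest.approx(
            2 * negative_log_likelihood(params, obs), rel=1e-12
        )

    def test_matches_bivariate_normal_density_oracle(self, rng):
        A = rng.normal(size=(3, 3))
        params = GaussianPDFParams(
            mu=rng.normal(size=3), sigma=A @ A.T + np.eye(3), meas_var=0.25
        )
        obs, _ = synth_observations([1, -1, 2], [3, 4, 2], 30, seed=2)
        expected = 0.0
        for o in obs:
            mean, cov = project_gaussian(params, o.gantry_angle)
            expected -= multivariate_normal(mean, cov).logpdf([o.u, o.v])
        assert negative_log_likelihood(params, obs) == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_static_target_recovered_with_floor_covariance(self, geom):
        tip = np.array([3.0, -2.0, 5.0])
        obs = []
        for i, ang in enumerate(np.arange(0, 360, 1.0)):
            a, b, _ = beam_frame(ang)
            obs.append(Observation2D(i, float(ang), float(a @ tip), float(b @ tip)))
        params = fit_gaussian_ml(obs)
        np.testing.assert_allclose(params.mu, tip, atol=0.05)
        assert np.all(np.diag(params.sigma) < 5 * VARIANCE_FLOOR)

    def test_parameter_recovery_from_gaussian_motion(self):
        sig = np.array([3.0, 5.0, 2.0])
        obs, _ = synth_observations([3, -2, 5], sig, 600, seed=42, meas_sd=0.5)
        params = fit_gaussian_ml(obs)
        np.testing.assert_allclose(params.mu, [3, -2, 5], atol=0.5)
        np.testing.assert_allclose(np.sqrt(np.diag(params.sigma)), sig, rtol=0.15)

    def test_single_angle_raises_identifiability_warning(self):
        obs = [Observation2D(i, 0.0, float(i), float(-i)) for i in range(20)]
        with pytest.warns(IdentifiabilityWarning):
            fit_gaussian_ml(obs)

    def test_narrow_arc_warns(self):
        obs, _ = synth_observations([0, 0, 0], [2, 2, 2], 50, seed=1, arc=20.0)
        with pytest.warns(IdentifiabilityWarning):
            fit_gaussian_ml(obs)

    def test_mean_converges_with_observation_count(self):
        """Noiseless full-arc consistency: mu error non-increasing in n."""
        errors = []
        for n in (100, 400, 1600):
            obs, _ = synth_observations([2, -1, 3], [3, 5, 2], n, seed=7)
            params = fit_gaussian_ml(obs)
            errors.append(np.linalg.norm(params.mu - [2, -1, 3]))
        assert errors[2] <= errors[0] + 1e-9
        assert errors[2] < 0.5

    def test_freeze_cross_covariance_option(self):
        obs, _ = synth_observations([0, 0, 0], [3, 5, 2], 200, seed=3)
        params = fit_gaussian_ml(obs, fit_cross=False)
        off = params.sigma[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_ml([Observation2D(0, 0.0, 0.0, 0.0)])

    def test_rotation_equivariance(self):
        """Rotating the trajectory and all gantry angles by a common
        offset about SI rotates mu and Sigma accordingly: the shifted
        observations are numerically identical, so the fits must agree
        after transforming back."""
        phi = 90.0
        obs0, _ = synth_observations([4, -1, 2], [3, 5, 2], 400, seed=11)
        obs_rot = [
            Observation2D(o.projection_index, o.gantry_angle + phi, o.u, o.v)
            for o in obs0
        ]
        p0 = fit_gaussian_ml(obs0)
        p_rot = fit_gaussian_ml(obs_rot)
        r = np.deg2rad(phi)
        R = np.array(
            [
                [np.cos(r), 0.0, -np.sin(r)],
                [0.0, 1.0, 0.0],
                [np.sin(r), 0.0, np.cos(r)],
            ]
        )
        np.testing.assert_allclose(p_rot.mu, R @ p0.mu, atol=1e-3)
        np.testing.assert_allclose(p_rot.sigma, R @ p0.sigma @ R.T, atol=1e-2)


class TestEstimate3D:
    def test_observation_at_projected_mean_returns_mu(self):
        params = GaussianPDFParams(mu=np.array([1.0, 2.0, 3.0]), sigma=4.0 * np.eye(3))
        for theta in (0.0, 65.0, 213.0):
            a, b, _ = beam_frame(theta)
            o = Observation2D(0, theta, float(a @ params.mu), float(b @ params.mu))
            est = estimate_3d(params, [o], refine_passes=0)
            np.testing.assert_allclose(est.positions[0], params.mu, atol=1e-10)

    def test_resolved_components_reproduce_observation(self, rng):
        A = rng.normal(size=(3, 3))
        params = GaussianPDFParams(mu=rng.normal(size=3), sigma=A @ A.T + np.eye(3))
        obs, _ = synth_observations([0, 1, -1], [2, 3, 1], 25, seed=5)
        est = estimate_3d(params, obs, refine_passes=0)
        for o, p in zip(obs, est.positions):
            a, b, _ = beam_frame(o.gantry_angle)
            assert a @ p == pytest.approx(o.u, abs=1e-12)
            assert b @ p == pytest.approx(o.v, abs=1e-12)

    def test_conditional_depth_matches_quadrature(self, rng):
        """Depth estimate equals 1D quadrature of the Gaussian along the
        observation ray."""
        for trial in range(10):
            A = rng.normal(size=(3, 3))
            params = GaussianPDFParams(
                mu=rng.normal(0, 3, 3), sigma=A @ A.T + 0.5 * np.eye(3), meas_var=0.25
            )
            theta = rng.uniform(0, 360)
            a, b, c = beam_frame(theta)
            o = Observation2D(0, theta, rng.normal(0, 3), rng.normal(0, 3))
            est = estimate_3d(params, [o], refine_passes=0)
            w_est = float(c @ est.positions[0])
            total = params.sigma + params.meas_var * np.eye(3)
            mvn = multivariate_normal(params.mu, total)
            ws = np.linspace(w_est - 60, w_est + 60, 400_001)
            pts = o.u * a[None] + o.v * b[None] + ws[:, None] * c[None]
            dens = mvn.pdf(pts)
            w_quad = np.trapezoid(ws * dens, ws) / np.trapezoid(dens, ws)
            assert w_est == pytest.approx(w_quad, abs=1e-6)

    def test_refinement_corrects_magnification(self, geom):
        """With the true depth known, one refinement pass moves resolved
        coordinates toward their true isocenter-scale values."""
        from leadtrack.geometry import backproject_resolved, project_point

        tip = np.array([10.0, 5.0, 60.0])
        params = GaussianPDFParams(mu=tip, sigma=VARIANCE_FLOOR * np.eye(3), meas_var=0.01)
        theta = 0.0
        a, b, _ = beam_frame(theta)
        u_img, v_img = project_point(tip, theta, geom)
        u0, v0 = backproject_resolved(u_img, v_img, theta, geom)  # nominal
        o = Observation2D(0, theta, u0, v0)
        coarse = estimate_3d(params, [o], geom=geom, refine_passes=0)
        refined = estimate_3d(params, [o], geom=geom, refine_passes=1)
        err_coarse = np.linalg.norm(coarse.positions[0][[0, 1]] - tip[[0, 1]])
        err_refined = np.linalg.norm(refined.positions[0][[0, 1]] - tip[[0, 1]])
        assert err_refined < err_coarse

    def test_empty_observations_rejected(self):
        params = GaussianPDFParams(mu=np.zeros(3), sigma=np.eye(3))
        with pytest.raises(ValueError):
            estimate_3d(params, [])


@pytest.fixture(scope="module")
def truth_table():
    import pandas as pd

    from leadtrack import MotionModel, default_metas, simulate_trajectory
    from leadtrack.geometry import imager_mm_to_px, project_point

    geom = BeamGeometry()
    metas = default_metas(120)
    model = MotionModel.for_mode("FB", resp_amplitude=(2, 8, 3))
    traj = simulate_trajectory(model, metas)
    rows = []
    for m, p in zip(metas, traj.positions):
        u, v = project_point(p, m.gantry_angle, geom)
        col, row = imager_mm_to_px(u, v, geom)
        rows.append((m.index, m.gantry_angle, float(col), float(row)))
    df = pd.DataFrame(rows, columns=["index", "gantry_deg", "u_px", "v_px"])
    return geom, df, traj


class TestGroundTruthPath:
    def test_noiseless_pipeline_rmse_below_1mm(self, truth_table):
        geom, df, traj = truth_table
        est = estimate_from_ground_truth(df, geom)
        err = est.positions - traj.positions
        rmse = np.sqrt((err**2).mean(axis=0))
        assert np.all(rmse < 1.0)

    def test_identical_to_explicit_fit_path(self, truth_table):
        geom, df, _ = truth_table
        est1 = estimate_from_ground_truth(df, geom)
        obs = observations_from_ground_truth(df, geom)
        params = fit_gaussian_ml(obs)
        est2 = estimate_3d(params, obs, geom=geom, refine_passes=1, source="truth")
        np.testing.assert_array_equal(est1.positions, est2.positions)

    def test_empty_truth_rejected(self):
        import pandas as pd

        df = pd.DataFrame(columns=["index", "gantry_deg", "u_px", "v_px"])
        with pytest.raises(ValueError):
            estimate_from_ground_truth(df, BeamGeometry())
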