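"""2D-to-3D trajectory estimation via a maximum-likelihood Gaussian PDF.

A single projection resolves only two of the three position coordinates:
the in-plane lateral direction and SI. The depth along the ray is
recovered statistically. Over a CBCT scan the target positions are
modeled as draws from one 3D Gaussian N(mu, Sigma); its nine free
parameters (mean and covariance factor) are fitted by maximizing the
likelihood of all angled 2D observations, each of which sees the
marginal of the Gaussian onto its resolved plane. Per projection the
unresolved depth is then the conditional mean of the Gaussian given the
observed resolved coordinates, and the 3D estimate keeps the observed
in-plane values untouched.

An isotropic measurement-noise variance ``meas_var`` (default 0.25 mm^2,
roughly half-pixel localization noise at isocenter scale) is added to
the Gaussian's covariance, so the fitted Sigma describes true motion
spread rather than absorbing segmentation jitter. The covariance is
parameterized by a lower-triangular Cholesky factor with log-diagonal,
which keeps it positive semidefinite without constraints; a small floor
(1e-4 mm^2) on the diagonal guards the degenerate static-target case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import BeamGeometry, beam_frame, imager_px_to_mm

__all__ = [
    "Observation2D",
    "GaussianPDFParams",
    "TrajectoryEstimate",
    "FitError",
    "IdentifiabilityWarning",
    "observations_from_segmentations",
    "observations_from_ground_truth",
    "project_gaussian",
    "negative_log_likelihood",
    "fit_gaussian_ml",
    "estimate_3d",
    "estimate_from_ground_truth",
]

VARIANCE_FLOOR = 1e-4  # mm^2, on the Sigma diagonal
DEFAULT_MEAS_VAR = 0.25  # mm^2, isotropic measurement noise


class FitError(RuntimeError):
    """Maximum-likelihood fit failed; carries the last iterate."""

    def __init__(self, message: str, params: "GaussianPDFParams", diagnostics: dict):
        super().__init__(message)
        self.params = params
        self.diagnostics = diagnostics


class IdentifiabilityWarning(UserWarning):
    """Observation geometry too narrow to constrain all parameters."""


@dataclass(frozen=True)
class Observation2D:
    """Resolved coordinates of one projection, at isocenter scale (mm)."""

    projection_index: int
    gantry_angle: float
    u: float
    v: float


@dataclass(frozen=True)
class GaussianPDFParams:
    """Fitted 3D Gaussian over target positions (room frame lr/si/ap)."""

    mu: np.ndarray  # (3,) mm
    sigma: np.ndarray  # (3, 3) mm^2, symmetric PSD, diagonal >= floor
    meas_var: float = DEFAULT_MEAS_VAR

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.mu.shape != (3,) or self.sigma.shape != (3, 3):
            raise ValueError("mu must be (3,) and sigma (3, 3)")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-9):
            raise ValueError("sigma must be symmetric")


@dataclass(frozen=True)
class TrajectoryEstimate:
    """Per-projection 3D estimates for one scan.

    Frames rejected by the filter carry no estimate and are listed in
    ``skipped_indices``.
    """

    indices: np.ndarray  # (n,) int
    gantry_angles: np.ndarray  # (n,) deg
    positions: np.ndarray  # (n, 3) mm lr/si/ap
    source: str = "filtered"  # truth | filtered | raw
    skipped_indices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "gantry_angles", np.asarray(self.gantry_angles, dtype=float))
        object.__setattr__(self, "positions", np.atleast_2d(np.asarray(self.positions, dtype=float)))
        if self.positions.shape != (len(self.indices), 3):
            raise ValueError("positions must be (n, 3) matching indices")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


def observations_from_segmentations(segs, geom: BeamGeometry, metas) -> list[Observation2D]:
    """Backproject accepted segmentation centroids to isocenter scale."""
    angle_of = {m.index: m.gantry_angle for m in metas}
    obs = []
    for seg in segs:
        if not seg.accepted:
            continue
        u_mm, v_mm = imager_px_to_mm(seg.centroid[0], seg.centroid[1], geom)
        scale = geom.sad / geom.sdd  # nominal-magnification backprojection
        obs.append(
            Observation2D(
                projection_index=seg.projection_index,
                gantry_angle=angle_of[seg.projection_index],
                u=float(u_mm) * scale,
                v=float(v_mm) * scale,
            )
        )
    return obs


def observations_from_ground_truth(truth, geom: BeamGeometry) -> list[Observation2D]:
    """Observations from a ground-truth table with u_px/v_px columns."""
    obs = []
    scale = geom.sad / geom.sdd
    for idx, ang, col, row in zip(
        truth["index"], truth["gantry_deg"], truth["u_px"], truth["v_px"]
    ):
        u_mm, v_mm = imager_px_to_mm(col, row, geom)
        obs.append(
            Observation2D(
                projection_index=int(idx),
                gantry_angle=float(ang),
                u=float(u_mm) * scale,
                v=float(v_mm) * scale,
            )
        )
    return obs


def _resolved_basis(angles_deg: np.ndarray) -> np.ndarray:
    """Stack of (2, 3) resolved-direction matrices, one per angle."""
    A = np.empty((len(angles_deg), 2, 3))
    for i, ang in enumerate(angles_deg):
        a, b, _ = beam_frame(ang)
        A[i, 0] = a
        A[i, 1] = b
    return A


def project_gaussian(
    params: GaussianPDFParams, gantry_angle: float
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal of the 3D Gaussian onto the resolved plane at one angle.

    Returns the 2D mean and 2x2 covariance, with the isotropic
    measurement variance added on the diagonal.
    """
    a, b, _ = beam_frame(gantry_angle)
    A = np.stack([a, b])
    mean = A @ params.mu
    cov = A @ params.sigma @ A.T + params.meas_var * np.eye(2)
    return mean, cov


def _unpack(theta: np.ndarray, meas_var: float) -> GaussianPDFParams:
    """Parameter vector -> params: mu(3), log-diag L(3), off-diag L(3)."""
    mu = theta[:3]
    L = np.zeros((3, 3))
    L[0, 0], L[1, 1], L[2, 2] = np.exp(theta[3:6])
    L[1, 0], L[2, 0], L[2, 1] = theta[6:9]
    sigma = L @ L.T + VARIANCE_FLOOR * np.eye(3)
    return GaussianPDFParams(mu=mu, sigma=sigma, meas_var=meas_var)


def _nll_vectorized(theta: np.ndarray, A: np.ndarray, uv: np.ndarray, meas_var: float) -> float:
    p = _unpack(theta, meas_var)
    mean = A @ p.mu  # (n, 2)
    M = A @ p.sigma  # (n, 2, 3)
    C = np.einsum("nij,nkj->nik", M, A) + meas_var * np.eye(2)
    r = uv - mean
    det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    # closed-form 2x2 inverse quadratic form
    quad = (
        C[:, 1, 1] * r[:, 0] ** 2
        - 2.0 * C[:, 0, 1] * r[:, 0] * r[:, 1]
        + C[:, 0, 0] * r[:, 1] ** 2
    ) / det
    return float(np.sum(np.log(2.0 * np.pi) + 0.5 * np.log(det) + 0.5 * quad))


def negative_log_likelihood(
    params: GaussianPDFParams, observations: list[Observation2D]
) -> float:
    """Sum of bivariate-normal negative log densities of the observations."""
    if not observations:
        raise ValueError("observations must be non-empty")
    angles = np.array([o.gantry_angle for o in observations])
    uv = np.array([[o.u, o.v] for o in observations])
    A = _resolved_basis(angles)
    mean = A @ params.mu
    M = A @ params.sigma
    C = np.einsum("nij,nkj->nik", M, A) + params.meas_var * np.eye(2)
    r = uv - mean
    det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    quad = (
        C[:, 1, 1] * r[:, 0] ** 2
        - 2.0 * C[:, 0, 1] * r[:, 0] * r[:, 1]
        + C[:, 0, 0] * r[:, 1] ** 2
    ) / det
    return float(np.sum(np.log(2.0 * np.pi) + 0.5 * np.log(det) + 0.5 * quad))


def _initial_guess(angles: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Closed-form start: SI mean from v, (lr, ap) mean by least squares."""
    th = np.deg2rad(angles)
    design = np.stack([np.cos(th), np.sin(th)], axis=1)
    mu_lr_ap, *_ = np.linalg.lstsq(design, uv[:, 0], rcond=None)
    mu = np.array([mu_lr_ap[0], float(np.mean(uv[:, 1])), mu_lr_ap[1]])
    log_diag = np.full(3, np.log(5.0))  # Sigma init = 25 mm^2 * I
    return np.concatenate([mu, log_diag, np.zeros(3)])


def fit_gaussian_ml(
    observations: list[Observation2D],
    meas_var: float = DEFAULT_MEAS_VAR,
    fit_cross: bool = True,
    max_iter: int = 500,
) -> GaussianPDFParams:
    """Maximum-likelihood fit of the 3D Gaussian position PDF.

    Quasi-Newton (L-BFGS) minimization of the negative log likelihood in
    the 9-parameter (mean + Cholesky factor) space. ``fit_cross=False``
    freezes the cross-covariances at zero. Warns when the observations
    span less than 30 degrees of gantry arc, where the lr/ap components
    are barely identifiable.
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 observations to fit the PDF")
    angles = np.array([o.gantry_angle for o in observations])
    uv = np.array([[o.u, o.v] for o in observations])
    span = float(np.ptp(angles))
    if span < 30.0 or len(np.unique(angles)) < 2:
        warnings.warn(
            f"observations span only {span:.1f} deg of gantry arc; "
            "mean/covariance along the unresolved axes are weakly identifiable",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    A = _resolved_basis(angles)
    x0 = _initial_guess(angles, uv)

    if fit_cross:
        fun = lambda th: _nll_vectorized(th, A, uv, meas_var)
        x_full = lambda th: th
    else:
        fun = lambda th: _nll_vectorized(np.concatenate([th, np.zeros(3)]), A, uv, meas_var)
        x0 = x0[:6]
        x_full = lambda th: np.concatenate([th, np.zeros(3)])

    res = minimize(
        fun,
        x0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 1e-6, "ftol": 1e-14},
    )
    params = _unpack(x_full(res.x), meas_var)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    if not res.success and grad_norm > 1e-3:
        raise FitError(
            f"ML fit did not converge after {res.nit} iterations: {res.message}",
            params,
            {"nll": float(res.fun), "grad_norm": grad_norm, "n_iter": int(res.nit)},
        )
    return params


def estimate_3d(
    params: GaussianPDFParams,
    observations: list[Observation2D],
    geom: BeamGeometry | None = None,
    refine_passes: int = 1,
    source: str = "filtered",
    skipped_indices: tuple[int, ...] = (),
) -> TrajectoryEstimate:
    """Per-projection 3D estimates by Gaussian depth conditioning.

    For each observation the unresolved depth is the conditional mean of
    the (measurement-noise-augmented) Gaussian given the resolved
    coordinates; the resolved components are kept at their observed
    values. With ``refine_passes >= 1`` and a geometry, the observation
    is re-scaled with the magnification at the estimated depth and the
    conditioning repeated, correcting the nominal-magnification
    approximation.
    """
    if not observations:
        raise ValueError("observations must be non-empty")
    n = len(observations)
    positions = np.empty((n, 3))
    for i, o in enumerate(observations):
        a, b, c = beam_frame(o.gantry_angle)
        mean_uv, C = project_gaussian(params, o.gantry_angle)
        k = np.array([a @ params.sigma @ c, b @ params.sigma @ c])
        m_w = float(c @ params.mu)
        u, v = o.u, o.v
        for _ in range(max(0, refine_passes) + 1):
            w_hat = m_w + k @ np.linalg.solve(C, np.array([u, v]) - mean_uv)
            if geom is None or refine_passes == 0:
                break
            # re-scale: observed at nominal magnification, true depth w_hat
            scale = (geom.sad - w_hat) / geom.sad
            u, v = o.u * scale, o.v * scale
        positions[i] = u * a + v * b + w_hat * c
    return TrajectoryEstimate(
        indices=np.array([o.projection_index for o in observations]),
        gantry_angles=np.array([o.gantry_angle for o in observations]),
        positions=positions,
        source=source,
        skipped_indices=tuple(skipped_indices),
    )


def estimate_from_ground_truth(
    truth,
    geom: BeamGeometry,
    meas_var: float = DEFAULT_MEAS_VAR,
    refine_passes: int = 1,
) -> TrajectoryEstimate:
    """Reference trajectory: the same fit + conditioning applied to
    ground-truth 2D positions instead of segmentations."""
    obs = observations_from_ground_truth(truth, geom)
    if not obs:
        raise ValueError("ground truth is empty")
    params = fit_gaussian_ml(obs, meas_var=meas_var)
    return estimate_3d(params, obs, geom=geom, refine_passes=refine_passes, source="truth")
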