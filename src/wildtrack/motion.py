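"""Constant-velocity Kalman filter over box state.

State is the 8-vector ``(cx, cy, a, h, vcx, vcy, va, vh)`` — box center,
aspect ratio ``a = w/h``, height, and their per-frame velocities — with the
measurement selecting the first four components.  Process and measurement
noise standard deviations scale with the box height (weights 1/20 for
position-like terms, 1/160 for velocity-like terms), the de-facto standard
for appearance-based tracking-by-detection.  The time step is one frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["KalmanState", "KalmanFilter"]

_STD_WEIGHT_POSITION = 1.0 / 20
_STD_WEIGHT_VELOCITY = 1.0 / 160


@dataclass
class KalmanState:
    mean: np.ndarray        # (8,)
    covariance: np.ndarray  # (8, 8) symmetric PSD


class KalmanFilter:
    """Shared filter matrices; states are passed in and out explicitly."""

    def __init__(self) -> None:
        ndim, dt = 4, 1.0
        self._motion_mat = np.eye(2 * ndim)
        for i in range(ndim):
            self._motion_mat[i, ndim + i] = dt
        self._update_mat = np.eye(ndim, 2 * ndim)

    def initiate(self, measurement: np.ndarray) -> KalmanState:
        """Create a track state from an unassociated (cx, cy, a, h) box,
        with zero initial velocity and height-scaled uncertainty."""
        measurement = np.asarray(measurement, dtype=float)
        if measurement[3] <= 0:
            raise ValueError(f"box height must be positive, got {measurement[3]}")
        mean = np.concatenate([measurement, np.zeros(4)])
        h = measurement[3]
        std = np.array(
            [
                2 * _STD_WEIGHT_POSITION * h,
                2 * _STD_WEIGHT_POSITION * h,
                1e-2,
                2 * _STD_WEIGHT_POSITION * h,
                10 * _STD_WEIGHT_VELOCITY * h,
                10 * _STD_WEIGHT_VELOCITY * h,
                1e-5,
                10 * _STD_WEIGHT_VELOCITY * h,
            ]
        )
        return KalmanState(mean=mean, covariance=np.diag(std**2))

    def _process_noise(self, h: float) -> np.ndarray:
        std = np.array(
            [
                _STD_WEIGHT_POSITION * h,
                _STD_WEIGHT_POSITION * h,
                1e-2,
                _STD_WEIGHT_POSITION * h,
                _STD_WEIGHT_VELOCITY * h,
                _STD_WEIGHT_VELOCITY * h,
                1e-5,
                _STD_WEIGHT_VELOCITY * h,
            ]
        )
        return np.diag(std**2)

    def _measurement_noise(self, h: float) -> np.ndarray:
        std = np.array(
            [
                _STD_WEIGHT_POSITION * h,
                _STD_WEIGHT_POSITION * h,
                1e-1,
                _STD_WEIGHT_POSITION * h,
            ]
        )
        return np.diag(std**2)

    def predict(self, state: KalmanState) -> KalmanState:
        """Advance one frame under constant velocity; covariance grows by the
        process noise and stays symmetric PSD."""
        F = self._motion_mat
        mean = F @ state.mean
        cov = F @ state.covariance @ F.T + self._process_noise(state.mean[3])
        cov = (cov + cov.T) / 2.0
        return KalmanState(mean=mean, covariance=cov)

    def project(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        """Project state onto measurement space: (Hx, HPH' + R)."""
        H = self._update_mat
        mean = H @ state.mean
        cov = H @ state.covariance @ H.T + self._measurement_noise(state.mean[3])
        return mean, (cov + cov.T) / 2.0

    def update(self, state: KalmanState, measurement: np.ndarray) -> KalmanState:
        """Standard Kalman correction with a (cx, cy, a, h) measurement."""
        measurement = np.asarray(measurement, dtype=float)
        proj_mean, proj_cov = self.project(state)
        chol, lower = scipy.linalg.cho_factor(proj_cov, lower=True, check_finite=False)
        kalman_gain = scipy.linalg.cho_solve(
            (chol, lower),
            (state.covariance @ self._update_mat.T).T,
            check_finite=False,
        ).T
        innovation = measurement - proj_mean
        mean = state.mean + kalman_gain @ innovation
        cov = state.covariance - kalman_gain @ proj_cov @ kalman_gain.T
        cov = (cov + cov.T) / 2.0
        return KalmanState(mean=mean, covariance=cov)

    def gating_distance(self, state: KalmanState, measurements: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each (cx, cy, a, h) row against the
        projected state distribution (4 degrees of freedom)."""
        measurements = np.atleast_2d(np.asarray(measurements, dtype=float))
        proj_mean, proj_cov = self.project(state)
        chol = np.linalg.cholesky(proj_cov)
        d = measurements - proj_mean
        z = scipy.linalg.solve_triangular(
            chol, d.T, lower=True, check_finite=False, overwrite_b=True
        )
        return np.sum(z * z, axis=0)
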