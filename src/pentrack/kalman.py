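"""Constant-velocity Kalman filter over bounding boxes.

State is the 8-vector ``(cx, cy, a, h, v_cx, v_cy, v_a, v_h)`` — box center,
aspect ratio w/h, height, and their per-frame velocities.  Process and
measurement noise scale with the box height, following the convention of the
tracker family this module serves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Box

__all__ = [
    "KalmanState",
    "KalmanFilter",
    "kalman_initiate",
    "kalman_predict",
    "kalman_update",
]

_NDIM = 4


@dataclass
class KalmanState:
    """Gaussian belief over the 8-dimensional box state."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(8)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(8, 8)

    def to_box(self) -> Box:
        """Project (cx, cy, a, h) back to a corner box."""
        cx, cy, a, h = self.mean[:_NDIM]
        w = a * h
        return Box(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


def _measurement(box: Box) -> np.ndarray:
    return np.array([*box.center, box.width / box.height, box.height])


class KalmanFilter:
    """Linear-Gaussian constant-velocity filter with h-scaled noise."""

    def __init__(
        self,
        std_weight_position: float = 1.0 / 20,
        std_weight_velocity: float = 1.0 / 160,
        measurement_scale: float = 1.0,
    ) -> None:
        self._std_pos = std_weight_position
        self._std_vel = std_weight_velocity
        self._meas_scale = measurement_scale
        self._motion = np.eye(8)
        for i in range(_NDIM):
            self._motion[i, _NDIM + i] = 1.0
        self._project = np.eye(_NDIM, 8)

    def initiate(self, box: Box) -> KalmanState:
        """Belief from a first observation: zero velocity, h-scaled spread."""
        mean = np.zeros(8)
        mean[:_NDIM] = _measurement(box)
        h = box.height
        std = np.array(
            [
                2 * self._std_pos * h,
                2 * self._std_pos * h,
                1e-2,
                2 * self._std_pos * h,
                10 * self._std_vel * h,
                10 * self._std_vel * h,
                1e-5,
                10 * self._std_vel * h,
            ]
        )
        return KalmanState(mean, np.diag(std**2))

    def predict(self, state: KalmanState) -> KalmanState:
        """Advance one frame under constant velocity; inflate covariance."""
        h = state.mean[3]
        std = np.array(
            [
                self._std_pos * h,
                self._std_pos * h,
                1e-2,
                self._std_pos * h,
                self._std_vel * h,
                self._std_vel * h,
                1e-5,
                self._std_vel * h,
            ]
        )
        mean = self._motion @ state.mean
        cov = self._motion @ state.covariance @ self._motion.T + np.diag(std**2)
        return KalmanState(mean, cov)

    def update(self, state: KalmanState, box: Box) -> KalmanState:
        """Standard correction toward the observed (cx, cy, a, h)."""
        h = state.mean[3]
        std = self._meas_scale * np.array(
            [self._std_pos * h, self._std_pos * h, 1e-1, self._std_pos * h]
        )
        R = np.diag(std**2)
        H = self._project
        S = H @ state.covariance @ H.T + R
        K = np.linalg.solve(S.T, (state.covariance @ H.T).T).T
        innovation = _measurement(box) - H @ state.mean
        mean = state.mean + K @ innovation
        cov = (np.eye(8) - K @ H) @ state.covariance
        cov = 0.5 * (cov + cov.T)  # keep symmetric under round-off
        return KalmanState(mean, cov)


_DEFAULT = KalmanFilter()


def kalman_initiate(box: Box) -> KalmanState:
    return _DEFAULT.initiate(box)


def kalman_predict(state: KalmanState) -> KalmanState:
    return _DEFAULT.predict(state)


def kalman_update(state: KalmanState, box: Box) -> KalmanState:
    return _DEFAULT.update(state, box)
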