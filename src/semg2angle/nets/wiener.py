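"""FIR least-squares baseline: joint angle as a linear filter of lagged envelopes.

The estimator minimizes mean squared error over lagged inputs with an
(unpenalized) intercept and optional ridge regularization of the filter
coefficients — the discrete linear minimum-MSE filter fit by normal
equations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wiener_fit", "wiener_predict", "WienerModel"]


def _lagged_design(x: np.ndarray, lag_order: int) -> np.ndarray:
    """Rows [1, x_t, x_{t-1}, ..., x_{t-L}] flattened channel-major per lag."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.ndim != 2:
        raise ValueError("envelopes must be (T, n_channels)")
    T, C = x.shape
    if T < lag_order + 1:
        raise ValueError(f"need at least lag_order+1 = {lag_order + 1} samples, got {T}")
    n = T - lag_order
    cols = [np.ones((n, 1))]
    for lag in range(lag_order + 1):
        cols.append(x[lag_order - lag: T - lag])
    return np.concatenate(cols, axis=1)


def wiener_fit(
    envelopes: np.ndarray, angles: np.ndarray, lag_order: int = 9, ridge: float = 0.0
) -> np.ndarray:
    """Solve for the FIR coefficient matrix, intercept in row 0.

    ``envelopes`` is (T, C); ``angles`` is (T, J) or (T,), aligned so the
    prediction at time t uses envelope samples t, t-1, ..., t-L. Returns
    coefficients of shape (1 + C*(L+1), J).
    """
    y = np.asarray(angles, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y.T).T
    X = _lagged_design(envelopes, lag_order)
    yt = y[lag_order:]
    if len(yt) != len(X):
        raise ValueError("envelopes and angles must have equal length")
    A = X.T @ X
    if ridge > 0:
        pen = np.full(A.shape[0], ridge)
        pen[0] = 0.0  # intercept unpenalized
        A = A + np.diag(pen)
    try:
        coeffs = np.linalg.solve(A, X.T @ yt)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "normal equations are singular; set ridge > 0 to regularize"
        ) from err
    return coeffs[:, 0] if squeeze else coeffs


def wiener_predict(envelopes: np.ndarray, coeffs: np.ndarray, lag_order: int | None = None) -> np.ndarray:
    """Linear filter output for times t >= lag_order (shape (T-L, J))."""
    coeffs = np.atleast_2d(coeffs.T).T
    x = np.atleast_2d(np.asarray(envelopes, dtype=float))
    C = x.shape[1]
    if lag_order is None:
        lag_order = (coeffs.shape[0] - 1) // C - 1
    X = _lagged_design(x, lag_order)
    out = X @ coeffs
    return out[:, 0] if np.asarray(coeffs).shape[1] == 1 else out


class WienerModel:
    """Window-set adapter: each (W, C) window supplies the W-1 lags directly."""

    def __init__(self, n_joints: int, ridge: float = 0.0):
        self.n_joints = n_joints
        self.ridge = ridge
        self.coeffs: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        return 0 if self.coeffs is None else self.coeffs.size

    def fit(self, inputs: np.ndarray, targets: np.ndarray) -> "WienerModel":
        N, W, C = inputs.shape
        X = np.concatenate([np.ones((N, 1)), inputs[:, ::-1, :].reshape(N, -1)], axis=1)
        A = X.T @ X
        if self.ridge > 0:
            pen = np.full(A.shape[0], self.ridge)
            pen[0] = 0.0
            A = A + np.diag(pen)
        try:
            self.coeffs = np.linalg.solve(A, X.T @ targets)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "normal equations are singular; set ridge > 0 to regularize"
            ) from err
        return self

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        if self.coeffs is None:
            raise RuntimeError("model is not fitted")
        N = len(inputs)
        X = np.concatenate([np.ones((N, 1)), inputs[:, ::-1, :].reshape(N, -1)], axis=1)
        return X @ self.coeffs
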