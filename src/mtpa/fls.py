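"""Framewise time-varying connectivity by flexible least squares (FLS).

For a predictor series x and response y of length T, the coefficient
sequence beta minimises

    C(beta) = sum_t (y_t - x_t beta_t)^2 + mu * sum_{t<T} (beta_{t+1} - beta_t)^2

i.e. a measurement-fit term plus mu times a dynamic (increment) penalty.
The stationarity conditions form a symmetric tridiagonal system
(diagonal x_t^2 + mu * degree_t, off-diagonal -mu, right-hand side
x_t y_t) solved exactly in O(T). Large mu drives the solution to the
static OLS slope; small mu tracks the data frame by frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .errors import NonUniqueSolutionError
from .simulate import SubjectRecording, pair_index

__all__ = [
    "FlsConfig",
    "DfcSeries",
    "FlsCostBreakdown",
    "DfcTensor",
    "fls_pair",
    "fls_batch",
    "fls_all_pairs",
    "static_fc",
]


@dataclass(frozen=True)
class FlsConfig:
    mu: float = 100.0
    direction_rule: str = "lower-index-predictor"  # or "average-both"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.direction_rule not in ("lower-index-predictor", "average-both"):
            raise ValueError(f"unknown direction rule {self.direction_rule!r}")


@dataclass(frozen=True)
class DfcSeries:
    pair: tuple[int, int]
    beta: np.ndarray


@dataclass(frozen=True)
class FlsCostBreakdown:
    measurement_error: float
    dynamic_error: float
    mu: float

    @property
    def total(self) -> float:
        return self.mu * self.dynamic_error + self.measurement_error


@dataclass
class DfcTensor:
    """All-pairs coefficient stack for one recording."""

    subject_id: str
    condition: str
    beta: np.ndarray  # pairs x frames
    pairs: np.ndarray  # pairs x 2, lexicographic, i < j
    mu: float

    @property
    def n_pairs(self) -> int:
        return self.beta.shape[0]

    @property
    def n_frames(self) -> int:
        return self.beta.shape[1]


def _fls_costs(x: np.ndarray, y: np.ndarray, beta: np.ndarray, mu: float) -> FlsCostBreakdown:
    meas = float(np.sum((y - x * beta) ** 2))
    dyn = float(np.sum(np.diff(beta) ** 2))
    return FlsCostBreakdown(measurement_error=meas, dynamic_error=dyn, mu=mu)


def fls_pair(
    x: np.ndarray, y: np.ndarray, mu: float = 100.0
) -> tuple[DfcSeries, FlsCostBreakdown]:
    """Exact FLS minimizer for one directed pair (x predicts y).

    Solved with a symmetric banded Cholesky factorisation. With mu = 0 the
    problem decouples per frame and requires every x_t to be nonzero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    t = x.size
    if t < 2:
        raise ValueError("need at least two frames")
    if not np.any(x):
        raise ValueError("x is identically zero; coefficient undefined")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if mu == 0:
        if np.any(x == 0):
            raise NonUniqueSolutionError(
                "mu=0 with zero predictor frames leaves coefficients unconstrained"
            )
        beta = y / x
    else:
        ab = np.zeros((2, t))
        ab[0, 1:] = -mu
        ab[1] = x * x + mu
        ab[1, 1:-1] += mu
        beta = solveh_banded(ab, x * y, lower=False)
    return DfcSeries(pair=(0, 1), beta=beta), _fls_costs(x, y, beta, mu)


def fls_batch(x: np.ndarray, y: np.ndarray, mu: float) -> np.ndarray:
    """Row-wise FLS solutions for stacked systems (P x T each of x, y).

    Thomas-algorithm sweep vectorised over rows; used by ``fls_all_pairs``
    where thousands of pairs share a frame grid.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if mu <= 0:
        raise ValueError("fls_batch requires mu > 0")
    p, t = x.shape
    diag = x * x + mu
    diag[:, 1:-1] += mu
    rhs = x * y
    c = -mu
    cp = np.empty((p, t - 1))
    dp = np.empty((p, t))
    cp[:, 0] = c / diag[:, 0]
    dp[:, 0] = rhs[:, 0] / diag[:, 0]
    for k in range(1, t):
        denom = diag[:, k] - c * cp[:, k - 1]
        if k < t - 1:
            cp[:, k] = c / denom
        dp[:, k] = (rhs[:, k] - c * dp[:, k - 1]) / denom
    beta = np.empty((p, t))
    beta[:, -1] = dp[:, -1]
    for k in range(t - 2, -1, -1):
        beta[:, k] = dp[:, k] - cp[:, k] * beta[:, k + 1]
    return beta


def _as_matrix(recording) -> np.ndarray:
    if isinstance(recording, SubjectRecording):
        return recording.timeseries
    return np.asarray(recording, dtype=float)


def fls_all_pairs(recording, config: FlsConfig = FlsConfig()) -> DfcTensor:
    """FLS coefficient series for every unordered region pair.

    Pairs are ordered lexicographically. Under the default direction rule
    the lower-index region is the predictor; ``average-both`` averages the
    two directed solutions.
    """
    ts = _as_matrix(recording)
    pairs = pair_index(ts.shape[0])
    xi, yi = pairs[:, 0], pairs[:, 1]
    beta = fls_batch(ts[xi], ts[yi], config.mu)
    if config.direction_rule == "average-both":
        beta = 0.5 * (beta + fls_batch(ts[yi], ts[xi], config.mu))
    sid = recording.subject_id if isinstance(recording, SubjectRecording) else ""
    cond = recording.condition if isinstance(recording, SubjectRecording) else ""
    return DfcTensor(subject_id=sid, condition=cond, beta=beta, pairs=pairs, mu=config.mu)


def static_fc(recording) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation per unordered pair (vector aligned with the
    lexicographic pair table). Constant regions yield NaN with a warning."""
    ts = _as_matrix(recording)
    pairs = pair_index(ts.shape[0])
    sd = ts.std(axis=1)
    constant = sd < 1e-12
    if np.any(constant):
        warnings.warn(
            f"constant regions {np.flatnonzero(constant).tolist()}; their pairs are NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts)
    vals = r[pairs[:, 0], pairs[:, 1]]
    vals[constant[pairs[:, 0]] | constant[pairs[:, 1]]] = np.nan
    return vals, pairs
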