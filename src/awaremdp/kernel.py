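"""Transition kernel of the awareness random walk.

The decision-maker's awareness level lives on a discrete grid inside (0, 1)
and moves at most one step per epoch (a birth/stay/death chain).  The
probability of moving *up* depends on the chosen degree of analyticity
``u`` through two fixed unimodal curves — one for a purely analytical
reasoner, one for a purely intuitive one — mixed with the individual's
reasoning propensity ``p_r``:

    P1(u) = p_r * P1_analytical(u) + (1 - p_r) * P1_intuitive(u)

The analytical curve rises with ``u`` up to a peak and then declines
(excessive analyticity overfits the available information and stops
paying off); the intuitive curve peaks at low ``u`` and declines as the
decision becomes more analytical, while still requiring a minimum of
analyticity near ``u = 0``.  The probability of staying put is a constant
``p_stay`` (inertia), and the downward probability is the residual.

Both base curves are normalised beta-style bumps::

    p(u) = p_floor + (p_peak - p_floor) * u^a (1-u)^b / max_u[u^a (1-u)^b]

with exponents chosen so the maximiser sits at the requested peak
location: ``a = peak * sharpness`` and ``b = (1 - peak) * sharpness``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfigurationError",
    "StateGrid",
    "CurveShape",
    "TransitionRow",
    "base_forward_analytical",
    "base_forward_intuitive",
    "forward_prob",
    "transition_row",
    "transition_matrix",
    "sample_shock",
    "step_state",
]

DEFAULT_P_STAY = 0.1


class ConfigurationError(ValueError):
    """A parameter combination violates the model's probability budget."""


@dataclass(frozen=True)
class StateGrid:
    """Equally spaced awareness levels strictly inside (0, 1).

    The default grid is {0.01, 0.02, ..., 0.99}: the open unit interval
    discretised with step 0.01.  The same construction is reused for the
    action (decision) grid.
    """

    step: float = 0.01
    lower: float = 0.01
    upper: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper < 1.0):
            raise ConfigurationError(
                f"grid bounds must satisfy 0 < lower < upper < 1, "
                f"got ({self.lower}, {self.upper})"
            )
        if self.step <= 0:
            raise ConfigurationError(f"grid step must be positive, got {self.step}")
        n = (self.upper - self.lower) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "grid bounds must be an integer number of steps apart"
            )

    @property
    def n(self) -> int:
        return int(round((self.upper - self.lower) / self.step)) + 1

    @property
    def levels(self) -> np.ndarray:
        return np.round(self.lower + self.step * np.arange(self.n), 10)

    def index_of(self, s: float, warn: bool = True) -> int:
        """Map a level to its grid index, snapping off-grid values to the
        nearest level (with a warning) and clamping out-of-range values."""
        x = (s - self.lower) / self.step
        idx = int(round(x))
        if warn and abs(x - idx) > 1e-6:
            warnings.warn(
                f"state {s} is off-grid; snapped to nearest level",
                RuntimeWarning,
                stacklevel=2,
            )
        return min(max(idx, 0), self.n - 1)

    def level_at(self, idx: int) -> float:
        return float(self.levels[idx])


@dataclass(frozen=True)
class CurveShape:
    """Parameters of the two base forward-probability curves.

    ``p_floor``/``p_peak`` bound both curves; ``peak_analytical`` and
    ``peak_intuitive`` locate their maxima; the ``sharp_*`` parameters are
    the beta-bump concentrations ``a + b`` (larger = narrower hump).  The
    analytical default ``sharp_analytical = 5`` with peak 0.8 gives
    exponents (a, b) = (4, 1); the intuitive default is a much broader
    hump, calibrated so that a moderately analytical individual
    (p_r = 0.6) has a mixed curve with substantial forward probability at
    mid-range decisions and a maximum near u = 0.8 (see docs/methods.md).
    """

    p_floor: float = 0.05
    p_peak: float = 0.85
    peak_analytical: float = 0.8
    peak_intuitive: float = 0.2
    sharp_analytical: float = 5.0
    sharp_intuitive: float = 0.72

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_floor < self.p_peak <= 1.0):
            raise ConfigurationError(
                f"need 0 <= p_floor < p_peak <= 1, got "
                f"({self.p_floor}, {self.p_peak})"
            )
        if not (0.0 < self.peak_intuitive < self.peak_analytical < 1.0):
            raise ConfigurationError(
                "need 0 < peak_intuitive < peak_analytical < 1"
            )
        if self.sharp_analytical <= 0 or self.sharp_intuitive <= 0:
            raise ConfigurationError("curve sharpness must be positive")

    @property
    def exponents_analytical(self) -> tuple[float, float]:
        a = self.peak_analytical * self.sharp_analytical
        return a, self.sharp_analytical - a

    @property
    def exponents_intuitive(self) -> tuple[float, float]:
        a = self.peak_intuitive * self.sharp_intuitive
        return a, self.sharp_intuitive - a


@dataclass(frozen=True)
class TransitionRow:
    """One row of the action-indexed kernel: P(w = +1), P(w = 0), P(w = -1)."""

    p_up: float
    p_stay: float
    p_down: float

    def __post_init__(self) -> None:
        for p in (self.p_up, self.p_stay, self.p_down):
            if not (-1e-12 <= p <= 1.0 + 1e-12):
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if abs(self.p_up + self.p_stay + self.p_down - 1.0) > 1e-12:
            raise ConfigurationError("transition row does not sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_up, self.p_stay, self.p_down])


def _check_u(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("decision u must lie in the open interval (0, 1)")
    return u


def _bump(u: np.ndarray, a: float, b: float, peak: float) -> np.ndarray:
    # u^a (1-u)^b normalised by its maximum, attained at peak = a/(a+b);
    # computed in log space for numerical stability at extreme exponents.
    log_ratio = a * (np.log(u) - np.log(peak)) + b * (np.log1p(-u) - np.log1p(-peak))
    return np.exp(log_ratio)


def base_forward_analytical(u, shape: CurveShape = CurveShape()):
    """Forward probability of a purely analytical reasoner (p_r = 1).

    Low near both endpoints, maximum ``p_peak`` at ``peak_analytical``;
    the decline beyond the peak encodes the overfitting penalty of
    excessive analyticity.
    """
    u = _check_u(u)
    a, b = shape.exponents_analytical
    out = shape.p_floor + (shape.p_peak - shape.p_floor) * _bump(
        u, a, b, shape.peak_analytical
    )
    return out if out.ndim else float(out)


def base_forward_intuitive(u, shape: CurveShape = CurveShape()):
    """Forward probability of a purely intuitive reasoner (p_r = 0).

    Maximum ``p_peak`` at ``peak_intuitive``, decreasing over most of the
    remaining range, and dropping toward ``p_floor`` as u -> 0+ (some
    minimum analyticity is indispensable) and as u -> 1-.
    """
    u = _check_u(u)
    a, b = shape.exponents_intuitive
    out = shape.p_floor + (shape.p_peak - shape.p_floor) * _bump(
        u, a, b, shape.peak_intuitive
    )
    return out if out.ndim else float(out)


def forward_prob(u, p_r: float, shape: CurveShape = CurveShape()):
    """Convex combination of the two base curves with coefficient ``p_r``."""
    if not (0.0 <= p_r <= 1.0):
        raise ValueError(f"reasoning propensity p_r must lie in [0, 1], got {p_r}")
    return p_r * base_forward_analytical(u, shape) + (1.0 - p_r) * base_forward_intuitive(
        u, shape
    )


def transition_row(
    u: float,
    p_r: float,
    shape: CurveShape = CurveShape(),
    p_stay: float = DEFAULT_P_STAY,
) -> TransitionRow:
    """Build the (p_up, p_stay, p_down) row for one decision.

    ``p_stay`` is the constant inertia term (0.1 in every experiment);
    the downward probability is the residual.  A negative residual means
    the curve shapes violate the probability budget and raises
    :class:`ConfigurationError`.
    """
    p_up = float(forward_prob(u, p_r, shape))
    p_down = 1.0 - p_up - p_stay
    if p_down < -1e-12:
        raise ConfigurationError(
            f"forward_prob({u}) + p_stay = {p_up + p_stay:.6f} exceeds 1; "
            "lower p_peak or p_stay"
        )
    return TransitionRow(p_up, p_stay, max(p_down, 0.0))


def transition_matrix(
    actions: np.ndarray,
    p_r: float,
    shape: CurveShape = CurveShape(),
    p_stay: float = DEFAULT_P_STAY,
) -> np.ndarray:
    """Rows (p_up, p_stay, p_down) for every action on the grid, shape (A, 3)."""
    p_up = forward_prob(np.asarray(actions, dtype=float), p_r, shape)
    p_down = 1.0 - p_up - p_stay
    if np.any(p_down < -1e-12):
        raise ConfigurationError("curve shapes violate the probability budget")
    rows = np.column_stack([p_up, np.full_like(p_up, p_stay), np.clip(p_down, 0.0, 1.0)])
    return rows


def sample_shock(row: TransitionRow, rng: np.random.Generator) -> int:
    """Draw w in {+1, 0, -1} with the row's probabilities.

    Uses a single uniform compared against the cumulative (up, stay)
    thresholds, so the draw is a deterministic function of the stream
    state.
    """
    x = rng.random()
    if x < row.p_up:
        return 1
    if x < row.p_up + row.p_stay:
        return 0
    return -1


def step_state(s: float, shock: int, grid: StateGrid = StateGrid()) -> float:
    """Apply a shock of one grid step, clamping at the grid boundaries."""
    idx = grid.index_of(s)
    return grid.level_at(min(max(idx + int(shock), 0), grid.n - 1))
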