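"""Secretion kinetics across culture densities.

Cytokine amounts (pg per reference cell count) sampled at ordered timepoints
form a per-donor, per-condition time course. Finite differences over
consecutive intervals give production rates; a negative rate is flagged as
clearance (consumption/degradation of already-secreted cytokine, observed
for TNFα at high cell densities). ``shutoff_time`` operationalizes "stopped
production" as the earliest time the course reaches a set fraction (default
95%) of its final amount — at high density the production window shortens,
so shutoff comes earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "TimeCourse",
    "interval_rates",
    "normalize_to_max",
    "rate_sum_check",
    "shutoff_time",
]


@dataclass(frozen=True)
class TimeCourse:
    """Cytokine amounts at ordered timepoints for one donor and condition.

    ``amounts`` are pg per reference cell count; the first timepoint is
    conventionally t=0 with amount 0 (no cytokine before stimulation).
    """

    donor: str
    condition: str
    timepoints_h: np.ndarray = field(repr=False)
    amounts: np.ndarray = field(repr=False)
    cytokine: str = "IL-10"

    def __post_init__(self):
        t = np.asarray(self.timepoints_h, dtype=float)
        y = np.asarray(self.amounts, dtype=float)
        if t.size != y.size:
            raise InvalidInputError("timepoints and amounts differ in length")
        if t.size < 1:
            raise InvalidInputError("time course must contain at least one timepoint")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("timepoints must be strictly increasing (no duplicates)")
        if np.any(y < 0):
            raise InvalidInputError("amounts must be nonnegative")
        object.__setattr__(self, "timepoints_h", t)
        object.__setattr__(self, "amounts", y)


def interval_rates(tc: TimeCourse) -> pd.DataFrame:
    """Finite-difference production rates for each consecutive interval.

    Returns a table with columns ``t_start_h``, ``t_end_h``,
    ``rate_pg_per_h`` and ``clearance`` (True exactly when the rate is
    negative, i.e. cytokine disappeared faster than it was produced).
    """
    if tc.timepoints_h.size < 2:
        raise InvalidInputError("need >= 2 timepoints to compute interval rates")
    dt = np.diff(tc.timepoints_h)
    dy = np.diff(tc.amounts)
    rates = dy / dt
    return pd.DataFrame(
        {
            "t_start_h": tc.timepoints_h[:-1],
            "t_end_h": tc.timepoints_h[1:],
            "rate_pg_per_h": rates,
            "clearance": rates < 0,
        }
    )


def normalize_to_max(tc: TimeCourse) -> TimeCourse:
    """Scale the course by its per-donor maximum so the peak maps to 1.0.

    Invariant under any positive rescaling of the input (and hence to the
    reference cell count used upstream).
    """
    peak = tc.amounts.max()
    if peak <= 0:
        raise InvalidInputError("cannot normalize an all-zero time course")
    return replace(tc, amounts=tc.amounts / peak)


def rate_sum_check(tc: TimeCourse, rates: pd.DataFrame, tol: float = 1e-9):
    """Telescoping consistency: sum(rate x interval) must equal the net change.

    Returns ``(ok, residual)`` where residual is
    ``|sum_i rate_i (t_end_i - t_start_i) - (amount_last - amount_first)|``.
    """
    if len(rates) != tc.timepoints_h.size - 1:
        raise InvalidInputError(
            f"rate table has {len(rates)} intervals but the course has "
            f"{tc.timepoints_h.size - 1}"
        )
    if len(rates) and not (
        np.array_equal(rates["t_start_h"].to_numpy(), tc.timepoints_h[:-1])
        and np.array_equal(rates["t_end_h"].to_numpy(), tc.timepoints_h[1:])
    ):
        raise InvalidInputError("rate table interval endpoints do not match the time course")
    integral = float(
        (rates["rate_pg_per_h"] * (rates["t_end_h"] - rates["t_start_h"])).sum()
    )
    net = float(tc.amounts[-1] - tc.amounts[0])
    residual = abs(integral - net)
    return residual <= tol, residual


def shutoff_time(tc: TimeCourse, fraction: float = 0.95, interpolate: bool = False) -> float:
    """Earliest time at which the course reaches ``fraction`` of its final amount.

    With ``interpolate=False`` (default) the answer is the first sampled
    timepoint whose amount is >= fraction x final — a plateau reached at 8 h
    reports 8 h. With ``interpolate=True`` the crossing is located by linear
    interpolation inside the bracketing interval.
    """
    if not (0 < fraction <= 1):
        raise InvalidInputError(f"fraction must lie in (0, 1], got {fraction}")
    final = tc.amounts[-1]
    if final <= 0:
        raise InvalidInputError("final amount must be positive to define a shutoff time")
    target = fraction * final
    idx = int(np.argmax(tc.amounts >= target))  # first True; amounts[-1] >= target always
    if not interpolate or idx == 0 or tc.amounts[idx] == target:
        return float(tc.timepoints_h[idx])
    t0, t1 = tc.timepoints_h[idx - 1], tc.timepoints_h[idx]
    y0, y1 = tc.amounts[idx - 1], tc.amounts[idx]
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))
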