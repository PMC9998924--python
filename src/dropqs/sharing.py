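"""Cytokine-sharing model for IL-10 positivity in multi-cell droplets.

A minority fraction ``b`` of LPS-stimulated macrophages secrete IL-10.
When several cells share a droplet, IL-10 secreted by a producer is captured
by every co-encapsulated cell, so one producer renders its whole droplet
IL-10 positive. Three routes predict the resulting fraction of positive
cells at mean occupancy ``a``:

``fraction_positive_quadratic``
    The quadratic-weight formula: droplets of size k contribute
    ``(a^k e^-a / k!) * b * k^2`` positive cells (each of the b*k expected
    producers converts all k cells), normalized by the expected cell count
    ``(a^k e^-a / k!) * k``, summed over k = 1..kmax and expressed in
    percent. Untruncated, the sums collapse to ``100 * b * (1 + a)``, so
    the value can exceed 100% — droplets holding two or more producers are
    double-counted. A cap at 100% is applied by default.

``fraction_positive_exact``
    The exact expectation under the same mechanism: a droplet of size k has
    all k cells positive iff it holds at least one producer, so the expected
    number of positive cells is ``k * (1 - (1-b)^k)``. Always <= 100%.

``simulate_sharing``
    A stochastic droplet simulator (Poisson occupancy, binomial producers,
    at-least-one-producer positivity) whose fraction converges to the exact
    expectation.

The quadratic formula is an upper bound on the exact model (``b*k >=
1 - (1-b)^k``), and the two agree in the small-b limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidInputError
from .occupancy import DEFAULT_KMAX, occupancy_pmf

__all__ = [
    "SharingParams",
    "ModelPrediction",
    "SharingSimulation",
    "ProducerFractionEstimate",
    "fraction_positive_quadratic",
    "fraction_positive_exact",
    "simulate_sharing",
    "estimate_producer_fraction",
    "prediction_band",
]


@dataclass(frozen=True)
class SharingParams:
    """Inputs of the sharing model.

    Parameters
    ----------
    a : float
        Mean cells per droplet (> 0).
    b : float
        Producer fraction in [0, 1], estimated from single-cell experiments.
    kmax : int
        Truncation of the occupancy sums (default 30).
    cap_at_100 : bool
        Whether the reported fraction is capped at 100% (the quadratic
        formula can exceed it).
    """

    a: float
    b: float
    kmax: int = DEFAULT_KMAX
    cap_at_100: bool = True

    def __post_init__(self):
        if not (self.a > 0 and np.isfinite(self.a)):
            raise InvalidInputError(f"a must be finite and > 0, got {self.a}")
        if not (0.0 <= self.b <= 1.0):
            raise InvalidInputError(f"b must lie in [0, 1], got {self.b}")
        if int(self.kmax) < 1:
            raise InvalidInputError(f"kmax must be >= 1, got {self.kmax}")


@dataclass(frozen=True)
class ModelPrediction:
    """A predicted percentage of IL-10 positive cells.

    ``fraction_positive`` is capped at 100 when the generating params say so;
    ``uncapped_value`` always carries the raw model output. ``band`` is an
    optional (lower, upper) percent pair.
    """

    fraction_positive: float
    uncapped_value: float
    method: str
    band: tuple | None = None

    def __post_init__(self):
        if self.band is not None:
            lo, hi = self.band
            if not (lo <= self.fraction_positive <= hi):
                raise InvalidInputError(
                    f"band {self.band} does not bracket the point {self.fraction_positive}"
                )


def fraction_positive_quadratic(params: SharingParams) -> ModelPrediction:
    """Quadratic-weight prediction of the percent of IL-10 positive cells.

    Evaluates, term by term over k = 1..kmax,

        100 * sum_k (a^k e^-a / k!) b k^2  /  sum_k (a^k e^-a / k!) k

    and caps at 100% if ``params.cap_at_100``.
    """
    dist = occupancy_pmf(params.a, params.kmax)
    k = dist.k[1:].astype(float)
    w = dist.raw_terms[1:]
    numerator = float(np.sum(w * params.b * k**2))
    denominator = float(np.sum(w * k))
    uncapped = 100.0 * numerator / denominator
    value = min(uncapped, 100.0) if params.cap_at_100 else uncapped
    return ModelPrediction(fraction_positive=value, uncapped_value=uncapped, method="quadratic")


def fraction_positive_exact(params: SharingParams) -> ModelPrediction:
    """Exact expected percent of positive cells under the sharing mechanism.

    A droplet of size k is fully positive iff it holds >= 1 producer:

        100 * sum_k p(k) k (1 - (1-b)^k)  /  sum_k p(k) k

    Always <= 100, so the cap never binds.
    """
    dist = occupancy_pmf(params.a, params.kmax)
    k = dist.k[1:].astype(float)
    w = dist.raw_terms[1:]
    numerator = float(np.sum(w * k * (1.0 - (1.0 - params.b) ** k)))
    denominator = float(np.sum(w * k))
    value = 100.0 * numerator / denominator
    return ModelPrediction(fraction_positive=value, uncapped_value=value, method="exact")


@dataclass(frozen=True)
class SharingSimulation:
    """Monte-Carlo sharing result: percent positive, its standard error, droplets."""

    fraction_positive: float
    standard_error: float
    n_droplets: int
    n_cells: int
    droplets: pd.DataFrame = field(repr=False)

    def as_prediction(self) -> ModelPrediction:
        return ModelPrediction(
            fraction_positive=self.fraction_positive,
            uncapped_value=self.fraction_positive,
            method="simulated",
        )


def simulate_sharing(params: SharingParams, n_droplets: int, seed=None) -> SharingSimulation:
    """Simulate droplet encapsulation and IL-10 sharing.

    Occupancy is untruncated Poisson(a); each encapsulated cell is a producer
    with probability b; every cell in a droplet holding >= 1 producer is
    positive. The fraction is positive cells over all encapsulated cells
    (empty droplets contribute none). The standard error treats droplets as
    the independent sampling unit (cells within a droplet are perfectly
    correlated), via the ratio-estimator variance.
    """
    n_droplets = int(n_droplets)
    if n_droplets < 1:
        raise InvalidInputError(f"n_droplets must be >= 1, got {n_droplets}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.poisson(params.a, size=n_droplets)
    producers = rng.binomial(k, params.b)
    positive = np.where(producers > 0, k, 0)
    total_cells = int(k.sum())
    if total_cells == 0:
        raise InvalidInputError(
            "all simulated droplets are empty; increase n_droplets or the mean occupancy a"
        )
    p = positive.sum() / total_cells
    # ratio-estimator (cluster) variance with droplets as units
    resid = positive - p * k
    se = float(np.sqrt(np.sum(resid**2)) / total_cells)
    droplets = pd.DataFrame(
        {
            "droplet_id": np.arange(n_droplets),
            "n_cells": k,
            "n_producers": producers,
            "n_positive": positive,
        }
    )
    return SharingSimulation(
        fraction_positive=100.0 * p,
        standard_error=100.0 * se,
        n_droplets=n_droplets,
        n_cells=total_cells,
        droplets=droplets,
    )


@dataclass(frozen=True)
class ProducerFractionEstimate:
    """Estimated producer fraction b with a 95% Wilson-score interval."""

    b_hat: float
    ci_lower: float
    ci_upper: float
    n_events: int
    n_positive: int
    threshold: float


def default_positivity_threshold(control_signals, quantile: float = 0.99) -> float:
    """Positivity gate: the 99th percentile of an unstimulated-control signal."""
    control_signals = np.asarray(control_signals, dtype=float)
    if control_signals.size == 0:
        raise InvalidInputError("control signal distribution is empty")
    return float(np.quantile(control_signals, quantile))


def estimate_producer_fraction(
    events: pd.DataFrame,
    positivity_threshold: float | None = None,
    control_signals=None,
    signal_column: str = "il10_signal",
    alpha: float = 0.05,
) -> ProducerFractionEstimate:
    """Estimate the IL-10 producer fraction b from single-cell events.

    Events should come from single-cell (occupancy <= 1) conditions so that
    positivity reflects production, not sharing. A cell is positive when its
    ``signal_column`` value exceeds the threshold; if no threshold is given
    it is derived as the 99th percentile of ``control_signals``. Rows with a
    ``viable`` column are filtered to viable cells first. The interval is the
    Wilson score interval, which remains one-sided-sensible at b_hat = 0.
    """
    if positivity_threshold is None:
        if control_signals is None:
            raise InvalidInputError(
                "provide positivity_threshold or control_signals to derive one"
            )
        positivity_threshold = default_positivity_threshold(control_signals)
    if signal_column not in events.columns:
        raise InvalidInputError(f"events table lacks column '{signal_column}'")
    if "viable" in events.columns:
        events = events[events["viable"].astype(bool)]
    n = len(events)
    if n == 0:
        raise InvalidInputError("no (viable) events to estimate from")
    n_pos = int((events[signal_column].to_numpy(dtype=float) > positivity_threshold).sum())
    lo, hi = proportion_confint(n_pos, n, alpha=alpha, method="wilson")
    return ProducerFractionEstimate(
        b_hat=n_pos / n,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_events=n,
        n_positive=n_pos,
        threshold=float(positivity_threshold),
    )


def prediction_band(
    b_values,
    a_grid,
    kmax: int = DEFAULT_KMAX,
    cap_at_100: bool = True,
    method: str = "mean-ci",
) -> pd.DataFrame:
    """95% prediction band for the positive fraction across mean occupancies.

    ``method="mean-ci"`` (default) computes the t-based 95% confidence
    interval of the mean replicate producer fraction and maps its endpoints
    through the quadratic formula — valid because the formula is monotone
    increasing in b. ``method="percentile"`` instead maps every replicate b
    through the model and takes the 2.5/97.5 percentiles of the predictions.

    Returns a DataFrame with columns a, fraction_pct, uncapped_pct,
    lower_pct, upper_pct.
    """
    b_values = np.asarray(b_values, dtype=float)
    if b_values.size < 2:
        raise InvalidInputError("need >= 2 replicate b values for a dispersion estimate")
    if np.any((b_values < 0) | (b_values > 1)):
        raise InvalidInputError("replicate b values must lie in [0, 1]")
    b_mean = float(b_values.mean())

    if method == "mean-ci":
        sem = float(b_values.std(ddof=1) / np.sqrt(b_values.size))
        tcrit = float(stats.t.ppf(0.975, b_values.size - 1))
        b_lo = float(np.clip(b_mean - tcrit * sem, 0.0, 1.0))
        b_hi = float(np.clip(b_mean + tcrit * sem, 0.0, 1.0))
    elif method != "percentile":
        raise InvalidInputError(f"unknown band method '{method}'")

    rows = []
    for a in np.atleast_1d(np.asarray(a_grid, dtype=float)):
        point = fraction_positive_quadratic(SharingParams(a, b_mean, kmax, cap_at_100))
        if method == "mean-ci":
            lo = fraction_positive_quadratic(SharingParams(a, b_lo, kmax, cap_at_100))
            hi = fraction_positive_quadratic(SharingParams(a, b_hi, kmax, cap_at_100))
            lower, upper = lo.fraction_positive, hi.fraction_positive
        else:
            preds = [
                fraction_positive_quadratic(
                    SharingParams(a, float(b), kmax, cap_at_100)
                ).fraction_positive
                for b in b_values
            ]
            lower, upper = float(np.percentile(preds, 2.5)), float(np.percentile(preds, 97.5))
            # the percentile band need not bracket the mean-b point for skewed
            # replicates; widen minimally so the table stays self-consistent
            lower = min(lower, point.fraction_positive)
            upper = max(upper, point.fraction_positive)
        rows.append(
            {
                "a": float(a),
                "fraction_pct": point.fraction_positive,
                "uncapped_pct": point.uncapped_value,
                "lower_pct": lower,
                "upper_pct": upper,
            }
        )
    return pd.DataFrame(rows)
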