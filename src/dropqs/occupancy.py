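"""Poisson cell-encapsulation statistics for droplet microfluidics.

Cells are loaded into droplets at random, so the number of cells per droplet
follows a Poisson distribution whose mean ``a`` is set by the cell
concentration and the droplet volume:

    a = concentration [cells/mL] x volume [nL] x 1e-6 [mL/nL]

This module computes the occupancy distribution (both the raw, truncated
Poisson terms used by the downstream sharing model and a renormalized pmf
for simulation), simulates encapsulation, and compares an observed occupancy
histogram against the Poisson expectation with a chi-square statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

#: Droplet volume (nL) implied by the concentration/occupancy pairings used
#: in the multi-cell experiments (2.5e6 cells/mL ~ 2 cells/droplet, ...,
#: 15e6 cells/mL ~ 12 cells/droplet). Overridable everywhere it appears.
DEFAULT_DROPLET_VOLUME_NL = 0.8

#: Highest occupancy carried by the truncated model sums.
DEFAULT_KMAX = 30


@dataclass(frozen=True)
class DropletSpec:
    """Physical loading parameters that determine mean droplet occupancy.

    Parameters
    ----------
    cell_concentration : float
        Cell concentration at the droplet-formation point, cells/mL. Must be
        positive.
    droplet_volume_nl : float
        Droplet volume in nanolitres. Must be positive.
    kmax : int
        Highest occupancy considered by truncated sums, >= 1.
    """

    cell_concentration: float
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    kmax: int = DEFAULT_KMAX

    def __post_init__(self):
        if not (self.cell_concentration > 0 and np.isfinite(self.cell_concentration)):
            raise InvalidInputError(
                f"cell_concentration must be finite and > 0, got {self.cell_concentration}"
            )
        if not (self.droplet_volume_nl > 0 and np.isfinite(self.droplet_volume_nl)):
            raise InvalidInputError(
                f"droplet_volume_nl must be finite and > 0, got {self.droplet_volume_nl}"
            )
        if int(self.kmax) < 1:
            raise InvalidInputError(f"kmax must be >= 1, got {self.kmax}")


def mean_occupancy(spec: DropletSpec) -> float:
    """Mean cells per droplet, ``a = concentration x volume`` (mL/nL converted).

    Linear in both concentration and volume; no rounding is applied, so the
    canonical pairings (2.5e6 cells/mL, 0.8 nL) -> 2.0 and
    (15e6 cells/mL, 0.8 nL) -> 12.0 hold exactly.
    """
    return spec.cell_concentration * spec.droplet_volume_nl * 1e-6


@dataclass(frozen=True)
class OccupancyDistribution:
    """Truncated Poisson occupancy distribution over k = 0..kmax.

    ``raw_terms[k] = a^k e^(-a) / k!`` are the untruncated Poisson masses and
    sum to <= 1; ``normalized_pmf`` rescales them to sum to 1 for use as a
    sampling distribution or renormalized expectation.
    """

    a: float
    raw_terms: np.ndarray = field(repr=False)
    normalized_pmf: np.ndarray = field(repr=False)

    @property
    def k(self) -> np.ndarray:
        return np.arange(len(self.raw_terms))

    @property
    def kmax(self) -> int:
        return len(self.raw_terms) - 1


def occupancy_pmf(a: float, kmax: int = DEFAULT_KMAX) -> OccupancyDistribution:
    """Poisson occupancy masses at k = 0..kmax for mean occupancy ``a``.

    Evaluation goes through ``scipy.stats.poisson.pmf`` (log-space internally),
    so it is overflow-safe for kmax well beyond 170 where naive factorials fail.
    """
    if not (a > 0 and np.isfinite(a)):
        raise InvalidInputError(f"mean occupancy a must be finite and > 0, got {a}")
    kmax = int(kmax)
    if kmax < 1:
        raise InvalidInputError(f"kmax must be >= 1, got {kmax}")
    k = np.arange(kmax + 1)
    raw = stats.poisson.pmf(k, a)
    return OccupancyDistribution(a=a, raw_terms=raw, normalized_pmf=raw / raw.sum())


def simulate_encapsulation(a: float, n_droplets: int, seed=None) -> np.ndarray:
    """Draw per-droplet cell counts from an untruncated Poisson(a).

    The physical loading process is untruncated, so simulation does not apply
    the kmax cutoff used by the model sums. ``seed`` may be an int or a
    ``numpy.random.Generator``; a fixed seed reproduces the counts exactly.
    """
    if not (a > 0 and np.isfinite(a)):
        raise InvalidInputError(f"mean occupancy a must be finite and > 0, got {a}")
    n_droplets = int(n_droplets)
    if n_droplets < 1:
        raise InvalidInputError(f"n_droplets must be >= 1, got {n_droplets}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.poisson(a, size=n_droplets)


@dataclass(frozen=True)
class OccupancyComparison:
    """Observed vs expected occupancy frequencies and the chi-square statistic."""

    table: pd.DataFrame = field(repr=False)
    statistic: float
    dof: int
    pvalue: float


def counts_to_histogram(counts: np.ndarray) -> np.ndarray:
    """Histogram a vector of per-droplet counts into frequencies over k = 0..max."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise InvalidInputError("empty count vector")
    return np.bincount(counts)


def compare_occupancy(
    observed: np.ndarray,
    a: float,
    min_expected: float = 1.0,
    renormalize: bool = True,
) -> OccupancyComparison:
    """Compare an observed occupancy histogram with the Poisson expectation.

    Parameters
    ----------
    observed : array-like
        Frequencies at k = 0, 1, 2, ... (``observed[k]`` droplets held k cells).
    a : float
        Poisson mean occupancy.
    min_expected : float
        Bins with expected count below this floor are pooled into the tail bin
        before the statistic is computed (small-expected-count safeguard).
    renormalize : bool
        If True the expectation is the truncated pmf renormalized over the
        compared range (frequencies sum to the observed total); if False the
        raw Poisson masses are used and the residual tail mass is assigned to
        an overflow bin.

    Returns
    -------
    OccupancyComparison
        Per-bin table (k, observed, expected, pooled bin id) plus the
        chi-square statistic ``sum (obs-exp)^2/exp`` over pooled bins, its
        degrees of freedom (bins - 1) and asymptotic p-value.
    """
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    if observed.size == 0 or total < 1:
        raise InvalidInputError("observed histogram must contain at least one droplet")
    if np.any(observed < 0):
        raise InvalidInputError("observed frequencies must be nonnegative")

    # extend the support so the Poisson tail beyond the observed range is covered
    kmax = max(observed.size - 1, int(np.ceil(a + 8 * np.sqrt(a) + 8)))
    dist = occupancy_pmf(a, kmax=kmax)
    pmf = dist.normalized_pmf if renormalize else dist.raw_terms
    expected = total * pmf
    if not renormalize:
        # residual untruncated tail mass goes to the last (overflow) bin
        expected[-1] += total * (1.0 - dist.raw_terms.sum())
    obs_full = np.zeros(kmax + 1)
    obs_full[: observed.size] = observed

    # pool high-k bins with tiny expectation into a single tail bin
    cut = kmax + 1
    while cut > 1 and expected[cut - 1 :].sum() < min_expected:
        cut -= 1
    pooled_obs = np.concatenate([obs_full[: cut - 1], [obs_full[cut - 1 :].sum()]])
    pooled_exp = np.concatenate([expected[: cut - 1], [expected[cut - 1 :].sum()]])
    keep = pooled_exp > 0
    statistic = float(np.sum((pooled_obs[keep] - pooled_exp[keep]) ** 2 / pooled_exp[keep]))
    dof = max(int(keep.sum()) - 1, 1)
    pvalue = float(stats.chi2.sf(statistic, dof))

    bin_id = np.minimum(np.arange(kmax + 1), cut - 1)
    table = pd.DataFrame(
        {
            "k": np.arange(kmax + 1),
            "observed": obs_full,
            "expected": expected,
            "pooled_bin": bin_id,
        }
    )
    return OccupancyComparison(table=table, statistic=statistic, dof=dof, pvalue=pvalue)
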