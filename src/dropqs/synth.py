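"""Synthetic data with the statistical structure the analysis assumes.

Every pipeline input can be generated here, so each stage is testable
without biological material:

* single-cell event tables with a bimodal producer/non-producer IL-10
  distribution (producer fraction b = 0.10 by default) and near-universal
  TNFα secretion;
* multi-cell droplet datasets implementing the sharing mechanism exactly —
  Poisson occupancy, binomial producers, every cell in a droplet holding at
  least one producer becomes positive, and the droplet's secreted IL-10 is
  split equally over its occupants before being rendered through the
  titration curve;
* monotone titration standards with multiplicative log-normal noise;
* density-dependent ELISA time courses in which higher cell density
  shortens the production window (earlier shutoff, lower normalized total)
  and TNFα decays after its peak at the two highest densities, producing
  negative apparent production rates.

All generators are deterministic under a fixed seed. Donor heterogeneity is
multiplicative log-normal on totals only, which per-donor normalization
removes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .quantify import four_parameter_logistic

__all__ = [
    "GeneratorConfig",
    "true_forward",
    "generate_single_cell_events",
    "generate_multicell_dataset",
    "generate_titration_standards",
    "generate_density_timecourse",
]


def _geomspace(lo, hi, n):
    return tuple(float(x) for x in np.geomspace(lo, hi, n))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic forward model.

    The defaults are the study conditions: producer fraction b = 0.10, mean
    occupancies 2/4/8/12 cells per droplet, cell densities 2.5/5/10/15 x
    10^6 cells/mL, sampling at 0/2/4/8/24 h, and per-producer IL-10
    secretion log-normal with median 1 pg/cell and geometric SD 2 (an
    order-of-magnitude scale; no per-cell amounts are published, so the
    value is configurable rather than falsely precise).

    The titration axis is pg per cell; the default response is the power law
    ``signal = scale * amount^exponent`` (log-log linear, so the
    interpolating curve fit is exact through it), with a four-parameter
    logistic alternative for parametric-recovery exercises. The positivity
    gate sits between the non-producer background (median 5 MFI, GSD 1.5)
    and the producer signal cloud, where both misclassification rates are
    negligible.
    """

    # producer / signal model
    producer_fraction: float = 0.10
    producer_median_pg: float = 1.0
    producer_gsd: float = 2.0
    tnfa_median_pg: float = 5.0
    tnfa_gsd: float = 2.0
    background_median_mfi: float = 5.0
    background_gsd: float = 1.5
    signal_noise_gsd: float = 1.05
    viable_fraction: float = 0.98
    positivity_gate_mfi: float = 100.0
    # titration response
    titration_form: str = "powerlaw"
    titration_scale: float = 1000.0
    titration_exponent: float = 1.0
    titration_4pl: tuple = (20.0, 50000.0, 10.0, 1.2)  # bottom, top, ec50, hill
    titration_concentrations: tuple = field(default_factory=lambda: _geomspace(1e-3, 100.0, 11))
    titration_noise_gsd: float = 1.02
    # droplet occupancy conditions
    occupancy_means: tuple = (2.0, 4.0, 8.0, 12.0)
    n_droplets: int = 5000
    # density time-course conditions
    densities_e6: tuple = (2.5, 5.0, 10.0, 15.0)
    il10_shutoff_h: tuple = (24.0, 8.0, 4.0, 2.0)
    tnfa_shutoff_h: tuple = (24.0, 8.0, 4.0, 2.0)
    il10_totals_pg: tuple = (400.0, 300.0, 200.0, 120.0)
    tnfa_totals_pg: tuple = (2000.0, 1600.0, 1200.0, 800.0)
    tnfa_decay_per_h: float = 0.01
    n_decay_densities: int = 2  # TNFα decays post-peak at this many highest densities
    timepoints_h: tuple = (0.0, 2.0, 4.0, 8.0, 24.0)
    n_donors: int = 7
    donor_gsd: float = 1.3
    # sample sizes
    n_cells: int = 50_000
    n_control: int = 10_000

    def __post_init__(self):
        if not (0.0 <= self.producer_fraction <= 1.0):
            raise InvalidInputError("producer_fraction must lie in [0, 1]")
        for name in (
            "producer_median_pg",
            "producer_gsd",
            "background_median_mfi",
            "titration_scale",
            "donor_gsd",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if np.any(np.diff(self.densities_e6) <= 0):
            raise InvalidInputError("densities_e6 must be strictly increasing")
        for name in ("il10_shutoff_h", "tnfa_shutoff_h"):
            if np.any(np.diff(getattr(self, name)) >= 0):
                raise InvalidInputError(f"{name} must be strictly decreasing in density")
        if np.any(np.diff(self.timepoints_h) <= 0):
            raise InvalidInputError("timepoints_h must be strictly increasing")

    def to_yaml(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - fields
        if unknown:
            raise InvalidInputError(f"unknown generator config keys: {sorted(unknown)}")
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)


def true_forward(config: GeneratorConfig, amounts):
    """The generator's ground-truth amount -> signal response."""
    amounts = np.asarray(amounts, dtype=float)
    if config.titration_form == "powerlaw":
        return config.titration_scale * amounts**config.titration_exponent
    if config.titration_form == "4pl":
        return four_parameter_logistic(amounts, *config.titration_4pl)
    raise InvalidInputError(f"unknown titration_form '{config.titration_form}'")


def _lognormal(rng, median, gsd, size):
    """Log-normal draws parameterized by median and geometric SD."""
    return median * np.exp(np.log(gsd) * rng.standard_normal(size))


def _signal_noise(rng, config, size):
    if config.signal_noise_gsd <= 1.0:
        return np.ones(size)
    return np.exp(np.log(config.signal_noise_gsd) * rng.standard_normal(size))


def generate_single_cell_events(
    config: GeneratorConfig,
    n_cells: int | None = None,
    seed=None,
    stimulated: bool = True,
) -> pd.DataFrame:
    """Single-cell event table with ground-truth producer flags.

    Each cell is independently an IL-10 producer with probability b; its
    secreted amount (log-normal) is rendered through the titration response
    with multiplicative noise. Non-producers draw IL-10 signal from the
    staining background. Essentially all cells secrete TNFα. With
    ``stimulated=False`` an unstimulated control table is produced (all
    background, no producers).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(config.n_cells if n_cells is None else n_cells)
    if n < 1:
        raise InvalidInputError("n_cells must be >= 1")
    if stimulated:
        producer = rng.random(n) < config.producer_fraction
        il10_amount = np.zeros(n)
        il10_amount[producer] = _lognormal(
            rng, config.producer_median_pg, config.producer_gsd, int(producer.sum())
        )
        il10_signal = _lognormal(rng, config.background_median_mfi, config.background_gsd, n)
        il10_signal[producer] = (
            true_forward(config, il10_amount[producer])
            * _signal_noise(rng, config, int(producer.sum()))
        )
        tnfa_amount = _lognormal(rng, config.tnfa_median_pg, config.tnfa_gsd, n)
        tnfa_signal = true_forward(config, tnfa_amount) * _signal_noise(rng, config, n)
        condition = "single-cell-lps"
    else:
        producer = np.zeros(n, dtype=bool)
        il10_signal = _lognormal(rng, config.background_median_mfi, config.background_gsd, n)
        tnfa_signal = _lognormal(rng, config.background_median_mfi, config.background_gsd, n)
        condition = "unstimulated"
    viable = rng.random(n) < config.viable_fraction
    donor = np.array([f"D{1 + i % config.n_donors}" for i in range(n)])
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "donor": donor,
            "condition": condition,
            "tnfa_signal": tnfa_signal,
            "il10_signal": il10_signal,
            "viable": viable,
            "true_producer": producer,
        }
    )


def generate_multicell_dataset(config: GeneratorConfig, seed=None):
    """Multi-cell droplet dataset implementing the sharing mechanism exactly.

    For each configured mean occupancy ``a``: droplet occupancy is Poisson(a),
    producers are Binomial(k, b), and every cell in a droplet with at least
    one producer is IL-10 positive. The droplet's total secreted IL-10 (sum
    of its producers' log-normal amounts) is shared equally over its k
    occupants, so per-cell received amounts shrink as occupancy grows — at
    high occupancy some positive cells fall below the positivity gate, which
    is the capture-dilution the gated readout then reflects.

    Returns ``(droplets, events)``: a droplet table (droplet_id, condition,
    n_cells, n_producers, n_positive) and a per-cell event table carrying
    ground-truth positivity and producer flags.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    droplet_frames, event_frames = [], []
    b = config.producer_fraction
    for a in config.occupancy_means:
        n_d = int(config.n_droplets)
        k = rng.poisson(a, size=n_d)
        producers = rng.binomial(k, b)
        positive_droplet = producers > 0
        condition = f"a={a:g}"
        droplet_frames.append(
            pd.DataFrame(
                {
                    "droplet_id": np.arange(n_d),
                    "condition": condition,
                    "n_cells": k,
                    "n_producers": producers,
                    "n_positive": np.where(positive_droplet, k, 0),
                }
            )
        )
        # per-droplet secreted totals: sum of log-normal amounts per producer
        totals = np.zeros(n_d)
        prod_droplet = np.repeat(np.arange(n_d), producers)
        if prod_droplet.size:
            np.add.at(
                totals,
                prod_droplet,
                _lognormal(rng, config.producer_median_pg, config.producer_gsd, prod_droplet.size),
            )
        # expand to cells
        cell_droplet = np.repeat(np.arange(n_d), k)
        n_cells = cell_droplet.size
        received = np.where(
            positive_droplet[cell_droplet],
            totals[cell_droplet] / np.maximum(k[cell_droplet], 1),
            0.0,
        )
        # first n_producers cells of each droplet are the producers themselves
        in_droplet_rank = np.concatenate([np.arange(n) for n in k]) if n_cells else np.array([], dtype=int)
        is_producer = in_droplet_rank < producers[cell_droplet]
        il10_signal = _lognormal(rng, config.background_median_mfi, config.background_gsd, n_cells)
        pos_cell = received > 0
        il10_signal[pos_cell] = (
            true_forward(config, received[pos_cell])
            * _signal_noise(rng, config, int(pos_cell.sum()))
        )
        tnfa_signal = (
            true_forward(config, _lognormal(rng, config.tnfa_median_pg, config.tnfa_gsd, n_cells))
            * _signal_noise(rng, config, n_cells)
        )
        event_frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(n_cells),
                    "donor": "D1",
                    "condition": condition,
                    "droplet_id": cell_droplet,
                    "tnfa_signal": tnfa_signal,
                    "il10_signal": il10_signal,
                    "viable": True,
                    "true_producer": is_producer,
                    "true_positive": pos_cell,
                }
            )
        )
    droplets = pd.concat(droplet_frames, ignore_index=True)
    events = pd.concat(event_frames, ignore_index=True)
    return droplets, events


def generate_titration_standards(
    config: GeneratorConfig, seed=None, cytokines=("IL-10", "TNFa")
) -> pd.DataFrame:
    """Monotone titration standards from the configured response curve.

    Signals are the true response times multiplicative log-normal noise
    (GSD ``titration_noise_gsd``; 1.0 means noiseless). Noisy draws that
    would break monotonicity are re-sorted — the calibration contract
    requires a monotone standard series.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = np.asarray(config.titration_concentrations, dtype=float)
    frames = []
    for cytokine in cytokines:
        signal = true_forward(config, conc)
        if config.titration_noise_gsd > 1.0:
            signal = signal * np.exp(
                np.log(config.titration_noise_gsd) * rng.standard_normal(conc.size)
            )
            signal = np.sort(signal)
        frames.append(
            pd.DataFrame(
                {"cytokine": cytokine, "concentration_pg_ml": conc, "mfi": signal}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _density_course(t, total, shutoff, tau, decay_per_h=0.0):
    """Cumulative amount: saturating rise until shutoff, then plateau or decay."""
    t = np.asarray(t, dtype=float)
    rising = total * (1.0 - np.exp(-np.minimum(t, shutoff) / tau))
    plateau = total * (1.0 - np.exp(-shutoff / tau))
    post = np.clip(plateau * (1.0 - decay_per_h * (t - shutoff)), 0.0, None)
    return np.where(t <= shutoff, rising, post if decay_per_h > 0 else plateau)


def generate_density_timecourse(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Per-density ELISA time courses for IL-10 and TNFα, per donor.

    Cumulative amounts follow ``total x (1 - exp(-t/tau))`` with
    ``tau = shutoff/3`` and a hard plateau after the density-specific
    shutoff time, which decreases with density (the quorum-sensing
    signature). TNFα additionally decays after its peak at the
    ``n_decay_densities`` highest densities, so those courses show negative
    apparent production rates. Donor effects are multiplicative log-normal
    on totals only.

    Returns a long table: donor, condition, cytokine, timepoint_h,
    amount_pg_per_1e5_cells.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(config.timepoints_h, dtype=float)
    n_dens = len(config.densities_e6)
    rows = []
    for d in range(config.n_donors):
        donor = f"D{d + 1}"
        for cytokine in ("IL-10", "TNFa"):
            donor_scale = float(_lognormal(rng, 1.0, config.donor_gsd, 1)[0])
            for i, density in enumerate(config.densities_e6):
                if cytokine == "IL-10":
                    total, shutoff = config.il10_totals_pg[i], config.il10_shutoff_h[i]
                    decay = 0.0
                else:
                    total, shutoff = config.tnfa_totals_pg[i], config.tnfa_shutoff_h[i]
                    decay = (
                        config.tnfa_decay_per_h
                        if i >= n_dens - config.n_decay_densities
                        else 0.0
                    )
                amounts = donor_scale * _density_course(t, total, shutoff, shutoff / 3.0, decay)
                for tp, amt in zip(t, amounts):
                    rows.append(
                        {
                            "donor": donor,
                            "condition": f"{density:g}e6/mL",
                            "cytokine": cytokine,
                            "timepoint_h": float(tp),
                            "amount_pg_per_1e5_cells": float(amt),
                        }
                    )
    return pd.DataFrame(rows)
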