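"""Fluorescence-to-cytokine calibration and ELISA normalization.

Cell-bound capture antibodies trap secreted cytokine, which is then read out
as median fluorescence intensity (MFI). Incubating reference samples with
recombinant cytokine at known concentrations yields a titration curve — a
monotone mapping between concentration (pg/mL) and signal — through which
per-cell fluorescent values are converted to absolute cytokine content.

Two curve forms are supported:

* ``loglog`` (default): piecewise-linear interpolation in log-log space,
  exact through every standard, so forward-then-invert round-trips exactly.
* ``4pl``: a four-parameter logistic fit
  ``y = bottom + (top - bottom) / (1 + (ec50/x)^hill)``, inverted in closed
  form.

Bulk ELISA measurements are normalized to sample volume and cell count so
bulk and single-cell cultures can be compared on a common
pg-per-reference-cells scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InvalidInputError

__all__ = [
    "TitrationCurve",
    "fit_titration",
    "four_parameter_logistic",
    "signal_to_amount",
    "total_production",
    "elisa_normalize",
]

DEFAULT_REFERENCE_COUNT = 100_000


def four_parameter_logistic(x, bottom, top, ec50, hill):
    """Increasing 4PL response: bottom + (top-bottom) / (1 + (ec50/x)^hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def _validate_standards(concentrations, signals):
    conc = np.asarray(concentrations, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if conc.size != sig.size:
        raise InvalidInputError("concentration and signal arrays differ in length")
    if conc.size < 2:
        raise InvalidInputError("need at least 2 titration standards")
    if np.any(conc <= 0) or np.any(sig <= 0):
        raise InvalidInputError("standards must have strictly positive concentration and signal")
    for i in range(conc.size - 1):
        if conc[i + 1] <= conc[i]:
            raise InvalidInputError(
                f"standard concentrations not strictly increasing at rows {i},{i + 1}: "
                f"{conc[i]} -> {conc[i + 1]}"
            )
        if sig[i + 1] <= sig[i]:
            raise InvalidInputError(
                f"standard signals not strictly increasing at rows {i},{i + 1}: "
                f"{sig[i]} -> {sig[i + 1]} (curve must be monotone)"
            )
    return conc, sig


@dataclass(frozen=True)
class TitrationCurve:
    """Monotone concentration <-> signal mapping fitted to titration standards.

    Attributes
    ----------
    concentrations, signals : ndarray
        The standards, strictly increasing in both coordinates.
    form : str
        ``"loglog"`` or ``"4pl"``.
    params : tuple or None
        (bottom, top, ec50, hill) for the 4PL form.
    """

    concentrations: np.ndarray
    signals: np.ndarray
    form: str = "loglog"
    params: tuple | None = None

    @property
    def valid_range(self) -> tuple:
        """Concentration validity range: [lowest standard, highest standard]."""
        return float(self.concentrations[0]), float(self.concentrations[-1])

    @property
    def signal_range(self) -> tuple:
        return float(self.signals[0]), float(self.signals[-1])

    def forward(self, concentration):
        """Signal expected at a given concentration (vectorized)."""
        c = np.asarray(concentration, dtype=float)
        if self.form == "loglog":
            out = np.exp(
                np.interp(np.log(c), np.log(self.concentrations), np.log(self.signals))
            )
        else:
            out = four_parameter_logistic(c, *self.params)
        return float(out) if np.isscalar(concentration) else out

    def invert(self, signal):
        """Concentration at a given signal (vectorized); inverse of ``forward``."""
        s = np.asarray(signal, dtype=float)
        if self.form == "loglog":
            out = np.exp(np.interp(np.log(s), np.log(self.signals), np.log(self.concentrations)))
        else:
            bottom, top, ec50, hill = self.params
            s_clip = np.clip(s, self.signals[0], self.signals[-1])
            out = ec50 / ((top - bottom) / (s_clip - bottom) - 1.0) ** (1.0 / hill)
        return float(out) if np.isscalar(signal) else out

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "concentrations": self.concentrations.tolist(),
            "signals": self.signals.tolist(),
            "params": list(self.params) if self.params is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TitrationCurve":
        return cls(
            concentrations=np.asarray(d["concentrations"], dtype=float),
            signals=np.asarray(d["signals"], dtype=float),
            form=d["form"],
            params=tuple(d["params"]) if d.get("params") else None,
        )


def fit_titration(standards, form: str = "loglog") -> TitrationCurve:
    """Fit a titration curve to standards.

    Parameters
    ----------
    standards : DataFrame with columns ``concentration_pg_ml`` and ``mfi``,
        or a (concentrations, signals) pair.
    form : "loglog" (interpolating, exact through standards) or "4pl".
    """
    if isinstance(standards, pd.DataFrame):
        missing = {"concentration_pg_ml", "mfi"} - set(standards.columns)
        if missing:
            raise InvalidInputError(f"standards table lacks columns {sorted(missing)}")
        conc, sig = standards["concentration_pg_ml"], standards["mfi"]
    else:
        conc, sig = standards
    conc, sig = _validate_standards(conc, sig)
    if form == "loglog":
        return TitrationCurve(concentrations=conc, signals=sig, form="loglog")
    if form == "4pl":
        p0 = (0.5 * sig[0], 1.5 * sig[-1], float(np.sqrt(conc[0] * conc[-1])), 1.0)
        bounds = ([0.0, sig[0], conc[0] / 100, 0.1], [sig[0], 100 * sig[-1], conc[-1] * 100, 10.0])
        params, _ = curve_fit(
            four_parameter_logistic, conc, sig, p0=p0, bounds=bounds, maxfev=20000
        )
        return TitrationCurve(
            concentrations=conc, signals=sig, form="4pl", params=tuple(float(p) for p in params)
        )
    raise InvalidInputError(f"unknown titration form '{form}' (use 'loglog' or '4pl')")


def signal_to_amount(
    curve: TitrationCurve,
    events: pd.DataFrame,
    signal_column: str = "il10_signal",
    conversion: float = 1.0,
    amount_column: str = "amount_pg",
) -> pd.DataFrame:
    """Invert the titration curve for every event to per-cell cytokine amounts.

    Events whose signal falls below the lowest standard are clamped to the
    lowest-standard concentration and flagged ``below_range``; events above
    the highest standard are clamped and flagged ``saturated`` (the capture
    antibodies have finite capacity). Clamp-and-flag, rather than dropping,
    keeps cell counts intact for downstream fraction estimates.

    ``conversion`` rescales the inverted concentration to pg per cell; the
    default 1.0 treats the curve's concentration axis as already on the
    per-cell scale used during calibration.
    """
    if signal_column not in events.columns:
        raise InvalidInputError(f"events table lacks column '{signal_column}'")
    out = events.copy()
    s = out[signal_column].to_numpy(dtype=float)
    lo_s, hi_s = curve.signal_range
    below = s < lo_s
    above = s > hi_s
    amounts = curve.invert(np.clip(s, lo_s, hi_s)) * conversion
    out[amount_column] = amounts
    out["below_range"] = below
    out["saturated"] = above
    return out


def total_production(
    per_cell_amounts, reference_count: int = DEFAULT_REFERENCE_COUNT
) -> float:
    """Total cytokine production scaled to a reference cell count.

    ``sum(amounts) * reference_count / n_cells`` — invariant under duplicating
    every cell, so cultures of different sizes compare directly.
    """
    amounts = np.asarray(per_cell_amounts, dtype=float)
    if amounts.size == 0:
        raise InvalidInputError("no quantified cells")
    if np.any(amounts < 0):
        raise InvalidInputError("per-cell amounts must be nonnegative")
    return float(amounts.sum() * reference_count / amounts.size)


def elisa_normalize(
    concentration_pg_ml: float,
    volume_ml: float,
    cell_count: float,
    reference_count: int = DEFAULT_REFERENCE_COUNT,
) -> float:
    """Normalize a bulk ELISA concentration to pg per reference cell count.

    ``concentration x volume / cell_count x reference_count``; volume and
    cell count are registered at collection precisely to enable this
    bulk-vs-single-cell comparison.
    """
    if concentration_pg_ml < 0:
        raise InvalidInputError("concentration must be nonnegative")
    if volume_ml <= 0:
        raise InvalidInputError("sample volume must be positive")
    if cell_count <= 0:
        raise InvalidInputError("cell count must be positive")
    return float(concentration_pg_ml * volume_ml / cell_count * reference_count)
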