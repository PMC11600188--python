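"""Capillary electropherogram calibration and band quantification.

In chip electrophoresis the detector response per unit analyte falls off
with migration time, so raw peak areas under-represent late (large) species.
Sizing instruments report both a raw "area" and a "time-corrected area" for
each ladder peak; the correction ratio is well described by a power law
``r(t) = a * t**b`` of the aligned migration time.  Multiplying a trace by
``r(t)`` makes the interval integral proportional to protein amount, after
which a band's amount follows from comparison with a ladder peak of known
amount:

    amount_band = integral(sample - water baseline over the band window)
                  * ladder_amount / ladder_corrected_area

Molecular-weight windows are mapped to time windows by the standard sizing
convention: piecewise-linear interpolation of log(MW) against migration
time through the ladder peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError, FormatError

__all__ = [
    "Trace",
    "LadderPeak",
    "PowerLawCalibration",
    "MWTimeMap",
    "BandQuant",
    "fit_ladder_powerlaw",
    "time_correct",
    "map_mw_axis",
    "quantify_band",
    "LOW_MW_BAND",
]

# The diagnostic low-molecular-weight window (kDa): proteins in this range
# pass the glomerular sieve and appear in urine when tubular reabsorption
# fails.
LOW_MW_BAND = (10.0, 40.0)


@dataclass
class Trace:
    """A signal-versus-aligned-migration-time trace."""

    time: np.ndarray  # seconds, strictly increasing
    signal: np.ndarray
    label: str = "sample"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be equal-length 1D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("migration times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "signal": self.signal}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, label: str = "sample") -> "Trace":
        df = pd.read_csv(path, comment="#")
        if "time_s" not in df or "signal" not in df:
            raise FormatError(f"{path}: expected columns time_s, signal")
        return cls(df["time_s"].to_numpy(), df["signal"].to_numpy(), label=label)


@dataclass
class LadderPeak:
    """One sizing-ladder peak of known molecular weight and amount."""

    mw_kda: float
    amount_ng: float
    time_s: float
    raw_area: float | None = None
    corrected_area: float | None = None
    ratio: float | None = None  # instrument "time-corrected area"/"area"

    def correction_ratio(self) -> float:
        if self.ratio is not None:
            return float(self.ratio)
        if self.raw_area and self.corrected_area is not None:
            return float(self.corrected_area / self.raw_area)
        raise ValueError(
            f"ladder peak at {self.mw_kda} kDa carries neither a ratio nor "
            "raw+corrected areas"
        )


@dataclass
class PowerLawCalibration:
    """r(t) = a * t**b fitted over [t_min, t_max]."""

    a: float
    b: float
    t_min: float
    t_max: float
    residual_norm: float = 0.0

    def __call__(self, t) -> np.ndarray:
        return self.a * np.asarray(t, dtype=float) ** self.b


def fit_ladder_powerlaw(peaks: Sequence[LadderPeak]) -> PowerLawCalibration:
    """Fit the correction ratio as a power law of migration time.

    OLS of log(ratio) on log(t): exact for true power laws and
    deterministic.  Requires >= 2 peaks with positive times and ratios.
    """
    if len(peaks) < 2:
        raise FitError("need >= 2 ladder peaks")
    t = np.array([p.time_s for p in peaks], dtype=float)
    r = np.array([p.correction_ratio() for p in peaks], dtype=float)
    if np.any(t <= 0) or np.any(r <= 0):
        raise FitError("ladder times and correction ratios must be positive")
    b, log_a = np.polyfit(np.log(t), np.log(r), 1)
    a = float(np.exp(log_a))
    resid = np.log(r) - (log_a + b * np.log(t))
    return PowerLawCalibration(
        a=a,
        b=float(b),
        t_min=float(t.min()),
        t_max=float(t.max()),
        residual_norm=float(np.linalg.norm(resid)),
    )


def time_correct(trace: Trace, cal: PowerLawCalibration) -> Trace:
    """Multiply the signal pointwise by r(t).

    Points outside the calibration's fit domain are still corrected (the
    power law extrapolates smoothly) but a warning is emitted.
    """
    outside = (trace.time < cal.t_min) | (trace.time > cal.t_max)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} of {trace.time.size} points lie outside the "
            f"calibration domain [{cal.t_min:g}, {cal.t_max:g}] s; "
            "extrapolating the power law",
            stacklevel=2,
        )
    return Trace(trace.time.copy(), trace.signal * cal(trace.time), label=trace.label)


class MWTimeMap:
    """Invertible molecular-weight <-> migration-time mapping.

    Piecewise-linear in (time, log MW) through the ladder peaks; defined on
    the ladder's span only.
    """

    def __init__(self, peaks: Sequence[LadderPeak]):
        if len(peaks) < 2:
            raise FitError("need >= 2 ladder peaks")
        order = np.argsort([p.time_s for p in peaks])
        self._t = np.array([peaks[i].time_s for i in order], dtype=float)
        self._mw = np.array([peaks[i].mw_kda for i in order], dtype=float)
        self._log_mw = np.log(self._mw)
        if np.any(np.diff(self._t) <= 0) or np.any(np.diff(self._log_mw) <= 0):
            raise FitError(
                "ladder must be jointly monotone: MW strictly increasing "
                "with migration time"
            )

    @property
    def mw_span(self) -> tuple:
        return float(self._mw[0]), float(self._mw[-1])

    @property
    def time_span(self) -> tuple:
        return float(self._t[0]), float(self._t[-1])

    def _check(self, value: float, lo: float, hi: float, what: str) -> None:
        if not lo <= value <= hi:
            raise ValueError(f"{what} {value:g} outside ladder span [{lo:g}, {hi:g}]")

    def mw_for_time(self, t: float) -> float:
        self._check(t, *self.time_span, "time")
        if t == self.time_span[0]:
            return float(self._mw[0])
        if t == self.time_span[1]:
            return float(self._mw[-1])
        return float(np.exp(np.interp(t, self._t, self._log_mw)))

    def time_for_mw(self, mw: float) -> float:
        self._check(mw, *self.mw_span, "MW")
        return float(np.interp(np.log(mw), self._log_mw, self._t))


def map_mw_axis(peaks: Sequence[LadderPeak]) -> MWTimeMap:
    """Build the MW <-> time mapping from the ladder."""
    return MWTimeMap(peaks)


@dataclass
class BandQuant:
    """Quantified protein amount in one molecular-weight window."""

    mw_range: tuple  # kDa
    time_window: tuple  # s
    corrected_area: float  # may be negative (sample below baseline)
    amount_ng: float  # floored at 0
    clipped: bool  # True when the raw estimate was negative


def _resample(trace: Trace, time: np.ndarray) -> np.ndarray:
    return np.interp(time, trace.time, trace.signal)


def _window_integral(time: np.ndarray, signal: np.ndarray, t_lo: float, t_hi: float) -> float:
    """Trapezoidal integral over [t_lo, t_hi] with interpolated endpoints."""
    inside = (time > t_lo) & (time < t_hi)
    t = np.concatenate([[t_lo], time[inside], [t_hi]])
    y = np.interp(t, time, signal)
    return float(np.trapezoid(y, t))


def quantify_band(
    sample: Trace,
    baseline: Trace,
    mw_range: tuple,
    mapping: MWTimeMap,
    ladder_reference: tuple,
) -> BandQuant:
    """Protein amount in a molecular-weight window of a corrected trace.

    Parameters
    ----------
    sample, baseline : time-corrected sample and breeding-water traces.
        Resampled onto the sample grid by linear interpolation if needed.
    mw_range : (lo, hi) in kDa; must lie within the ladder span.
    ladder_reference : (corrected_area, amount_ng) of a ladder peak, giving
        the area-to-amount conversion.

    A negative baseline-subtracted integral is reported as amount 0 with a
    warning (``clipped=True``).
    """
    lo, hi = sorted(map(float, mw_range))
    t_lo = mapping.time_for_mw(lo)
    t_hi = mapping.time_for_mw(hi)
    if t_lo < sample.time[0] or t_hi > sample.time[-1]:
        raise ValueError("band window extends beyond the sample trace")
    diff = sample.signal - _resample(baseline, sample.time)
    area = _window_integral(sample.time, diff, t_lo, t_hi)
    ref_area, ref_amount = ladder_reference
    if ref_area <= 0:
        raise ValueError("ladder reference area must be positive")
    amount = float(area * ref_amount / ref_area)
    clipped = amount < 0
    if clipped:
        warnings.warn(
            f"negative amount estimate ({amount:.4g} ng) in {mw_range} kDa "
            "window floored at 0",
            stacklevel=2,
        )
    return BandQuant(
        mw_range=(lo, hi),
        time_window=(t_lo, t_hi),
        corrected_area=area,
        amount_ng=max(0.0, amount),
        clipped=clipped,
    )
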