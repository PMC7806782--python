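"""Melting-temperature extraction from thermal denaturation curves.

Works on any (temperature, fluorescence) table — DSF dye traces or
Trp-fluorescence summaries at coarser sampling.  Tm is read from peaks of
the first derivative dF/dT after light moving-average smoothing, with
parabolic refinement through each peak and its neighbours, so a curve with
two resolvable transitions reports two Tm values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ValidationError

__all__ = ["MeltCurve", "MeltResult", "melt_derivative", "find_tm", "read_meltcurves"]


@dataclass
class MeltCurve:
    temperature: np.ndarray  # degC, strictly increasing
    signal: np.ndarray  # fluorescence, arbitrary units
    label: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape or self.temperature.ndim != 1:
            raise ValidationError("temperature and signal must be equal-length 1-D")
        if self.temperature.size < 10:
            raise ValidationError("need >= 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValidationError("temperatures must be strictly increasing")


@dataclass
class MeltResult:
    tm_values: list[float]  # ascending, degC
    derivative: np.ndarray  # dF/dT at the input temperatures
    n_transitions: int


def _smooth(signal: np.ndarray, window: int) -> np.ndarray:
    # centred moving average; the half-width shrinks symmetrically at the
    # edges so a linear signal is preserved everywhere
    n = signal.size
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(signal)])
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def melt_derivative(curve: MeltCurve, smoothing_window: int = 5) -> np.ndarray:
    """dF/dT after a centred moving average; one-sided at the endpoints."""
    if smoothing_window % 2 == 0:
        raise ValidationError("smoothing_window must be odd")
    if smoothing_window >= curve.temperature.size:
        raise ValidationError("smoothing_window must be smaller than the series")
    smoothed = _smooth(curve.signal, smoothing_window)
    return np.gradient(smoothed, curve.temperature)


def find_tm(
    curve: MeltCurve,
    min_prominence: float = 0.2,
    smoothing_window: int = 5,
) -> MeltResult:
    """Transition midpoints = dF/dT peaks with prominence >= fraction of max.

    A curve whose derivative never rises above zero (no unfolding upswing)
    reports zero transitions rather than raising.
    """
    deriv = melt_derivative(curve, smoothing_window=smoothing_window)
    dmax = float(deriv.max(initial=0.0))
    # guard against float noise on flat curves: a genuine transition moves
    # the signal by far more than machine epsilon of its own magnitude
    flat_tol = 1e-12 * (1.0 + float(np.abs(curve.signal).max()))
    if dmax <= flat_tol:
        return MeltResult(tm_values=[], derivative=deriv, n_transitions=0)
    peaks, _ = find_peaks(deriv, prominence=min_prominence * dmax)
    tms = []
    t = curve.temperature
    for p in peaks:
        if 0 < p < deriv.size - 1:
            # vertex of the parabola through the peak and its neighbours
            coeff = np.polyfit(t[p - 1 : p + 2], deriv[p - 1 : p + 2], 2)
            tm = float(-coeff[1] / (2 * coeff[0])) if coeff[0] < 0 else float(t[p])
            lo, hi = t[p - 1], t[p + 1]
            tm = min(max(tm, lo), hi)
        else:
            tm = float(t[p])
        tms.append(tm)
    tms.sort()
    return MeltResult(tm_values=tms, derivative=deriv, n_transitions=len(tms))


def read_meltcurves(path) -> list[MeltCurve]:
    """Read CSV of (temperature_C, signal[, label]); one curve per label."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("temperature_c") or cols.get("temperature")
    scol = cols.get("signal") or cols.get("fluorescence")
    if tcol is None or scol is None:
        raise ValidationError("need temperature_C and signal columns")
    if "label" in cols:
        out = []
        for label, grp in df.groupby(cols["label"], sort=False):
            out.append(MeltCurve(grp[tcol].to_numpy(), grp[scol].to_numpy(), str(label)))
        return out
    return [MeltCurve(df[tcol].to_numpy(), df[scol].to_numpy(), "")]
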