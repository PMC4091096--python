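"""Aggregation-assay quantification and spectral processing.

Covers the arithmetic around the wet-lab readouts used to characterize
amyloid-inhibitor designs: relative Congo red binding (rCb) for
transthyretin fibrillization, ThT-based percent inhibition for Aβ,
Beer–Lambert concentration determination, Savitzky–Golay smoothing and
second derivatives, amide-I band assignment (including the two-band α-sheet
signature) and CD ellipticity conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

from .config import AssayConstants

__all__ = [
    "AssayCurve",
    "Spectrum",
    "BandAssignment",
    "congo_red_rcb",
    "normalize_curve",
    "percent_inhibition",
    "concentration_from_absorbance",
    "savitzky_golay",
    "assign_amide1_bands",
    "ellipticity_convert",
    "read_curves_csv",
    "write_curves_csv",
    "read_spectrum",
    "write_spectrum",
]


@dataclass
class AssayCurve:
    """Time series of an aggregation readout (times in hours)."""

    times: np.ndarray
    signals: np.ndarray
    condition: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape:
            raise ValueError("times and signals must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def at(self, t: float) -> float:
        """Signal at time t, linearly interpolated between samples."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"time {t} outside curve range")
        return float(np.interp(t, self.times, self.signals))


@dataclass
class Spectrum:
    """x (wavenumber cm⁻¹ or wavelength nm) vs intensity, strictly monotone x."""

    x: np.ndarray
    y: np.ndarray
    kind: str = "FTIR_absorbance"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        d = np.diff(self.x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("x must be strictly monotone")


# ---------------------------------------------------------------------------
# closed-form assay arithmetic


def congo_red_rcb(abs540: float, abs477: float,
                  constants: Optional[AssayConstants] = None) -> float:
    """Relative Congo red binding: rCb = Abs540/25295 − Abs477/46306.

    The result may legitimately be negative and is reported unclipped.
    """
    c = constants or AssayConstants()
    if abs540 < 0 or abs477 < 0:
        raise ValueError("absorbances must be nonnegative")
    return abs540 / c.cr_denominator_540 - abs477 / c.cr_denominator_477


def concentration_from_absorbance(absorbance: float, epsilon: float,
                                  path_cm: float = 1.0,
                                  dilution: float = 1.0) -> float:
    """Beer–Lambert concentration in M: c = (A / (ε·l)) · dilution."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    if absorbance < 0:
        raise ValueError("absorbance must be nonnegative")
    return absorbance / (epsilon * path_cm) * dilution


def normalize_curve(curve: AssayCurve, reference: AssayCurve, at: float) -> AssayCurve:
    """Divide a curve by the reference's value at the anchor time.

    The anchor value is linearly interpolated if it falls between samples;
    normalizing the reference against itself gives 1.0 at the anchor.
    """
    ref_value = reference.at(at)
    if ref_value == 0:
        raise ValueError(f"reference value at t={at} is zero")
    return AssayCurve(
        times=curve.times.copy(),
        signals=curve.signals / ref_value,
        condition=curve.condition,
        replicate=curve.replicate,
    )


def percent_inhibition(
    treated: AssayCurve,
    control: AssayCurve,
    at: float,
    baseline: Optional[float] = None,
) -> float:
    """Percent inhibition of signal growth at the anchor time.

    100 × (1 − (treated(at) − b) / (control(at) − b)), where the baseline b
    defaults to the control's signal at the start of the treatment window
    (the curves' shared starting value).  Passing an explicit baseline
    supports the pre-aggregated protocol, where only the aggregation
    *remaining* after inhibitor addition is compared.
    """
    b = control.at(float(control.times[0])) if baseline is None else float(baseline)
    denom = control.at(at) - b
    if denom == 0:
        raise ValueError("degenerate control: no signal change relative to baseline")
    return 100.0 * (1.0 - (treated.at(at) - b) / denom)


def ellipticity_convert(
    spectrum: Spectrum,
    concentration_m: float,
    path_cm: float,
    n_residues: int = 1,
    mode: str = "molar",
) -> Spectrum:
    """Convert a CD spectrum from millidegrees to (mean-residue) molar
    ellipticity: [θ] = θ_mdeg / (10 · c · l), optionally / n_residues."""
    if concentration_m <= 0 or path_cm <= 0:
        raise ValueError("concentration and path length must be positive")
    if mode not in ("molar", "mean_residue"):
        raise ValueError("mode must be 'molar' or 'mean_residue'")
    factor = 10.0 * concentration_m * path_cm
    if mode == "mean_residue":
        if n_residues <= 0:
            raise ValueError("n_residues must be positive")
        factor *= n_residues
    return Spectrum(x=spectrum.x.copy(), y=spectrum.y / factor,
                    kind="CD_molar_ellipticity")


# ---------------------------------------------------------------------------
# spectral processing


def savitzky_golay(spectrum: Spectrum, window: int, order: int,
                   deriv: int = 0) -> Spectrum:
    """Savitzky–Golay least-squares smoothing (deriv 0) or second derivative.

    Output is truncated to the valid interior (no edge padding), matching
    instrument-style behavior; derivatives are scaled by the grid spacing.
    The window must be odd — a 12-point request should be made as 13.
    """
    if window % 2 == 0:
        raise ValueError(
            f"window must be odd (use {window + 1} instead of {window})"
        )
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    if deriv not in (0, 2):
        raise ValueError("deriv must be 0 or 2")
    dx = np.diff(spectrum.x)
    spacing = float(np.mean(dx))
    if np.max(np.abs(dx - spacing)) > 1e-6 * abs(spacing):
        raise ValueError("x grid must be uniform for Savitzky–Golay filtering")
    coeffs = savgol_coeffs(window, order, deriv=deriv, delta=abs(spacing))
    half = window // 2
    y = np.convolve(spectrum.y, coeffs[::-1], mode="valid")
    kind = "FTIR_second_derivative" if deriv == 2 else spectrum.kind
    return Spectrum(x=spectrum.x[half:-half].copy(), y=y, kind=kind)


AMIDE1_WINDOWS = {
    "alpha_sheet_high": (1675.0, 1680.0),
    "alpha_sheet_low": (1636.0, 1644.0),
    "turn": (1666.0, 1674.0),
    "alpha_helix": (1650.0, 1658.0),
    "beta_sheet": (1620.0, 1640.0),
}


@dataclass
class BandAssignment:
    """Detected band minima (cm⁻¹), their labels, and the overall verdict."""

    bands: list  # (position, label)
    verdict: str


def _label_band(position: float, windows: dict, has_high_band: bool) -> str:
    lo, hi = windows["alpha_sheet_high"]
    if lo <= position <= hi:
        return "alpha_sheet_high"
    lo, hi = windows["alpha_helix"]
    if lo <= position <= hi:
        return "alpha_helix"
    lo, hi = windows["turn"]
    if lo <= position <= hi:
        return "turn"
    in_low = windows["alpha_sheet_low"][0] <= position <= windows["alpha_sheet_low"][1]
    in_beta = windows["beta_sheet"][0] <= position <= windows["beta_sheet"][1]
    if in_low and (has_high_band or not in_beta):
        return "alpha_sheet_low"
    if in_beta:
        return "beta_sheet"
    return "other"


def assign_amide1_bands(
    spectrum: Spectrum,
    windows: Optional[dict] = None,
    prominence: Optional[float] = None,
) -> BandAssignment:
    """Assign amide-I second-derivative minima to secondary-structure bands.

    Minima deeper than the prominence threshold (default: 3× the median
    absolute deviation of the second derivative outside the 1600–1700 cm⁻¹
    region, falling back to the whole-spectrum MAD) become bands.  Each band
    is labeled by window membership; the verdict is ALPHA_SHEET when both
    the ~1640 cm⁻¹ and 1675–1680 cm⁻¹ signature minima are present,
    otherwise the label of the deepest band.
    """
    windows = windows or AMIDE1_WINDOWS
    x, y = spectrum.x, spectrum.y
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    if x[0] > 1600.0 or x[-1] < 1700.0:
        raise ValueError("spectrum must cover the amide-I region (1600–1700 cm⁻¹)")
    if prominence is None:
        outside = y[(x < 1600.0) | (x > 1700.0)]
        ref = outside if outside.size >= 10 else y
        mad = float(np.median(np.abs(ref - np.median(ref))))
        prominence = 3.0 * mad

    interior = (y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])
    candidates = np.where(interior)[0] + 1
    amide = (x[candidates] >= 1600.0) & (x[candidates] <= 1700.0)
    candidates = candidates[amide]
    candidates = candidates[y[candidates] <= -prominence]

    has_high = any(
        windows["alpha_sheet_high"][0] <= x[k] <= windows["alpha_sheet_high"][1]
        for k in candidates
    )
    bands = [(float(x[k]), _label_band(float(x[k]), windows, has_high))
             for k in candidates]
    labels = {label for _, label in bands}
    if "alpha_sheet_high" in labels and "alpha_sheet_low" in labels:
        verdict = "ALPHA_SHEET"
    elif bands:
        deepest = min(candidates, key=lambda k: y[k])
        verdict = _label_band(float(x[deepest]), windows, has_high)
    else:
        verdict = "NONE"
    return BandAssignment(bands=bands, verdict=verdict)


# ---------------------------------------------------------------------------
# tabular IO


def read_curves_csv(path: Union[str, Path]) -> list:
    """Read assay curves from CSV with header time_h, signal, condition, replicate."""
    df = pd.read_csv(path)
    required = {"time_h", "signal", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve CSV must have columns {sorted(required)}")
    curves = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(AssayCurve(times=grp["time_h"].to_numpy(),
                                 signals=grp["signal"].to_numpy(),
                                 condition=str(cond), replicate=int(rep)))
    return curves


def write_curves_csv(curves: Sequence[AssayCurve], path: Union[str, Path]) -> None:
    rows = []
    for c in curves:
        for t, s in zip(c.times, c.signals):
            rows.append({"time_h": t, "signal": s,
                         "condition": c.condition, "replicate": c.replicate})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spectrum(path: Union[str, Path], kind: str = "FTIR_absorbance") -> Spectrum:
    """Two-column whitespace- or comma-separated spectrum file."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError("spectrum file must have two columns (x, y)")
    return Spectrum(x=df.iloc[:, 0].to_numpy(float),
                    y=df.iloc[:, 1].to_numpy(float), kind=kind)


def write_spectrum(spectrum: Spectrum, path: Union[str, Path]) -> None:
    np.savetxt(path, np.column_stack([spectrum.x, spectrum.y]), fmt="%.6f")
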