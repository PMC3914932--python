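"""1D NMR spectrum model: Lorentzian synthesis, integration, noise, peak picking.

Every downstream stage of the screening pipeline (quantification, cocktail
design, hit calling) works on the :class:`Spectrum1D` container defined here.
Spectra are stored with an ascending ppm axis internally; NMR display
convention (descending ppm) is a presentation concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Multiplet",
    "PredictedSpectrum",
    "Spectrum1D",
    "Region",
    "synthesize_spectrum",
    "integrate",
    "estimate_noise",
    "pick_peaks",
]

# ppm window outside which no 1H signal is physically plausible
_PPM_FLOOR, _PPM_CEIL = -2.0, 16.0

#: nominal sub-line count per multiplicity label (singlet, doublet, ...)
_LABEL_LINES = {"s": 1, "d": 2, "t": 3, "q": 4, "quint": 5, "m": 3, "dd": 4}


@dataclass(frozen=True)
class Region:
    """Closed ppm interval [low, high]."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"Region requires low < high, got [{self.low}, {self.high}]")

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, ppm: float) -> bool:
        return self.low <= ppm <= self.high

    def overlaps(self, other: "Region") -> bool:
        """Positive-length intersection; touching endpoints do not count."""
        return min(self.high, other.high) > max(self.low, other.low)


@dataclass(frozen=True)
class Multiplet:
    """One predicted multiplet: a chemical-shift range carrying n protons.

    ``n_protons`` may be None when unknown. ``exchangeable`` marks protons
    (OH, NH) whose shifts are solvent-dependent and hard to predict.
    """

    center: float
    low: float
    high: float
    n_protons: int | None = 1
    exchangeable: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"multiplet range requires low < high, got [{self.low}, {self.high}]")
        if not self.low <= self.center <= self.high:
            raise ValueError(
                f"multiplet center {self.center} outside range [{self.low}, {self.high}]"
            )
        if self.n_protons is not None and self.n_protons < 1:
            raise ValueError("n_protons must be >= 1 when known")


@dataclass(frozen=True)
class PredictedSpectrum:
    """Predicted 1H multiplet list for one compound."""

    compound_id: str
    multiplets: tuple[Multiplet, ...]

    def __init__(self, compound_id: str, multiplets: Sequence[Multiplet]):
        if not compound_id:
            raise ValueError("compound_id must be non-empty")
        for m in multiplets:
            if m.low < _PPM_FLOOR or m.high > _PPM_CEIL:
                raise ValueError(
                    f"multiplet [{m.low}, {m.high}] outside plausible 1H window "
                    f"[{_PPM_FLOOR}, {_PPM_CEIL}] ppm"
                )
        object.__setattr__(self, "compound_id", compound_id)
        object.__setattr__(self, "multiplets", tuple(multiplets))


@dataclass
class Spectrum1D:
    """Sampled 1D spectrum: strictly monotone ppm axis + intensity trace.

    ``experiment`` tags the pulse sequence the trace came from: plain 1H
    (WATERGATE), STD or WaterLOGSY. ``noise_sd`` is set by
    :func:`estimate_noise` and consumed by peak picking.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    experiment: str = "H1"
    noise_sd: float | None = None

    _EXPERIMENTS = ("H1", "STD", "WLOGSY")

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if len(d) and np.all(d < 0):  # store ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        if self.experiment not in self._EXPERIMENTS:
            raise ValueError(f"experiment must be one of {self._EXPERIMENTS}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def slice(self, region: Region) -> tuple[np.ndarray, np.ndarray]:
        """Axis and intensity restricted to the closed region."""
        mask = (self.ppm >= region.low) & (self.ppm <= region.high)
        return self.ppm[mask], self.intensity[mask]

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum1D":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian lineshape."""
    hwhm = fwhm / 2.0
    return (hwhm / np.pi) / ((x - center) ** 2 + hwhm**2)


def _subline_positions(m: Multiplet) -> np.ndarray:
    """Positions of the fine-structure sub-lines of a multiplet.

    The label decides the nominal line count (singlet 1, doublet 2, ...);
    lines are spread evenly across [low, high] with equal areas. Without a
    recognized label a single line at the center is used.
    """
    n = _LABEL_LINES.get(m.label, 1)
    if n == 1:
        return np.array([m.center])
    return np.linspace(m.low, m.high, n)


def synthesize_spectrum(
    multiplets: Sequence[Multiplet],
    scale: float = 1.0,
    linewidth: float = 0.02,
    axis: Region = Region(-1.0, 12.0),
    n_points: int = 4096,
    noise_sd: float = 0.0,
    seed: int | None = None,
    experiment: str = "H1",
    sign: float = 1.0,
) -> Spectrum1D:
    """Render a multiplet list as a sampled Lorentzian spectrum.

    Each multiplet contributes total integrated area ``scale * n_protons``
    (split evenly over its fine-structure sub-lines), plus i.i.d. Gaussian
    noise of standard deviation ``noise_sd``. ``sign`` flips the peaks, used
    to emulate sign-inverted WaterLOGSY responses. Identical arguments and
    seed give bit-identical output.
    """
    if linewidth <= 0:
        raise ValueError("linewidth must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = np.linspace(axis.low, axis.high, n_points)
    y = np.zeros_like(x)
    for m in multiplets:
        n_h = m.n_protons if m.n_protons is not None else 1
        positions = _subline_positions(m)
        area_per_line = scale * n_h / len(positions)
        for pos in positions:
            y += area_per_line * _lorentzian(x, pos, linewidth)
    y *= sign
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    return Spectrum1D(ppm=x, intensity=y, experiment=experiment)


def integrate(spectrum: Spectrum1D, region: Region) -> float:
    """Trapezoidal area of the intensity over a ppm region."""
    x, y = spectrum.slice(region)
    if len(x) < 2:
        raise ValueError(f"region [{region.low}, {region.high}] does not overlap the axis")
    return float(np.trapezoid(y, x))


def estimate_noise(spectrum: Spectrum1D, quiet_region: Region, store: bool = True) -> float:
    """Noise standard deviation from a signal-free region (mean-centred).

    Requires at least 16 points in the region; the estimate is stored on the
    spectrum so that peak picking can threshold against it.
    """
    _, y = spectrum.slice(quiet_region)
    if len(y) < 16:
        raise ValueError(
            f"quiet region holds {len(y)} points; >= 16 required for a noise estimate"
        )
    sd = float(np.std(y, ddof=1))
    if store:
        spectrum.noise_sd = sd
    return sd


def pick_peaks(
    spectrum: Spectrum1D,
    region: Region,
    k_noise: float = 3.0,
    merge_width: float | None = None,
    negative: bool = False,
    min_width: float | None = None,
) -> list[tuple[float, float]]:
    """Local maxima above ``k_noise * noise_sd`` in a region, sorted by ppm.

    ``negative=True`` picks sign-inverted peaks (local minima below the
    threshold), returning their (ppm, intensity) with the true negative
    intensity. Peaks closer than ``merge_width`` ppm collapse to the taller
    one, avoiding double counting of shoulders. ``min_width`` (ppm) discards
    maxima narrower than the stated width at half prominence: a genuine NMR
    line spans at least its linewidth, whereas noise excursions above the
    threshold are one or two samples wide.
    """
    if spectrum.noise_sd is None:
        raise ValueError("noise_sd is unset; call estimate_noise first")
    if k_noise <= 0:
        raise ValueError("k_noise must be positive")
    x, y = spectrum.slice(region)
    if len(x) < 3:
        return []
    trace = -y if negative else y
    threshold = k_noise * spectrum.noise_sd
    width_samples = None
    if min_width is not None and min_width > 0:
        dx = float(np.median(np.diff(x)))
        width_samples = min_width / dx
    idx, _ = find_peaks(
        trace,
        height=threshold if threshold > 0 else None,
        width=width_samples,
    )
    if threshold == 0:
        idx = idx[trace[idx] > 0]
    peaks = [(float(x[i]), float(y[i])) for i in idx]
    if merge_width and len(peaks) > 1:
        peaks.sort(key=lambda p: p[0])
        merged: list[tuple[float, float]] = [peaks[0]]
        for ppm, inten in peaks[1:]:
            last_ppm, last_int = merged[-1]
            if ppm - last_ppm < merge_width:
                if abs(inten) > abs(last_int):
                    merged[-1] = (ppm, inten)
            else:
                merged.append((ppm, inten))
        peaks = merged
    return sorted(peaks, key=lambda p: p[0])
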