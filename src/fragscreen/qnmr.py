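"""Quantitative NMR: concentration from a 1D spectrum by best-fit proton counting.

Signal intensity per proton is proportional to concentration under fixed
acquisition parameters, so quantification reduces to finding H_T, the total
number of protons contributing to the area of interest (AOI, default
6-10 ppm — chosen to dodge DMSO/buffer interference in the aliphatic region).
H_T is bounded from the predicted spectrum, then best-fitted by requiring
that per-multiplet integrals, rescaled so they sum to a candidate H, land as
close to integers as possible (protons come in whole numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra import PredictedSpectrum, Region, Spectrum1D, integrate

__all__ = [
    "HTRange",
    "ReferenceStandard",
    "QuantResult",
    "ht_bounds",
    "best_fit_ht",
    "measure_concentration",
    "impurity_fraction",
    "qc_gate",
    "quantify_compound",
    "AOI",
    "INNER_WINDOW",
    "OUTER_WINDOW",
]

#: integration window avoiding aliphatic solvent/buffer interference
AOI = Region(6.0, 10.0)
#: window for the H_T lower bound: predicted aromatic shifts with <=1 ppm slack
INNER_WINDOW = Region(7.0, 9.0)
#: window for the H_T upper bound, catching exchangeables and 1 ppm deviation
OUTER_WINDOW = Region(5.0, 11.0)


@dataclass(frozen=True)
class HTRange:
    ht_min: int
    ht_max: int

    def __post_init__(self) -> None:
        if self.ht_min < 0 or self.ht_max < self.ht_min:
            raise ValueError(f"invalid H_T range ({self.ht_min}, {self.ht_max})")

    def candidates(self) -> range:
        return range(self.ht_min, self.ht_max + 1)


@dataclass(frozen=True)
class ReferenceStandard:
    """A pure, fully soluble compound of known concentration acquired under
    identical parameters; anchors the intensity-per-proton scale."""

    concentration: float  # mM
    intensity_per_proton: float

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.intensity_per_proton <= 0:
            raise ValueError("reference concentration and intensity must be positive")


@dataclass
class QuantResult:
    compound_id: str
    best_ht: int
    accuracy_curve: dict[int, float]
    intensity_per_proton: float
    concentration: float  # mM
    impurity_fraction: float
    qc_pass: bool = False
    qc_reasons: list[str] = field(default_factory=list)


def ht_bounds(
    predicted: PredictedSpectrum,
    inner: Region = INNER_WINDOW,
    outer: Region = OUTER_WINDOW,
    clamp_min: bool = True,
) -> HTRange:
    """Bound H_T from the predicted multiplet list.

    Lower bound: non-exchangeable protons whose multiplet center lies in the
    inner window (where a predicted aromatic shift stays even under ~1 ppm
    prediction error). Upper bound: all protons, exchangeables included, with
    centers in the outer window. A compound with signal only outside the
    inner window still needs >= 1 observable proton, hence the clamp.
    """
    if not (outer.low <= inner.low and inner.high <= outer.high):
        raise ValueError("inner window must lie within the outer window")
    ht_min = sum(
        m.n_protons or 1
        for m in predicted.multiplets
        if not m.exchangeable and inner.contains(m.center)
    )
    ht_max = sum(m.n_protons or 1 for m in predicted.multiplets if outer.contains(m.center))
    if ht_max == 0:
        raise ValueError(
            f"{predicted.compound_id}: no observable protons in the AOI window "
            f"[{outer.low}, {outer.high}] ppm"
        )
    if clamp_min and ht_min < 1:
        ht_min = 1
    return HTRange(ht_min=ht_min, ht_max=ht_max)


def best_fit_ht(
    spectrum: Spectrum1D,
    peak_regions: Sequence[Region],
    bounds: HTRange,
    aoi: Region = AOI,
) -> tuple[int, dict[int, float]]:
    """Best-fit H_T by the integration-accuracy criterion.

    For each candidate H the per-region integrals are rescaled so their sum
    equals H; the cost is the RMS deviation of the rescaled integrals from
    their nearest integers. Ties break to the smallest H (the conservative
    concentration estimate). Returns (best H, full accuracy curve).
    """
    regs = sorted(peak_regions, key=lambda r: r.low)
    for a, b in zip(regs, regs[1:]):
        if a.high > b.low:
            raise ValueError("peak regions must be non-overlapping")
    for r in regs:
        if r.low < aoi.low or r.high > aoi.high:
            raise ValueError(f"peak region [{r.low}, {r.high}] outside the AOI")
    if not regs:
        raise ValueError("at least one peak region is required")
    raw = np.array([integrate(spectrum, r) for r in regs])
    total = raw.sum()
    if total <= 0:
        raise ValueError("no signal: total AOI integral is non-positive")
    curve: dict[int, float] = {}
    for h in bounds.candidates():
        scaled = raw * (h / total)
        curve[h] = float(np.sqrt(np.mean((scaled - np.round(scaled)) ** 2)))
    best = min(curve, key=lambda h: (curve[h], h))
    return best, curve


def measure_concentration(
    spectrum: Spectrum1D,
    best_ht: int,
    aoi: Region,
    ref: ReferenceStandard,
) -> tuple[float, float]:
    """Concentration (mM) from intensity-per-proton against the reference.

    Returns (concentration, intensity_per_proton).
    """
    if best_ht < 1:
        raise ValueError("best_ht must be >= 1")
    area = integrate(spectrum, aoi)
    if area <= 0:
        raise ValueError("non-positive AOI integral")
    ipp = area / best_ht
    return ref.concentration * ipp / ref.intensity_per_proton, ipp


def impurity_fraction(
    spectrum: Spectrum1D,
    peak_regions: Sequence[Region],
    aoi: Region = AOI,
) -> float:
    """Share of AOI integrated area lying outside all predicted peak regions.

    A concrete stand-in for visual impurity inspection: signal where the
    structure predicts none is attributed to impurities. Clipped to [0, 1]
    (noise can push either integral slightly past the other).
    """
    total = integrate(spectrum, aoi)
    if total <= 0:
        raise ValueError("non-positive AOI integral")
    inside = sum(
        integrate(spectrum, Region(max(r.low, aoi.low), min(r.high, aoi.high)))
        for r in peak_regions
        if r.high > aoi.low and r.low < aoi.high
    )
    return float(min(1.0, max(0.0, 1.0 - inside / total)))


def qc_gate(
    result: QuantResult,
    min_conc: float = 0.1,
    max_impurity: float = 0.15,
) -> QuantResult:
    """Apply library-entry QC: measured solubility and impurity share.

    Pass requires concentration >= 0.1 mM (enough sensitivity for screening
    and the downstream affinity assay) and impurity fraction strictly below
    15%. Reasons enumerate each violated gate; the result is updated in place
    and returned.
    """
    reasons = []
    if result.concentration < min_conc:
        reasons.append("low solubility")
    if result.impurity_fraction >= max_impurity:
        reasons.append("impurity")
    result.qc_pass = not reasons
    result.qc_reasons = reasons
    return result


def _merge_regions(regions: list[Region]) -> list[Region]:
    regions = sorted(regions, key=lambda r: r.low)
    merged = [regions[0]]
    for r in regions[1:]:
        if r.low <= merged[-1].high:
            merged[-1] = Region(merged[-1].low, max(merged[-1].high, r.high))
        else:
            merged.append(r)
    return merged


def predicted_peak_regions(
    predicted: PredictedSpectrum, aoi: Region = AOI, pad: float = 0.0
) -> list[Region]:
    """Disjoint integration regions from predicted multiplet ranges in the AOI."""
    regs = []
    for m in predicted.multiplets:
        lo, hi = max(m.low - pad, aoi.low), min(m.high + pad, aoi.high)
        if hi > lo:
            regs.append(Region(lo, hi))
    if not regs:
        raise ValueError(f"{predicted.compound_id}: no predicted multiplets in the AOI")
    return _merge_regions(regs)


def quantify_compound(
    spectrum: Spectrum1D,
    predicted: PredictedSpectrum,
    ref: ReferenceStandard,
    aoi: Region = AOI,
    inner: Region = INNER_WINDOW,
    outer: Region = OUTER_WINDOW,
    min_conc: float = 0.1,
    max_impurity: float = 0.15,
    region_pad: float = 0.05,
) -> QuantResult:
    """End-to-end quantification of one compound: bounds, best fit, QC."""
    bounds = ht_bounds(predicted, inner, outer)
    regions = predicted_peak_regions(predicted, aoi, pad=region_pad)
    best, curve = best_fit_ht(spectrum, regions, bounds, aoi)
    conc, ipp = measure_concentration(spectrum, best, aoi, ref)
    imp = impurity_fraction(spectrum, regions, aoi)
    result = QuantResult(
        compound_id=predicted.compound_id,
        best_ht=best,
        accuracy_curve=curve,
        intensity_per_proton=ipp,
        concentration=conc,
        impurity_fraction=imp,
    )
    return qc_gate(result, min_conc=min_conc, max_impurity=max_impurity)
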