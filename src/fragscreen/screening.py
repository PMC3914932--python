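"""Hit calling from cocktail STD + WaterLOGSY spectra, with secondary confirmation.

Ligand-observed screening acquires three 1D spectra per cocktail: a plain 1H
(WATERGATE) reference, STD (saturation transfer lights up binder protons) and
WaterLOGSY (water-mediated NOE inverts binder signals). A hit needs positive
evidence in BOTH STD and WaterLOGSY, assigned to a cocktail member by
matching the pattern of its reference aromatic peaks. Candidates from the
cocktail (primary) screen are confirmed by re-screening the compound alone:
aggregation artifacts produce cocktail-only signal and are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .spectra import Region, Spectrum1D, pick_peaks

__all__ = [
    "ReferencePeak",
    "ScreeningRecord",
    "HitCall",
    "HitReport",
    "QCResult",
    "negative_control_qc",
    "call_hits",
    "confirm_secondary",
    "AROMATIC_REGION",
]

AROMATIC_REGION = Region(6.0, 10.0)


@dataclass(frozen=True)
class ReferencePeak:
    """One peak of a member's reference 1H pattern (cocktail conditions)."""

    ppm: float
    degeneracy: int = 1  # proton count / multiplicity collapsed into the peak
    exchangeable: bool = False


@dataclass
class ScreeningRecord:
    """One database record: the three screening spectra for a cocktail plus
    the reference pattern of every member."""

    cocktail_id: str
    spectra: dict[str, Spectrum1D]  # keys: H1, STD, WLOGSY
    references: dict[str, list[ReferencePeak]]
    has_protein: bool = True

    def __post_init__(self) -> None:
        missing = {"H1", "STD", "WLOGSY"} - set(self.spectra)
        if missing:
            raise ValueError(f"{self.cocktail_id}: missing spectra {sorted(missing)}")
        if not self.references:
            raise ValueError(f"{self.cocktail_id}: empty references")


@dataclass
class HitCall:
    compound_id: str
    matched_peaks: list[tuple[float, float, float]]  # (ref ppm, STD ppm, WLOGSY ppm)
    evidence: dict[str, bool] = field(default_factory=dict)
    status: str = "candidate"  # candidate | confirmed | rejected

    def __post_init__(self) -> None:
        if self.status == "candidate" and not (
            self.evidence.get("std") and self.evidence.get("wlogsy")
        ):
            raise ValueError("candidate status requires both STD and WaterLOGSY evidence")


@dataclass
class HitReport:
    cocktail_id: str
    hits: list[HitCall]
    unassigned_peaks: list[float] = field(default_factory=list)
    ambiguous: list[tuple[float, list[str]]] = field(default_factory=list)


@dataclass
class QCResult:
    cocktail_id: str
    clean: bool
    reasons: list[str] = field(default_factory=list)


#: minimum credible peak width (ppm) — half a typical linewidth; discards
#: single-sample noise excursions that clear the intensity threshold
MIN_PEAK_WIDTH = 0.01


def _wlogsy_peaks(
    spectrum: Spectrum1D, region: Region, k_noise: float, min_width: float
) -> list[tuple[float, float]]:
    """WaterLOGSY peaks of either sign (binder signals are sign-inverted)."""
    pos = pick_peaks(spectrum, region, k_noise, min_width=min_width)
    neg = pick_peaks(spectrum, region, k_noise, negative=True, min_width=min_width)
    return sorted(pos + neg, key=lambda p: p[0])


def negative_control_qc(
    record: ScreeningRecord,
    aromatic: Region = AROMATIC_REGION,
    k_noise: float = 3.0,
    tol: float = 0.15,
    min_peak_width: float = MIN_PEAK_WIDTH,
) -> QCResult:
    """QC a protein-free control record.

    Without protein, STD should be empty (aromatic STD signal indicates
    compound aggregation or cancellation artifacts) and WaterLOGSY peaks
    should share one sign except for exchangeable protons. Flagged records
    enumerate the offending ppm values.
    """
    if record.has_protein:
        raise ValueError("negative-control QC applies to protein-free records")
    reasons: list[str] = []
    std_peaks = pick_peaks(record.spectra["STD"], aromatic, k_noise, min_width=min_peak_width)
    if std_peaks:
        ppms = ", ".join(f"{p:.2f}" for p, _ in std_peaks)
        reasons.append(f"aggregation suspect: STD aromatic peaks at {ppms} ppm")
    exchangeable_ppms = [
        p.ppm for refs in record.references.values() for p in refs if p.exchangeable
    ]
    inverted = pick_peaks(
        record.spectra["WLOGSY"], aromatic, k_noise, negative=True, min_width=min_peak_width
    )
    offending = [
        ppm
        for ppm, _ in inverted
        if not any(abs(ppm - e) <= tol for e in exchangeable_ppms)
    ]
    if offending:
        ppms = ", ".join(f"{p:.2f}" for p in offending)
        reasons.append(f"sign-inverted non-exchangeable WaterLOGSY peaks at {ppms} ppm")
    return QCResult(record.cocktail_id, clean=not reasons, reasons=reasons)


def call_hits(
    record: ScreeningRecord,
    tol: float = 0.15,
    k_noise: float = 3.0,
    aoi: Region = AROMATIC_REGION,
    quorum: float = 0.5,
    min_peak_width: float = MIN_PEAK_WIDTH,
) -> HitReport:
    """Dual-evidence hit calling on one protein-present record.

    STD peaks in the AOI are picked first, kept only when a WaterLOGSY peak
    lies within ``tol`` ppm (WaterLOGSY-only peaks arise from direct
    water-ligand interaction and are ignored), then assigned to the member
    whose reference pattern has a peak within ``tol``. A member becomes a
    candidate hit when at least ceil(quorum x its reference aromatic peak
    count) peaks match — pattern-based assignment rather than a single-peak
    match. Peaks matching no member are reported unassigned; peaks matching
    several members are ambiguous and not auto-called.
    """
    if not record.references:
        raise ValueError("empty references")
    std_peaks = pick_peaks(record.spectra["STD"], aoi, k_noise, min_width=min_peak_width)
    wl_peaks = _wlogsy_peaks(record.spectra["WLOGSY"], aoi, k_noise, min_peak_width)
    confirmed: list[tuple[float, float]] = []  # (std ppm, wlogsy ppm)
    for sp, _ in std_peaks:
        near = [wp for wp, _ in wl_peaks if abs(wp - sp) <= tol]
        if near:
            confirmed.append((sp, min(near, key=lambda wp: abs(wp - sp))))

    matches: dict[str, list[tuple[float, float, float]]] = {}
    unassigned: list[float] = []
    ambiguous: list[tuple[float, list[str]]] = []
    for sp, wp in confirmed:
        owners: list[tuple[str, float]] = []
        for member, refs in record.references.items():
            aromatic_refs = [p.ppm for p in refs if aoi.contains(p.ppm)]
            close = [rp for rp in aromatic_refs if abs(rp - sp) <= tol]
            if close:
                owners.append((member, min(close, key=lambda rp: abs(rp - sp))))
        if not owners:
            unassigned.append(sp)
        elif len(owners) > 1:
            ambiguous.append((sp, [m for m, _ in owners]))
        else:
            member, rp = owners[0]
            matches.setdefault(member, []).append((rp, sp, wp))

    hits: list[HitCall] = []
    for member, matched in matches.items():
        n_ref = sum(1 for p in record.references[member] if aoi.contains(p.ppm))
        needed = max(1, math.ceil(quorum * n_ref))
        if len({rp for rp, _, _ in matched}) >= needed:
            hits.append(
                HitCall(
                    compound_id=member,
                    matched_peaks=sorted(matched),
                    evidence={"std": True, "wlogsy": True},
                )
            )
    hits.sort(key=lambda h: h.compound_id)
    return HitReport(record.cocktail_id, hits, unassigned, ambiguous)


def confirm_secondary(
    candidate: HitCall,
    individual_record: ScreeningRecord,
    tol: float = 0.15,
    k_noise: float = 3.0,
    aoi: Region = AROMATIC_REGION,
    quorum: float = 0.5,
    min_peak_width: float = MIN_PEAK_WIDTH,
) -> HitCall:
    """Secondary screening of a candidate on its single-compound record.

    Confirmed iff re-calling hits on the individual record reproduces the
    candidate's matched peaks (same shifts within tol, both evidences);
    cocktail-only signal (aggregation, cancellation artifacts) is rejected.
    """
    if candidate.compound_id not in individual_record.references:
        raise ValueError(
            f"secondary record does not cover compound {candidate.compound_id}"
        )
    if len(individual_record.references) != 1:
        raise ValueError("secondary record must contain a single compound")
    report = call_hits(
        individual_record,
        tol=tol,
        k_noise=k_noise,
        aoi=aoi,
        quorum=quorum,
        min_peak_width=min_peak_width,
    )
    secondary = next(
        (h for h in report.hits if h.compound_id == candidate.compound_id), None
    )
    status = "rejected"
    if secondary is not None:
        sec_std = [sp for _, sp, _ in secondary.matched_peaks]
        reproduced = all(
            any(abs(sp - sp2) <= tol for sp2 in sec_std)
            for _, sp, _ in candidate.matched_peaks
        )
        if reproduced:
            status = "confirmed"
    return HitCall(
        compound_id=candidate.compound_id,
        matched_peaks=candidate.matched_peaks,
        evidence=candidate.evidence,
        status=status,
    )
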