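"""Cocktail design: pairwise spectral dispersity and greedy grouping.

Screening throughput comes from mixing compounds into cocktails, but mixture
spectra must stay interpretable: every pair of compounds in one cocktail
needs mostly non-overlapping aromatic multiplets so a hit can be assigned
without deconvolution. The pairwise dispersity D(i,k) is the larger, over the
two compounds, of the fraction of its multiplet ranges that intersect any
range of the other; pairs are admissible when D is strictly below the
threshold (default 0.5 — at least half of either compound's peaks stay
distinct).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "RangeSet",
    "Cocktail",
    "RackLayout",
    "dispersity",
    "group_compounds",
    "rack_layout",
    "component_concentration",
    "audit_cocktail",
]


@dataclass(frozen=True)
class RangeSet:
    """Per-compound multiplet chemical-shift ranges within the AOI."""

    compound_id: str
    ranges: tuple[tuple[float, float], ...]

    def __init__(self, compound_id: str, ranges: Sequence[tuple[float, float]]):
        if not ranges:
            raise ValueError(f"{compound_id}: RangeSet must be non-empty")
        for lo, hi in ranges:
            if not lo < hi:
                raise ValueError(f"{compound_id}: range requires low < high, got ({lo}, {hi})")
        object.__setattr__(self, "compound_id", compound_id)
        object.__setattr__(self, "ranges", tuple((float(lo), float(hi)) for lo, hi in ranges))


@dataclass
class Cocktail:
    cocktail_id: str
    member_ids: list[str]
    well: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError(f"{self.cocktail_id}: duplicate member ids")


@dataclass
class RackLayout:
    """Mapping of 96-well rack positions (A1..H12) to cocktail ids."""

    plate_id: str
    wells: dict[str, str] = field(default_factory=dict)

    ROWS = string.ascii_uppercase[:8]
    COLS = range(1, 13)

    def __post_init__(self) -> None:
        valid = {f"{r}{c}" for r in self.ROWS for c in self.COLS}
        bad = set(self.wells) - valid
        if bad:
            raise ValueError(f"invalid well labels: {sorted(bad)}")
        if len(self.wells) > 96:
            raise ValueError("more than 96 wells on one plate")


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    # touching endpoints carry zero integral and do not count as overlap
    return min(a[1], b[1]) > max(a[0], b[0])


def dispersity(a: RangeSet, b: RangeSet) -> float:
    """Pairwise dispersity D(i,k) in [0, 1].

    For each compound, count its multiplets whose range has a positive-length
    intersection with any multiplet range of the other compound; D is the
    larger of the two overlapped fractions. D=0 means fully disjoint spectra,
    D=1 means every multiplet of at least one compound is overlapped; D=0.5
    means at least half of either compound's peaks remain distinct.
    """
    o_a = sum(1 for ra in a.ranges if any(_overlaps(ra, rb) for rb in b.ranges))
    o_b = sum(1 for rb in b.ranges if any(_overlaps(rb, ra) for ra in a.ranges))
    return max(o_a / len(a.ranges), o_b / len(b.ranges))


def _fits(candidate: RangeSet, members: list[RangeSet], threshold: float) -> bool:
    return all(dispersity(candidate, m) < threshold for m in members)


def group_compounds(
    range_sets: Sequence[RangeSet],
    M: int = 10,
    threshold: float = 0.5,
    max_groups: int | None = None,
) -> tuple[list[Cocktail], list[str]]:
    """Greedy sequential grouping with forward swap.

    Compounds are taken in input order into the current group while their
    dispersity against every existing member is strictly below the threshold.
    When the next compound conflicts, the not-yet-placed compounds further
    down the list are scanned for one that fits, and that compound is swapped
    into the current slot (the conflicting compound waits for a later group).
    Compounds compatible with no existing group seed a new one; with a
    ``max_groups`` cap, leftovers are returned unassigned rather than
    silently dropped.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    pending: list[RangeSet] = list(range_sets)
    cocktails: list[Cocktail] = []
    while pending and (max_groups is None or len(cocktails) < max_groups):
        members: list[RangeSet] = [pending.pop(0)]
        i = 0
        while len(members) < M and i < len(pending):
            if _fits(pending[i], members, threshold):
                members.append(pending.pop(i))
            else:
                i += 1  # conflicting compound stays pending; scan onward (swap)
        cocktails.append(
            Cocktail(
                cocktail_id=f"C{len(cocktails) + 1:03d}",
                member_ids=[m.compound_id for m in members],
            )
        )
    return cocktails, [r.compound_id for r in pending]


def audit_cocktail(
    cocktail: Cocktail, range_sets: dict[str, RangeSet], threshold: float = 0.5
) -> bool:
    """Post-hoc check that every member pair satisfies D < threshold."""
    members = [range_sets[m] for m in cocktail.member_ids]
    return all(
        dispersity(a, b) < threshold
        for i, a in enumerate(members)
        for b in members[i + 1 :]
    )


def rack_layout(cocktails: Sequence[Cocktail], plate_capacity: int = 96) -> list[RackLayout]:
    """Row-major 96-well layout (A1, A2, ... H12); overflow starts a new plate."""
    labels = [f"{r}{c}" for r in RackLayout.ROWS for c in RackLayout.COLS][:plate_capacity]
    plates: list[RackLayout] = []
    for i, cocktail in enumerate(cocktails):
        plate_idx, well_idx = divmod(i, len(labels))
        if plate_idx >= len(plates):
            plates.append(RackLayout(plate_id=f"P{plate_idx + 1}"))
        well = labels[well_idx]
        plates[plate_idx].wells[well] = cocktail.cocktail_id
        cocktail.well = f"{plates[plate_idx].plate_id}:{well}"
    return plates


def component_concentration(stock_mM: float, n_components: int) -> float:
    """Per-component concentration after an equal-volume mix of n stocks.

    Ten 200 mM DMSO stocks mixed in equal volumes give 20 mM per component.
    """
    if stock_mM <= 0 or n_components < 1:
        raise ValueError("stock concentration must be positive and n_components >= 1")
    return stock_mM / n_components
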