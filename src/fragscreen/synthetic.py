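"""Seeded synthetic fixtures emulating every input the screening pipeline consumes.

No public dataset accompanies this kind of screening campaign, so the whole
workflow is exercised on synthetic data with known ground truth: compound
property tables straddling every library-filter bound, fingerprints with
planted near-duplicates, predicted multiplet lists, 1D screening spectra with
planted binders and aggregation artifacts, and HSQC titration series forward-
modeled from a known Kd. Every generator is a pure function of its arguments
and seed. Truth tables ship with each fixture so end-to-end tests can score
sensitivity and specificity without manual annotation.

These fixtures emulate observable signatures (Lorentzian multiplets,
co-located STD/WaterLOGSY signal, fast-exchange shift averaging), not spin
physics: there is no NOE buildup, relaxation or saturation-transfer kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cocktails import RangeSet
from .library import Fingerprint
from .screening import ReferencePeak, ScreeningRecord
from .spectra import Multiplet, PredictedSpectrum, Region, Spectrum1D, estimate_noise, synthesize_spectrum
from .titration import CSPCurve, IntensityTitration, bound_fraction

__all__ = [
    "CampaignSpec",
    "make_compound_set",
    "make_range_sets",
    "make_screening_campaign",
    "make_quant_fixture",
    "make_titration",
    "make_intensity_titration",
    "ScreeningCampaign",
]

#: titration design used throughout: ligand:protein molar ratios
DEFAULT_RATIOS = (0.1, 0.25, 0.5, 1.0, 2.0, 5.0)


@dataclass(frozen=True)
class CampaignSpec:
    """Study conditions of one synthetic screening campaign.

    Defaults mirror a realistic campaign: ~1000 candidate compounds, ten per
    cocktail, a hit rate under 10% (PPI targets sit well below that), a small
    aggregation-artifact rate, and 2% spectral noise relative to planted peak
    height.
    """

    n_compounds: int = 1008
    M: int = 10
    binder_fraction: float = 0.05
    artifact_fraction: float = 0.02
    duplicate_fraction: float = 0.05
    noise_frac: float = 0.02
    seed: int = 0
    protein_conc: float = 0.5  # mM, labeled protein in titrations
    true_kd: float = 0.11  # mM
    ratios: tuple[float, ...] = DEFAULT_RATIOS

    def __post_init__(self) -> None:
        for name in ("binder_fraction", "artifact_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# compound set: property table + fingerprints + predicted spectra


def _random_fingerprint(rng: np.random.Generator, n_on: int = 80, n_bits: int = 1024) -> Fingerprint:
    return Fingerprint(bits=frozenset(rng.choice(n_bits, size=n_on, replace=False).tolist()))


def _near_duplicate(rng: np.random.Generator, fp: Fingerprint, n_swap: int = 4) -> Fingerprint:
    """Perturb a fingerprint by swapping n_swap bits; Tanimoto stays > 0.8."""
    bits = list(fp.bits)
    rng.shuffle(bits)
    kept = set(bits[n_swap:])
    off = [b for b in range(fp.n_bits) if b not in fp.bits]
    kept.update(rng.choice(off, size=n_swap, replace=False).tolist())
    return Fingerprint(bits=frozenset(kept), n_bits=fp.n_bits)


def _random_predicted(rng: np.random.Generator, compound_id: str) -> PredictedSpectrum:
    """Random aromatic-region multiplet list with known proton counts."""
    n_mult = int(rng.integers(2, 5))
    centers = np.sort(rng.uniform(6.2, 9.8, size=n_mult))
    mults = []
    for c in centers:
        half = rng.uniform(0.02, 0.08)
        n_h = int(rng.integers(1, 4))
        exch = bool(rng.random() < 0.1)
        mults.append(
            Multiplet(center=float(c), low=float(c - half), high=float(c + half),
                      n_protons=n_h, exchangeable=exch)
        )
    return PredictedSpectrum(compound_id, mults)


def make_compound_set(
    spec: CampaignSpec,
) -> tuple[pd.DataFrame, dict[str, Fingerprint], dict[str, PredictedSpectrum], pd.DataFrame]:
    """Synthetic vendor catalog: properties, fingerprints, predicted spectra.

    Properties are drawn from ranges straddling every Rule-of-Three bound so
    the filter is exercised on both sides. A ``duplicate_fraction`` of
    compounds are near-copies (Tanimoto > 0.8) of an earlier compound, to be
    caught by the diversity gate. Returns (table, fingerprints, predicted
    spectra, truth table with a duplicate_of column).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    ids = [f"F{i + 1:04d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "compound_id": ids,
            "smiles": ["" for _ in ids],
            "mw": rng.uniform(95, 375, n).round(1),
            "clogp": rng.uniform(-1.0, 4.0, n).round(2),
            "n_rot": rng.integers(0, 6, n),
            "hbd": rng.integers(0, 6, n),
            "hba": rng.integers(0, 6, n),
            "tpsa": rng.uniform(20, 130, n).round(1),
            "logsw": rng.uniform(-6.0, -1.0, n).round(2),
            "n_aromatic_h": rng.integers(0, 7, n),
        }
    )
    fingerprints = {cid: _random_fingerprint(rng) for cid in ids}
    duplicate_of = [""] * n
    n_dup = int(round(spec.duplicate_fraction * n))
    if n_dup and n > 1:
        targets = rng.choice(np.arange(1, n), size=n_dup, replace=False)
        for j in targets:
            src = int(rng.integers(0, j))
            fingerprints[ids[j]] = _near_duplicate(rng, fingerprints[ids[src]])
            duplicate_of[j] = ids[src]
    predicted = {cid: _random_predicted(rng, cid) for cid in ids}
    truth = pd.DataFrame({"compound_id": ids, "duplicate_of": duplicate_of})
    return table, fingerprints, predicted, truth


# ---------------------------------------------------------------------------
# cocktail-design fixture


def make_range_sets(
    n: int = 893,
    M: int = 10,
    seed: int = 0,
    aoi: Region = Region(6.0, 10.0),
) -> list[RangeSet]:
    """Random aromatic multiplet ranges admitting a valid grouping at M per group.

    The AOI is partitioned into M disjoint blocks and the compound at
    position p within each cohort of M draws its 2-5 multiplet ranges inside
    block p, so consecutive cohorts are mutually dispersed by construction
    (a valid grouping exists) while compounds from different cohorts reuse
    the same blocks and overlap freely.
    """
    rng = np.random.default_rng(seed)
    block_w = aoi.width / M
    out = []
    for i in range(n):
        p = i % M
        lo_block = aoi.low + p * block_w
        k = int(rng.integers(2, 6))
        ranges = []
        for _ in range(k):
            width = rng.uniform(0.02, 0.06)
            lo = rng.uniform(lo_block + 0.01, lo_block + block_w - width - 0.01)
            ranges.append((float(lo), float(lo + width)))
        out.append(RangeSet(compound_id=f"F{i + 1:04d}", ranges=ranges))
    return out


# ---------------------------------------------------------------------------
# screening campaign with planted binders and artifacts


@dataclass
class ScreeningCampaign:
    records: list[ScreeningRecord]
    secondary: dict[str, ScreeningRecord]
    truth: pd.DataFrame = field(repr=False)


_AXIS = Region(5.5, 10.8)
_QUIET = Region(10.45, 10.75)
_LINEWIDTH = 0.02
_N_POINTS = 4096


def _peaks_to_multiplets(peaks: list[ReferencePeak], shift: float = 0.0) -> list[Multiplet]:
    half = _LINEWIDTH  # narrow range: peaks are synthesized as single lines
    return [
        Multiplet(
            center=p.ppm + shift,
            low=p.ppm + shift - half,
            high=p.ppm + shift + half,
            n_protons=p.degeneracy,
        )
        for p in peaks
    ]


def _finish(spectrum: Spectrum1D) -> Spectrum1D:
    estimate_noise(spectrum, _QUIET)
    spectrum.noise_sd = max(spectrum.noise_sd, 1e-9)
    return spectrum


def _synth(mults, scale, noise_sd, seed, experiment, sign=1.0) -> Spectrum1D:
    return _finish(
        synthesize_spectrum(
            mults,
            scale=scale,
            linewidth=_LINEWIDTH,
            axis=_AXIS,
            n_points=_N_POINTS,
            noise_sd=noise_sd,
            seed=seed,
            experiment=experiment,
            sign=sign,
        )
    )


def make_screening_campaign(
    n_cocktails: int = 50,
    M: int = 10,
    binder_fraction: float = 0.05,
    artifact_fraction: float = 0.02,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> ScreeningCampaign:
    """Cocktail screening records with planted binders and aggregation artifacts.

    Each cocktail holds M members with reference aromatic peaks confined to
    disjoint ppm blocks (assignment is unambiguous by construction, as a
    dispersity-designed cocktail guarantees). Binders produce co-located STD
    and (sign-inverted) WaterLOGSY signal, buffer-shifted by up to 0.08 ppm
    from the reference, in both the cocktail record and their individual
    secondary record. Artifacts produce the same cocktail signal but a flat
    secondary record — the signature of aggregation. ``noise_frac`` sets the
    Gaussian noise as a fraction of planted peak height.
    """
    rng = np.random.default_rng(seed)
    aoi = Region(6.0, 10.0)
    block_w = aoi.width / M
    scale = 1.0
    peak_height = scale * 2.0 / (np.pi * _LINEWIDTH)  # height of a 1H line
    noise_sd = noise_frac * peak_height

    records: list[ScreeningRecord] = []
    secondary: dict[str, ScreeningRecord] = {}
    truth_rows = []
    for c in range(n_cocktails):
        cid = f"C{c + 1:03d}"
        references: dict[str, list[ReferencePeak]] = {}
        roles: dict[str, str] = {}
        for p in range(M):
            member = f"F{c * M + p + 1:04d}"
            lo = aoi.low + p * block_w
            # reference peaks confined to the middle of the block so that a
            # buffer shift (<=0.08 ppm) plus matching tolerance (0.15 ppm)
            # cannot reach a neighbour's peaks
            n_pk = int(rng.integers(1, 3))
            positions = np.sort(rng.uniform(lo + 0.16, lo + 0.24, size=n_pk))
            while n_pk == 2 and positions[1] - positions[0] < 3 * _LINEWIDTH:
                positions = np.sort(rng.uniform(lo + 0.16, lo + 0.24, size=n_pk))
            references[member] = [
                ReferencePeak(ppm=float(x), degeneracy=int(rng.integers(1, 4)))
                for x in positions
            ]
            u = rng.random()
            roles[member] = (
                "binder"
                if u < binder_fraction
                else "artifact"
                if u < binder_fraction + artifact_fraction
                else "inactive"
            )
            truth_rows.append({"compound_id": member, "cocktail_id": cid, "role": roles[member]})

        h1_mults = [m for refs in references.values() for m in _peaks_to_multiplets(refs)]
        shifts = {m: float(rng.uniform(-0.08, 0.08)) for m in references}
        active = [m for m, r in roles.items() if r != "inactive"]
        active_mults = [
            m for member in active for m in _peaks_to_multiplets(references[member], shifts[member])
        ]
        base = int(rng.integers(0, 2**31 - 4))
        records.append(
            ScreeningRecord(
                cocktail_id=cid,
                spectra={
                    "H1": _synth(h1_mults, scale, noise_sd, base, "H1"),
                    "STD": _synth(active_mults, scale * 0.3, noise_sd * 0.3, base + 1, "STD"),
                    "WLOGSY": _synth(active_mults, scale * 0.5, noise_sd * 0.5, base + 2, "WLOGSY", sign=-1.0),
                },
                references=references,
                has_protein=True,
            )
        )
        for member in active:
            sec_refs = {member: references[member]}
            own = _peaks_to_multiplets(references[member], shifts[member])
            sec_base = int(rng.integers(0, 2**31 - 4))
            if roles[member] == "binder":
                std = _synth(own, scale * 0.3, noise_sd * 0.3, sec_base + 1, "STD")
                wl = _synth(own, scale * 0.5, noise_sd * 0.5, sec_base + 2, "WLOGSY", sign=-1.0)
            else:  # aggregation artifact: no signal once screened alone
                std = _synth([], scale * 0.3, noise_sd * 0.3, sec_base + 1, "STD")
                wl = _synth([], scale * 0.5, noise_sd * 0.5, sec_base + 2, "WLOGSY")
            secondary[member] = ScreeningRecord(
                cocktail_id=f"{cid}:{member}",
                spectra={
                    "H1": _synth(_peaks_to_multiplets(references[member]), scale, noise_sd, sec_base, "H1"),
                    "STD": std,
                    "WLOGSY": wl,
                },
                references=sec_refs,
                has_protein=True,
            )
    return ScreeningCampaign(records, secondary, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# quantification fixture


def make_quant_fixture(
    seed: int = 0,
    noise_frac: float = 0.05,
    scale: float = 1.0,
) -> tuple[Spectrum1D, PredictedSpectrum, int]:
    """One compound's 1D spectrum plus its predicted multiplets and true H_T.

    Multiplets carry integer proton counts with coprime region totals (a
    non-trivial best-fit problem: no smaller candidate reproduces integers),
    centers spread across the AOI with at least one inside the 7-9 ppm inner
    window. ``noise_frac`` is relative to the tallest planted line.
    """
    rng = np.random.default_rng(seed)
    while True:
        n_mult = int(rng.integers(2, 5))
        centers = 6.3 + np.sort(rng.choice(np.arange(0, 12), size=n_mult, replace=False)) * 0.29
        counts = rng.integers(1, 4, size=n_mult)
        if np.gcd.reduce(counts) == 1 and any(7.0 <= c <= 9.0 for c in centers):
            break
    mults = []
    for c, n_h in zip(centers, counts):
        half = rng.uniform(0.03, 0.08)
        mults.append(
            Multiplet(center=float(c), low=float(c - half), high=float(c + half), n_protons=int(n_h))
        )
    predicted = PredictedSpectrum(f"Q{seed}", mults)
    peak_height = scale * 2.0 / (np.pi * _LINEWIDTH)
    spectrum = synthesize_spectrum(
        mults,
        scale=scale,
        linewidth=_LINEWIDTH,
        axis=Region(4.0, 12.0),
        n_points=8192,
        noise_sd=noise_frac * peak_height,
        seed=seed,
    )
    return spectrum, predicted, int(counts.sum())


# ---------------------------------------------------------------------------
# titration fixtures


def make_titration(
    true_kd: float,
    protein_conc: float,
    ddmax: dict[str, float],
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> list[CSPCurve]:
    """CSP curves forward-modeled from the fast-exchange depletion model.

    ``noise_frac`` applies multiplicative Gaussian noise to each CSP value
    (shift-measurement error scales with the shift); values clamp at zero.
    """
    if not ratios:
        raise ValueError("ratios must be non-empty")
    rng = np.random.default_rng(seed)
    r = np.asarray(ratios, dtype=float)
    fb = bound_fraction(r, protein_conc, true_kd)
    curves = []
    for residue, amp in ddmax.items():
        dd = amp * fb
        if noise_frac > 0:
            dd = np.maximum(dd * (1.0 + rng.normal(0.0, noise_frac, size=len(r))), 0.0)
        curves.append(CSPCurve(residue=residue, points=list(zip(r.tolist(), dd.tolist()))))
    return curves


def make_intensity_titration(
    true_kd: float,
    protein_conc: float,
    ratios: tuple[float, ...] = (0.0, 0.1, 0.2, 0.4, 0.8, 1.0),
    n_residues: int = 13,
    noise_frac: float = 0.0,
    seed: int = 0,
    condition: str = "control",
) -> IntensityTitration:
    """Normalized intensity titration under the depletion model, f = 1 - fb.

    The ratio-0 anchor is exactly 1.0 per residue; later points carry
    additive Gaussian noise of sd ``noise_frac`` on the normalized scale.
    """
    rng = np.random.default_rng(seed)
    residues = [f"peak_{i + 1}" for i in range(n_residues)]
    points = []
    for r in ratios:
        if r == 0.0:
            points.append((0.0, {res: 1.0 for res in residues}))
            continue
        f = 1.0 - float(bound_fraction(r, protein_conc, true_kd))
        intens = {
            res: max(0.0, f + (rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0))
            for res in residues
        }
        points.append((float(r), intens))
    return IntensityTitration(condition=condition, points=points, noise_sd=noise_frac or None)
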