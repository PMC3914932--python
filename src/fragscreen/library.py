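"""Fragment library construction: extended Rule-of-Three filter + Tanimoto diversity gate.

Fragment libraries trade potency for coverage: small (110-350 Da), soluble,
conformationally simple compounds sample chemical space efficiently, and a
pairwise-similarity cap keeps the library diverse. Property thresholds follow
the extended Rule of Three (MW, clogP, rotatable bonds, H-bond donors and
acceptors, TPSA, predicted aqueous solubility), all bounds inclusive; the
diversity gate rejects a candidate whose maximum Tanimoto similarity to any
accepted member is strictly above the threshold (default 0.80).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CompoundRecord",
    "Fingerprint",
    "FilterReport",
    "RuleOfThreeThresholds",
    "rule_of_three_filter",
    "tanimoto",
    "diversity_gate",
    "build_library",
    "fingerprint_from_smiles",
    "records_from_table",
]


@dataclass(frozen=True)
class CompoundRecord:
    """Vendor-supplied physicochemical properties of one fragment."""

    compound_id: str
    smiles: str = ""
    mw: float | None = None  # Da
    clogp: float | None = None
    n_rot: int | None = None
    hbd: int | None = None
    hba: int | None = None
    tpsa: float | None = None  # A^2
    logsw: float | None = None  # log10(mol/L)
    n_aromatic_h: int | None = None

    def __post_init__(self) -> None:
        if self.mw is not None and self.mw <= 0:
            raise ValueError("mw must be positive")
        for name in ("n_rot", "hbd", "hba", "n_aromatic_h"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Fingerprint:
    """Hashed structural fingerprint as a set of on-bit indices."""

    bits: frozenset[int]
    n_bits: int = 1024

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(self.bits))
        if self.bits and not all(0 <= b < self.n_bits for b in self.bits):
            raise ValueError("bit index outside [0, n_bits)")


@dataclass
class FilterReport:
    compound_id: str
    passed: bool
    failed_rules: list[str] = field(default_factory=list)
    nearest_tanimoto: float | None = None

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_rules):
            raise ValueError("passed must be equivalent to failed_rules being empty")


@dataclass(frozen=True)
class RuleOfThreeThresholds:
    """Inclusive bounds of the extended Rule of Three.

    The aromatic-proton requirement is optional ("preferred") because it only
    matters when screening in protonated buffers where the aliphatic region
    is obscured.
    """

    mw_min: float = 110.0
    mw_max: float = 350.0
    clogp_max: float = 3.0
    n_rot_max: int = 3
    hbd_max: int = 3
    hba_max: int = 3
    tpsa_max: float = 110.0
    logsw_min: float = -4.5
    require_aromatic_h: bool = False


def rule_of_three_filter(
    record: CompoundRecord, thresholds: RuleOfThreeThresholds = RuleOfThreeThresholds()
) -> FilterReport:
    """Evaluate every extended Rule-of-Three bound on one compound.

    Failures are data, not exceptions: a missing property fails its rule with
    reason "<rule>:missing".
    """
    t = thresholds
    checks: list[tuple[str, float | int | None, bool]] = [
        ("mw", record.mw, record.mw is not None and t.mw_min <= record.mw <= t.mw_max),
        ("clogp", record.clogp, record.clogp is not None and record.clogp <= t.clogp_max),
        ("n_rot", record.n_rot, record.n_rot is not None and record.n_rot <= t.n_rot_max),
        ("hbd", record.hbd, record.hbd is not None and record.hbd <= t.hbd_max),
        ("hba", record.hba, record.hba is not None and record.hba <= t.hba_max),
        ("tpsa", record.tpsa, record.tpsa is not None and record.tpsa <= t.tpsa_max),
        ("logsw", record.logsw, record.logsw is not None and record.logsw >= t.logsw_min),
    ]
    if t.require_aromatic_h:
        checks.append(
            (
                "aromatic_h",
                record.n_aromatic_h,
                record.n_aromatic_h is not None and record.n_aromatic_h >= 1,
            )
        )
    failed = [
        name if value is not None else f"{name}:missing"
        for name, value, ok in checks
        if not ok
    ]
    return FilterReport(record.compound_id, passed=not failed, failed_rules=failed)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over fingerprint bit sets.

    Two empty fingerprints are defined maximally similar (1.0).
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint sizes differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def diversity_gate(
    candidate: Fingerprint,
    library: Sequence[Fingerprint],
    threshold: float = 0.80,
) -> tuple[bool, float | None]:
    """Accept a candidate unless it is too similar to an accepted member.

    Rejection requires max pairwise Tanimoto strictly above the threshold;
    a score exactly at the threshold is accepted. Empty library accepts with
    no score.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if not library:
        return True, None
    max_score = max(tanimoto(candidate, fp) for fp in library)
    return max_score <= threshold, max_score


def build_library(
    records: Sequence[CompoundRecord],
    fingerprints: dict[str, Fingerprint],
    thresholds: RuleOfThreeThresholds = RuleOfThreeThresholds(),
    tanimoto_threshold: float = 0.80,
) -> tuple[list[str], list[FilterReport]]:
    """Sequential property filter + greedy diversity gate over a candidate list.

    Order-dependent by design: candidates are gated in input order against
    the members accepted so far. Returns accepted ids and a report per input
    compound.
    """
    accepted: list[str] = []
    accepted_fps: list[Fingerprint] = []
    reports: list[FilterReport] = []
    for rec in records:
        report = rule_of_three_filter(rec, thresholds)
        if report.passed:
            fp = fingerprints.get(rec.compound_id)
            if fp is None:
                report = replace(
                    report, passed=False, failed_rules=["fingerprint:missing"]
                )
            else:
                ok, score = diversity_gate(fp, accepted_fps, tanimoto_threshold)
                report.nearest_tanimoto = score
                if ok:
                    accepted.append(rec.compound_id)
                    accepted_fps.append(fp)
                else:
                    report = replace(report, passed=False, failed_rules=["tanimoto"])
                    report.nearest_tanimoto = score
        reports.append(report)
    return accepted, reports


def fingerprint_from_smiles(smiles: str, n_bits: int = 1024) -> Fingerprint:
    """Path-based hashed fingerprint (RDKit topological, FP2-like) from SMILES.

    The structure engine is optional: precomputed fingerprints can be supplied
    to the gate directly, so rdkit is imported lazily.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "rdkit is required to compute fingerprints from SMILES; "
            "supply precomputed fingerprints instead"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    return Fingerprint(bits=frozenset(fp.GetOnBits()), n_bits=n_bits)


_TABLE_COLS = ("smiles", "mw", "clogp", "n_rot", "hbd", "hba", "tpsa", "logsw", "n_aromatic_h")


def records_from_table(df: pd.DataFrame) -> list[CompoundRecord]:
    """Build CompoundRecords from a vendor property table (CSV-loaded DataFrame)."""
    if "compound_id" not in df.columns:
        raise ValueError("table must have a compound_id column")
    records = []
    for row in df.to_dict("records"):
        kwargs = {}
        for col in _TABLE_COLS:
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if col in ("n_rot", "hbd", "hba", "n_aromatic_h"):
                v = int(v)
            elif col != "smiles":
                v = float(v)
            kwargs[col] = v
        records.append(CompoundRecord(compound_id=str(row["compound_id"]), **kwargs))
    return records
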