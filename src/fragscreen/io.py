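"""File formats: two-column spectrum CSV, JCAMP-DX, multiplet tables.

All formats are plain text. The spectrum CSV is ``ppm,intensity`` with one
header line. Multiplet lists travel as CSV with columns
``compound_id,center,low,high,n_protons,exchangeable,label`` (or a JSON
mirror keyed by compound).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .spectra import Multiplet, PredictedSpectrum, Spectrum1D

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcamp",
    "read_multiplets_csv",
    "write_multiplets_csv",
    "read_multiplets_json",
    "write_multiplets_json",
]


def read_spectrum_csv(path: str | Path, experiment: str = "H1") -> Spectrum1D:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum1D(
        ppm=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        experiment=experiment,
    )


def write_spectrum_csv(spectrum: Spectrum1D, path: str | Path) -> None:
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity}).to_csv(
        path, index=False
    )


def read_jcamp(path: str | Path, experiment: str = "H1") -> Spectrum1D:
    """Minimal JCAMP-DX reader: AFFN fixed-point ``(X++(Y..Y))`` XYDATA blocks.

    Supports FIRSTX/LASTX/NPOINTS/XFACTOR/YFACTOR headers as written by
    common 1D exporters. Compressed (SQZ/DIF/DUP) encodings are not handled.
    """
    text = Path(path).read_text()
    headers: dict[str, str] = {}
    for m in re.finditer(r"^##\$?([A-Z0-9 _/-]+)=\s*(.*)$", text, re.MULTILINE):
        headers[m.group(1).strip().upper()] = m.group(2).strip()
    m = re.search(r"##XYDATA=\s*\(X\+\+\(Y\.\.Y\)\)\s*\n(.*?)(?=##|\Z)", text, re.DOTALL)
    if m is None:
        raise ValueError(f"{path}: no (X++(Y..Y)) XYDATA block found")
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    ys: list[float] = []
    for line in m.group(1).strip().splitlines():
        vals = re.split(r"[\s,]+", line.strip())
        if not vals or vals == [""]:
            continue
        # first value on each line is the X of the first Y; remaining are Ys
        ys.extend(float(v) for v in vals[1:])
    n = int(headers.get("NPOINTS", len(ys)))
    if len(ys) != n:
        raise ValueError(f"{path}: NPOINTS={n} but {len(ys)} ordinates read")
    firstx = float(headers["FIRSTX"]) * xfactor
    lastx = float(headers["LASTX"]) * xfactor
    x = np.linspace(firstx, lastx, n)
    y = np.asarray(ys, dtype=float) * yfactor
    return Spectrum1D(ppm=x, intensity=y, experiment=experiment)


_MULTIPLET_COLS = ["compound_id", "center", "low", "high", "n_protons", "exchangeable", "label"]


def _rows_to_spectra(rows: Iterable[dict]) -> list[PredictedSpectrum]:
    by_compound: dict[str, list[Multiplet]] = {}
    for r in rows:
        n = r.get("n_protons")
        n_protons = None if n is None or (isinstance(n, float) and np.isnan(n)) else int(n)
        label = r.get("label", "") or ""
        if isinstance(label, float) and np.isnan(label):
            label = ""
        by_compound.setdefault(str(r["compound_id"]), []).append(
            Multiplet(
                center=float(r["center"]),
                low=float(r["low"]),
                high=float(r["high"]),
                n_protons=n_protons,
                exchangeable=bool(r.get("exchangeable", False)),
                label=str(label),
            )
        )
    return [PredictedSpectrum(cid, ms) for cid, ms in by_compound.items()]


def read_multiplets_csv(path: str | Path) -> list[PredictedSpectrum]:
    df = pd.read_csv(path)
    missing = {"compound_id", "center", "low", "high"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return _rows_to_spectra(df.to_dict("records"))


def write_multiplets_csv(spectra: Iterable[PredictedSpectrum], path: str | Path) -> None:
    rows = [
        {
            "compound_id": s.compound_id,
            "center": m.center,
            "low": m.low,
            "high": m.high,
            "n_protons": m.n_protons,
            "exchangeable": m.exchangeable,
            "label": m.label,
        }
        for s in spectra
        for m in s.multiplets
    ]
    pd.DataFrame(rows, columns=_MULTIPLET_COLS).to_csv(path, index=False)


def read_multiplets_json(path: str | Path) -> list[PredictedSpectrum]:
    data = json.loads(Path(path).read_text())
    out = []
    for cid, mults in data.items():
        out.extend(_rows_to_spectra([{**m, "compound_id": cid} for m in mults]))
    return out


def write_multiplets_json(spectra: Iterable[PredictedSpectrum], path: str | Path) -> None:
    data = {
        s.compound_id: [
            {
                "center": m.center,
                "low": m.low,
                "high": m.high,
                "n_protons": m.n_protons,
                "exchangeable": m.exchangeable,
                "label": m.label,
            }
            for m in s.multiplets
        ]
        for s in spectra
    }
    Path(path).write_text(json.dumps(data, indent=1))
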