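"""M-mode-derived cardiac functional parameters.

From tabulated left-ventricular measurements (internal diameters in
diastole and systole, heart rate, optionally long-axis length and areas)
this module computes fractional shortening (FS, %), end-diastolic and
end-systolic volumes (µl), ejection fraction (EF, %), stroke volume
(SV, µl) and cardiac output (CO, ml/min).

Volumes use the Teichholz cube-correction formula by default,
``V = 7 D^3 / (2.4 + D)`` with D in mm and V in µl — the standard M-mode
convention on small-animal instruments.  An area-length alternative,
``V = 8 A^2 / (3 π L)``, is available for records that carry a long-axis
endocardial area and LV length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CardiacRecord:
    """One mouse-day of M-mode measurements (diameters mm, HR bpm)."""

    mouse_id: str
    day: int
    lvidd_mm: float
    lvids_mm: float
    hr_bpm: float
    awthd_mm: float | None = None
    awths_mm: float | None = None
    pwthd_mm: float | None = None
    pwths_mm: float | None = None
    lv_length_mm: float | None = None
    endo_area_d_mm2: float | None = None
    endo_area_s_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.lvidd_mm <= 0:
            raise ValueError("diastolic diameter must be positive")
        if self.lvids_mm < 0:
            raise ValueError("systolic diameter must be non-negative")
        if self.lvids_mm > self.lvidd_mm:
            raise ValueError(
                f"LVIDs ({self.lvids_mm} mm) exceeds LVIDd ({self.lvidd_mm} mm)"
            )
        if self.hr_bpm <= 0:
            raise ValueError("heart rate must be positive")


@dataclass(frozen=True)
class CardiacParams:
    """Derived functional parameters of one record."""

    fs_pct: float
    edv_ul: float
    esv_ul: float
    sv_ul: float
    ef_pct: float
    co_ml_min: float


def fractional_shortening(record: CardiacRecord) -> float:
    """FS (%) = 100 (LVIDd - LVIDs) / LVIDd."""
    return 100.0 * (record.lvidd_mm - record.lvids_mm) / record.lvidd_mm


def teichholz_volume(diameter_mm: float) -> float:
    """LV volume (µl) from an M-mode internal diameter (mm): 7 D³ / (2.4 + D)."""
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    return 7.0 / (2.4 + diameter_mm) * diameter_mm**3


def area_length_volume(area_mm2: float, length_mm: float) -> float:
    """LV volume (µl) from a long-axis endocardial area and LV length."""
    if area_mm2 < 0 or length_mm <= 0:
        raise ValueError("area must be non-negative and length positive")
    return 8.0 * area_mm2**2 / (3.0 * np.pi * length_mm)


def _volumes(record: CardiacRecord, method: str) -> tuple[float, float]:
    if method == "teichholz":
        return teichholz_volume(record.lvidd_mm), teichholz_volume(record.lvids_mm)
    if method == "area_length":
        if None in (record.endo_area_d_mm2, record.endo_area_s_mm2, record.lv_length_mm):
            raise ValueError("area-length method needs endocardial areas and LV length")
        return (
            area_length_volume(record.endo_area_d_mm2, record.lv_length_mm),
            area_length_volume(record.endo_area_s_mm2, record.lv_length_mm),
        )
    raise ValueError(f"unknown volume method {method!r}")


def stroke_volume(record: CardiacRecord, method: str = "teichholz") -> float:
    """SV (µl) = EDV - ESV."""
    edv, esv = _volumes(record, method)
    return edv - esv


def ejection_fraction(record: CardiacRecord, method: str = "teichholz") -> float:
    """EF (%) = 100 (EDV - ESV) / EDV."""
    edv, esv = _volumes(record, method)
    return 100.0 * (edv - esv) / edv


def cardiac_output(record: CardiacRecord, method: str = "teichholz") -> float:
    """CO (ml/min) = SV (µl) x HR (bpm) / 1000."""
    return stroke_volume(record, method) * record.hr_bpm / 1000.0


def compute_params(record: CardiacRecord, method: str = "teichholz") -> CardiacParams:
    edv, esv = _volumes(record, method)
    sv = edv - esv
    return CardiacParams(
        fs_pct=fractional_shortening(record),
        edv_ul=edv,
        esv_ul=esv,
        sv_ul=sv,
        ef_pct=100.0 * sv / edv,
        co_ml_min=sv * record.hr_bpm / 1000.0,
    )


def params_table(records: pd.DataFrame, method: str = "teichholz") -> pd.DataFrame:
    """Per-row FS/EF/SV/CO for a cardiac measurement table.

    Expects columns ``mouse_id, day, lvidd_mm, lvids_mm, hr_bpm`` (plus the
    area-length columns when that method is selected); passes through
    ``group`` when present.
    """
    out = []
    for _, row in records.iterrows():
        rec = CardiacRecord(
            mouse_id=str(row["mouse_id"]),
            day=int(row["day"]),
            lvidd_mm=float(row["lvidd_mm"]),
            lvids_mm=float(row["lvids_mm"]),
            hr_bpm=float(row["hr_bpm"]),
            lv_length_mm=float(row["lv_length_mm"]) if "lv_length_mm" in row else None,
            endo_area_d_mm2=float(row["endo_area_d_mm2"]) if "endo_area_d_mm2" in row else None,
            endo_area_s_mm2=float(row["endo_area_s_mm2"]) if "endo_area_s_mm2" in row else None,
        )
        p = compute_params(rec, method=method)
        entry = {
            "mouse_id": rec.mouse_id,
            "day": rec.day,
            "fs": p.fs_pct,
            "ef": p.ef_pct,
            "sv": p.sv_ul,
            "co": p.co_ml_min,
        }
        if "group" in row:
            entry["group"] = row["group"]
        out.append(entry)
    return pd.DataFrame(out)
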