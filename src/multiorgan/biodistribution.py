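"""Ex vivo bioluminescence biodistribution: organ total flux and its change.

Total flux (photons/s) over an organ ROI is the sum of per-pixel radiance
times pixel area.  The study-level question is redistribution: in healthy
animals intravenously delivered cells are trapped in the lungs and die off
(flux decays everywhere between days 1 and 4), whereas with organ injury
the cells home to, and persist in, the injured liver and kidneys (flux
rises there).  Quantification is ex vivo only; whole-body in vivo images
lack the spatial resolution to assign flux to organs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ORGANS = ("heart", "lungs", "spleen", "liver", "kidney")


def total_flux(image: np.ndarray, mask: np.ndarray, pixel_area: float = 1.0) -> float:
    """Summed flux (photons/s) over the masked pixels of a radiance image."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image {image.shape}")
    if not mask.any():
        raise ValueError("organ mask is empty")
    if np.any(image[mask] < 0):
        raise ValueError("radiance must be non-negative")
    return float(image[mask].sum() * pixel_area)


def merge_kidneys(records: pd.DataFrame) -> pd.DataFrame:
    """Replace ``kidney_left``/``kidney_right`` rows by their per-mouse mean."""
    lr = records[records["organ"].isin(["kidney_left", "kidney_right"])]
    if lr.empty:
        return records
    keep = records[~records["organ"].isin(["kidney_left", "kidney_right"])]
    cols = [c for c in ("mouse_id", "group", "day") if c in records.columns]
    merged = lr.groupby(cols, as_index=False)["total_flux"].mean()
    merged["organ"] = "kidney"
    return pd.concat([keep, merged], ignore_index=True)[records.columns.tolist()]


def flux_change_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per organ and group: day-1 and day-4 mean flux and the change direction.

    Expects long-format rows ``mouse_id, group, day, organ, total_flux`` with
    days 1 and 4.  Missing (group, organ, day) cells are reported with NaN
    means rather than imputed; group-level significance testing is left to
    the statistics layer.
    """
    required = {"mouse_id", "group", "day", "organ", "total_flux"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"flux table lacks columns: {sorted(missing)}")
    if (records["total_flux"] < 0).any():
        raise ValueError("total flux must be non-negative")
    rows = []
    for (group, organ), sub in records.groupby(["group", "organ"], sort=True):
        d1 = sub.loc[sub["day"] == 1, "total_flux"]
        d4 = sub.loc[sub["day"] == 4, "total_flux"]
        m1 = d1.mean() if len(d1) else np.nan
        m4 = d4.mean() if len(d4) else np.nan
        if np.isnan(m1) or np.isnan(m4):
            direction = "missing"
        elif m4 > m1:
            direction = "increase"
        elif m4 < m1:
            direction = "decrease"
        else:
            direction = "unchanged"
        rows.append(
            {
                "group": group,
                "organ": organ,
                "day1_mean_flux": m1,
                "day4_mean_flux": m4,
                "n_day1": int(len(d1)),
                "n_day4": int(len(d4)),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
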