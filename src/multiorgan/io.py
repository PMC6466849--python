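"""Containers and file IO for multispectral stacks, component maps and ROI masks.

On disk a stack is a multi-frame TIFF (pages ordered frame-major, i.e. all
wavelengths of frame 0, then frame 1, ...) plus a CSV sidecar with one row
per page: ``frame_index, wavelength_nm, time_s``.  Component maps use the
same layout with a ``component`` column instead of ``wavelength_nm``.
ROI masks are single-page 8-bit labelled TIFFs (0 = background) with a JSON
file mapping label integers to ROI names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class MultispectralSeries:
    """Frame-indexed multispectral image stack.

    ``data`` is indexed ``(frame, wavelength, row, col)``; ``wavelengths``
    (nm) matches axis 1 and ``times`` (s, strictly increasing) axis 0.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4-D (frame, wavelength, row, col)")
        if self.data.shape[1] != self.wavelengths.size:
            raise ValueError("wavelength axis length does not match metadata")
        if self.data.shape[0] != self.times.size:
            raise ValueError("frame axis length does not match timestamps")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def band(self, wavelength_nm: float) -> np.ndarray:
        """Image series at one wavelength, shape (frame, row, col)."""
        idx = np.nonzero(np.isclose(self.wavelengths, wavelength_nm))[0]
        if idx.size == 0:
            raise KeyError(
                f"wavelength {wavelength_nm:g} nm not in stack "
                f"(have {self.wavelengths.tolist()})"
            )
        return self.data[:, idx[0]]


@dataclass
class ComponentMap:
    """Per-pixel chromophore amplitudes, indexed (frame, component, row, col)."""

    data: np.ndarray
    components: tuple[str, ...]
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("component map must be 4-D (frame, component, row, col)")
        if self.data.shape[1] != len(self.components):
            raise ValueError("component axis length does not match names")
        if self.data.shape[0] != self.times.size:
            raise ValueError("frame axis length does not match timestamps")

    def component(self, name: str) -> np.ndarray:
        try:
            i = self.components.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}; have {list(self.components)}") from None
        return self.data[:, i]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".csv")


def write_stack(path, series: MultispectralSeries) -> Path:
    """Write a stack as multi-frame TIFF plus CSV sidecar; returns sidecar path."""
    path = Path(path)
    t, w, r, c = series.data.shape
    pages = series.data.reshape(t * w, r, c).astype(np.float32)
    tifffile.imwrite(path, pages)
    rows = {
        "frame_index": np.repeat(np.arange(t), w),
        "wavelength_nm": np.tile(series.wavelengths, t),
        "time_s": np.repeat(series.times, w),
    }
    sidecar = _sidecar_path(path)
    pd.DataFrame(rows).to_csv(sidecar, index=False)
    return sidecar


def read_stack(path, sidecar=None) -> MultispectralSeries:
    """Read a multi-frame TIFF stack with its CSV sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta = pd.read_csv(sidecar)
    frames = meta["frame_index"].to_numpy()
    n_frames = int(frames.max()) + 1
    wavelengths = meta.loc[meta["frame_index"] == 0, "wavelength_nm"].to_numpy(dtype=float)
    times = meta.drop_duplicates("frame_index").sort_values("frame_index")["time_s"].to_numpy(dtype=float)
    n_wl = wavelengths.size
    data = np.asarray(pages).reshape(n_frames, n_wl, pages.shape[-2], pages.shape[-1])
    return MultispectralSeries(data=data, wavelengths=wavelengths, times=times)


def write_component_map(path, cmap: ComponentMap) -> Path:
    path = Path(path)
    t, k, r, c = cmap.data.shape
    tifffile.imwrite(path, cmap.data.reshape(t * k, r, c).astype(np.float32))
    rows = {
        "frame_index": np.repeat(np.arange(t), k),
        "component": np.tile(np.asarray(cmap.components, dtype=object), t),
        "time_s": np.repeat(cmap.times, k),
    }
    sidecar = _sidecar_path(path)
    pd.DataFrame(rows).to_csv(sidecar, index=False)
    return sidecar


def read_component_map(path, sidecar=None) -> ComponentMap:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta = pd.read_csv(sidecar)
    components = tuple(meta.loc[meta["frame_index"] == 0, "component"])
    times = meta.drop_duplicates("frame_index").sort_values("frame_index")["time_s"].to_numpy(dtype=float)
    n_frames = int(meta["frame_index"].max()) + 1
    data = np.asarray(pages).reshape(n_frames, len(components), pages.shape[-2], pages.shape[-1])
    return ComponentMap(data=data, components=components, times=times)


def write_mask(path, mask: np.ndarray, labels: dict[int, str]) -> Path:
    """Write a labelled 8-bit ROI mask plus JSON label map; returns JSON path."""
    path = Path(path)
    mask = np.asarray(mask)
    if mask.max(initial=0) > 255 or mask.min(initial=0) < 0:
        raise ValueError("mask labels must fit in uint8")
    tifffile.imwrite(path, mask.astype(np.uint8))
    jpath = path.with_suffix(".json")
    jpath.write_text(json.dumps({str(k): v for k, v in labels.items()}, indent=0))
    return jpath


def read_mask(path) -> tuple[np.ndarray, dict[int, str]]:
    path = Path(path)
    mask = tifffile.imread(path)
    jpath = path.with_suffix(".json")
    labels = {int(k): v for k, v in json.loads(jpath.read_text()).items()} if jpath.exists() else {}
    return np.asarray(mask), labels
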