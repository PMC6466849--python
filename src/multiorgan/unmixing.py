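"""Spectral unmixing of multispectral stacks.

Two protocols are supported:

* **linear regression** — per pixel and frame, ordinary least squares of
  the observed spectrum against reference component spectra (used for the
  six-wavelength liver/ICG protocol, with ICG, oxy- and deoxyhaemoglobin);
* **difference protocol** — the two-wavelength shortcut used for the
  kidney/IRDye protocol: amplitude = I(775 nm) - I(850 nm), valid because
  IRDye absorbs strongly at 775 nm and barely at 850 nm.

Amplitudes are unconstrained (negative values permitted) with an optional
nonnegativity flag; no spatial regularisation or fluence correction is
applied.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize

from .io import ComponentMap, MultispectralSeries
from .spectra import SpectralLibrary


def _collinear_pairs(design: np.ndarray, components) -> list[tuple[str, str]]:
    pairs = []
    norm = design / np.maximum(np.linalg.norm(design, axis=0), 1e-300)
    gram = norm.T @ norm
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            if abs(gram[i, j]) > 1.0 - 1e-10:
                pairs.append((components[i], components[j]))
    return pairs


def unmix_linear(
    series: MultispectralSeries,
    library: SpectralLibrary,
    components,
    nonnegative: bool = False,
    return_residual: bool = False,
):
    """Least-squares per-pixel unmixing of a stack against reference spectra.

    Returns a :class:`~multiorgan.io.ComponentMap`; with
    ``return_residual=True``, also the per-pixel residual 2-norm, shape
    ``(frame, row, col)``.

    Raises ``ValueError`` when the spectra matrix at the acquisition
    wavelengths is rank-deficient (naming the collinear components) and
    when there are fewer wavelengths than components.
    """
    components = list(components)
    design = library.design_matrix(components, series.wavelengths)
    if design.shape[0] < design.shape[1]:
        raise ValueError(
            f"{design.shape[0]} wavelengths cannot resolve {design.shape[1]} components"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        pairs = _collinear_pairs(design, components)
        detail = "; ".join(f"{a!r} ~ {b!r}" for a, b in pairs) or "degenerate spectra"
        raise ValueError(f"spectra matrix is rank-deficient at these wavelengths: {detail}")

    t, w, r, c = series.data.shape
    obs = series.data.reshape(t, w, r * c)  # (frame, wl, pixel)
    if nonnegative:
        amps = np.empty((t, design.shape[1], r * c))
        for fi in range(t):
            for pi in range(r * c):
                amps[fi, :, pi] = scipy.optimize.nnls(design, obs[fi, :, pi])[0]
    else:
        flat = np.moveaxis(obs, 1, 0).reshape(w, t * r * c)
        sol, *_ = np.linalg.lstsq(design, flat, rcond=None)
        amps = np.moveaxis(sol.reshape(design.shape[1], t, r * c), 1, 0)
    cmap = ComponentMap(
        data=amps.reshape(t, design.shape[1], r, c),
        components=tuple(components),
        times=series.times,
        meta={"mode": "regression", "wavelengths": series.wavelengths.tolist()},
    )
    if return_residual:
        fit = np.einsum("wk,tkp->twp", design, amps)
        resid = np.linalg.norm(obs - fit, axis=1).reshape(t, r, c)
        return cmap, resid
    return cmap


def unmix_difference(
    series: MultispectralSeries, wl_a: float = 775.0, wl_b: float = 850.0, name: str = "irdye800"
) -> ComponentMap:
    """Two-wavelength difference protocol: amplitude = I(wl_a) - I(wl_b).

    Equivalent, up to scale, to linear unmixing with a single pseudo
    component whose spectrum is (1, -1) at (wl_a, wl_b).
    """
    diff = series.band(wl_a) - series.band(wl_b)
    return ComponentMap(
        data=diff[:, None],
        components=(name,),
        times=series.times,
        meta={"mode": "difference", "wavelengths": [wl_a, wl_b]},
    )


def average_frames(series: MultispectralSeries, width: int) -> MultispectralSeries:
    """Boxcar-average consecutive multispectral cycles (respiration smoothing).

    Non-overlapping windows of ``width`` frames are averaged; a trailing
    partial window is dropped.  Timestamps become window means.
    """
    if width < 1:
        raise ValueError("averaging width must be >= 1")
    if width == 1:
        return series
    n = (series.n_frames // width) * width
    if n == 0:
        raise ValueError(f"stack has fewer than {width} frames")
    shape = (n // width, width) + series.data.shape[1:]
    data = series.data[:n].reshape(shape).mean(axis=1)
    times = series.times[:n].reshape(n // width, width).mean(axis=1)
    return MultispectralSeries(
        data=data, wavelengths=series.wavelengths, times=times, meta=dict(series.meta)
    )
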