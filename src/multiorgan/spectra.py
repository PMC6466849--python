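"""Reference absorption spectra of the chromophores resolved by the imaging protocols.

The bundled table holds literature-shaped relative absorption spectra
(each component normalised to unit peak over the tabulated near-infrared
band) for the four absorbers the protocols care about:

``hb``
    deoxyhaemoglobin — strong at 700-760 nm, falling towards 900 nm.
``hbo2``
    oxyhaemoglobin — rising monotonically over 700-900 nm.
``icg``
    indocyanine green bound to plasma proteins — peak near 800 nm with a
    sharp fall beyond 830 nm.
``irdye800``
    IRDye 800 carboxylate — peak near 775 nm, almost transparent at 850 nm
    (the property the two-wavelength difference protocol exploits).

Absolute molar absorptivities are not needed anywhere in the pipeline:
unmixed amplitudes are reported in instrument-arbitrary units and every
downstream statistic is either a ratio or a within-mouse difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np


@dataclass(frozen=True)
class SpectralLibrary:
    """Absorption spectra of named components over named wavelengths.

    Parameters
    ----------
    names : tuple of str
        Component names, one per row of ``matrix``.
    wavelengths : ndarray
        Wavelengths in nm, one per column of ``matrix``. Must be unique.
    matrix : ndarray, shape (n_components, n_wavelengths)
        Relative absorption coefficients (any consistent unit).
    """

    names: tuple[str, ...]
    wavelengths: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.matrix, dtype=float)
        if wl.ndim != 1:
            raise ValueError("wavelengths must be 1-D")
        if len(np.unique(wl)) != wl.size:
            raise ValueError("duplicate wavelengths in spectral library")
        if m.shape != (len(self.names), wl.size):
            raise ValueError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.names)} components x {wl.size} wavelengths"
            )
        if not np.all(np.isfinite(m)):
            raise ValueError("spectral matrix contains non-finite values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "matrix", m)

    def spectrum(self, name: str) -> np.ndarray:
        """Absorption spectrum of one component over all library wavelengths."""
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}; have {list(self.names)}") from None
        return self.matrix[i]

    def design_matrix(self, components, wavelengths) -> np.ndarray:
        """Regression design matrix, shape (n_wavelengths, n_components).

        Raises ``KeyError`` if a requested wavelength is not tabulated.
        """
        wl = np.asarray(wavelengths, dtype=float)
        cols = []
        for w in wl:
            idx = np.nonzero(np.isclose(self.wavelengths, w))[0]
            if idx.size == 0:
                raise KeyError(
                    f"wavelength {w:g} nm not in spectral library "
                    f"(have {self.wavelengths.tolist()})"
                )
            cols.append(idx[0])
        rows = [self.names.index(c) if c in self.names else None for c in components]
        for c, r in zip(components, rows):
            if r is None:
                raise KeyError(f"unknown component {c!r}; have {list(self.names)}")
        return self.matrix[np.ix_(rows, cols)].T


def builtin_library() -> SpectralLibrary:
    """Load the bundled reference spectra (unit-peak relative absorption)."""
    with resources.files("multiorgan.data").joinpath("reference_spectra.csv").open() as fh:
        header = fh.readline().strip().split(",")
        body = np.loadtxt(fh, delimiter=",")
    names = tuple(header[1:])
    return SpectralLibrary(names=names, wavelengths=body[:, 0], matrix=body[:, 1:].T)
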