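"""Optical constants and geometry for continuous-wave two-wavelength NIRS.

The conversion between optical density and chromophore concentration uses the
modified Beer-Lambert law (MBLL)::

    OD(lambda, t) = [eps(lambda, HbO) * dHbO(t) + eps(lambda, HbR) * dHbR(t)] * d * DPF

where ``eps`` are molar extinction coefficients (1/(M*cm)), ``d`` the
source-detector separation in cm, and ``DPF`` the dimensionless differential
pathlength factor.  With measurements at two wavelengths the 2x2 system is
inverted per time point to yield concentration changes in umol/L.

Unit convention (handled in exactly one place, :meth:`OpticalGeometry.mbll_matrix`):
extinction in 1/(M*cm), separation in cm, concentrations in umol/L, so the
effective matrix carries a 1e-6 factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EXTINCTION_1_M_CM", "OpticalGeometry", "DEFAULT_GEOMETRY"]

# Molar extinction coefficients of hemoglobin, 1/(M*cm), at the emitter peak
# wavelengths.  Values from the standard compiled tabulation of hemoglobin
# spectra (S. Prahl, Oregon Medical Laser Center, omlc.org), rows = wavelength
# (nm), columns = chromophore.
EXTINCTION_1_M_CM: dict[int, dict[str, float]] = {
    660: {"hbo": 319.6, "hbr": 3226.56},
    860: {"hbo": 1058.0, "hbr": 694.32},
}


@dataclass(frozen=True)
class OpticalGeometry:
    """Probe geometry and pathlength model for one source-detector pair.

    Parameters
    ----------
    dpf : float
        Differential pathlength factor, dimensionless.  A single fixed value
        is applied at both wavelengths (default 6.06).
    separation_mm : float
        Source-detector separation in millimetres (default 20).
    wavelengths_nm : tuple of int
        Emitter peak wavelengths; must index into ``extinction``.
    extinction : dict
        ``{wavelength: {"hbo": eps, "hbr": eps}}`` in 1/(M*cm).
    """

    dpf: float = 6.06
    separation_mm: float = 20.0
    wavelengths_nm: tuple[int, int] = (660, 860)
    extinction: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in EXTINCTION_1_M_CM.items()}
    )

    def __post_init__(self) -> None:
        if self.dpf <= 0:
            raise ValueError(f"dpf must be positive, got {self.dpf}")
        if self.separation_mm <= 0:
            raise ValueError(f"separation must be positive, got {self.separation_mm}")
        for wl in self.wavelengths_nm:
            if wl not in self.extinction:
                raise ValueError(f"no extinction coefficients for {wl} nm")
        if abs(np.linalg.det(self.mbll_matrix())) < 1e-300:
            raise ValueError("extinction matrix is singular")

    @property
    def pathlength_cm(self) -> float:
        """Effective photon pathlength d * DPF in cm."""
        return self.separation_mm / 10.0 * self.dpf

    def mbll_matrix(self) -> np.ndarray:
        """Effective 2x2 matrix mapping [dHbO; dHbR] in umol/L to [OD_wl1; OD_wl2].

        Rows follow ``wavelengths_nm`` order, columns are (HbO, HbR).
        """
        rows = [
            [self.extinction[wl]["hbo"], self.extinction[wl]["hbr"]]
            for wl in self.wavelengths_nm
        ]
        return np.asarray(rows, dtype=float) * 1e-6 * self.pathlength_cm

    def mbll_inverse(self) -> np.ndarray:
        """Inverse of :meth:`mbll_matrix`; raises with the condition number if singular."""
        m = self.mbll_matrix()
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"extinction matrix is numerically singular (condition number {cond:.3g})"
            )
        return np.linalg.inv(m)


DEFAULT_GEOMETRY = OpticalGeometry()
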